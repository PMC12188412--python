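import numpy as np
import pytest

from scembi import (
    Channel,
    ConcentrationMap,
    MultiplexImage,
    SegmentationMask,
    cell_quantify,
    compare_consecutive_sections,
    kmeans_1d,
    kmeans_region_means,
    pixel_concentration,
)
from scembi.quantification import PT_MOLAR_MASS

from _oracles import brute_force_wcss, dp_optimal_wcss, per_pixel_cell_sums


class TestPixelConcentration:
    def test_hand_calculation_10uM(self):
        """0.975 fg spread over 100 um^2 at 5 um thickness is ~10.0 uM."""
        mass = np.full((10, 10), 0.975 / 100.0)  # 100 px of 1 um^2
        conc = pixel_concentration(mass, pixel_size=1.0, thickness=5.0)
        total_equiv = conc.values.mean()
        assert total_equiv == pytest.approx(9.9957, rel=1e-3)
        assert total_equiv == pytest.approx(10.0, rel=1e-3)

    def test_zero_mass_gives_zero_concentration(self):
        conc = pixel_concentration(np.zeros((4, 4)), 1.0, 5.0)
        assert np.all(conc.values == 0)

    def test_doubling_thickness_halves_concentration(self):
        mass = np.random.default_rng(0).uniform(0, 1, (8, 8))
        c1 = pixel_concentration(mass, 1.0, 5.0).values
        c2 = pixel_concentration(mass, 1.0, 10.0).values
        np.testing.assert_allclose(c2, c1 / 2)

    def test_non_positive_geometry_rejected(self):
        with pytest.raises(ValueError):
            pixel_concentration(np.zeros((2, 2)), 0.0, 5.0)


def _image_like(shape, n_channels=2, seed=0):
    rng = np.random.default_rng(seed)
    return MultiplexImage(
        channels=[Channel(f"ch{i}") for i in range(n_channels)],
        data=rng.poisson(5, size=(n_channels, *shape)).astype(np.uint32),
        pixel_size=1.0,
        thickness=5.0,
    )


class TestCellQuantify:
    def test_four_pixel_cell_sums_to_one_fg(self):
        labels = np.zeros((2, 2), dtype=np.int32)
        labels[:] = 1
        mass = np.array([[0.1, 0.1], [0.2, 0.6]])
        cells = cell_quantify(mass, SegmentationMask(labels=labels), _image_like((2, 2)))
        assert len(cells) == 1
        assert cells.loc[0, "pt_mass_fg"] == pytest.approx(1.0)

    def test_label_swap_swaps_rows_only(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[0, :2] = 1
        labels[3, 2:] = 2
        mass = np.random.default_rng(1).uniform(0, 1, (4, 4))
        img = _image_like((4, 4))
        a = cell_quantify(mass, SegmentationMask(labels=labels), img)
        swapped = labels.copy()
        swapped[labels == 1] = 2
        swapped[labels == 2] = 1
        b = cell_quantify(mass, SegmentationMask(labels=swapped), img)
        assert a.loc[a.cell_id == 1, "pt_mass_fg"].iloc[0] == pytest.approx(
            b.loc[b.cell_id == 2, "pt_mass_fg"].iloc[0]
        )

    def test_matches_brute_force_accumulation(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 12, size=(64, 64)).astype(np.int32)
        mass = rng.uniform(0, 0.1, (64, 64))
        cells = cell_quantify(mass, SegmentationMask(labels=labels), _image_like((64, 64)))
        oracle = per_pixel_cell_sums(mass, labels)
        for _, row in cells.iterrows():
            assert row["pt_mass_fg"] == pytest.approx(oracle[int(row["cell_id"])], rel=1e-12)

    def test_empty_mask_gives_empty_table(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        cells = cell_quantify(np.ones((4, 4)), SegmentationMask(labels=labels), _image_like((4, 4)))
        assert len(cells) == 0

    def test_mass_conservation_and_unit_round_trip(self, tumor, calibration_model):
        from scembi import counts_to_mass

        image, truth = tumor
        mass, _ = counts_to_mass(image.get("Pt"), calibration_model)
        cells = cell_quantify(mass, truth.cell_mask_true, image)
        assert cells["pt_mass_fg"].sum() <= mass.sum() + 1e-9
        recomputed = (
            cells["pt_mass_fg"]
            / (PT_MOLAR_MASS * cells["area_um2"] * image.thickness)
            * 1e6
        )
        np.testing.assert_allclose(recomputed, cells["pt_conc_uM"], rtol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            cell_quantify(
                np.zeros((4, 4)),
                SegmentationMask(labels=np.zeros((5, 5), dtype=np.int32)),
                _image_like((4, 4)),
            )


class TestKmeans1D:
    def test_perfectly_separated_values(self):
        values = np.array([1, 1, 1, 10, 10, 10, 100, 100], dtype=float)
        labels, centers, wcss = kmeans_1d(values, 3)
        np.testing.assert_allclose(centers, [1, 10, 100])
        assert wcss == pytest.approx(0.0, abs=1e-9)

    def test_k1_is_grand_mean(self):
        values = np.random.default_rng(0).uniform(0, 1, 50)
        _, centers, _ = kmeans_1d(values, 1)
        assert centers[0] == pytest.approx(values.mean())

    def test_k_exceeding_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_1d(np.array([1.0, 1.0, 2.0]), 3)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_wcss_attains_dp_optimum(self, k):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            values = rng.uniform(0, 100, 200)
            _, _, wcss = kmeans_1d(values, k)
            assert wcss == pytest.approx(dp_optimal_wcss(values, k), rel=1e-9)

    @pytest.mark.parametrize("k", [2, 3])
    def test_wcss_matches_exhaustive_enumeration_tiny(self, k):
        rng = np.random.default_rng(5)
        for _ in range(5):
            values = rng.normal(size=10)
            _, _, wcss = kmeans_1d(values, k)
            assert wcss == pytest.approx(brute_force_wcss(values, k), rel=1e-9)

    def test_cluster_means_reported_ascending(self):
        values = np.random.default_rng(1).uniform(0, 50, 300)
        conc = ConcentrationMap(values=values.reshape(15, 20), element="Pt", pixel_size=1, thickness=5)
        res = kmeans_region_means(conc, np.ones((15, 20), bool), 4)
        assert np.all(np.diff(res.means_uM) >= 0)
        assert res.pixel_counts.sum() == 300


class TestSectionComparison:
    def test_identical_maps_are_consistent_with_zero_difference(self):
        values = np.random.default_rng(3).gamma(5, 2, (40, 40))
        conc = ConcentrationMap(values=values, element="Pt", pixel_size=1, thickness=5)
        cmp_ = compare_consecutive_sections(conc, conc, k=3)
        np.testing.assert_allclose(cmp_.relative_difference, 0.0, atol=1e-12)
        assert cmp_.verdict == "consistent"

    def test_halved_map_is_inconsistent_at_50pct(self):
        values = np.random.default_rng(3).gamma(5, 2, (40, 40))
        a = ConcentrationMap(values=values, element="Pt", pixel_size=1, thickness=5)
        b = ConcentrationMap(values=values / 2, element="Pt", pixel_size=1, thickness=5)
        cmp_ = compare_consecutive_sections(a, b, k=3)
        np.testing.assert_allclose(cmp_.relative_difference, 0.5, rtol=1e-9)
        assert cmp_.verdict == "inconsistent"
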