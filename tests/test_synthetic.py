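import numpy as np
import pytest

from scembi import GeneratorConfig, generate_droplet_array, generate_tumor_image


class TestConfigValidation:
    def test_unknown_layout_rejected(self):
        with pytest.raises(ValueError, match="layout"):
            GeneratorConfig(region_layout="liver")

    def test_non_positive_image_size_rejected(self):
        with pytest.raises(ValueError, match="image size"):
            GeneratorConfig(image_size=(0, 100))

    def test_negative_droplet_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            GeneratorConfig(droplet_masses=(1.0, -2.0))

    def test_region_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="fractions"):
            GeneratorConfig(
                region_fractions={"parenchyma": 0.5, "stroma": 0.2, "necrosis": 0.2}
            )


class TestDeterminism:
    def test_identical_config_gives_bit_identical_images(self):
        cfg = GeneratorConfig(seed=9, image_size=(200, 200))
        img1, truth1 = generate_tumor_image(cfg)
        img2, truth2 = generate_tumor_image(cfg)
        np.testing.assert_array_equal(img1.data, img2.data)
        np.testing.assert_array_equal(
            truth1.cell_mask_true.labels, truth2.cell_mask_true.labels
        )
        np.testing.assert_array_equal(truth1.cell_pt_true, truth2.cell_pt_true)

    def test_same_seed_gives_identical_droplet_tables(self):
        cfg = GeneratorConfig(seed=4)
        assert generate_droplet_array(cfg) == generate_droplet_array(cfg)

    def test_noise_seed_changes_counts_but_not_truth(self):
        a_img, a_truth = generate_tumor_image(
            GeneratorConfig(seed=9, image_size=(200, 200), noise_seed=1)
        )
        b_img, b_truth = generate_tumor_image(
            GeneratorConfig(seed=9, image_size=(200, 200), noise_seed=2)
        )
        np.testing.assert_array_equal(
            a_truth.pixel_concentration_true, b_truth.pixel_concentration_true
        )
        assert np.any(a_img.get("Pt") != b_img.get("Pt"))


class TestTumorImage:
    def test_channel_panel_is_complete(self, tumor):
        image, _ = tumor
        for name in [
            "Ir", "CD44", "Ecad", "panCK", "vimentin", "aSMA",
            "collagen", "Ki67", "pS6", "pHH3", "Fe", "Pt",
        ]:
            assert name in image.channel_names

    def test_zero_sensitivity_gives_all_zero_pt(self):
        cfg = GeneratorConfig(seed=2, image_size=(150, 150), sensitivity_true=0.0)
        image, _ = generate_tumor_image(cfg)
        assert image.get("Pt").max() == 0

    def test_region_truth_means_match_configured_means(self, tumor):
        """Per-region empirical mean of the true concentration within 5 %."""
        _, truth = tumor
        cfg_means = GeneratorConfig().region_means()
        for name, target in cfg_means.items():
            got = truth.pixel_concentration_true[truth.region_pixels(name)].mean()
            assert got == pytest.approx(target, rel=0.05)

    def test_region_fractions_exact_over_tissue(self, tumor):
        _, truth = tumor
        tissue = truth.region_map > 0
        for name, frac in GeneratorConfig().fractions().items():
            got = truth.region_pixels(name).sum() / tissue.sum()
            assert got == pytest.approx(frac, abs=0.01)

    def test_cell_labels_contiguous_and_nonempty(self, tumor):
        _, truth = tumor
        labels = truth.cell_mask_true.labels
        ids = np.unique(labels[labels > 0])
        assert ids[0] == 1 and ids[-1] == ids.size
        assert np.bincount(labels.ravel())[1:].min() >= 1

    def test_control_cell_content_matches_target_moments(self):
        """Control background: mean ~0.02 fg, SD ~0.03 fg per cell (20 %)."""
        cfg = GeneratorConfig(seed=21, region_layout="control", image_size=(1000, 1000))
        _, truth = generate_tumor_image(cfg)
        assert truth.cell_pt_true.size >= 2000
        assert truth.cell_pt_true.mean() == pytest.approx(0.02, rel=0.20)
        assert truth.cell_pt_true.std() == pytest.approx(0.03, rel=0.20)

    def test_poisson_dispersion_in_constant_patch(self):
        """Index of dispersion within [0.8, 1.2] where true mass is constant."""
        cfg = GeneratorConfig(
            seed=5,
            image_size=(300, 300),
            cell_density=0.0,
            region_layout="resistant",
            pt_microstructure="uniform_region",
            extracellular_gamma_shape=1e9,  # effectively constant level
        )
        image, truth = generate_tumor_image(cfg)
        patch = truth.region_pixels("necrosis")
        counts = image.get("Pt")[patch].astype(float)
        assert counts.size >= 10_000
        assert 0.8 <= counts.var() / counts.mean() <= 1.2


class TestDropletArray:
    def test_noiseless_counts_exactly_linear(self):
        cfg = GeneratorConfig(
            seed=0, droplet_masses=(1, 2, 4, 8), droplet_replicates=1,
            sensitivity_true=100.0, background_rate=0.0,
        )
        counts = [d.counts for d in generate_droplet_array(cfg, noiseless=True)]
        assert counts == [100, 200, 400, 800]

    def test_volume_spread_matches_nominal_sd(self):
        cfg = GeneratorConfig(seed=8, droplet_masses=(1.0,), droplet_replicates=1000)
        vols = np.array([d.volume_measured_pL for d in generate_droplet_array(cfg)])
        assert vols.mean() == pytest.approx(400.0, rel=0.01)
        assert vols.std() == pytest.approx(10.0, rel=0.15)
        assert (vols > 0).all()

    def test_empty_mass_list_rejected(self):
        cfg = GeneratorConfig(droplet_masses=(1.0,))
        object.__setattr__(cfg, "droplet_masses", ())
        with pytest.raises(ValueError, match="non-empty"):
            generate_droplet_array(cfg)
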