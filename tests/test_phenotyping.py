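import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from scembi import (
    DEFAULT_RULES,
    PhenotypeRule,
    PhenotypeRuleTable,
    cluster_phenotypes,
    name_phenotypes,
    pearson_r,
    phenotype_pt_stats,
    transform_features,
)
from scembi.phenotyping import PhenotypeResult

from _oracles import pearson_direct


def _cells_from_matrix(matrix, markers):
    return pd.DataFrame({f"mean_{m}": matrix[:, i] for i, m in enumerate(markers)})


class TestTransformFeatures:
    def test_constant_marker_becomes_zero_column_with_warning(self):
        cells = _cells_from_matrix(
            np.column_stack([np.full(20, 7.0), np.arange(20.0)]), ["a", "b"]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            z, markers = transform_features(cells, markers=["a", "b"])
        assert np.all(z[:, 0] == 0)
        assert np.std(z[:, 1]) == pytest.approx(1.0)

    def test_arcsinh_of_zero_is_zero_before_standardization(self):
        assert np.arcsinh(0.0 / 5.0) == 0.0

    def test_arcsinh_is_invertible_to_raw_counts(self):
        cells = _cells_from_matrix(
            np.random.default_rng(0).uniform(0, 50, (30, 1)), ["a"]
        )
        x = np.arcsinh(cells["mean_a"].to_numpy() / 5.0)
        np.testing.assert_allclose(np.sinh(x) * 5.0, cells["mean_a"], rtol=1e-9)

    def test_nucleus_and_drug_channels_excluded_by_default(self):
        cells = _cells_from_matrix(
            np.random.default_rng(0).uniform(0, 5, (20, 3)), ["Ir", "Pt", "CD44"]
        )
        _, markers = transform_features(cells)
        assert markers == ["CD44"]

    def test_non_positive_cofactor_rejected(self):
        cells = _cells_from_matrix(np.ones((20, 1)), ["a"])
        with pytest.raises(ValueError, match="cofactor"):
            transform_features(cells, cofactor=0.0)


class TestClusterPhenotypes:
    def test_three_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(4)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        labels_true = np.repeat([0, 1, 2], 100)
        x = centers[labels_true] + rng.normal(0, 0.3, (300, 2))
        res = cluster_phenotypes(x, seed=0)
        assert res.n_clusters == 3
        assert adjusted_rand_score(labels_true, res.cell_cluster_ids) == 1.0

    def test_single_gaussian_has_no_separated_structure(self):
        """A structureless cloud yields clusters with poor separation, unlike
        genuine blobs (silhouette < 0.3 vs > 0.8)."""
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(5)
        gauss = rng.normal(size=(300, 2))
        res_g = cluster_phenotypes(gauss, seed=0)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        blobs = centers[np.repeat([0, 1, 2], 100)] + rng.normal(0, 0.3, (300, 2))
        res_b = cluster_phenotypes(blobs, seed=0)
        assert silhouette_score(gauss, res_g.cell_cluster_ids) < 0.3
        assert silhouette_score(blobs, res_b.cell_cluster_ids) > 0.8

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="cells"):
            cluster_phenotypes(np.zeros((10, 2)), k_neighbors=15)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(200, 3))
        a = cluster_phenotypes(x, seed=3).cell_cluster_ids
        b = cluster_phenotypes(x, seed=3).cell_cluster_ids
        np.testing.assert_array_equal(a, b)

    def test_generator_tumor_ari_above_08(self, tumor_cells):
        """Phenotype structure of the default tumor recovered at ARI >= 0.8."""
        features, markers = transform_features(tumor_cells)
        res = cluster_phenotypes(features, seed=1, marker_names=markers)
        ari = adjusted_rand_score(tumor_cells["phenotype_true"], res.cell_cluster_ids)
        assert ari >= 0.8


class TestNamePhenotypes:
    def _result(self, profile, markers):
        return PhenotypeResult(
            cell_cluster_ids=np.zeros(1, dtype=int),
            marker_names=markers,
            profile_matrix=np.asarray(profile, dtype=float),
            params={},
        )

    FULL_PANEL = [
        "CD44", "Ecad", "panCK", "vimentin", "aSMA", "collagen", "Ki67", "pS6", "pHH3", "Fe",
    ]

    def _profile(self, **z):
        return [[z.get(m, 0.0) for m in self.FULL_PANEL]]

    def test_caf_profile_named_caf(self):
        res = self._result(
            self._profile(vimentin=2.0, aSMA=1.8, collagen=1.5, Fe=1.2), self.FULL_PANEL
        )
        assert name_phenotypes(res, DEFAULT_RULES).phenotype_names[0] == "CAF"

    def test_flat_profile_is_unassigned(self):
        res = self._result(self._profile(), self.FULL_PANEL)
        assert name_phenotypes(res, DEFAULT_RULES).phenotype_names[0] == "unassigned"

    def test_rule_priority_resolves_double_match(self):
        markers = ["a", "b"]
        rules = PhenotypeRuleTable(
            rules=(PhenotypeRule("first", high=("a",)), PhenotypeRule("second", high=("b",)))
        )
        res = self._result([[1.0, 1.0]], markers)
        assert name_phenotypes(res, rules).phenotype_names[0] == "first"

    def test_unknown_marker_in_rules_rejected(self):
        rules = PhenotypeRuleTable(rules=(PhenotypeRule("x", high=("nonexistent",)),))
        res = self._result([[1.0]], ["a"])
        with pytest.raises(ValueError, match="unknown marker"):
            name_phenotypes(res, rules)

    def test_relabeling_clusters_does_not_change_names(self):
        caf = self._profile(vimentin=2.0, aSMA=1.8, collagen=1.5, Fe=1.2)[0]
        flat = [0.0] * len(self.FULL_PANEL)
        res = self._result([caf, flat], self.FULL_PANEL)
        res.cell_cluster_ids = np.array([0, 1])
        named = name_phenotypes(res, DEFAULT_RULES)
        flipped = self._result([flat, caf], self.FULL_PANEL)
        flipped.cell_cluster_ids = np.array([1, 0])
        named_f = name_phenotypes(flipped, DEFAULT_RULES)
        assert list(named.cell_phenotypes()) == list(named_f.cell_phenotypes())

    def test_yaml_round_trip(self, tmp_path):
        DEFAULT_RULES.to_yaml(tmp_path / "rules.yaml")
        back = PhenotypeRuleTable.from_yaml(tmp_path / "rules.yaml")
        assert back == DEFAULT_RULES


class TestPhenotypePtStats:
    def test_basic_arithmetic(self):
        cells = pd.DataFrame(
            {"phenotype": ["x"] * 3, "pt_mass_fg": [0.1, 0.3, 0.5], "above_ld": [False, True, True]}
        )
        stats = phenotype_pt_stats(cells)
        row = stats.iloc[0]
        assert row["mean_fg"] == pytest.approx(0.3)
        assert row["max_fg"] == pytest.approx(0.5)
        assert row["frac_above_ld"] == pytest.approx(2 / 3)
        assert sum(int(c) for c in row["histogram"].split(",")) == 3

    def test_empty_table_gives_empty_report(self):
        cells = pd.DataFrame({"phenotype": [], "pt_mass_fg": []})
        assert len(phenotype_pt_stats(cells)) == 0

    def test_phenotype_with_zero_cells_reported_with_n0(self):
        cells = pd.DataFrame({"phenotype": ["x"], "pt_mass_fg": [0.1]})
        stats = phenotype_pt_stats(cells, phenotypes=["x", "y"])
        assert int(stats.set_index("phenotype").loc["y", "n"]) == 0


class TestPearson:
    def test_identical_channels_give_r_one(self):
        x = np.random.default_rng(0).uniform(0, 1, 100)
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_negated_channel_gives_r_minus_one(self):
        x = np.random.default_rng(0).uniform(0, 1, 100)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_three_point_worked_example(self):
        # by hand: cov-sum 5, sum squares 2 and 38/3 -> r = 5/sqrt(76/3)
        assert pearson_r([1, 2, 3], [2, 4, 7]) == pytest.approx(
            5 / np.sqrt(2 * 38 / 3), abs=1e-12
        )

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(9)
        x, y = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
        assert pearson_r(x, y) == pytest.approx(pearson_direct(x, y), abs=1e-12)

    def test_constant_channel_gives_none(self):
        assert pearson_r(np.ones(10), np.arange(10.0)) is None

    def test_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(9)
        x, y = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
        assert pearson_r(3.2 * x + 1.0, y) == pytest.approx(pearson_r(x, y), abs=1e-12)
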