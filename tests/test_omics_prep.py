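"""Feature filtering, CV-based selection, probe aggregation."""

import numpy as np
import pandas as pd
import pytest

from prognomics.datatypes import FeatureMatrix
from prognomics.omics_prep import (
    PriorList,
    ProbeGeneMap,
    aggregate_probes_to_genes,
    coefficient_of_variation,
    filter_low_quality,
    impute_feature_means,
    log_transform,
    select_features,
)


class TestFilterLowQuality:
    def test_strict_boundary_five_percent_kept(self, matrix_factory):
        vals = np.ones((20, 2))
        vals[0, 0] = np.nan  # exactly 5% NA -> kept ("more than" is strict)
        vals[:2, 1] = 0.0    # 10% zeros -> removed
        m = matrix_factory(vals)
        out = filter_low_quality(m, max_bad_frac=0.05)
        assert list(out.feature_ids) == ["F0"]

    def test_counts_match_direct_scan(self, matrix_factory):
        # bad fractions 0, 0.1, 0.3, 0.6 on 10 samples
        vals = np.ones((10, 4))
        vals[:1, 1] = np.nan
        vals[:3, 2] = 0.0
        vals[:6, 3] = np.nan
        out = filter_low_quality(matrix_factory(vals), max_bad_frac=0.2)
        assert list(out.feature_ids) == ["F0", "F1"]

    def test_beta_scale_zero_is_valid(self, matrix_factory):
        vals = np.full((10, 1), 0.5)
        vals[:3, 0] = 0.0  # 30% exact zeros, legitimate beta values
        m = matrix_factory(vals, layer="methylation", scale="beta")
        assert filter_low_quality(m).n_features == 1

    def test_error_when_nothing_survives(self, matrix_factory):
        m = matrix_factory(np.zeros((5, 3)))
        with pytest.raises(ValueError, match="no features survive"):
            filter_low_quality(m)

    def test_pure_column_selection(self, matrix_factory):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(12, 6)) + 5
        vals[:4, 2] = 0.0
        m = matrix_factory(vals)
        out = filter_low_quality(m)
        kept = list(out.feature_ids)
        assert out.values.equals(m.values[kept])


class TestCoefficientOfVariation:
    def test_hand_values(self, matrix_factory):
        m = matrix_factory(np.array([[2.0, 1.0], [2.0, 2.0], [2.0, 3.0]]))
        cv = coefficient_of_variation(m)
        assert cv["F0"] == 0.0
        assert cv["F1"] == pytest.approx(0.5)

    def test_na_entries_skipped(self, matrix_factory):
        m = matrix_factory(np.array([[1.0], [np.nan], [3.0]]))
        assert coefficient_of_variation(m)["F0"] == pytest.approx(np.sqrt(2) / 2)

    def test_zero_mean_is_na(self, matrix_factory):
        m = matrix_factory(np.array([[-1.0], [1.0], [0.0]]))
        assert np.isnan(coefficient_of_variation(m)["F0"])


class TestSelectFeatures:
    def test_top_fraction_union_prior(self, matrix_factory):
        # 8 features with increasing CV; top 25% = ceil(2) = 2 features
        rng = np.random.default_rng(1)
        base = np.abs(rng.normal(size=(30, 8))) * 0.05 + 10
        for j in range(8):
            base[:, j] *= 1 + j * 0.0  # keep means equal
            base[:, j] += rng.normal(0, 0.1 * (j + 1), size=30)
        m = matrix_factory(base)
        cv = coefficient_of_variation(m)
        top2 = set(cv.sort_values(ascending=False).index[:2])
        lowest = cv.sort_values().index[0]
        out = select_features(m, top_frac=0.25, prior=PriorList("expression", {lowest}))
        assert set(out.feature_ids) == top2 | {lowest}
        assert out.n_features == 3

    def test_identity_when_top_frac_one(self, matrix_factory):
        m = matrix_factory(np.random.default_rng(2).normal(size=(10, 6)) + 10)
        out = select_features(m, top_frac=1.0, prior=None)
        assert out.values.equals(m.values)

    def test_brute_force_union_on_graded_cvs(self, matrix_factory):
        """100 features with strictly increasing CV + prior holding the
        lowest-CV feature -> ceil(25) + 1 = 26 selected."""
        rng = np.random.default_rng(3)
        n = 40
        cols = {}
        for j in range(100):
            target_cv = 0.01 * (j + 1)
            x = rng.normal(0, 1, n)
            x = (x - x.mean()) / x.std(ddof=1)
            cols[f"F{j:03d}"] = 10.0 + 10.0 * target_cv * x  # mean 10, sd 10*cv
        m = FeatureMatrix(pd.DataFrame(cols, index=[f"S{i}" for i in range(n)]),
                          "expression", "fpkm")
        cv = coefficient_of_variation(m)
        lowest = cv.sort_values().index[0]
        out = select_features(m, top_frac=0.25, prior=PriorList("expression", {lowest}))
        assert out.n_features == 26
        assert lowest in out.feature_ids

    def test_monotone_in_prior(self, matrix_factory):
        m = matrix_factory(np.random.default_rng(4).normal(size=(20, 10)) + 5)
        small = select_features(m, 0.25, PriorList("expression", {"F0"}))
        large = select_features(m, 0.25, PriorList("expression", {"F0", "F1", "F2"}))
        assert set(small.feature_ids) <= set(large.feature_ids)

    def test_absent_prior_warns_not_errors(self, matrix_factory):
        m = matrix_factory(np.random.default_rng(5).normal(size=(10, 4)) + 5)
        with pytest.warns(UserWarning, match="absent"):
            select_features(m, 0.5, PriorList("expression", {"NOT_A_FEATURE"}))

    def test_feature_order_preserved(self, matrix_factory):
        m = matrix_factory(np.random.default_rng(6).normal(size=(15, 12)) + 5)
        out = select_features(m, 0.5, None)
        positions = [list(m.feature_ids).index(f) for f in out.feature_ids]
        assert positions == sorted(positions)


class TestAggregateProbes:
    def _probe_matrix(self, vals, probes):
        df = pd.DataFrame(vals, index=[f"S{i}" for i in range(vals.shape[0])], columns=probes)
        return FeatureMatrix(df, "methylation", "beta")

    def test_simple_mean(self):
        m = self._probe_matrix(np.array([[0.2, 0.4, 0.6]]), ["p1", "p2", "p3"])
        pmap = ProbeGeneMap(pd.DataFrame(
            {"probe": ["p1", "p2", "p3"], "gene": ["G1"] * 3, "chromosome": ["1"] * 3}))
        out = aggregate_probes_to_genes(m, pmap)
        assert out.values.loc["S0", "G1"] == pytest.approx(0.4)

    def test_sex_chromosome_genes_absent(self):
        m = self._probe_matrix(np.array([[0.2, 0.8]]), ["px", "p1"])
        pmap = ProbeGeneMap(pd.DataFrame(
            {"probe": ["px", "p1"], "gene": ["GX", "G1"], "chromosome": ["X", "2"]}))
        out = aggregate_probes_to_genes(m, pmap)
        assert list(out.feature_ids) == ["G1"]

    def test_na_probe_dropped_then_groupby_mean_matches_oracle(self):
        rng = np.random.default_rng(8)
        n = 20
        vals = rng.uniform(0.1, 0.9, size=(n, 6))
        vals[:2, 3] = np.nan  # 10% NA -> probe dropped
        probes = [f"p{j}" for j in range(6)]
        genes = ["G1", "G1", "G2", "G2", "G3", "G3"]
        m = self._probe_matrix(vals, probes)
        pmap = ProbeGeneMap(pd.DataFrame(
            {"probe": probes, "gene": genes, "chromosome": ["1"] * 6}))
        out = aggregate_probes_to_genes(m, pmap)
        # brute-force: G2 loses p3, so its value is just p2's column
        assert np.allclose(out.values["G1"], vals[:, :2].mean(axis=1))
        assert np.allclose(out.values["G2"], vals[:, 2])
        assert np.allclose(out.values["G3"], vals[:, 4:6].mean(axis=1))

    def test_output_within_probe_range(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 1, size=(15, 8))
        probes = [f"p{j}" for j in range(8)]
        genes = ["G1"] * 5 + ["G2"] * 3
        m = self._probe_matrix(vals, probes)
        pmap = ProbeGeneMap(pd.DataFrame({"probe": probes, "gene": genes, "chromosome": ["3"] * 8}))
        out = aggregate_probes_to_genes(m, pmap)
        assert np.all(out.values["G1"] >= vals[:, :5].min(axis=1))
        assert np.all(out.values["G1"] <= vals[:, :5].max(axis=1))

    def test_error_when_map_covers_nothing(self):
        m = self._probe_matrix(np.array([[0.5]]), ["p1"])
        pmap = ProbeGeneMap(pd.DataFrame({"probe": ["q"], "gene": ["G"], "chromosome": ["1"]}))
        with pytest.raises(ValueError, match="covers none"):
            aggregate_probes_to_genes(m, pmap)


def test_log_transform_and_imputation(matrix_factory):
    vals = np.array([[1.0, np.nan], [3.0, 4.0], [5.0, 6.0]])
    m = matrix_factory(vals)
    assert np.allclose(log_transform(m).values.to_numpy()[0, 0], np.log(2.0))
    beta = matrix_factory(np.full((3, 2), 0.5), layer="methylation", scale="beta")
    assert log_transform(beta) is beta
    filled = impute_feature_means(m)
    assert filled.values.iloc[0, 1] == pytest.approx(5.0)
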