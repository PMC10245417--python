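"""Estimator engine: normalization, PC scoring, the three profiles, NNLS, binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cellwise._utils import CELL_TYPES
from cellwise.estimators import (
    InsufficientMarkersError,
    cpm_log2,
    first_pc_score,
    mgp,
    msp,
    reference_proportions,
    to_ordered_factor,
    wgbs_msp,
)


class TestCpmLog2:
    def test_whole_library_in_one_feature(self):
        counts = pd.DataFrame({"s1": [10]}, index=["f1"])
        assert cpm_log2(counts).iloc[0, 0] == pytest.approx(np.log2(1e6 + 1))

    def test_zero_counts_map_to_zero(self):
        counts = pd.DataFrame({"s1": [0, 100]}, index=["f1", "f2"])
        assert cpm_log2(counts).loc["f1", "s1"] == 0.0

    def test_three_by_two_hand_computation(self):
        counts = pd.DataFrame({"s1": [10, 30, 60], "s2": [5, 5, 0]},
                              index=["f1", "f2", "f3"])
        out = cpm_log2(counts)
        expected = np.log2(np.array([[1e5, 5e5], [3e5, 5e5], [6e5, 0.0]]) + 1)
        np.testing.assert_allclose(out.to_numpy(), expected)

    def test_zero_library_names_sample(self):
        counts = pd.DataFrame({"good": [5], "empty": [0]}, index=["f1"])
        with pytest.raises(ValueError, match="empty"):
            cpm_log2(counts)


class TestFirstPcScore:
    def test_rank_one_matrix_reproduces_single_feature(self, rng):
        base = rng.normal(size=12)
        mat = pd.DataFrame(np.outer([1.0, 2.0, -0.5], base) + 3,
                           index=["f1", "f2", "f3"], columns=[f"s{i}" for i in range(12)])
        score = first_pc_score(mat)
        r = np.corrcoef(score, mat.loc["f1"])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_duplicating_features_preserves_scores(self, rng):
        mat = pd.DataFrame(rng.normal(size=(6, 15)),
                           index=[f"f{i}" for i in range(6)],
                           columns=[f"s{i}" for i in range(15)])
        doubled = pd.concat([mat, mat.set_axis([f"g{i}" for i in range(6)])])
        a, b = first_pc_score(mat), first_pc_score(doubled)
        np.testing.assert_allclose(a.to_numpy() * np.sqrt(2), b.to_numpy(), atol=1e-8)

    def test_matches_dense_eigendecomposition(self, rng):
        mat = pd.DataFrame(rng.normal(size=(10, 20)),
                           index=[f"f{i}" for i in range(10)],
                           columns=[f"s{i}" for i in range(20)])
        score = first_pc_score(mat, scale_features=True)
        # oracle: eigendecomposition of the sample-by-sample Gram matrix of
        # standardized features
        X = mat.to_numpy()
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1)[:, None]
        w, v = np.linalg.eigh(Z.T @ Z)
        oracle = v[:, -1] * np.sqrt(w[-1])
        r = np.corrcoef(score, oracle)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_orientation_follows_mean_marker_signal(self, rng):
        shared = rng.normal(size=20)
        mat = pd.DataFrame(np.outer(np.ones(5), shared) + rng.normal(0, 0.05, size=(5, 20)),
                           index=[f"f{i}" for i in range(5)],
                           columns=[f"s{i}" for i in range(20)])
        score = first_pc_score(mat)
        assert np.corrcoef(score, shared)[0, 1] > 0.99

    def test_insufficient_features_error(self):
        mat = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [0.5]}, index=["only"])
        with pytest.raises(InsufficientMarkersError):
            first_pc_score(mat)

    def test_zero_variance_features_dropped(self, rng):
        mat = pd.DataFrame(rng.normal(size=(4, 10)), index=list("abcd"),
                           columns=[f"s{i}" for i in range(10)])
        mat.loc["a"] = 7.0
        score_with = first_pc_score(mat)
        score_without = first_pc_score(mat.drop(index="a"))
        np.testing.assert_allclose(score_with, score_without, atol=1e-10)


class TestProfiles:
    def test_mgp_endpoints_for_pure_samples(self):
        # three samples spanning neuron fraction 0, 0.5, 1 over two marker genes
        counts = pd.DataFrame(
            {"pure0": [10, 10, 500], "half": [250, 260, 500], "pure1": [520, 500, 500]},
            index=["n1", "n2", "bg"],
        )
        est = mgp(counts, {"neuron": {"n1", "n2"}})
        s = est.scores["neuron"]
        assert s["pure0"] == 0.0 and s["pure1"] == 1.0 and 0 < s["half"] < 1

    def test_sample_permutation_equivariance(self, study50, study50_markers):
        rip = study50["bundle"].rip_counts
        sites = study50_markers["marker_sites"]
        base = msp(rip, sites).scores
        perm = rip.iloc[:, ::-1]
        permuted = msp(perm, sites).scores
        pd.testing.assert_frame_equal(base.loc[permuted.index], permuted)

    def test_profile_columns_span_exactly_unit_interval(self, study50_estimates):
        for name in ("MGP", "MSP", "WGBS_MSP"):
            scores = study50_estimates[name].scores
            np.testing.assert_allclose(scores.min(axis=0), 0.0, atol=1e-12)
            np.testing.assert_allclose(scores.max(axis=0), 1.0, atol=1e-12)

    def test_mgp_recovers_whole_tissue_neuron_fraction(self, study50, study50_estimates):
        truth = study50["comp"].wide("whole")
        scores = study50_estimates["MGP"].scores
        r = np.corrcoef(scores["neuron"], truth.loc[scores.index, "neuron"])[0, 1]
        assert r >= 0.9

    def test_identical_inputs_give_bitwise_identical_scores(self, study50, study50_markers):
        rip = study50["bundle"].rip_counts
        sites = study50_markers["marker_sites"]
        a = msp(rip, sites).scores
        b = msp(rip.copy(), {k: set(v) for k, v in sites.items()}).scores
        pd.testing.assert_frame_equal(a, b)


class TestWgbsMsp:
    def _marks(self, sites, ct="neuron"):
        return pd.DataFrame({"site_id": sites, "cell_type": ct})

    def test_monotone_in_true_neuron_fraction(self):
        frac = np.linspace(0.05, 0.95, 12)
        beta = pd.DataFrame(
            {f"s{i}": f * 0.1 + (1 - f) * np.array([0.9, 0.85, 0.92])
             for i, f in enumerate(frac)},
            index=["m1", "m2", "m3"],
        )
        est = wgbs_msp(beta, self._marks(["m1", "m2", "m3"]))
        s = est.scores["neuron"].to_numpy()
        assert (np.diff(s) > 0).all()

    def test_median_imputation_keeps_sites_with_one_observation(self):
        beta = pd.DataFrame(np.full((3, 6), 0.5), index=["m1", "m2", "m3"],
                            columns=[f"s{i}" for i in range(6)])
        beta += np.linspace(0, 0.3, 6)
        beta.iloc[0, :5] = np.nan
        est = wgbs_msp(beta, self._marks(["m1", "m2", "m3"]))
        assert est.scores["neuron"].notna().all()

    def test_complementing_beta_flips_scores(self, rng):
        beta = pd.DataFrame(rng.uniform(0.1, 0.9, size=(5, 10)),
                            index=[f"m{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(10)])
        marks = self._marks(list(beta.index))
        a = wgbs_msp(beta, marks).scores["neuron"]
        b = wgbs_msp(1.0 - beta, marks).scores["neuron"]
        np.testing.assert_allclose(a, 1.0 - b, atol=1e-10)


class TestReferenceProportions:
    def signature(self, rng, k=5, f=60):
        return pd.DataFrame(rng.lognormal(0, 1, size=(f, k)),
                            index=[f"g{i}" for i in range(f)],
                            columns=list(CELL_TYPES)[:k])

    def test_pure_signature_column_recovered(self, rng):
        sig = self.signature(rng)
        bulk = sig[["neuron"]].rename(columns={"neuron": "s1"})
        est = reference_proportions(bulk, sig)
        assert est.scores.loc["s1", "neuron"] == pytest.approx(1.0, abs=1e-9)

    def test_even_two_way_mix_recovered(self, rng):
        sig = self.signature(rng)
        bulk = pd.DataFrame({"s1": 0.5 * sig["neuron"] + 0.5 * sig["astrocyte"]})
        est = reference_proportions(bulk, sig)
        assert est.scores.loc["s1", "neuron"] == pytest.approx(0.5, abs=1e-9)
        assert est.scores.loc["s1", "astrocyte"] == pytest.approx(0.5, abs=1e-9)

    def test_noiseless_random_mixes_recovered_exactly(self, rng):
        sig = self.signature(rng)
        props = rng.dirichlet(np.ones(5), size=8)
        bulk = pd.DataFrame(sig.to_numpy() @ props.T, index=sig.index,
                            columns=[f"s{i}" for i in range(8)])
        est = reference_proportions(bulk, sig)
        assert np.abs(est.scores.to_numpy() - props).max() < 1e-6

    def test_rows_on_simplex(self, rng):
        sig = self.signature(rng)
        bulk = pd.DataFrame(rng.lognormal(0, 1, size=(60, 4)), index=sig.index,
                            columns=[f"s{i}" for i in range(4)])
        est = reference_proportions(bulk, sig)
        np.testing.assert_allclose(est.scores.sum(axis=1), 1.0, atol=1e-9)
        assert (est.scores.to_numpy() >= 0).all()

    def test_rank_deficient_signature_rejected(self, rng):
        sig = self.signature(rng)
        sig["endothelial"] = sig["neuron"]
        with pytest.raises(ValueError, match="rank"):
            reference_proportions(sig[["neuron"]].rename(columns={"neuron": "s"}), sig)


class TestToOrderedFactor:
    def test_even_split_of_ten_scores(self):
        s = pd.Series(np.arange(10.0))
        assert list(to_ordered_factor(s, 5)) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_all_equal_scores_collapse_to_level_one(self):
        s = pd.Series([3.3] * 7)
        assert set(to_ordered_factor(s, 5)) == {1}

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40),
           st.integers(2, 6))
    def test_monotonicity_property(self, values, n_levels):
        s = pd.Series(values)
        levels = to_ordered_factor(s, n_levels)
        order = np.argsort(s.to_numpy(), kind="stable")
        assert (np.diff(levels.to_numpy()[order]) >= 0).all()
        # equal scores share a level
        for v in set(values):
            assert levels[s == v].nunique() == 1
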