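"""Bias quantification against sorted-cell references and region sets."""

import numpy as np
import pandas as pd
import pytest

from cellwise.bias import (
    classify_by_reference_da,
    direction_vs_annotation,
    effect_size_correlation,
    overlap_with_region_sets,
)


def da_frame(ids, log2fc, fdr):
    return pd.DataFrame({"log2fc": log2fc, "mean_count": 1000.0,
                         "p_value": np.asarray(fdr) / 2, "fdr": fdr},
                        index=pd.Index(ids, name="feature_id"))


class TestClassifyByReference:
    def test_case_equal_to_reference_is_pure_confounding(self, rng):
        ids = [f"p{i}" for i in range(40)]
        lfc = np.where(np.arange(40) < 20, 5.0, -5.0)
        ref = da_frame(ids, lfc, np.full(40, 1e-4))
        case = da_frame(ids, lfc, np.full(40, 1e-4))
        out = classify_by_reference_da(case, ref)
        hypo = out[(out.direction == "hypo_in_case") & (out.region_class == "cell2_up")]
        hyper = out[(out.direction == "hyper_in_case") & (out.region_class == "cell1_up")]
        assert hypo.fraction.iloc[0] == 1.0
        assert hyper.fraction.iloc[0] == 1.0

    def test_independent_case_matches_reference_base_rates(self, rng):
        n = 4000
        ids = [f"p{i}" for i in range(n)]
        ref_lfc = rng.choice([4.0, -4.0, 0.0], size=n, p=[0.3, 0.2, 0.5])
        ref = da_frame(ids, ref_lfc, np.where(ref_lfc == 0, 0.9, 1e-4))
        case = da_frame(ids, rng.choice([1.0, -1.0], size=n), np.full(n, 1e-3))
        out = classify_by_reference_da(case, ref)
        hypo = out[out.direction == "hypo_in_case"].set_index("region_class")
        assert hypo.loc["cell1_up", "fraction"] == pytest.approx(0.3, abs=0.04)
        assert hypo.loc["cell2_up", "fraction"] == pytest.approx(0.2, abs=0.04)

    def test_fractions_sum_to_one_per_direction(self, rng):
        ids = [f"p{i}" for i in range(100)]
        ref = da_frame(ids, rng.normal(0, 4, 100), rng.uniform(size=100))
        case = da_frame(ids, rng.normal(size=100), rng.uniform(size=100))
        out = classify_by_reference_da(case, ref)
        for _, sub in out.groupby("direction"):
            if sub.denominator.iloc[0] > 0:
                assert sub.fraction.sum() == pytest.approx(1.0)

    def test_empty_significant_set_reports_missing(self):
        ids = ["a", "b"]
        ref = da_frame(ids, [4.0, -4.0], [1e-4, 1e-4])
        case = da_frame(ids, [1.0, -1.0], [0.9, 0.9])
        out = classify_by_reference_da(case, ref)
        assert (out.denominator == 0).all()
        assert out.fraction.isna().all()

    def test_require_lfc_filters_weak_reference_calls(self):
        ids = ["a", "b"]
        ref = da_frame(ids, [2.0, 5.0], [1e-4, 1e-4])
        case = da_frame(ids, [-1.0, -1.0], [1e-3, 1e-3])
        out = classify_by_reference_da(case, ref, require_lfc=3.0)
        hypo = out[out.direction == "hypo_in_case"].set_index("region_class")
        assert hypo.loc["cell1_up", "count"] == 1
        assert hypo.loc["unclassified", "count"] == 1


class TestOverlapWithRegionSets:
    def region(self, chrom, start, end):
        return pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})

    def test_unique_overlap_gets_label(self):
        peaks = pd.DataFrame({"peak_id": ["p1"], "chrom": ["chr1"],
                              "start": [100], "end": [200]})
        sets = {"neuron": self.region("chr1", 150, 400),
                "astrocyte": self.region("chr1", 1000, 1100)}
        out = overlap_with_region_sets(peaks, sets)
        assert out["p1"] == "neuron"

    def test_peak_spanning_two_sets_is_ambiguous(self):
        peaks = pd.DataFrame({"peak_id": ["p1"], "chrom": ["chr1"],
                              "start": [100], "end": [1050]})
        sets = {"neuron": self.region("chr1", 150, 400),
                "astrocyte": self.region("chr1", 1000, 1100)}
        assert overlap_with_region_sets(peaks, sets)["p1"] == "ambiguous"

    def test_no_overlap_is_none(self):
        peaks = pd.DataFrame({"peak_id": ["p1"], "chrom": ["chr2"],
                              "start": [100], "end": [200]})
        sets = {"neuron": self.region("chr1", 100, 200)}
        assert overlap_with_region_sets(peaks, sets)["p1"] == "none"

    def test_malformed_interval_rejected_with_line(self):
        peaks = pd.DataFrame({"peak_id": ["p1"], "chrom": ["chr1"],
                              "start": [100], "end": [200]})
        sets = {"neuron": pd.DataFrame({"chrom": ["chr1"], "start": [300], "end": [300]})}
        with pytest.raises(ValueError, match="line 1"):
            overlap_with_region_sets(peaks, sets)

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        for _ in range(10):
            n_p = int(rng.integers(20, 100))
            starts = rng.integers(0, 50_000, size=n_p)
            peaks = pd.DataFrame({"peak_id": [f"p{i}" for i in range(n_p)],
                                  "chrom": rng.choice(["c1", "c2"], size=n_p),
                                  "start": starts,
                                  "end": starts + rng.integers(50, 2_000, size=n_p)})
            sets = {}
            for label in ("neuron", "astrocyte", "microglia"):
                m = int(rng.integers(3, 25))
                s = rng.integers(0, 50_000, size=m)
                sets[label] = pd.DataFrame({"chrom": rng.choice(["c1", "c2"], size=m),
                                            "start": s,
                                            "end": s + rng.integers(50, 2_000, size=m)})
            got = overlap_with_region_sets(peaks, sets)
            for p in peaks.itertuples(index=False):
                hits = {label for label, regions in sets.items()
                        if any(p.chrom == r.chrom and p.start < r.end and r.start < p.end
                               for r in regions.itertuples(index=False))}
                expected = ("none" if not hits else
                            next(iter(hits)) if len(hits) == 1 else "ambiguous")
                assert got[p.peak_id] == expected


class TestEffectSizeCorrelation:
    def test_perfect_anticorrelation(self, rng):
        ids = [f"p{i}" for i in range(30)]
        lfc = rng.normal(size=30)
        out = effect_size_correlation(da_frame(ids, lfc, np.full(30, 0.01)),
                                      da_frame(ids, -lfc, np.full(30, 0.01)))
        assert out["r"] == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self, rng):
        n = 2000
        ids = [f"p{i}" for i in range(n)]
        out = effect_size_correlation(
            da_frame(ids, rng.normal(size=n), np.full(n, 0.5)),
            da_frame(ids, rng.normal(size=n), np.full(n, 0.5)))
        assert abs(out["r"]) < 0.06

    def test_constant_vector_reports_missing(self):
        ids = ["a", "b", "c"]
        out = effect_size_correlation(da_frame(ids, [1, 1, 1], [0.01] * 3),
                                      da_frame(ids, [1, 2, 3], [0.01] * 3))
        assert np.isnan(out["r"])

    def test_significant_subset_uses_case_fdr(self, rng):
        ids = [f"p{i}" for i in range(50)]
        lfc = rng.normal(size=50)
        fdr = np.where(np.arange(50) < 10, 0.01, 0.5)
        out = effect_size_correlation(da_frame(ids, lfc, fdr),
                                      da_frame(ids, -lfc, np.full(50, 0.01)),
                                      subset="significant")
        assert out["n"] == 10


class TestDirectionVsAnnotation:
    def test_all_hypo_neuron_gives_fraction_one(self):
        ids = ["a", "b", "c"]
        case = da_frame(ids, [-1, -1, 1], [0.01, 0.01, 0.5])
        labels = pd.Series({"a": "neuron", "b": "neuron", "c": "astrocyte"})
        out = direction_vs_annotation(case, labels, "neuron")
        hypo = out[out.direction == "hypo_in_case"].iloc[0]
        assert hypo.fraction == 1.0 and hypo.denominator == 2

    def test_eight_peak_hand_case(self):
        ids = list("abcdefgh")
        case = da_frame(ids, [-1, -1, -1, -1, 1, 1, 1, 1], [0.01] * 8)
        labels = pd.Series(dict(zip(ids, ["neuron", "neuron", "astrocyte", "none",
                                          "neuron", "ambiguous", "oligodendrocyte",
                                          "microglia"])))
        out = direction_vs_annotation(case, labels, "neuron").set_index("direction")
        # hypo: labelled = {a,b,c}; neuron = 2/3.  hyper: labelled = {e,g,h}; neuron = 1/3
        assert out.loc["hypo_in_case", "fraction"] == pytest.approx(2 / 3)
        assert out.loc["hyper_in_case", "fraction"] == pytest.approx(1 / 3)

    def test_zero_denominator_missing(self):
        ids = ["a"]
        case = da_frame(ids, [-1], [0.01])
        labels = pd.Series({"a": "none"})
        out = direction_vs_annotation(case, labels, "neuron")
        assert out[out.direction == "hypo_in_case"].fraction.isna().all()


def test_unadjusted_hypo_bias_attenuates_with_true_adjustment(confounded_run):
    """Neuron-region share of hypoacetylated hits shrinks under true adjustment."""
    lad = confounded_run["ladder"]
    panel = confounded_run["panel"]
    bundle = confounded_run["bundle"]
    labels = overlap_with_region_sets(bundle.peaks, panel.region_sets())
    fr = {}
    for model in ("none", "continuous_true"):
        out = direction_vs_annotation(lad[model][0], labels, "neuron").set_index("direction")
        fr[model] = out.loc["hypo_in_case", "fraction"]
    assert fr["none"] > 0.6
    assert not (fr["continuous_true"] > 0.3)  # attenuated or no labelled hits at all
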