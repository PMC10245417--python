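"""Residual cell-composition bias in a differential-analysis output.

When case-control differences in cell composition are not fully adjusted,
the "differential" regions a model reports are dominated by cell-type-specific
signal: regions hypoacetylated in cases are really neuron-enriched regions
lost with neurons, and vice versa.  This module quantifies that bias two
ways: by classifying significant case-control regions against a sorted-cell
(neuron vs glia) differential reference, and by overlapping them with
cell-type-specific promoter/enhancer region sets.  It also correlates
case-control effect sizes with the neuron-vs-glia effect sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "classify_by_reference_da",
    "overlap_with_region_sets",
    "effect_size_correlation",
    "direction_vs_annotation",
]

DIRECTIONS = ("hypo_in_case", "hyper_in_case")


def _split_directions(case_da: pd.DataFrame, fdr_cut: float) -> dict[str, pd.Index]:
    sig = case_da[case_da.fdr < fdr_cut]
    return {
        "hypo_in_case": sig.index[sig.log2fc < 0],
        "hyper_in_case": sig.index[sig.log2fc > 0],
    }


def classify_by_reference_da(
    case_da: pd.DataFrame,
    reference_da: pd.DataFrame,
    fdr_cut: float = 0.05,
    require_lfc: float | None = 3.0,
) -> pd.DataFrame:
    """Classify significant case-control regions against a cell1-vs-cell2 reference.

    ``reference_da`` is a differential result between two sorted cell
    populations with log2fc > 0 meaning cell1-up (e.g. neuron-up when the
    reference is neurons vs glia).  A region counts as cell1_up/cell2_up when
    the reference calls it significant (adjusted p < 0.05 and |log2fc| >
    ``require_lfc`` when given); otherwise it is unclassified.  Fractions are
    relative to all significant case regions in that direction; an empty
    direction reports denominator 0 and missing fractions.
    """
    ref_sig = reference_da.fdr < 0.05
    if require_lfc is not None:
        ref_sig &= reference_da.log2fc.abs() > require_lfc
    ref_class = pd.Series("unclassified", index=reference_da.index)
    ref_class[ref_sig & (reference_da.log2fc > 0)] = "cell1_up"
    ref_class[ref_sig & (reference_da.log2fc < 0)] = "cell2_up"

    rows = []
    for direction, ids in _split_directions(case_da, fdr_cut).items():
        shared = ids.intersection(reference_da.index)
        denom = len(shared)
        for cls in ("cell1_up", "cell2_up", "unclassified"):
            count = int((ref_class.loc[shared] == cls).sum()) if denom else 0
            frac = count / denom if denom else np.nan
            rows.append((direction, cls, count, frac, denom))
    return pd.DataFrame(
        rows, columns=["direction", "region_class", "count", "fraction", "denominator"]
    )


def overlap_with_region_sets(
    peaks: pd.DataFrame,
    region_sets: dict[str, pd.DataFrame],
    min_overlap: int = 1,
) -> pd.Series:
    """Label each peak with the unique cell type whose region set it overlaps.

    ``region_sets`` maps cell-type label -> BED-style intervals (chrom, start,
    end; 0-based half-open).  A peak overlapping >= ``min_overlap`` positions
    of exactly one cell type's set gets that label; several sets ->
    "ambiguous"; no set -> "none".  Multiple hits within one set count once.
    """
    for label, regions in region_sets.items():
        bad = regions.index[regions.end.to_numpy() <= regions.start.to_numpy()]
        if len(bad):
            raise ValueError(
                f"malformed interval in region set {label!r} at line {int(bad[0]) + 1}: end <= start"
            )
    gr_p = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": peaks.chrom,
                "Start": peaks.start,
                "End": peaks.end,
                "peak_id": peaks.peak_id,
            }
        )
    )
    hits: dict[str, set[str]] = {pid: set() for pid in peaks.peak_id}
    for label, regions in region_sets.items():
        gr_r = pr.PyRanges(
            pd.DataFrame(
                {"Chromosome": regions.chrom, "Start": regions.start, "End": regions.end}
            )
        )
        joined = gr_p.join(gr_r).df
        if joined.empty:
            continue
        width = np.minimum(joined.End, joined.End_b) - np.maximum(joined.Start, joined.Start_b)
        for pid in joined.peak_id[width >= min_overlap].unique():
            hits[pid].add(label)
    out = {}
    for pid, labels in hits.items():
        if not labels:
            out[pid] = "none"
        elif len(labels) == 1:
            out[pid] = next(iter(labels))
        else:
            out[pid] = "ambiguous"
    return pd.Series(out, name="region_label").loc[list(peaks.peak_id)]


def effect_size_correlation(
    case_da: pd.DataFrame,
    reference_da: pd.DataFrame,
    subset: str = "all",
    fdr_cut: float = 0.05,
) -> dict[str, float]:
    """Pearson correlation between case-control and reference log2 fold changes.

    ``subset`` is "all" or "significant" (case FDR < ``fdr_cut``).  Returns
    r, n, and quartiles of the case effect sizes in the subset; r is missing
    (nan) when either vector is constant or fewer than 3 peaks are shared.
    """
    shared = case_da.index.intersection(reference_da.index)
    if subset == "significant":
        shared = shared.intersection(case_da.index[case_da.fdr < fdr_cut])
    a = case_da.loc[shared, "log2fc"].to_numpy()
    b = reference_da.loc[shared, "log2fc"].to_numpy()
    if len(shared) < 3 or a.std() == 0 or b.std() == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    q = np.percentile(a, [25, 50, 75]) if len(a) else [np.nan] * 3
    return {"r": r, "n": len(shared), "case_lfc_q25": q[0], "case_lfc_q50": q[1], "case_lfc_q75": q[2]}


def direction_vs_annotation(
    case_da: pd.DataFrame,
    labels: pd.Series,
    focal_type: str,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Fraction of significant regions per direction carrying the focal label.

    The denominator per direction is the number of significant regions with
    any unique cell-type label (not "none"/"ambiguous"); a zero denominator
    reports a missing fraction.
    """
    rows = []
    for direction, ids in _split_directions(case_da, fdr_cut).items():
        ids = ids.intersection(labels.index)
        lab = labels.loc[ids]
        unique = lab[~lab.isin(["none", "ambiguous"])]
        denom = len(unique)
        count = int((unique == focal_type).sum())
        rows.append((direction, focal_type, count, count / denom if denom else np.nan, denom))
    return pd.DataFrame(
        rows, columns=["direction", "region_class", "count", "fraction", "denominator"]
    )
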