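"""Derivation of cell-type-specific marker features.

Acetylation marker sites are derived the way cell-sorted reference data are
used in practice: call differential acetylation between sorted neuronal
(NeuN+) and non-neuronal (NeuN-) populations, keep strong differential
regions, annotate them to genes by promoter-window overlap, and reassign each
region to a specific cell type when every gene it touches is an
expression-defined marker of that one type with a concordant direction of
acetylation.  Methylation marks are filtered on unique assignment and
coverage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pyranges as pr

from .nbglm import fit_nb_wald

logger = logging.getLogger("cellwise")

__all__ = [
    "call_differential",
    "filter_dars",
    "annotate_peaks",
    "assign_marker_sites",
    "filter_methylation_marks",
]


def build_design(
    group: pd.Series, covariates: pd.DataFrame | None
) -> tuple[pd.DataFrame, str, tuple[str, str]]:
    """Design matrix with intercept, expanded covariates and a group indicator.

    The group coefficient codes level 2 vs level 1 (categorical order if the
    factor is categorical, otherwise sorted order).  Categorical covariates
    are expanded to treatment-coded indicators; constant columns are dropped
    with a warning.
    """
    if isinstance(group.dtype, pd.CategoricalDtype):
        levels = [l for l in group.cat.categories if (group == l).any()]
    else:
        levels = sorted(pd.unique(group.dropna()))
    if len(levels) != 2:
        raise ValueError(f"group must have exactly two levels, got {levels}")
    if min((group == l).sum() for l in levels) < 2:
        raise ValueError("need at least 2 samples per group level")
    cols = {"intercept": np.ones(len(group))}
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if pd.api.types.is_numeric_dtype(col):
                expanded = {name: col.to_numpy(dtype=float)}
            else:
                dm = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
                expanded = {c: dm[c].to_numpy() for c in dm.columns}
            for cname, values in expanded.items():
                if np.ptp(values) == 0:
                    logger.warning("dropping constant covariate column %r", cname)
                    continue
                cols[cname] = values
    test_coef = f"group[{levels[1]}]"
    cols[test_coef] = (group == levels[1]).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=group.index)
    return X, test_coef, (str(levels[0]), str(levels[1]))


def call_differential(
    counts: pd.DataFrame,
    group: pd.Series,
    covariates: pd.DataFrame | None = None,
    trend_shrinkage: float = 0.0,
) -> pd.DataFrame:
    """Per-feature NB-GLM Wald test of a two-level group factor.

    Returns a DataFrame indexed by feature_id with log2fc (level 2 vs level 1),
    mean_count, p_value and Benjamini-Hochberg fdr.
    """
    group = group.loc[counts.columns]
    if covariates is not None:
        covariates = covariates.loc[counts.columns]
    X, test_coef, _ = build_design(group, covariates)
    return fit_nb_wald(counts, X, test_coef, trend_shrinkage=trend_shrinkage)


def filter_dars(
    da: pd.DataFrame, fc_fold: float = 4.0, min_mean: float = 1000.0
) -> dict[str, set[str]]:
    """Split strong differential regions by sign.

    Keeps features with |fold change| strictly greater than ``fc_fold`` and
    mean count strictly greater than ``min_mean``; returns ``{"up": ids with
    positive log2fc, "down": ids with negative log2fc}`` (group level 2 vs 1).
    """
    keep = (np.abs(da.log2fc) > np.log2(fc_fold)) & (da.mean_count > min_mean)
    kept = da[keep]
    return {
        "up": set(kept.index[kept.log2fc > 0]),
        "down": set(kept.index[kept.log2fc < 0]),
    }


def gene_windows(genes: pd.DataFrame, upstream: int = 5000, stranded: bool = True) -> pd.DataFrame:
    """Strand-aware promoter windows: TSS - upstream through the 5'UTR end.

    Coordinates are 0-based half-open; on the minus strand the window is
    reflected ([utr5_end, tss + upstream)).  With ``stranded=False`` every
    gene gets the plus-strand layout.  Negative starts are clamped to 0.
    """
    tss = genes.tss.to_numpy()
    utr = genes.utr5_end.to_numpy()
    if stranded:
        minus = genes.strand.to_numpy() == "-"
    else:
        minus = np.zeros(len(genes), dtype=bool)
    start = np.where(minus, utr, tss - upstream)
    end = np.where(minus, tss + upstream, utr)
    if (start < 0).any():
        logger.warning("clamping %d gene windows at coordinate 0", int((start < 0).sum()))
        start = np.maximum(start, 0)
    bad = end <= start
    if bad.any():
        raise ValueError(f"degenerate gene windows for {list(genes.gene_id[bad])}")
    return pd.DataFrame(
        {"gene_id": genes.gene_id, "chrom": genes.chrom, "start": start, "end": end}
    )


def annotate_peaks(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    upstream: int = 5000,
    stranded: bool = True,
) -> pd.DataFrame:
    """Many-to-many peak -> gene map by >= 1 base overlap with promoter windows.

    ``peaks`` needs columns peak_id, chrom, start, end; ``genes`` needs
    gene_id, chrom, strand, tss, utr5_end.  Peaks overlapping no window are
    absent from the result.
    """
    win = gene_windows(genes, upstream=upstream, stranded=stranded)
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
    gr_g = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": win.chrom,
                "Start": win.start,
                "End": win.end,
                "gene_id": win.gene_id,
            }
        )
    )
    joined = gr_p.join(gr_g).df
    if joined.empty:
        return pd.DataFrame(columns=["peak_id", "gene_id"])
    out = joined[["peak_id", "gene_id"]].drop_duplicates()
    return out.sort_values(["peak_id", "gene_id"]).reset_index(drop=True)


def assign_marker_sites(
    dar_ids: dict[str, set[str]],
    peak_gene_map: pd.DataFrame,
    expression_markers: dict[str, set[str]],
    neuron_up: str = "up",
) -> dict[str, set[str]]:
    """Reassign differential acetylated regions to specific cell types.

    A region joins cell type K iff (a) it maps to at least one gene, (b) every
    gene it maps to is a K expression marker, and (c) its sign is concordant:
    the neuronal type requires the ``neuron_up`` sign, non-neuronal types the
    opposite.  Regions touching markers of several cell types, or any
    non-marker gene, are dropped.  The returned sets are mutually exclusive.
    """
    overlap = [
        (a, b)
        for a in expression_markers
        for b in expression_markers
        if a < b and expression_markers[a] & expression_markers[b]
    ]
    if overlap:
        raise ValueError(f"expression marker sets overlap between cell types: {overlap}")
    gene_to_ct = {
        g: ct for ct, gs in expression_markers.items() for g in gs
    }
    glia_sign = "down" if neuron_up == "up" else "up"
    by_peak = peak_gene_map.groupby("peak_id")["gene_id"].agg(set)
    result: dict[str, set[str]] = {ct: set() for ct in expression_markers}
    for sign, ids in dar_ids.items():
        for pid in ids:
            genes = by_peak.get(pid)
            if not genes:
                continue
            cts = {gene_to_ct.get(g) for g in genes}
            if len(cts) != 1 or None in cts:
                continue  # ambiguous across cell types or touches a non-marker gene
            (ct,) = cts
            required = neuron_up if ct == "neuron" else glia_sign
            if sign == required:
                result[ct].add(pid)
    return result


def filter_methylation_marks(
    marks: pd.DataFrame,
    coverage: pd.DataFrame,
    min_cov: int = 10,
    max_low_frac: float = 0.2,
) -> pd.DataFrame:
    """Filter cell-assigned methylation marks.

    ``marks`` has columns site_id, cell_type (a site may appear several times
    if assigned to several cell types).  Drops multi-assigned sites and sites
    whose fraction of samples with coverage < ``min_cov`` strictly exceeds
    ``max_low_frac``.  Returns the retained one-row-per-site table.
    """
    counts = marks.groupby("site_id")["cell_type"].nunique()
    unique_sites = set(counts.index[counts == 1])
    single = marks[marks.site_id.isin(unique_sites)].drop_duplicates()
    present = single[single.site_id.isin(coverage.index)]
    if len(present) < len(single):
        logger.warning(
            "%d marks missing from the coverage matrix were dropped",
            len(single) - len(present),
        )
    cov = coverage.loc[present.site_id]
    low_frac = (cov < min_cov).mean(axis=1)
    keep = low_frac.to_numpy() <= max_low_frac
    return present[keep].reset_index(drop=True)
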