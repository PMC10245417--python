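"""Cell-composition estimators for bulk brain-tissue omics.

Three "profile" estimators share one engine: subset the (normalized) data
matrix to a cell type's marker features, take the samples' scores on the
first principal component, and rescale to [0, 1]:

* MGP (marker gene profile) — expression counts, log2(CPM + 1);
* MSP (marker site profile) — H3K27ac reads-in-peaks, log2(CPM + 1);
* WGBS-MSP — methylation beta at cell-assigned marks, median-imputed,
  reported as 1 minus the rescaled score (marks are hypomethylated in their
  cell type, so raw scores run opposite to abundance).

Profile scores are relative: they order samples by cell-type abundance but
are not proportions.  A constrained (nonnegative, sum-to-one) least-squares
estimator against a reference signature is provided as the absolute-scale
comparator class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger("cellwise")

__all__ = [
    "Estimates",
    "InsufficientMarkersError",
    "cpm_log2",
    "first_pc_score",
    "mgp",
    "msp",
    "wgbs_msp",
    "reference_proportions",
    "to_ordered_factor",
]


class InsufficientMarkersError(ValueError):
    """Fewer than two usable marker features for a requested cell type."""


@dataclass
class Estimates:
    """Samples x cell-types estimate matrix with the producing method's label.

    Profile methods guarantee each column spans exactly [0, 1]; the
    reference-based method returns rows on the probability simplex.
    """

    scores: pd.DataFrame
    method: str

    def column(self, cell_type: str) -> pd.Series:
        return self.scores[cell_type]


def cpm_log2(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million then log2(CPM + 1), column-wise."""
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample {zero.index[0]!r}")
    return np.log2(counts.div(lib, axis=1) * 1e6 + 1.0)


def first_pc_score(matrix: pd.DataFrame, scale_features: bool = True) -> pd.Series:
    """Samples' scores on the first principal component of the feature set.

    Features (rows) are centered across samples, and unit-variance scaled when
    ``scale_features``; zero-variance features are dropped with a log record.
    The score's sign is oriented so that it correlates positively with the
    across-feature mean of the (scaled) signal; an exact zero correlation is
    broken toward a positive sum of first-component loadings.
    """
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    usable = sd > 0
    if (~usable).any():
        logger.info("first_pc_score: dropping %d zero-variance features", int((~usable).sum()))
        X = X[usable]
        sd = sd[usable]
    if X.shape[0] < 2:
        raise InsufficientMarkersError("need at least 2 non-constant features")
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    D = X.T - X.mean(axis=1)  # samples x features, centered
    if scale_features:
        D = D / sd
    U, S, Vt = np.linalg.svd(D, full_matrices=False)
    score = U[:, 0] * S[0]
    summary = D.mean(axis=1)
    c = float(score @ (summary - summary.mean()))
    if c < 0 or (c == 0 and Vt[0].sum() < 0):
        score = -score
    return pd.Series(score, index=matrix.columns, name="pc1_score")


def _rescale_unit(s: pd.Series) -> pd.Series:
    rng = s.max() - s.min()
    if rng == 0:
        raise ValueError("cannot rescale a constant score to [0, 1]")
    return (s - s.min()) / rng


def _profile(
    data: pd.DataFrame,
    marker_sets: dict[str, set[str]],
    method: str,
    flip: bool = False,
    scale_features: bool = True,
) -> Estimates:
    cols = {}
    for ct, ids in marker_sets.items():
        feats = sorted(set(ids) & set(data.index))
        if len(feats) < 2:
            logger.warning("%s: cell type %r omitted (%d markers present)", method, ct, len(feats))
            continue
        score = first_pc_score(data.loc[feats], scale_features=scale_features)
        score = _rescale_unit(score)
        cols[ct] = 1.0 - score if flip else score
    if not cols:
        raise InsufficientMarkersError(f"{method}: no cell type had >= 2 usable markers")
    return Estimates(scores=pd.DataFrame(cols), method=method)


def mgp(expression: pd.DataFrame, markers: dict[str, set[str]]) -> Estimates:
    """Marker gene profiles from an expression count matrix (genes x samples)."""
    return _profile(cpm_log2(expression), markers, "MGP")


def msp(rip_counts: pd.DataFrame, marker_sites: dict[str, set[str]]) -> Estimates:
    """Marker site profiles from H3K27ac reads-in-peaks (peaks x samples)."""
    return _profile(cpm_log2(rip_counts), marker_sites, "MSP")


def wgbs_msp(
    methylation_beta: pd.DataFrame,
    marks: pd.DataFrame,
    methylation_coverage: pd.DataFrame | None = None,
) -> Estimates:
    """Methylation-based profiles at cell-assigned marks.

    ``marks`` has columns site_id, cell_type (one row per retained site; see
    :func:`cellwise.markers.filter_methylation_marks`).  Missing beta values
    are imputed with the site's across-sample median; sites missing in every
    sample are dropped with a log record.  Scores are reported as 1 minus the
    rescaled first-PC score.
    """
    marker_sets = {
        ct: set(sub.site_id) for ct, sub in marks.groupby("cell_type")
    }
    beta = methylation_beta
    all_missing = beta.isna().all(axis=1)
    if all_missing.any():
        logger.warning("wgbs_msp: dropping %d sites missing in all samples", int(all_missing.sum()))
        beta = beta[~all_missing]
    imputed = beta.apply(lambda row: row.fillna(row.median()), axis=1)
    return _profile(imputed, marker_sets, "WGBS_MSP", flip=True)


def reference_proportions(bulk: pd.DataFrame, signature: pd.DataFrame) -> Estimates:
    """Constrained least-squares deconvolution against a reference signature.

    ``bulk`` (features x samples) and ``signature`` (features x cell types)
    must be on the same linear scale.  Per sample, solves nonnegative least
    squares and renormalizes the solution to the simplex.
    """
    feats = bulk.index.intersection(signature.index)
    A = signature.loc[feats].to_numpy(dtype=float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("signature matrix is rank deficient on the shared features")
    B = bulk.loc[feats].to_numpy(dtype=float)
    out = np.empty((bulk.shape[1], A.shape[1]))
    for j in range(B.shape[1]):
        coef, _ = nnls(A, B[:, j])
        total = coef.sum()
        out[j] = coef / total if total > 0 else 1.0 / len(coef)
    return Estimates(
        scores=pd.DataFrame(out, index=bulk.columns, columns=signature.columns),
        method="refprop",
    )


def to_ordered_factor(scores: pd.Series, n_levels: int = 5) -> pd.Series:
    """Quantile-bin scores into ``n_levels`` ordered integer levels (1-based).

    Monotone: score_i <= score_j implies level_i <= level_j; tied scores share
    the lowest level of their tie block, so an all-equal input is all level 1.
    """
    n = len(scores)
    values = scores.to_numpy()
    order = np.argsort(values, kind="stable")
    levels = np.empty(n, dtype=int)
    levels[order] = 1 + (np.arange(n) * n_levels) // n
    out = pd.Series(levels, index=scores.index, name="level")
    return out.groupby(scores.to_numpy()).transform("min")
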