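"""Agreement between estimate sets and principal-structure association.

Covers the three evaluation views used for composition estimates: pairwise
Pearson correlation per cell type across shared samples, correlation-based
hierarchical clustering of all estimate columns (which separates estimators
by the tissue fraction — nuclear vs whole tissue — that their input modality
captures), and regression of a data matrix's leading principal components on
covariates and estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
import statsmodels.api as sm

from .estimators import Estimates

__all__ = [
    "estimate_correlations",
    "correlation_cluster",
    "ClusterResult",
    "pc_covariate_association",
]


def estimate_correlations(
    estimates: list[Estimates], exclude_samples: set[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation per cell type over intersecting samples.

    ``exclude_samples`` are removed before intersecting (e.g. individuals
    measured twice from the same extract, which would inflate agreement).
    Returns a tidy table with method_a, method_b, cell_type, r, n.
    """
    exclude = exclude_samples or set()
    rows = []
    for i, ea in enumerate(estimates):
        for eb in estimates[i + 1 :]:
            shared = [
                s
                for s in ea.scores.index.intersection(eb.scores.index)
                if s not in exclude
            ]
            if len(shared) < 3:
                raise ValueError(
                    f"fewer than 3 shared samples between {ea.method} and {eb.method}"
                )
            for ct in ea.scores.columns.intersection(eb.scores.columns):
                a = ea.scores.loc[shared, ct].to_numpy()
                b = eb.scores.loc[shared, ct].to_numpy()
                r = float(np.corrcoef(a, b)[0, 1])
                rows.append((ea.method, eb.method, ct, r, len(shared)))
    return pd.DataFrame(rows, columns=["method_a", "method_b", "cell_type", "r", "n"])


@dataclass
class ClusterResult:
    linkage: np.ndarray
    columns: list[str]
    correlation: pd.DataFrame

    @property
    def leaf_order(self) -> list[str]:
        return [self.columns[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> dict[str, int]:
        """Cluster label per column at a k-cluster cut."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.columns, (int(l) for l in labels)))


def correlation_cluster(all_estimates: pd.DataFrame) -> ClusterResult:
    """Average-linkage hierarchical clustering of estimate columns.

    Distance is 1 - Pearson r.  Ties in the merge order are resolved by
    scipy's deterministic condensed-distance ordering (lower column index
    first), so the leaf order is reproducible.
    """
    if all_estimates.shape[1] < 3:
        raise ValueError("need at least 3 estimate columns")
    const = all_estimates.columns[all_estimates.std(axis=0, ddof=0) == 0]
    if len(const):
        raise ValueError(f"constant estimate column {const[0]!r}")
    corr = all_estimates.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return ClusterResult(linkage=Z, columns=list(all_estimates.columns), correlation=corr)


def _expand_variables(variables: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Numeric columns pass through; categoricals become treatment indicators."""
    blocks: dict[str, list[str]] = {}
    cols = {}
    for name in variables.columns:
        col = variables[name]
        if pd.api.types.is_numeric_dtype(col):
            cols[name] = col.to_numpy(dtype=float)
            blocks[name] = [name]
        else:
            dm = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            blocks[name] = list(dm.columns)
            for c in dm.columns:
                cols[c] = dm[c].to_numpy()
    return pd.DataFrame(cols, index=variables.index), blocks


def pc_covariate_association(
    data: pd.DataFrame,
    variables: pd.DataFrame,
    n_pcs: int = 5,
    standardize: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Associate the leading PCs of a feature matrix with covariates/estimates.

    PCA is run on the (optionally standardized) features of ``data``
    (features x samples).  For each PC one linear model regresses the PC
    scores on all variables jointly; the returned table holds each variable's
    coefficient p-value (single-coefficient t-test for numeric variables, a
    joint F-test over the indicator block for categoricals).  Collinear
    expanded columns are dropped with a warning column in the output attrs.
    Also returns the per-PC fraction of variance explained.
    """
    samples = data.columns
    variables = variables.loc[samples]
    X = data.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    if standardize:
        sd = X.std(axis=1, ddof=1)
        X = X[sd > 0] / sd[sd > 0, None]
    U, S, _ = np.linalg.svd(X.T, full_matrices=False)
    n_pcs = min(n_pcs, len(S))
    pcs = U[:, :n_pcs] * S[:n_pcs]
    var_explained = pd.Series(
        (S[:n_pcs] ** 2) / (S**2).sum(), index=[f"PC{i + 1}" for i in range(n_pcs)]
    )

    design, blocks = _expand_variables(variables)
    keep: list[str] = []
    dropped: list[str] = []
    base = np.ones((len(samples), 1))
    for c in design.columns:
        cand = np.column_stack([base, design[keep + [c]].to_numpy()])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            keep.append(c)
        else:
            dropped.append(c)
    design = design[keep]
    exog = sm.add_constant(design.to_numpy(dtype=float))
    names = ["const"] + keep

    out = pd.DataFrame(index=list(blocks), columns=var_explained.index, dtype=float)
    for i in range(n_pcs):
        fit = sm.OLS(pcs[:, i], exog).fit()
        for var, cols in blocks.items():
            cols = [c for c in cols if c in keep]
            if not cols:
                out.loc[var, f"PC{i + 1}"] = np.nan
            elif len(cols) == 1:
                out.loc[var, f"PC{i + 1}"] = fit.pvalues[names.index(cols[0])]
            else:
                R = np.zeros((len(cols), exog.shape[1]))
                for r, c in enumerate(cols):
                    R[r, names.index(c)] = 1.0
                out.loc[var, f"PC{i + 1}"] = float(fit.f_test(R).pvalue)
    out.attrs["dropped_columns"] = dropped
    return out, var_explained
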