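"""Case-control differential analysis under competing cell-adjustment models.

A condition-confounded count matrix (e.g. H3K27ac reads-in-peaks from a
disease with severe neuronal loss) can be modelled with:

* no cell adjustment,
* a within-group-shuffled estimate (a negative control that preserves the
  estimate's marginal distribution but destroys its sample linkage),
* a five-level ordered-factor version of one estimate (the historical
  approach), or
* several estimates entered as continuous covariates.

All models share the NB-GLM engine; nuisance covariates such as age bands
enter as ordered factors coded with orthogonal polynomial contrasts.  The
module also provides group tests on the estimates themselves and a stepwise
(AIC, bidirectional) search for cell types independently associated with the
condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimators import to_ordered_factor
from .nbglm import fit_nb_wald

logger = logging.getLogger("cellwise")

__all__ = [
    "ModelSpec",
    "fit_adjusted_da",
    "shuffle_within_group",
    "estimate_group_test",
    "stepwise_cell_association",
    "poly_contrasts",
]


def poly_contrasts(k: int) -> np.ndarray:
    """Orthogonal polynomial contrast matrix for k ordered levels (k x k-1)."""
    x = np.arange(k, dtype=float)
    V = np.vander(x - x.mean(), N=k, increasing=True)
    Q, _ = np.linalg.qr(V)
    C = Q[:, 1:]
    return C / np.linalg.norm(C, axis=0)


def _ordered_factor_columns(codes: pd.Series, prefix: str) -> pd.DataFrame:
    """Polynomial-contrast columns for 1-based ordered level codes."""
    levels = np.sort(codes.unique())
    C = poly_contrasts(len(levels))
    lookup = {lev: C[i] for i, lev in enumerate(levels)}
    mat = np.vstack([lookup[c] for c in codes])
    names = ["linear", "quadratic", "cubic"] + [f"deg{d}" for d in range(4, len(levels))]
    return pd.DataFrame(
        mat, index=codes.index, columns=[f"{prefix}.{names[d]}" for d in range(len(levels) - 1)]
    )


def _expand_nuisance(
    meta: pd.DataFrame, nuisance: list[str], ordered: tuple[str, ...]
) -> pd.DataFrame:
    parts = []
    for name in nuisance:
        col = meta[name]
        if name in ordered or (
            isinstance(col.dtype, pd.CategoricalDtype) and col.cat.ordered
        ):
            levels = np.sort(col.unique())
            codes = pd.Series(
                np.searchsorted(levels, col.to_numpy()) + 1, index=col.index
            )
            parts.append(_ordered_factor_columns(codes, name))
        elif pd.api.types.is_numeric_dtype(col):
            parts.append(col.to_frame(name).astype(float))
        else:
            parts.append(pd.get_dummies(col, prefix=name, drop_first=True, dtype=float))
    if not parts:
        return pd.DataFrame(index=meta.index)
    out = pd.concat(parts, axis=1)
    constant = [c for c in out.columns if out[c].nunique() == 1]
    if constant:
        logger.warning("dropping constant covariate columns: %s", constant)
        out = out.drop(columns=constant)
    return out


@dataclass
class ModelSpec:
    """Specification of one adjusted case-control model.

    ``cell_adjustment`` is one of none / ordered_factor / continuous /
    shuffled; ``cell_estimates`` holds the estimate columns it consumes.
    ordered_factor enters each column as a five-level quantile binning with
    polynomial contrasts; shuffled permutes each column within condition
    groups and enters it as a continuous covariate (the negative control).
    """

    condition: str = "condition"
    nuisance: list[str] = field(default_factory=lambda: ["age_band", "sex"])
    cell_adjustment: str = "none"
    cell_estimates: pd.DataFrame | None = None
    n_levels: int = 5
    shuffle_seed: int = 0
    ordered_nuisance: tuple[str, ...] = ("age_band",)
    baseline: str = "control"

    def label(self) -> str:
        return self.cell_adjustment


def shuffle_within_group(values: pd.Series, group: pd.Series, seed: int = 0) -> pd.Series:
    """Permute values uniformly at random within each group level.

    Deterministic given ``seed``; groups are visited in sorted level order.
    """
    rng = np.random.default_rng(int(seed))
    out = values.copy()
    for level in sorted(pd.unique(group)):
        idx = group.index[group == level]
        out.loc[idx] = values.loc[idx].to_numpy()[rng.permutation(len(idx))]
    return out


def build_da_design(
    sample_meta: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, str]:
    """Realized design matrix for :func:`fit_adjusted_da` plus the tested column."""
    cond = sample_meta[spec.condition]
    levels = sorted(pd.unique(cond))
    if len(levels) != 2:
        raise ValueError(f"condition must be two-level, got {levels}")
    baseline = spec.baseline if spec.baseline in levels else levels[0]
    test_level = [l for l in levels if l != baseline][0]

    parts = [pd.DataFrame({"intercept": 1.0}, index=sample_meta.index)]
    parts.append(_expand_nuisance(sample_meta, spec.nuisance, spec.ordered_nuisance))

    if spec.cell_adjustment != "none":
        if spec.cell_estimates is None:
            raise ValueError(f"cell_adjustment={spec.cell_adjustment!r} needs cell_estimates")
        est = spec.cell_estimates.loc[sample_meta.index]
        if spec.cell_adjustment == "continuous":
            parts.append(est.astype(float))
        elif spec.cell_adjustment == "shuffled":
            # the shuffle is the negative control: a continuous covariate with
            # the estimate's marginal distribution but no within-group linkage
            shuffled = est.apply(
                lambda col: shuffle_within_group(col, cond, seed=spec.shuffle_seed)
            )
            parts.append(shuffled.astype(float).add_suffix("_shuffled"))
        elif spec.cell_adjustment == "ordered_factor":
            for name in est.columns:
                codes = to_ordered_factor(est[name], n_levels=spec.n_levels)
                parts.append(_ordered_factor_columns(codes, f"{name}_of{spec.n_levels}"))
        else:
            raise ValueError(f"unknown cell_adjustment {spec.cell_adjustment!r}")

    test_coef = f"condition[{test_level}]"
    parts.append(
        pd.DataFrame({test_coef: (cond == test_level).astype(float)}, index=sample_meta.index)
    )
    X = pd.concat(parts, axis=1)
    return X, test_coef


def fit_adjusted_da(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    spec: ModelSpec,
    trend_shrinkage: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition test per peak under one adjustment model.

    Returns (DAResult with log2fc for case vs baseline, realized design
    matrix for audit).  Dispersion uses the trend-shrunk method-of-moments
    estimate.
    """
    meta = sample_meta.set_index("sample_id") if "sample_id" in sample_meta else sample_meta
    meta = meta.loc[counts.columns]
    X, test_coef = build_da_design(meta, spec)
    res = fit_nb_wald(counts, X, test_coef, trend_shrinkage=trend_shrinkage)
    return res, X


def estimate_group_test(
    estimate: pd.Series,
    condition: pd.Series,
    nuisance: pd.DataFrame | None = None,
    ordered_nuisance: tuple[str, ...] = ("age_band",),
    baseline: str = "control",
) -> dict[str, float]:
    """Linear-model group difference of one estimate, adjusting for nuisance.

    Returns the condition coefficient (non-baseline vs baseline) with its 95%
    confidence interval and p-value.
    """
    levels = sorted(pd.unique(condition))
    if baseline not in levels:
        baseline = levels[0]
    test_level = [l for l in levels if l != baseline][0]
    parts = [pd.DataFrame({"intercept": 1.0}, index=estimate.index)]
    if nuisance is not None:
        parts.append(_expand_nuisance(nuisance, list(nuisance.columns), ordered_nuisance))
    parts.append(
        pd.DataFrame({"condition": (condition == test_level).astype(float)}, index=estimate.index)
    )
    X = pd.concat(parts, axis=1)
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValueError("singular design in estimate_group_test")
    fit = sm.OLS(estimate.to_numpy(dtype=float), X.to_numpy(dtype=float)).fit()
    j = list(X.columns).index("condition")
    ci = fit.conf_int(alpha=0.05)
    return {
        "effect": float(fit.params[j]),
        "ci_low": float(ci[j][0]),
        "ci_high": float(ci[j][1]),
        "p": float(fit.pvalues[j]),
        "test_level": test_level,
    }


def stepwise_cell_association(
    estimates: pd.DataFrame,
    condition: pd.Series,
    nuisance: pd.DataFrame | None = None,
    ordered_nuisance: tuple[str, ...] = ("age_band",),
    baseline: str = "control",
) -> pd.DataFrame:
    """Bidirectional AIC-stepwise search for condition-associated cell types.

    The condition (coded 0/1 against ``baseline``) is regressed on cell
    estimates plus always-included nuisance covariates; cell-estimate columns
    are added/removed greedily by AIC.  Returns the retained cell types with
    final-model coefficients, signs and p-values (may be empty).
    """
    if estimates.shape[1] < 2:
        raise ValueError("need estimates for at least 2 cell types")
    levels = sorted(pd.unique(condition))
    if baseline not in levels:
        baseline = levels[0]
    y = (condition != baseline).astype(float).to_numpy()
    base = [pd.DataFrame({"intercept": 1.0}, index=estimates.index)]
    if nuisance is not None:
        base.append(_expand_nuisance(nuisance, list(nuisance.columns), ordered_nuisance))
    base_df = pd.concat(base, axis=1)

    def aic_of(selected: list[str]) -> float:
        X = pd.concat([base_df, estimates[selected]], axis=1).to_numpy(dtype=float)
        return float(sm.OLS(y, X).fit().aic)

    selected: list[str] = []
    current = aic_of(selected)
    while True:
        moves = []
        for ct in estimates.columns:
            trial = selected + [ct] if ct not in selected else [c for c in selected if c != ct]
            moves.append((aic_of(trial), trial))
        best_aic, best = min(moves, key=lambda m: m[0])
        if best_aic < current - 1e-9:
            current, selected = best_aic, best
        else:
            break

    if not selected:
        return pd.DataFrame(columns=["cell_type", "coef", "sign", "p"])
    X = pd.concat([base_df, estimates[selected]], axis=1)
    fit = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    names = list(X.columns)
    rows = []
    for ct in selected:
        j = names.index(ct)
        rows.append((ct, float(fit.params[j]), int(np.sign(fit.params[j])), float(fit.pvalues[j])))
    return pd.DataFrame(rows, columns=["cell_type", "coef", "sign", "p"])
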