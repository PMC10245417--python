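"""Synthetic multi-omic bulk brain-tissue studies with known cell composition.

The generator emulates the structure of a two-cohort post-mortem brain study:
each individual contributes two adjacent tissue samples (TS1/TS2) whose cell
compositions are correlated but not identical, whole-tissue modalities
(RNA-seq) carry extra neuron-attributed signal mass from neuropil that nuclear
modalities (H3K27ac reads-in-peaks, WGBS methylation) do not see, and
case-control studies can build in condition-confounded neuronal loss plus a
sprinkling of genuine differential-acetylation effects.

Compositions are Dirichlet draws perturbed on the centered log-ratio scale;
counts are negative binomial around library-size-scaled mixture means;
methylation is a convex combination of cell-type beta profiles with bounded
noise and Poisson coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import CELL_TYPES, check_probability_rows, child_seeds, clr, inv_clr

MODALITIES = ("expression", "methylation", "h3k27ac")

__all__ = [
    "TrueComposition",
    "ReferencePanel",
    "OmicsBundle",
    "SimulationTruth",
    "draw_compositions",
    "make_reference_panel",
    "simulate_study",
    "simulate_sorted_populations",
]


@dataclass
class TrueComposition:
    """Ground-truth per-sample cell-type proportions.

    ``table`` is long-form with columns sample_id, individual_id,
    tissue_sample, condition, cell_type, p_nuclear, p_whole.  p_nuclear is the
    nuclear (cell-count) composition seen by nuclear modalities; p_whole adds a
    per-sample neuropil weight to the neuron coordinate and renormalizes, and
    is the composition seen by whole-tissue modalities.
    """

    table: pd.DataFrame

    def wide(self, kind: str = "nuclear", tissue_sample: str | None = None) -> pd.DataFrame:
        """Samples x cell-types matrix of proportions (``kind`` in {nuclear, whole})."""
        col = {"nuclear": "p_nuclear", "whole": "p_whole"}[kind]
        tab = self.table
        if tissue_sample is not None:
            tab = tab[tab.tissue_sample == tissue_sample]
        w = tab.pivot(index="sample_id", columns="cell_type", values=col)
        return w.loc[:, list(CELL_TYPES)]

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table.sample_id))

    def meta(self) -> pd.DataFrame:
        cols = ["sample_id", "individual_id", "tissue_sample", "condition"]
        return self.table[cols].drop_duplicates().reset_index(drop=True)

    def validate(self) -> None:
        for col in ("p_nuclear", "p_whole"):
            w = self.table.pivot(index="sample_id", columns="cell_type", values=col)
            check_probability_rows(w.to_numpy())


@dataclass
class ReferencePanel:
    """Cell-type reference signals per modality plus the synthetic genome layout.

    signals[modality] is a features x cell-types DataFrame; expression and
    h3k27ac signals are expected counts at unit library size (columns sum to
    1), methylation signals are beta values.  marker[modality] maps feature id
    -> cell type for designed marker features (absent ids are non-markers).
    """

    signals: dict[str, pd.DataFrame]
    marker: dict[str, pd.Series]
    genes: pd.DataFrame  # gene_id, chrom, strand, tss, utr5_end
    peaks: pd.DataFrame  # peak_id, chrom, start, end
    sites: pd.DataFrame  # site_id, chrom, pos
    marker_fold: float = 8.0

    def marker_sets(self, modality: str) -> dict[str, set[str]]:
        m = self.marker[modality]
        return {ct: set(m.index[m == ct]) for ct in CELL_TYPES}

    def region_sets(self, pad: int = 200) -> dict[str, pd.DataFrame]:
        """Cell-type-specific promoter/enhancer-like region sets (BED-style).

        One interval per marker peak, padded; disjoint across cell types by
        construction of the synthetic genome.
        """
        out = {}
        pk = self.peaks.set_index("peak_id")
        for ct, ids in self.marker_sets("h3k27ac").items():
            sub = pk.loc[sorted(ids)]
            out[ct] = pd.DataFrame(
                {
                    "chrom": sub.chrom.to_numpy(),
                    "start": np.maximum(sub.start.to_numpy() - pad, 0),
                    "end": sub.end.to_numpy() + pad,
                    "name": sub.index,
                }
            ).reset_index(drop=True)
        return out

    def validate(self) -> None:
        for mod in ("expression", "h3k27ac"):
            sig = self.signals[mod]
            mk = self.marker[mod]
            for fid, ct in mk.items():
                row = sig.loc[fid]
                others = row.drop(ct).max()
                if not row[ct] >= self.marker_fold * others:
                    raise AssertionError(f"{mod} marker {fid} below {self.marker_fold}-fold")
        beta = self.signals["methylation"]
        mk = self.marker["methylation"]
        for fid, ct in mk.items():
            row = beta.loc[fid]
            if not (row.drop(ct) - row[ct]).abs().min() >= 0.5:
                raise AssertionError(f"methylation mark {fid} differs by < 0.5 beta")


@dataclass
class OmicsBundle:
    """Linked multi-omic matrices sharing one sample axis."""

    expression: pd.DataFrame
    methylation_beta: pd.DataFrame
    methylation_coverage: pd.DataFrame
    rip_counts: pd.DataFrame
    peaks: pd.DataFrame
    sample_meta: pd.DataFrame

    def validate(self) -> None:
        samples = list(self.sample_meta.sample_id)
        for name in ("expression", "rip_counts", "methylation_beta", "methylation_coverage"):
            mat = getattr(self, name)
            if list(mat.columns) != samples:
                raise ValueError(f"{name} columns do not match sample_meta")
        for name in ("expression", "rip_counts", "methylation_coverage"):
            arr = getattr(self, name).to_numpy()
            if arr.min() < 0 or not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(f"{name} must hold nonnegative integers")
        beta_missing = self.methylation_beta.isna().to_numpy()
        cov_zero = self.methylation_coverage.to_numpy() == 0
        if not np.array_equal(beta_missing, cov_zero):
            raise ValueError("beta must be missing exactly where coverage is 0")


@dataclass
class SimulationTruth:
    composition: TrueComposition
    da_truth: pd.DataFrame  # peak_id, is_da, log2fc_effect
    marker_truth: ReferencePanel = field(repr=False)


def draw_compositions(
    n_individuals: int,
    alpha: tuple[float, ...] = (16.0, 8.0, 2.0, 8.0, 2.0),
    adjacency_sd: float = 0.5,
    neuropil_weight: float = 0.8,
    condition_shift: tuple[float, ...] = (0.0,) * 5,
    seed: int = 0,
    *,
    neuropil_cv: float = 0.5,
    case_fraction: float = 0.5,
) -> TrueComposition:
    """Draw ground-truth compositions for TS1 and TS2 of each individual.

    TS1 nuclear proportions are Dirichlet(alpha); for case individuals the
    log of each coordinate is shifted by ``condition_shift`` (log-ratio scale)
    before renormalization.  TS2 perturbs TS1 by additive Gaussian noise of sd
    ``adjacency_sd`` on the centered log-ratio scale.  Whole-tissue proportions
    add a per-sample neuropil weight (mean ``neuropil_weight``, lognormal with
    coefficient of variation ``neuropil_cv``) to the neuron coordinate and
    renormalize; ``neuropil_cv=0`` gives a constant weight.

    Deterministic given ``seed``; the stream order is condition labels, TS1
    Dirichlet draws, TS2 perturbations, neuropil weights.
    """
    alpha = np.asarray(alpha, dtype=float)
    shift = np.asarray(condition_shift, dtype=float)
    if alpha.shape != (len(CELL_TYPES),) or np.any(alpha <= 0):
        raise ValueError("alpha must be strictly positive, one entry per cell type")
    if shift.shape != (len(CELL_TYPES),):
        raise ValueError("condition_shift needs one entry per cell type")
    if adjacency_sd < 0 or neuropil_weight < 0 or neuropil_cv < 0:
        raise ValueError("adjacency_sd, neuropil_weight and neuropil_cv must be nonnegative")

    rng = np.random.default_rng(int(seed))
    n_case = int(round(case_fraction * n_individuals))
    condition = np.array(["case"] * n_case + ["control"] * (n_individuals - n_case))
    rng.shuffle(condition)

    ts1 = rng.dirichlet(alpha, size=n_individuals)
    # guard against numerically exact zeros (extreme alpha) before the
    # log-ratio transforms
    ts1 = np.clip(ts1, 1e-12, None)
    ts1 /= ts1.sum(axis=1, keepdims=True)
    is_case = condition == "case"
    shifted = ts1[is_case] * np.exp(shift)
    ts1[is_case] = shifted / shifted.sum(axis=1, keepdims=True)

    noise = rng.normal(0.0, adjacency_sd, size=ts1.shape)
    ts2 = inv_clr(clr(ts1) + noise)

    n_samples = 2 * n_individuals
    if neuropil_cv > 0:
        sigma = np.sqrt(np.log1p(neuropil_cv**2))
        w = neuropil_weight * rng.lognormal(-sigma**2 / 2.0, sigma, size=n_samples)
    else:
        w = np.full(n_samples, neuropil_weight)

    rows = []
    nuc = np.vstack([ts1, ts2])
    neuron_ix = CELL_TYPES.index("neuron")
    for j, (ind, ts) in enumerate(
        [(i, t) for t in ("TS1", "TS2") for i in range(n_individuals)]
    ):
        p = nuc[j]
        pw = p.copy()
        pw[neuron_ix] += w[j]
        pw = pw / pw.sum()
        sid = f"I{ind + 1:03d}_{ts}"
        for k, ct in enumerate(CELL_TYPES):
            rows.append((sid, f"I{ind + 1:03d}", ts, condition[ind], ct, p[k], pw[k]))
    table = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "individual_id",
            "tissue_sample",
            "condition",
            "cell_type",
            "p_nuclear",
            "p_whole",
        ],
    )
    comp = TrueComposition(table)
    comp.validate()
    return comp


def make_reference_panel(
    n_genes: int = 1500,
    n_peaks: int = 1500,
    n_sites: int = 600,
    markers_per_type: int = 80,
    peak_markers_per_type: int = 150,
    site_marks_per_type: int = 60,
    marker_fold: float = 8.0,
    type_sd: float = 0.15,
    seed: int = 0,
) -> ReferencePanel:
    """Build a coherent cell-type reference panel across the three modalities.

    Marker genes and marker peaks are paired on a synthetic genome (peak i sits
    in the promoter window of gene i), so that acetylation marker sites can be
    re-derived downstream by differential acetylation + gene annotation, the
    way expression-driven marker reassignment works on real data.  Methylation
    marks for cell type K are hypomethylated (beta ~ 0.2) in K and methylated
    (beta ~ 0.8) elsewhere.
    """
    if n_peaks > n_genes:
        raise ValueError("the synthetic genome pairs each peak with a gene; need n_peaks <= n_genes")
    rng = np.random.default_rng(int(seed))
    # markers are designed to be strongly exclusive: the guaranteed fold is a
    # floor, typical folds sit well above it so that marker regions survive
    # dilution in pooled non-neuronal populations
    fold_range = (marker_fold * 3.5, marker_fold * 10.0)

    block = max(markers_per_type, peak_markers_per_type)
    need = block * len(CELL_TYPES)
    if need > n_peaks:
        raise ValueError("too many markers requested for the peak count")
    order = rng.permutation(n_peaks)[:need]

    # paired gene/peak markers: marker rows share the same genome slots, and get
    # a stronger baseline so marker regions are not weak features
    ids_g = [f"gene{i + 1:05d}" for i in range(n_genes)]
    ids_p = [f"peak{i + 1:05d}" for i in range(n_peaks)]
    base = rng.lognormal(0.0, 1.0, size=n_genes)
    base_p = rng.lognormal(0.0, 1.0, size=n_peaks)
    base[order] = rng.lognormal(0.8, 0.4, size=need)
    base_p[order] = rng.lognormal(0.8, 0.4, size=need)
    expr = base[:, None] * rng.lognormal(0.0, type_sd, size=(n_genes, len(CELL_TYPES)))
    acet = base_p[:, None] * rng.lognormal(0.0, type_sd, size=(n_peaks, len(CELL_TYPES)))
    expr /= expr.sum(axis=0)
    acet /= acet.sum(axis=0)

    # boosts applied after normalization so the exclusivity fold holds exactly
    expr_marker = pd.Series(dtype=object)
    peak_marker = pd.Series(dtype=object)
    pos = 0
    for k, ct in enumerate(CELL_TYPES):
        rows = order[pos : pos + block]
        pos += block
        for j, row in enumerate(rows):
            f_e = np.exp(rng.uniform(np.log(fold_range[0]), np.log(fold_range[1])))
            f_p = np.exp(rng.uniform(np.log(fold_range[0]), np.log(fold_range[1])))
            if j < markers_per_type:
                expr[row, k] = np.delete(expr[row], k).max() * f_e
                expr_marker.loc[ids_g[row]] = ct
            if j < peak_markers_per_type:
                acet[row, k] = np.delete(acet[row], k).max() * f_p
                peak_marker.loc[ids_p[row]] = ct

    expr_df = pd.DataFrame(expr, index=ids_g, columns=list(CELL_TYPES))
    acet_df = pd.DataFrame(acet, index=ids_p, columns=list(CELL_TYPES))

    # methylation marks
    ids_s = [f"site{i + 1:05d}" for i in range(n_sites)]
    common = rng.uniform(0.25, 0.75, size=n_sites)
    beta = np.clip(
        common[:, None] + rng.normal(0.0, 0.03, size=(n_sites, len(CELL_TYPES))), 0.01, 0.99
    )
    site_marker = pd.Series(dtype=object)
    s_order = rng.permutation(n_sites)
    pos = 0
    for k, ct in enumerate(CELL_TYPES):
        for row in s_order[pos : pos + site_marks_per_type]:
            lo = rng.uniform(0.05, 0.2)
            beta[row] = lo + rng.uniform(0.55, 0.75)
            beta[row, k] = lo
            site_marker.loc[ids_s[row]] = ct
        pos += site_marks_per_type
    beta_df = pd.DataFrame(np.clip(beta, 0.0, 1.0), index=ids_s, columns=list(CELL_TYPES))

    # synthetic genome: 20 kb slot per gene, alternating strands; peak i in gene i's window
    slot = 20_000
    strands = np.where(np.arange(n_genes) % 2 == 0, "+", "-")
    tss = np.where(strands == "+", np.arange(n_genes) * slot + 6_000, np.arange(n_genes) * slot + 14_000)
    utr5 = np.where(strands == "+", tss + 1_500, tss - 1_500)
    genes = pd.DataFrame(
        {"gene_id": ids_g, "chrom": "chrS1", "strand": strands, "tss": tss, "utr5_end": utr5}
    )
    pk_start = tss[:n_peaks] - 400
    peaks = pd.DataFrame(
        {"peak_id": ids_p, "chrom": "chrS1", "start": pk_start, "end": pk_start + 800}
    )
    sites = pd.DataFrame(
        {"site_id": ids_s, "chrom": "chrS2", "pos": np.arange(n_sites) * 1_000 + 500}
    )

    panel = ReferencePanel(
        signals={"expression": expr_df, "h3k27ac": acet_df, "methylation": beta_df},
        marker={"expression": expr_marker, "h3k27ac": peak_marker, "methylation": site_marker},
        genes=genes,
        peaks=peaks,
        sites=sites,
        marker_fold=marker_fold,
    )
    return panel


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.maximum(mu, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape=r, scale=mu / r))


def simulate_study(
    composition: TrueComposition,
    panel: ReferencePanel,
    lib_sizes: dict[str, np.ndarray] | float | None = None,
    dispersion: float = 0.1,
    coverage_mean: float = 30.0,
    missing_rate: float = 0.05,
    seed: int = 0,
    *,
    da_fraction: float = 0.0,
    da_log2fc: float = 0.5,
    meth_noise_sd: float = 0.04,
) -> tuple[OmicsBundle, SimulationTruth]:
    """Simulate one multi-omic study from ground-truth compositions and a panel.

    Expression counts use whole-tissue proportions, reads-in-peaks and
    methylation use nuclear proportions.  ``da_fraction`` of peaks receive a
    genuine condition effect of magnitude ``da_log2fc`` (random sign) that
    multiplies case-sample means.  Deterministic given ``seed``; independent
    child streams in the order library sizes, metadata, expression, rip,
    da-flags, methylation, coverage.
    """
    meta = composition.meta()
    samples = list(meta.sample_id)
    n = len(samples)
    s_lib, s_meta, s_expr, s_rip, s_da, s_meth, s_cov = child_seeds(seed, 7)

    if lib_sizes is None:
        rng = np.random.default_rng(s_lib)
        lib_sizes = {
            "expression": rng.lognormal(np.log(3e5), 0.2, size=n),
            "h3k27ac": rng.lognormal(np.log(3e5), 0.2, size=n),
        }
    elif np.isscalar(lib_sizes):
        lib_sizes = {
            "expression": np.full(n, float(lib_sizes)),
            "h3k27ac": np.full(n, float(lib_sizes)),
        }
    for mod in ("expression", "h3k27ac"):
        if len(lib_sizes[mod]) != n or np.any(np.asarray(lib_sizes[mod]) <= 0):
            raise ValueError(f"lib_sizes[{mod!r}] must be {n} positive values")

    rng_meta = np.random.default_rng(s_meta)
    individuals = list(dict.fromkeys(meta.individual_id))
    age = dict(zip(individuals, rng_meta.choice([f"A{i}" for i in range(1, 6)], size=len(individuals))))
    sex = dict(zip(individuals, rng_meta.choice(["F", "M"], size=len(individuals))))
    sample_meta = meta.assign(
        age_band=[age[i] for i in meta.individual_id], sex=[sex[i] for i in meta.individual_id]
    )

    p_whole = composition.wide("whole").loc[samples].to_numpy()
    p_nuc = composition.wide("nuclear").loc[samples].to_numpy()

    sig_e = panel.signals["expression"].to_numpy()
    mu_e = (sig_e @ p_whole.T) * np.asarray(lib_sizes["expression"])[None, :]
    expr = _nb_draw(np.random.default_rng(s_expr), mu_e, dispersion)

    sig_p = panel.signals["h3k27ac"].to_numpy()
    mu_p = (sig_p @ p_nuc.T) * np.asarray(lib_sizes["h3k27ac"])[None, :]

    n_peaks = sig_p.shape[0]
    rng_da = np.random.default_rng(s_da)
    is_da = np.zeros(n_peaks, dtype=bool)
    effect = np.zeros(n_peaks)
    if da_fraction > 0:
        n_da = int(round(da_fraction * n_peaks))
        # genuine effects are placed outside designed marker regions so that
        # composition-driven and genuine signal stay separable in the truth
        peak_ids = panel.signals["h3k27ac"].index
        non_marker = np.flatnonzero(~peak_ids.isin(panel.marker["h3k27ac"].index))
        n_da = min(n_da, len(non_marker))
        flagged = rng_da.choice(non_marker, size=n_da, replace=False)
        is_da[flagged] = True
        # heterogeneous genuine effects: |log2fc| lognormal around da_log2fc
        magnitude = rng_da.lognormal(np.log(da_log2fc), 0.6, size=n_da)
        effect[flagged] = magnitude * rng_da.choice([-1.0, 1.0], size=n_da)
    case_cols = (sample_meta.condition == "case").to_numpy()
    mu_p = mu_p * np.where(case_cols[None, :], 2.0 ** effect[:, None], 1.0)
    rip = _nb_draw(np.random.default_rng(s_rip), mu_p, dispersion)

    beta_ref = panel.signals["methylation"].to_numpy()
    rng_meth = np.random.default_rng(s_meth)
    beta = beta_ref @ p_nuc.T + rng_meth.normal(0.0, meth_noise_sd, size=(beta_ref.shape[0], n))
    beta = np.clip(beta, 0.0, 1.0)
    rng_cov = np.random.default_rng(s_cov)
    cov = rng_cov.poisson(coverage_mean, size=beta.shape)
    if missing_rate > 0:
        cov[rng_cov.random(beta.shape) < missing_rate] = 0
    beta = np.where(cov == 0, np.nan, beta)

    bundle = OmicsBundle(
        expression=pd.DataFrame(expr, index=panel.signals["expression"].index, columns=samples),
        methylation_beta=pd.DataFrame(beta, index=panel.signals["methylation"].index, columns=samples),
        methylation_coverage=pd.DataFrame(
            cov, index=panel.signals["methylation"].index, columns=samples
        ),
        rip_counts=pd.DataFrame(rip, index=panel.signals["h3k27ac"].index, columns=samples),
        peaks=panel.peaks.copy(),
        sample_meta=sample_meta,
    )
    truth = SimulationTruth(
        composition=composition,
        da_truth=pd.DataFrame(
            {"peak_id": panel.signals["h3k27ac"].index, "is_da": is_da, "log2fc_effect": effect}
        ),
        marker_truth=panel,
    )
    return bundle, truth


def simulate_sorted_populations(
    panel: ReferencePanel,
    n_per_group: int = 8,
    lib_size: float = 2e6,
    dispersion: float = 0.05,
    comp_noise: float = 300.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate sorted NeuN+ / NeuN- H3K27ac reads-in-peaks reference samples.

    NeuN+ samples are (nearly) pure neurons; NeuN- samples are a glial mixture.
    ``comp_noise`` is the Dirichlet concentration of per-sample jitter around
    those target compositions.  Returns (rip counts, group labels, nuisance
    covariates) suitable for differential acetylation between the populations.
    """
    rng = np.random.default_rng(int(seed))
    target_pos = np.array([0.96, 0.01, 0.01, 0.01, 0.01])
    target_neg = np.array([0.02, 0.245, 0.245, 0.245, 0.245])
    comps = np.vstack(
        [rng.dirichlet(target_pos * comp_noise) for _ in range(n_per_group)]
        + [rng.dirichlet(target_neg * comp_noise) for _ in range(n_per_group)]
    )
    sig = panel.signals["h3k27ac"].to_numpy()
    libs = rng.lognormal(np.log(lib_size), 0.15, size=2 * n_per_group)
    mu = (sig @ comps.T) * libs[None, :]
    counts = _nb_draw(rng, mu, dispersion)
    names = [f"NeuNpos{i + 1}" for i in range(n_per_group)] + [
        f"NeuNneg{i + 1}" for i in range(n_per_group)
    ]
    group = pd.Series(["NeuN+"] * n_per_group + ["NeuN-"] * n_per_group, index=names, name="group")
    covars = pd.DataFrame(
        {"sex": rng.choice(["F", "M"], size=2 * n_per_group)}, index=names
    )
    rip = pd.DataFrame(counts, index=panel.signals["h3k27ac"].index, columns=names)
    return rip, group, covars
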