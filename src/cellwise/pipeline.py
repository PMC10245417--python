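"""End-to-end synthetic-study pipeline.

simulate -> derive markers -> estimate composition -> adjusted differential
analysis under a ladder of cell-adjustment models -> concordance and bias
reports.  Every output is a plain-text table under the run directory and is
listed in a manifest together with the configuration hash and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import concordance as concord_mod
from ._utils import CELL_TYPES, child_seeds
from .differential import ModelSpec, estimate_group_test, fit_adjusted_da, stepwise_cell_association
from .estimators import cpm_log2, mgp, msp, reference_proportions, wgbs_msp
from .io import RunConfig, write_bed, write_matrix, write_methylation
from .markers import (
    annotate_peaks,
    assign_marker_sites,
    call_differential,
    filter_dars,
    filter_methylation_marks,
)
from .synthetic import (
    draw_compositions,
    make_reference_panel,
    simulate_study,
    simulate_sorted_populations,
)

logger = logging.getLogger("cellwise")

LADDER_ORDER = ["none", "shuffled", "ordered_factor", "continuous_msp", "continuous_true"]


def simulate_stage(config: RunConfig):
    """Compositions, panel and bundle from the config (child seeds 0-2)."""
    s_comp, s_panel, s_study, s_sorted = child_seeds(config.seed, 4)
    comp = draw_compositions(
        n_individuals=config.n_individuals,
        alpha=tuple(config.alpha),
        adjacency_sd=config.adjacency_sd,
        neuropil_weight=config.neuropil_weight,
        neuropil_cv=config.neuropil_cv,
        condition_shift=tuple(config.condition_shift),
        seed=s_comp,
    )
    panel = make_reference_panel(
        n_genes=config.n_genes,
        n_peaks=config.n_peaks,
        n_sites=config.n_sites,
        markers_per_type=config.markers_per_type,
        peak_markers_per_type=config.peak_markers_per_type,
        site_marks_per_type=config.site_marks_per_type,
        marker_fold=config.marker_fold,
        seed=s_panel,
    )
    bundle, truth = simulate_study(
        comp,
        panel,
        dispersion=config.dispersion,
        coverage_mean=config.coverage_mean,
        missing_rate=config.missing_rate,
        da_fraction=config.da_fraction,
        da_log2fc=config.da_log2fc,
        seed=s_study,
    )
    return comp, panel, bundle, truth, s_sorted


def markers_stage(config: RunConfig, panel, bundle, sorted_seed: int):
    """Sorted-population DA -> DAR filter -> annotation -> marker-site sets."""
    rip_ref, group, covars = simulate_sorted_populations(panel, seed=sorted_seed)
    group = pd.Series(
        pd.Categorical(group, categories=["NeuN-", "NeuN+"]), index=group.index, name="group"
    )  # level 2 = NeuN+, so log2fc > 0 means neuron-up
    ref_da = call_differential(rip_ref, group, covars)
    dars = filter_dars(ref_da, fc_fold=config.dar_fc_fold, min_mean=config.dar_min_mean)
    peak_gene = annotate_peaks(bundle.peaks, panel.genes)
    expr_markers = panel.marker_sets("expression")
    marker_sites = assign_marker_sites(dars, peak_gene, expr_markers, neuron_up="up")
    marks_df = (
        panel.marker["methylation"].rename("cell_type").rename_axis("site_id").reset_index()
    )
    meth_marks = filter_methylation_marks(marks_df, bundle.methylation_coverage)
    return ref_da, dars, peak_gene, marker_sites, meth_marks


def estimate_stage(config: RunConfig, panel, bundle, marker_sites, meth_marks):
    est_mgp = mgp(bundle.expression, panel.marker_sets("expression"))
    est_msp = msp(bundle.rip_counts, marker_sites)
    est_wgbs = wgbs_msp(bundle.methylation_beta, meth_marks)
    lib = bundle.expression.sum(axis=0)
    cpm_linear = bundle.expression.div(lib, axis=1) * 1e6
    signature = panel.signals["expression"] * 1e6
    est_ref = reference_proportions(cpm_linear, signature)
    return {"MGP": est_mgp, "MSP": est_msp, "WGBS_MSP": est_wgbs, "refprop": est_ref}


def model_ladder(config: RunConfig, bundle, truth, estimates, shuffle_seed: int):
    """Fit the configured adjustment models on TS1 samples; returns DAResults."""
    meta = bundle.sample_meta.set_index("sample_id")
    ts1 = meta.index[meta.tissue_sample == "TS1"]
    counts = bundle.rip_counts[ts1]
    msp_scores = estimates["MSP"].scores
    true_nuc = truth.composition.wide("nuclear").loc[ts1]
    log_true = np.log(true_nuc[["neuron", "astrocyte", "microglia", "oligodendrocyte"]].clip(lower=1e-6))
    log_true = log_true.add_prefix("log_true_")

    # the historical single-estimate adjustment came from methylation of the
    # *neighbouring* tissue sample; emulate it with the adjacent-sample
    # WGBS-derived neuronal score
    adjacent = estimates["WGBS_MSP"].scores["neuron"]
    adjacent_neuron = pd.DataFrame(
        {"adj_neuron": [adjacent[s.replace("_TS1", "_TS2")] for s in ts1]}, index=ts1
    )

    def spec_for(name: str) -> ModelSpec:
        if name == "none":
            return ModelSpec(cell_adjustment="none")
        if name == "shuffled":
            return ModelSpec(
                cell_adjustment="shuffled",
                cell_estimates=adjacent_neuron,
                shuffle_seed=shuffle_seed,
            )
        if name == "ordered_factor":
            return ModelSpec(cell_adjustment="ordered_factor", cell_estimates=adjacent_neuron)
        if name == "continuous_msp":
            cts = [c for c in ("neuron", "microglia", "oligodendrocyte") if c in msp_scores]
            return ModelSpec(cell_adjustment="continuous", cell_estimates=msp_scores.loc[ts1, cts])
        if name == "continuous_true":
            return ModelSpec(cell_adjustment="continuous", cell_estimates=log_true)
        raise ValueError(f"unknown model {name!r}")

    results = {}
    for name in config.models:
        da, design = fit_adjusted_da(counts, meta.loc[ts1].reset_index(), spec_for(name))
        results[name] = (da, design)
    return results


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage and write all tables; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outputs: list[str] = []

    def save(df: pd.DataFrame, name: str, index: bool = True) -> None:
        df.to_csv(out / name, sep="\t", index=index)
        outputs.append(name)

    stage = "simulate"
    try:
        comp, panel, bundle, truth, s_sorted = simulate_stage(config)
        write_matrix(bundle.expression, out / "expression.tsv")
        write_matrix(bundle.rip_counts, out / "rip_counts.tsv")
        write_methylation(bundle.methylation_beta, bundle.methylation_coverage, out / "methylation.tsv")
        peaks_bed = bundle.peaks.rename(columns={"peak_id": "name"})[["chrom", "start", "end", "name"]]
        write_bed(peaks_bed, out / "peaks.bed")
        outputs += ["expression.tsv", "rip_counts.tsv", "methylation.tsv", "peaks.bed"]
        save(bundle.sample_meta, "sample_meta.tsv", index=False)
        save(comp.table, "true_composition.tsv", index=False)
        save(truth.da_truth, "da_truth.tsv", index=False)

        stage = "markers"
        ref_da, dars, peak_gene, marker_sites, meth_marks = markers_stage(
            config, panel, bundle, s_sorted
        )
        save(ref_da, "reference_da.tsv")
        ms_rows = [(ct, pid) for ct, ids in marker_sites.items() for pid in sorted(ids)]
        save(pd.DataFrame(ms_rows, columns=["cell_type", "feature_id"]), "marker_sites.tsv", index=False)
        save(meth_marks, "methylation_marks.tsv", index=False)

        stage = "estimate"
        estimates = estimate_stage(config, panel, bundle, marker_sites, meth_marks)
        for name, est in estimates.items():
            save(est.scores.rename_axis("sample_id"), f"estimates_{name}.tsv")

        stage = "concordance"
        profile = [estimates["MGP"], estimates["MSP"], estimates["WGBS_MSP"]]
        corr = concord_mod.estimate_correlations(profile)
        save(corr, "estimate_correlations.tsv", index=False)
        combined = pd.concat(
            {name: est.scores for name, est in estimates.items()}, axis=1
        )
        combined.columns = [f"{m}.{ct}" for m, ct in combined.columns]
        clus = concord_mod.correlation_cluster(combined)
        save(clus.correlation, "estimate_cluster_correlation.tsv")
        (out / "estimate_cluster_order.txt").write_text("\n".join(clus.leaf_order) + "\n")
        outputs.append("estimate_cluster_order.txt")
        meta_idx = bundle.sample_meta.set_index("sample_id")
        variables = pd.concat(
            [
                estimates["MSP"].scores[["neuron", "oligodendrocyte", "microglia"]].add_prefix("MSP_"),
                meta_idx[["age_band", "sex", "condition"]],
            ],
            axis=1,
        )
        pcs_p, varexp = concord_mod.pc_covariate_association(cpm_log2(bundle.rip_counts), variables)
        save(pcs_p.rename_axis("variable"), "pc_association.tsv")
        save(varexp.rename("variance_explained").rename_axis("PC").to_frame(), "pc_variance.tsv")

        stage = "differential"
        shuffle_seed = child_seeds(config.seed, 6)[5]
        ladder = model_ladder(config, bundle, truth, estimates, shuffle_seed)
        for name, (da, design) in ladder.items():
            save(da, f"da_{name}.tsv")
            save(design, f"design_{name}.tsv")
        meta_ts1 = meta_idx[meta_idx.tissue_sample == "TS1"]
        group_rows = []
        for ct in CELL_TYPES:
            res = estimate_group_test(
                estimates["MSP"].scores.loc[meta_ts1.index, ct],
                meta_ts1.condition,
                meta_ts1[["age_band", "sex"]],
            )
            group_rows.append({"cell_type": ct, **res})
        save(pd.DataFrame(group_rows), "estimate_group_tests.tsv", index=False)
        step = stepwise_cell_association(
            estimates["MSP"].scores.loc[meta_ts1.index],
            meta_ts1.condition,
            meta_ts1[["age_band", "sex"]],
        )
        save(step, "stepwise_selection.tsv", index=False)

        stage = "bias"
        labels = bias_mod.overlap_with_region_sets(bundle.peaks, panel.region_sets())
        save(labels.rename_axis("peak_id").to_frame(), "peak_region_labels.tsv")
        bias_rows, es_rows = [], []
        for name, (da, _) in ladder.items():
            cls = bias_mod.classify_by_reference_da(da, ref_da)
            cls.insert(0, "model", name)
            bias_rows.append(cls)
            dva = bias_mod.direction_vs_annotation(da, labels, "neuron")
            dva.insert(0, "model", name)
            bias_rows.append(dva.assign(region_class="neuron_regions"))
            for subset in ("all", "significant"):
                es = bias_mod.effect_size_correlation(da, ref_da, subset=subset)
                es_rows.append({"model": name, "subset": subset, **es})
        save(pd.concat(bias_rows, ignore_index=True), "bias_summary.tsv", index=False)
        save(pd.DataFrame(es_rows), "effect_size_correlations.tsv", index=False)
    except Exception:
        logger.error("pipeline failed during stage %r", stage)
        raise

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "outputs": sorted(outputs),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    config.to_yaml(out / "config.yaml")
    return out
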