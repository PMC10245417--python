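"""Concordance analyses: adjacent-sample disagreement and the modality split.

Correlates estimates between two assay noise realizations of the same tissue
sample versus between adjacent tissue samples of the same individual, then
clusters estimate columns by correlation to show that nuclear-modality
estimates (MSP, WGBS-MSP) group together apart from whole-tissue MGP, and
regresses the leading principal components of the reads-in-peaks matrix on
composition and covariates.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cellwise._utils import child_seeds
from cellwise.concordance import correlation_cluster, pc_covariate_association
from cellwise.estimators import cpm_log2
from cellwise.io import RunConfig
from cellwise.pipeline import estimate_stage, markers_stage, simulate_stage
from cellwise.synthetic import simulate_study

OUT = Path("results/concordance")


def main() -> None:
    cfg = RunConfig.from_yaml("results/cohort/config.yaml")
    comp, panel, bundle, truth, s_sorted = simulate_stage(cfg)
    _, _, _, marker_sites, meth_marks = markers_stage(cfg, panel, bundle, s_sorted)
    est1 = estimate_stage(cfg, panel, bundle, marker_sites, meth_marks)
    bundle2, _ = simulate_study(comp, panel, dispersion=cfg.dispersion,
                                coverage_mean=cfg.coverage_mean,
                                missing_rate=cfg.missing_rate,
                                seed=child_seeds(cfg.seed, 5)[4])
    est2 = estimate_stage(cfg, panel, bundle2, marker_sites, meth_marks)

    OUT.mkdir(parents=True, exist_ok=True)
    ts1 = [s for s in bundle.sample_meta.sample_id if s.endswith("TS1")]
    ts2 = [s.replace("TS1", "TS2") for s in ts1]
    rows = []
    for method in ("MGP", "MSP", "WGBS_MSP"):
        a, b = est1[method].scores, est2[method].scores
        for ct in a.columns:
            rows.append((method, ct,
                         round(float(np.corrcoef(a.loc[ts1, ct], b.loc[ts1, ct])[0, 1]), 4),
                         round(float(np.corrcoef(a.loc[ts1, ct], b.loc[ts2, ct])[0, 1]), 4)))
    same_adj = pd.DataFrame(rows, columns=["method", "cell_type", "r_same_sample",
                                           "r_adjacent_sample"])
    same_adj.to_csv(OUT / "same_vs_adjacent.tsv", sep="\t", index=False)
    print("same-sample vs adjacent-sample estimate correlation:")
    print(same_adj.groupby("method")[["r_same_sample", "r_adjacent_sample"]].mean().round(3))

    splits = []
    for ct in ("neuron", "astrocyte", "oligodendrocyte"):
        cols = pd.DataFrame({m: est1[m].scores.loc[ts1, ct]
                             for m in ("MGP", "MSP", "WGBS_MSP")})
        cl = correlation_cluster(cols)
        cut = cl.cut(2)
        splits.append({"cell_type": ct, "leaf_order": ">".join(cl.leaf_order),
                       "nuclear_vs_whole_split":
                           cut["MSP"] == cut["WGBS_MSP"] != cut["MGP"]})
    pd.DataFrame(splits).to_csv(OUT / "modality_clustering.tsv", sep="\t", index=False)
    print("\nnuclear/whole-tissue split at k=2:",
          all(s["nuclear_vs_whole_split"] for s in splits))

    meta = bundle.sample_meta.set_index("sample_id")
    variables = pd.concat([
        est1["MSP"].scores[["neuron", "oligodendrocyte", "microglia"]].add_prefix("MSP_"),
        meta[["age_band", "sex"]]], axis=1)
    table, varexp = pc_covariate_association(cpm_log2(bundle.rip_counts), variables)
    table.rename_axis("variable").to_csv(OUT / "pc_association.tsv", sep="\t")
    varexp.rename("variance_explained").to_csv(OUT / "pc_variance.tsv", sep="\t")
    print("\nPC association p-values (leading PCs dominated by composition):")
    print(table.map(lambda p: f"{p:.1e}" if p == p else "-"))


if __name__ == "__main__":
    main()
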