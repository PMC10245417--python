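"""Quantify residual composition bias in each model's differential output.

Classifies FDR-significant case-control peaks against the sorted-cell
neuron-vs-glia reference, overlaps them with cell-type-specific region sets,
and correlates case-control effect sizes with the neuron-vs-glia effect
sizes — the three statistics that show whether an adjustment model actually
removed composition-driven signal.
"""

from pathlib import Path

import pandas as pd

from cellwise._utils import child_seeds
from cellwise.bias import (
    classify_by_reference_da,
    direction_vs_annotation,
    effect_size_correlation,
    overlap_with_region_sets,
)
from cellwise.io import RunConfig
from cellwise.pipeline import estimate_stage, markers_stage, model_ladder, simulate_stage

OUT = Path("results/bias")


def main() -> None:
    cfg = RunConfig.from_yaml("results/casecontrol/config.yaml")
    comp, panel, bundle, truth, s_sorted = simulate_stage(cfg)
    ref_da, _, _, marker_sites, meth_marks = markers_stage(cfg, panel, bundle, s_sorted)
    estimates = estimate_stage(cfg, panel, bundle, marker_sites, meth_marks)
    ladder = model_ladder(cfg, bundle, truth, estimates, child_seeds(cfg.seed, 6)[5])

    OUT.mkdir(parents=True, exist_ok=True)
    labels = overlap_with_region_sets(bundle.peaks, panel.region_sets())
    labels.rename_axis("peak_id").to_frame().to_csv(OUT / "peak_region_labels.tsv", sep="\t")

    cls_rows, ann_rows, es_rows = [], [], []
    for model, (da, _) in ladder.items():
        cls = classify_by_reference_da(da, ref_da)
        cls.insert(0, "model", model)
        cls_rows.append(cls)
        ann = direction_vs_annotation(da, labels, "neuron")
        ann.insert(0, "model", model)
        ann_rows.append(ann)
        for subset in ("all", "significant"):
            es = effect_size_correlation(da, ref_da, subset=subset)
            es_rows.append({"model": model, "subset": subset, **es})
    classification = pd.concat(cls_rows, ignore_index=True)
    classification.to_csv(OUT / "reference_classification.tsv", sep="\t", index=False)
    pd.concat(ann_rows, ignore_index=True).to_csv(
        OUT / "region_annotation_fractions.tsv", sep="\t", index=False)
    es_table = pd.DataFrame(es_rows)
    es_table.to_csv(OUT / "effect_size_correlations.tsv", sep="\t", index=False)

    hypo = classification[(classification.direction == "hypo_in_case")
                          & (classification.region_class == "cell1_up")]
    print("share of significant hypoacetylated-in-case peaks that are neuron-up "
          "reference regions:")
    for _, row in hypo.iterrows():
        pct = f"{row.fraction * 100:.1f}%" if row.fraction == row.fraction else "n/a"
        print(f"  {row.model:16s} {pct:>6s}  (of {row.denominator})")
    print("\neffect-size correlation with the neuron-vs-glia reference (all peaks):")
    for _, row in es_table[es_table.subset == "all"].iterrows():
        print(f"  {row.model:16s} r = {row.r:+.3f}")


if __name__ == "__main__":
    main()
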