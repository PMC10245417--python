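# cellwise

Cell-composition estimation and confounding assessment for brain bulk-tissue
omics — with a ground truth.

Bulk brain samples are mixtures of neurons, astrocytes, microglia,
oligodendrocytes and endothelial cells, and the mixing fractions vary so much
between samples (even directly adjacent dissections of one Brodmann area)
that they can dominate any case-control comparison. Analysts routinely
estimate composition from the omics data itself — marker-gene PC scores from
RNA-seq, marker-site scores from H3K27ac reads-in-peaks, neuron/glia scores
from methylation — and adjust their models with those estimates. Whether the
estimates agree with each other, whether an estimate from a neighbouring
tissue sample is a valid proxy, and whether the adjustment actually removes
composition-driven signal are exactly the questions this package makes
testable: it simulates multi-omic bulk brain studies with *known* per-sample
proportions and runs the full estimation/adjustment machinery against that
truth.

For whom: anyone analysing bulk brain epigenomics or transcriptomics who
adjusts for cell composition, and anyone building or benchmarking
deconvolution methods who needs a structured synthetic testbed.

## The core methods

**Profile estimators.** For cell type *k* with marker feature set *M_k*, the
score of sample *s* is the first principal component of the normalized
marker submatrix, rescaled to [0, 1]:

    MGP_k(s)      = rescale( PC1 of log2(CPM+1) expression over M_k )
    MSP_k(s)      = rescale( PC1 of log2(CPM+1) reads-in-peaks over M_k )
    WGBS_MSP_k(s) = 1 − rescale( PC1 of methylation β over M_k, median-imputed )

MSP marker sites are derived from sorted NeuN+/NeuN− populations: NB-GLM
differential acetylation, |FC| > 4 and mean count > 1000, annotation to
[TSS − 5 kb, 5′UTR end] windows, and reassignment to a cell type when every
annotated gene is that type's expression marker with concordant sign. A
constrained least-squares deconvolution (NNLS + simplex renormalization)
against a reference signature is included as the absolute-scale comparator.

**Differential analysis.** Per-feature NB GLM, log link, library-size
offset: `log μ_gs = x_sᵀ β_g + log N_s`, `Var = μ + φ_g μ²`, with
method-of-moments dispersion and a Wald t-test on the condition coefficient,
Benjamini–Hochberg FDR. Competing cell-adjustment models range from none,
through a within-group-shuffled estimate (negative control) and a five-level
ordered factor of a neighbouring-sample estimate, to continuous (log) true
proportions.

**Bias statistics.** Significant case-control peaks are classified against a
neuron-vs-glia sorted-cell reference (|log2FC| > 3, adjusted p < 0.05) and
against cell-type-unique region sets; effect sizes are correlated with the
neuron-vs-glia effect sizes.

## Worked example

```python
from cellwise import RunConfig, run_pipeline
run_pipeline(RunConfig(seed=1, n_individuals=50), "out/")
```

or, following the analysis scripts (`analysis/01…06`, each writes its tables
under `results/`):

```
$ python analysis/01_simulate_cohort.py
[cohort] 100 samples, 1500 peaks; mean neuron fraction by condition: {'case': 0.429, 'control': 0.428}
[casecontrol] 100 samples, 1500 peaks; mean neuron fraction by condition: {'case': 0.225, 'control': 0.428}

$ python analysis/03_estimate_composition.py
method              MGP     MSP  WGBS_MSP  refprop
cell_type
astrocyte        0.9646  0.9598    0.9958   0.9923
...
worst-case recovery per method: {'MGP': 0.946, 'MSP': 0.939, 'WGBS_MSP': 0.981, 'refprop': 0.985}
```

Every estimator recovers the proportions it is supposed to see (MGP tracks
whole-tissue fractions, MSP/WGBS-MSP nuclear fractions; Pearson r ≥ 0.94
across cell types at default noise). The concordance script then shows the
two structural findings: estimates from two assays of the *same* tissue
sample correlate at ~0.98 while adjacent-sample estimates drop to ~0.56–0.68,
and nuclear-modality estimates (MSP, WGBS-MSP) cluster apart from
whole-tissue MGP. Finally, the confounded case-control re-analysis
(`05`/`06`) prints the model ladder:

```
share of significant hypoacetylated-in-case peaks that are neuron-up reference regions:
  none              83.8%  (of 179)
  shuffled          87.8%  (of 164)
  ordered_factor    76.8%  (of 82)
  continuous_true    0.0%  (of 10)

effect-size correlation with the neuron-vs-glia reference (all peaks):
  none             r = -0.866
  shuffled         r = -0.852
  ordered_factor   r = -0.752
  continuous_true  r = -0.085
```

Read: with no (or sham) adjustment, the "differential" peaks are mostly
neuron-specific regions lost with neurons; a partial adjustment from a
neighbouring sample's estimate attenuates the bias only moderately; adjusting
with the true composition removes it, leaving the genuine effects.

A `cellwise` CLI wraps the same stages
(`cellwise simulate|markers|estimate|concord|diffacetyl|bias|run`), driven by
a YAML config; see `cellwise --help`.

## Layout

    src/cellwise/      library: synthetic, markers, estimators, concordance,
                       differential, bias, nbglm, io, pipeline, cli
    analysis/          numbered narrative drivers over the library
    tests/             pytest suite (unit, property, end-to-end)
    scripts/           acceptance.py
    docs/methods.md    model and methods documentation
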