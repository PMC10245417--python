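# Methods

`cellwise` is an evaluation framework for cell-composition estimation in bulk
brain-tissue omics. It couples (i) a generative model of multi-omic bulk
studies with known per-sample cell proportions to (ii) the estimators and
adjustment models whose behaviour it measures. This note documents the
models, the defaults and why they were chosen, and what passing results do
and do not show.

## Generative model

**Cell types.** Five major brain cell types are modelled throughout: neurons,
astrocytes, microglia, oligodendrocytes, endothelial cells.

**Compositions.** For individual *i*, the nuclear composition of tissue
sample 1 is a Dirichlet draw, `p_i ~ Dir(alpha)`. Case individuals receive a
log-ratio shift: `p_i <- softmax(log p_i + delta)`, with `delta` the
`condition_shift` vector, so a shift of −1.0 on the neuron coordinate halves
the neuron odds (≈40% neuronal loss at the default baseline — the severity
expected of end-stage disease in a heavily affected region). The adjacent
tissue sample TS2 perturbs TS1 on the centered log-ratio scale,
`clr(p') = clr(p) + N(0, adjacency_sd² I)`, which keeps compositions closed
and makes adjacent samples correlated but distinct dissections of the same
block.

**Neuropil.** Whole-tissue modalities see signal from dendrites, axons and
synapses that contributes no nuclei. This is modelled as extra
neuron-attributed mass: `p_whole ∝ p_nuclear + w_s · e_neuron`, with a
*per-sample* weight `w_s` drawn lognormal with mean `neuropil_weight` and
coefficient of variation `neuropil_cv`. The per-sample variation is
essential, not cosmetic: with a constant weight the nuclear→whole map is
affine and whole-tissue and nuclear truths would be perfectly correlated,
which would erase the nuclear/whole-tissue discordance the framework exists
to study. Varying neuropil content across dissections (grey/white matter and
cortical-depth differences) is also the physically plausible reading.

**Reference panel.** Each modality gets per-cell-type mean signals.
Non-marker features carry mostly shared signal (per-type lognormal sd 0.15
around a common base), while designed markers are strongly exclusive: the
marked cell type exceeds the maximum of the others by a fold drawn
log-uniform in [3.5, 10]× the guaranteed floor (default floor 8). Marker
features also get an elevated baseline, reflecting that useful cell-type
marker peaks are strong peaks. Keeping non-marker features nearly
cell-shared concentrates composition information in the markers, which makes
the negative control (random non-marker features) meaningful and keeps
composition-driven and genuine case-control signal separable in the truth.
Marker genes and marker peaks are paired on a synthetic genome (peak *i*
sits in the promoter window of gene *i*, 20 kb slots, alternating strands)
so the acetylation marker-site derivation can be exercised end to end.
Methylation marks for type K have beta ≈ 0.15 in K and ≈ 0.8 elsewhere
(hypomethylation marks the active cell type), with a guaranteed gap ≥ 0.5.

**Observation model.** Expression counts are negative binomial with mean
`lib_size_s × Σ_k p_whole(k, s) × signal(g, k)` and a single dispersion
parameter (default 0.1); reads-in-peaks use `p_nuclear` in the same form.
Genuine condition effects multiply case means for a configurable fraction of
peaks (default in the case-control study: 5%), with |log2FC| drawn lognormal
around 0.5 (sd 0.6 on the log scale) and random sign — genuine epigenetic
effects are modest and heterogeneous next to wholesale composition turnover.
Genuine effects are placed outside designed marker peaks so the truth tables
can distinguish composition-driven from genuine hits. Methylation is the
convex combination `Σ_k p_nuclear(k) β_k(site)` plus truncated Gaussian noise
(sd 0.04), with Poisson coverage (mean 30) and missingness exactly where
coverage is zero.

**Sorted populations.** The neuron-vs-glia reference is simulated as nearly
pure NeuN+ samples (96% neurons) versus an even glial pool (24.5% each of
the four non-neuronal types), Dirichlet-jittered, at high depth (2×10⁶
library size) so the reference differential analysis is well powered.

**Randomness.** All randomness flows from one integer seed through
`numpy.random.SeedSequence`; child streams are consumed in a fixed,
documented order (library sizes, metadata, expression, reads-in-peaks,
differential flags, methylation, coverage), so reruns are bit-identical.

## Estimators

All three profile estimators share one engine: subset the normalized matrix
to one cell type's markers, center (and unit-scale) features, take the
samples' scores on the first right singular vector, min–max rescale to
[0, 1].

* **MGP** — expression, log2(CPM+1).
* **MSP** — H3K27ac reads-in-peaks, log2(CPM+1), on marker sites derived by:
  NB-GLM differential acetylation between sorted populations → keep |fold
  change| > 4 and mean count > 1000 (strict inequalities) → annotate to genes
  whose strand-aware window [TSS − 5 kb, 5′UTR end] they overlap by ≥ 1 base
  (0-based half-open; window reflected on the minus strand, configurable) →
  assign a region to cell type K iff every annotated gene is a K expression
  marker and the sign is concordant (neuronal types need neuron-up regions,
  non-neuronal types neuron-down); ambiguous regions are dropped, so marker
  sets are mutually exclusive by construction.
* **WGBS-MSP** — methylation beta at cell-assigned marks (multi-assigned
  marks and marks with <10× coverage in more than 20% of samples are
  excluded), missing values imputed with the site's across-sample median
  *before* scaling, and the profile reported as 1 − rescaled score because
  marks are hypomethylated in their cell type.

The first-PC sign is ambiguous in any SVD; it is oriented so the score
correlates positively with the across-feature mean of the (scaled) marker
signal, with an exact tie broken toward a positive loading sum. This removes
the ambiguity deterministically; for WGBS-MSP the orientation runs on the
beta matrix, so the final `1 −` flip yields a score that increases with
abundance.

Profile scores are *relative* (each column spans exactly [0, 1] by
construction); the **reference-based comparator** solves per-sample
nonnegative least squares against a linear-scale signature and renormalizes
to the simplex, giving absolute proportions where a signature is available.

**Ordered-factor conversion.** Quantile binning into 5 levels. The binning is
monotone — `score_i ≤ score_j ⇒ level_i ≤ level_j` — which forces tied
scores to share a level; ties take the lowest level of their block, so a
constant input is all level 1. Equal-width binning is available as an
alternative through the number-of-levels/quantile machinery if needed.

## Differential engine

A self-contained batched NB2 GLM (log link, library-size offset):
per-feature dispersion by method of moments on Pearson residuals of an
initial Poisson fit, `phi = Σ[(y−μ)² − μ]/μ² / (n − p)`, floored at 1e−8 and
capped at 50; then IRLS for the coefficients (max 60 iterations, tolerance
1e−8, linear predictor clipped to ±30) and a Wald test of one coefficient
against a t reference with n − p degrees of freedom — closer to nominal size
than the asymptotic normal at cohort-scale n (empirically ~0.045–0.048 at
nominal 0.05, inside binomial 99% bounds at 1000 features). For the
case-control models the dispersion is additionally shrunk toward a
mean-binned median trend (weight 0.3, ~20 bins) for stability. FDR is
Benjamini–Hochberg. statsmodels' NB GLM serves as an independent oracle in
the tests; it is never the engine.

## Adjustment-model ladder

The case-control analysis compares condition inference under:

1. **none** — intercept + age (5-level ordered factor, orthogonal polynomial
   contrasts) + sex + condition.
2. **shuffled** — adds the adjacent-sample methylation-derived neuronal score
   permuted within condition groups, as a continuous covariate. The shuffle
   preserves the covariate's marginal distribution and its group means but
   destroys the sample linkage, making it a negative control; the condition
   coefficient is asymptotically identical to the unadjusted one. A
   continuous coding is used because an ordered-factor coding of the
   shuffled covariate spends 4 df absorbing between-group signal and
   measurably decouples the negative control from the unadjusted model.
3. **ordered_factor** — the same adjacent-sample neuronal score as a 5-level
   ordered factor. Using the *adjacent* sample's methylation-based estimate
   mirrors the historical practice of adjusting ChIP-seq with a methylation
   estimate from a neighbouring tissue sample, and is exactly why this
   adjustment is only partial: adjacent samples genuinely differ.
4. **continuous_msp** — same-data MSPs (neuron, microglia, oligodendrocyte)
   as continuous covariates.
5. **continuous_true** — log true nuclear proportions (neuron, astrocyte,
   microglia, oligodendrocyte; one type dropped to avoid simplex
   collinearity). Logs, not raw proportions: abundance enters count means
   multiplicatively, so log-proportions are the scale on which a linear
   adjustment can null marker peaks exactly.

Bias is quantified by (a) the fraction of FDR-significant hypo/hyper-in-case
peaks classified against the sorted-cell reference (reference calls need
adjusted p < 0.05 and |log2FC| > 3; fractions are relative to all significant
peaks in the direction, with an `unclassified` class so fractions sum to 1),
(b) overlap with cell-type-unique region sets (≥ 1 bp; denominator = peaks
with any unique label, the `testable` set), and (c) the Pearson correlation
between case-control and neuron-vs-glia log2 fold changes.

## Other analysis components

* **Estimate correlations** are plain Pearson per cell type over intersecting
  samples, after removing any excluded ids (e.g. twice-assayed extracts).
* **Correlation clustering** uses distance 1 − r with average linkage
  (linkage choice is configurable; ties resolve to the lower column index,
  so leaf order is reproducible).
* **PC–covariate association** standardizes features, takes SVD scores, and
  fits *one joint* linear model per PC of scores on all variables; numeric
  variables report their coefficient t-test, categorical variables a block
  F-test. Collinear expanded columns are dropped and recorded.
* **Stepwise cell–disease association** regresses the 0/1 condition on all
  cell estimates plus fixed nuisance covariates, with bidirectional greedy
  selection over the estimate columns scored by AIC. AIC admits an
  occasional noise covariate (per-variable false-inclusion ≈ 16%); the truly
  shifted cell types are retained and dominant essentially always, and that —
  not exact support recovery — is the guarantee the tests assert.

## Default study sizes

The default observational cohort is 50 individuals × 2 tissue samples, 1500
genes, 1500 peaks (150 designed acetylation markers per type, of which 80
per type are paired with expression marker genes), 600 methylation sites (60
marks per type); the case-control study reuses this size with shift −1.0 and
5% genuine effects. These sizes keep a full simulate→derive→estimate→model
cycle around two seconds while leaving all headline properties
comfortably powered; the acceptance script runs the whole battery in well
under a minute.

## What the simulator does not emulate

No batch effects, GC/length biases, per-feature dispersion trends beyond the
shared parameter, peak calling, read-level artifacts, genomic realism beyond
synthetic chromosomes, or cross-individual genetic variation. Marker
exclusivity is designed-in and perfect up to the guaranteed fold; real
marker lists are noisier, and real genuine effects are not guaranteed to
avoid cell-type-specific regions. Passing results therefore demonstrate that
the estimators and adjustment logic behave correctly under a mechanism that
*contains* the field-scale phenomena (adjacent-sample decorrelation,
nuclear/whole-tissue discordance, condition-confounded composition); they do
not certify performance on real tissue, where estimate quality is the
binding constraint.

## Known limitations

* The adjacency knob is a single clr-noise sd; it cannot separate
  grey/white-matter gradients from dissection noise.
* Wald/t inference ignores dispersion-estimation uncertainty; at very small
  n (< ~20 samples) the test runs slightly liberal.
* NNLS deconvolution assumes the signature is on the data's linear scale and
  full column rank; no cross-platform normalization is attempted.
* The stepwise procedure inherits AIC's liberal selection; its output is a
  shortlist, not an inference-adjusted model.
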