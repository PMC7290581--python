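# Methods

This note documents the statistical models behind `mircad`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer should know about.

## 1. Ct processing and normalization (`mircad.ct`, `mircad.pipeline.normalize`)

The processing chain is fixed in order: validity masking → feature filter →
sample filter → plate correction → global ΔCt normalization. Each `CtMatrix`
carries a history list so downstream objects record the order actually run;
`global_normalize` refuses matrices containing fully missing samples, which
can only occur when the sample filter was skipped.

**Validity masking.** Amplification-quality scoring is platform software
territory; the package accepts a boolean validity mask and sets invalid
wells to missing. No attempt is made to model amplification curves.

**Feature filter.** A miRNA is dropped when (a) it is missing in more than
90% of samples (strictly; exactly 90% is kept), or (b) some plate with any
observation of it has fewer than two observations, which makes a per-plate
scale estimate impossible. Reasons are reported per dropped miRNA.

**Sample filter.** A sample missing more than 95% of the panel (strictly)
is dropped. With a 51-miRNA panel this removes only near-empty wellsets.

**Plate correction.** Per-plate location/scale effects are removed by
parametric empirical-Bayes batch correction on the non-missing entries:
per-miRNA standardization, per-plate batch effect estimates (γ̂ additive,
δ̂² multiplicative), normal and inverse-gamma priors fitted across miRNAs
by method of moments, and a fixed-point iteration (tolerance 1e-4 on the
max absolute change) to the posterior estimates, which are then removed.
Assumptions: batch effects are shared across miRNAs up to the prior spread,
and data within plate are approximately Gaussian on the Ct scale.
Degenerate cases: a single plate is returned unchanged; a miRNA with zero
within-plate variance everywhere triggers a location-only adjustment with a
warning (shrinking a scale toward a zero-variance estimate is meaningless);
`eb=False` applies the unshrunk per-plate estimates, which removes a pure
location offset exactly and is used as a test oracle.

**Global normalization.** ΔCt = Ct − mean of the sample's *observed* Cts.
The global mean is preferred over a single reference miRNA because no
spike-in is assumed and panel-wide means are stable; its cost is a mild
attenuation of any single miRNA's group difference (the marker contributes
1/m of its own reference, m = panel size), visible in fold-change recovery
at m = 51 as a few percent shrinkage toward 1.

## 2. Censored differential expression (`mircad.censored`)

Non-detects are right-censored at the per-miRNA maximum *observed* ΔCt:
the reaction reports "at least this dilute", and pinning at the observed
maximum keeps the restricted mean inside the observed range.

**Restricted mean.** The Kaplan–Meier product-limit estimator is built on
the ΔCt axis; at tied values, events precede censorings (a censored
observation remains at risk at its own value). The restricted mean is
t_min + ∫ Ŝ dt over [t_min, t_max]. With no censoring this equals the
arithmetic mean exactly — an identity the tests exploit. When every
observation is censored the mean is undefined and the miRNA's row is
flagged rather than aborting the scan. The implementation is the package's
own (the estimator on the ΔCt axis, with this tie convention and
restriction, is the core primitive here); `lifelines` serves as an
independent cross-check in the tests.

**Testing and fold change.** Groups are compared with the two-group
log-rank test (delegated to `lifelines`, after shifting values to
non-negative "durations"; the statistic is shift-invariant). Fold change is
2^−(μ̂_case − μ̂_control), so FC > 1 means higher expression in cases
(lower ΔCt). Panel-wide p-values get Benjamini–Hochberg adjustment
(`statsmodels`). Both groups need at least one uncensored value for the
test to be defined; failures become flagged rows.

## 3. Case-cohort weighted Cox (`mircad.coxcc`)

**Design and weights.** All incident cases plus a random subcohort
(default target 4 subcohort members per case) stand in for the cohort.
Barlow weighting (default): subcohort person-time while event-free carries
weight 1/f, f = subcohort size / cohort size; each case enters the risk set
only just before its own failure, with weight 1; a case inside the
subcohort is split into an event-free (0, T−ε] record at 1/f and a failure
(T−ε, T] record at weight 1. ε is 1e-6 of the maximum follow-up time —
small enough never to cross another record's entry in continuous time.
Prentice weighting (subcohort person-time unweighted) is kept as an option
for sensitivity analysis.

**Estimation.** The weighted Breslow partial likelihood with late entry
(risk set at t: entry < t ≤ stop) is maximized by Newton iteration with
step-halving, starting at β = 0, converging on relative log-likelihood
change < 1e-9 (max 100 iterations). Covariates are centered at their
weighted means before fitting (conditioning only; coefficients are
invariant). Breslow tie handling is the estimator's definition here, not a
simplification: under it, duplicating a record is exactly equivalent to
doubling its weight, which is the property that makes the weighting scheme
coherent, and the tests assert it. Variances are the Lin–Wei robust
sandwich with score residuals summed within subject (the split case
records cluster on id); Wald 95% CIs and p-values follow. Zero-variance or
collinear covariates (checked by matrix rank after centering) and
event-free data raise informative errors. Per-miRNA scans fit two
adjustment sets — `base` (age, sex) and `full` (all six classical risk
factors) — on complete cases per miRNA (minimum 10), with BH adjustment
per scan and adjustment set; unfittable miRNAs are flagged rows.

**Absolute risk.** The Breslow baseline cumulative hazard at the centering
covariates is accumulated at event times; predicted h-year risk is
1 − S₀(h)^exp(lp − lp_center). `lifelines`, which implements the weighted
Cox model with Efron ties, is the independent cross-check on tie-free data
(where Efron and Breslow coincide).

## 4. Reclassification metrics (`mircad.reclassify`)

All metrics take paired baseline/extended predicted risks with subject
weights (cases 1, non-case subcohort members 1/f), so the case-cohort
sample represents the cohort. Continuous NRI (percent):
100·{[P_w(up|event) − P_w(down|event)] + [P_w(down|non-event) −
P_w(up|non-event)]}, exact ties counting neither direction. Categorical
NRI applies the same formula to category indices after cutting risk at the
cutoffs (default single cutoff 0.10 of ten-year risk, the conventional
intermediate/high boundary); a cutoff at 0 or 1 leaves one category and
returns 0. IDI is the difference of weighted discrimination slopes. The
weighted Harrell C uses pairs (i, j) with i an event and t_j > t_i, pair
weight w_i·w_j, risk ties counting ½; Δ concordance is reported as a point
estimate. Confidence intervals are percentile bootstrap over subjects
(default B = 1000, minimum 100), with a two-sided p-value equal to twice
the smaller tail mass around 0; the bootstrap fails loudly if the metric is
undefined (e.g. a resample without events) in more than 10% of resamples.

## 5. In-vitro screen (`mircad.arrays`)

Log2 expression across three ordered LDL exposures (nLDL, moxLDL, hoxLDL)
in two cell types, few replicates each. Per-feature variances from the
one-way layout are shrunk by empirical Bayes: the prior (d₀, s₀²) is fitted
by moments of log s² with a Newton inversion of the trigamma function
(tolerance 1e-8), and posterior variances are (d₀s₀² + d·s²)/(d₀ + d) with
t-tests on d₀ + d degrees of freedom. `prior_df=0` recovers the ordinary
pooled t-test exactly (a test oracle against `scipy.stats.ttest_ind`);
`prior_df=inf` pools fully and uses the normal reference. Dose-response is
tested with orthogonal-polynomial contrasts on the ordered condition index:
linear (−1, 0, +1) and quadratic (+1, −2, +1), fitted per feature by least
squares. The candidate rule — (|FC| ≥ 1.5 and p < 0.05 in moxLDL−nLDL or
hoxLDL−nLDL) and (linear or quadratic trend p < 0.05), in at least one cell
type, on *unadjusted* p-values — reflects screening practice: a permissive
discovery filter whose hits face confirmation in the serum study, so FDR
control is deferred to that stage. Cross-platform agreement between array
log2 FCs and qPCR −ΔΔCt summaries uses Spearman rank correlation (≥ 3
matched features; constant vectors are rejected).

## 6. Target enrichment (`mircad.enrichment`)

Predicted-target filtering keeps genes with context score strictly below
−0.3 and aggregate score ≥ 0.3 (the context boundary is exclusive, the
aggregate inclusive — both asserted in tests). Over-representation of the
filtered targets in each gene set is the hypergeometric upper tail
P(X ≥ k) with universe N, set size K, target count n, overlap k, computed
as `scipy.stats.hypergeom.sf(k−1, N, K, n)` and BH-adjusted across sets.
Gene symbols are case-normalized; sets must lie within the declared
universe. Expressed-target overlap reports per-cell-type intersection
counts, the intersection across all cell types, and optional cross-tabs
with curated sets.

## 7. Synthetic-data generator (`mircad.simulate`)

The generator is the package's validation instrument; its defaults encode
the study design the methods are built for and were fixed on design grounds.

**Case-control qPCR arm.** 476 cases / 487 controls (a realistic MI
case-control size), 51-miRNA panel on 8 plates; Ct = baseline − status ×
log2 FC + plate shift + plate scale × N(0, sd²); measurement sd 1.5 Ct,
plate shifts N(0, 0.8²) Ct, plate scale log-normal with sd 0.1 — magnitudes
typical of serum RT-qPCR panels where plate effects are smaller than but
non-negligible against biological spread. Cts above the detection limit
(default 31) become non-detects; baselines default to the 22–28 Ct range
with named miRNAs settable (e.g. the planted hsa-miR-122-5p at 26, which
keeps its non-detect fraction low even for controls). The truth table
records realized (pre-censoring) fold changes and non-detect fractions.

**Cohort arm.** 5000 subjects, 10-year administrative censoring,
exponential baseline hazard 0.002/year (Weibull optional), proportional
hazards with the six classical risk factors (plausible distributions and
log-HRs: e.g. age N(55, 10) years at 0.06/year, diabetes prevalence 12% at
log-HR 0.60) and standard-normal miRNA values, default planted
hsa-miR-143-3p log-HR log(0.56). These settings yield on the order of
100–170 events per realization — a ~2–3% ten-year event rate typical of a
middle-aged population cohort. Event times come from inversion
(T = H₀⁻¹(−log U / e^lp)); the case-cohort table is all events plus a
random subcohort of 4 × events. A draw with zero events is retried on a
fresh substream up to 5 times, then fails with a diagnostic.

**In-vitro and annotation arms.** Three exposures × 2 cell types × 3
replicates, planted flat/linear/quadratic log2 profiles with Gaussian
noise sd 0.25 — typical array replicate noise; 100 null background
features. The annotation generator plants one enriched target set (70% of
its members drawn from the filtered-target region of score space) among
null sets, plus per-cell-type expressed-gene lists.

**What it does not emulate** — hence what passing recovery tests do not
show about real data: qPCR amplification-efficiency differences between
miRNAs, hemolysis and other pre-analytical contamination of serum samples,
correlated miRNA co-regulation (panel miRNAs are independent given group),
informative (non-administrative) censoring and competing risks in the
cohort, measurement error in the classical risk factors, and
batch-by-group confounding (plates are assigned independently of case
status). Parameter recovery under this generator demonstrates correctness
of the estimators under their own assumptions, not robustness to these
violations.

**Reproducibility.** All randomness flows through named substreams:
`SeedSequence([seed, crc32(name)])`, so every generator and the bootstrap
are independently reproducible and adding a consumer never perturbs the
others.

## 8. Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` size their simulations to be
decisive yet quick: 1000 uncensored vectors for the restricted-mean
identity; 1000 (tests) / 500 (script) null replicates at n = 100/group for
log-rank calibration; 50 (tests) / 10 (script) study replicates for
fold-change recovery at the full 963-sample design; 100 (tests) / 25
(script) cohort replicates for the case-cohort log-HR; bootstrap B = 1000
in the pipeline default and 500 in the script. Enumeration oracles
(hypergeometric tails, reclassification metrics, grid-search Cox) run on
toys small enough for exhaustive computation (N ≤ 12 universes, ≤ 20
subjects, ≤ 6 records).

## 9. Known limitations

- The EB plate correction assumes missingness is non-informative within
  plate; heavy, expression-dependent non-detection biases the per-plate
  moments it shrinks toward.
- The restricted mean is bounded by the observed range, so under heavy
  censoring group means (and hence fold changes) compress toward each
  other; the log-rank p-value is the more trustworthy signal there.
- The ε-entry construction for case risk intervals assumes continuous
  follow-up time; on coarsely discretized times, records can collide and
  the weighting scheme (and Breslow ties) should be reconsidered.
- The bootstrap resamples subjects ignoring the two-phase sampling design;
  for small subcohorts a design-aware (stratified) bootstrap would be more
  faithful.
- The moderated-t screen assumes homoscedastic replicates within condition
  and Gaussian log2 intensities; the trend test inherits both.
- Concordance uses Harrell's pairing, which is optimistic under heavy
  censoring compared to inverse-probability-of-censoring-weighted variants.
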