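# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical conventions a user relying on the outputs should know.

## The exhaustion score model

The score is a supervised principal-components survival model. Given a
genes × samples matrix of CD3-normalised log2 expression `X` and survival
data `(t, δ)`:

1. **Screen.** Each candidate gene is fit in a univariate Cox proportional-
   hazards model; genes with Wald *p* < α are retained, ordered by ascending
   *p*. The published training used α = 0.001; α is exposed because the
   sensible value depends on cohort size.
2. **Summarise.** The selected submatrix is standardised per gene (training
   mean m<sub>i</sub>, SD s<sub>i</sub>) and its first principal component
   computed by SVD.
3. **Calibrate.** A univariate Cox model on the PC score gives coefficient β.
4. **Weights.** w<sub>i</sub> = β·v<sub>i</sub>/s<sub>i</sub>, where
   v<sub>i</sub> is the PC loading. The sample score
   ES<sub>j</sub> = Σ w<sub>i</sub>x<sub>ij</sub> − offset then equals
   β·PC<sub>j</sub> up to centring. The sign ambiguity of the PC cancels in
   β·v, so higher ES ⇒ higher hazard without an explicit flip.
5. **Offset.** The training mean of Σ w<sub>i</sub>x<sub>ij</sub>, making the
   training-cohort mean ES exactly zero. This reproduces the printed
   single-constant form of the score; the constant is subtracted once per
   sample, not once per feature.

Degenerate screens fall back rather than abort: one selected feature uses its
univariate Cox weight (the PC of a single standardised variable is itself);
zero selected features yield an all-zero score with a warning — necessary so
that leave-one-out folds on null data remain well-defined.

The univariate Cox machinery inside the fit is an in-package vectorised
Newton–Raphson maximiser of the Breslow partial likelihood, solving all genes
simultaneously. Survival times in the intended uses are continuous, where
Breslow and Efron coincide; the solver is cross-checked against lifelines in
the unit tests. The general `cox_fit` used for reported hazard ratios
delegates to statsmodels PHReg (Efron ties by default, Breslow on request)
and flags possible monotone likelihood (|β| > 20) instead of reporting a
spuriously converged fit.

**Cross-validation.** `loocv` refits the whole procedure (screen + PC + Cox)
per held-out sample, assigns high/low against the training-fold median (ties
low), and computes the Mantel–Cox statistic of the cross-validated groups. The
permutation *p* reruns the entire LOOCV under survival-label shuffles:
p = (1 + #{perm ≥ obs}) / (1 + B). A degenerate grouping (all one label)
scores statistic 0 so that permutations remain comparable.

## CD3 normalisation and CYT

Normalisation "to" the CD3D/E/G mean is implemented as subtraction on the
log2 scale (a ratio on the linear scale); the operation is invariant to adding
a common constant to a sample's signature and CD3 genes. CYT exponentiates
log2 input before the geometric mean √(GZMA·PRF1); nonpositive linear values
are an error rather than silently clipped.

## Methionine pathway scores

"Cumulative expression" is read literally as the arithmetic sum over the
available genes of each set (6 salvage, 5 de novo); a `mean` option exists for
users worried about the unequal sizes. Bulk samples use the salvage/de-novo
ratio (undefined ratios are NaN and flagged, never dropped silently); single
cells use the difference, which stays defined at zero sums. The salvage-high
rule is strict: difference > mean of all malignant cells, so an all-equal
population is uniformly de-novo-high. Tumor dominance is a strict majority
(> 0.5) of salvage-high cells — the description "composed predominantly"
gives no number, and a strict majority is the weakest defensible reading.
Group comparisons default to Student's equal-variance t (as reported), with
Welch behind a flag; a zero-variance pair of identical groups returns
t = 0, p = 1.

## Metabolite screen

Missing abundances are imputed with the per-metabolite observed minimum
(detection-limit reasoning). Ratios are per matched tumor/non-tumor pair.
Spearman *p*-values use the exact permutation null for n ≤ 9 and the
t-approximation above; BH adjustment runs across all metabolites surviving
the preconditions (≥ 8 paired samples, non-constant), which is the *m* that
the FDR guarantee refers to. Results are ordered by |ρ| for waterfall-style
reporting. Because the screen is rank-based it is invariant to any strictly
monotone transform of the score, which the tests assert.

## Survival statistics

Kaplan–Meier and log-rank go through lifelines; the log-rank statistic is the
pooled-event-time Mantel–Cox chi-square with df = groups − 1. Median splits
send ties to the low group — deterministic, conservative, and shared between
the score risk groups and metabolite/ratio stratifications. Whether the
published hazard ratios used Breslow or Efron ties is unknown; the tie method
is therefore always recorded in the fit output.

## Integration rules

Copy-number calls use the ±0.8 thresholds on the per-gene summary (median
probe) value, inclusive at the boundary. The driven-gene rule requires a
differential peak (q < 0.05, fold-change magnitude > 1.5), significant
expression upregulation in salvage-dominant tumors (q < 0.05, positive
log2FC), concordant direction (more accessible ∧ upregulated; the magnitude
filter is applied to |log2FC| first, then concordance), and absence from a
user-supplied tumor-specific exclusion list — no objective criterion for that
list exists upstream, so it is an explicit input. The rule is monotone:
relaxing any threshold can only grow the set.

## The synthetic world

Defaults are the stated conditions, fixed once:

| parameter | default | rationale |
|---|---|---|
| n_signature_genes | 82 | size of the published exhaustion signature |
| exhaustion_effect | 1.0 log2/SD | a clearly detectable but noisy bulk effect |
| hazard_log_hr | 1.0 | the planted effect used by the recovery criteria |
| censor_rate | 0.3 | typical for HCC survival cohorts |
| metabolite_rho | 0.444 | the reported top metabolite correlation |
| salvage_denovo_anticorr | −0.5 | pathways observed to be inversely expressed |
| noise_sd | 1.0 log2 | microarray-like residual noise |
| pathway effect | 1.0 log2/SD (fixed) | kept independent of exhaustion_effect so a null-exhaustion cohort retains its metabolic structure |
| exhaustion↔salvage coupling | 0.5 (fixed) | the two axes are related but distinct |
| null-metabolite missingness | 5% MAR | missingness exists but planted metabolites stay fully observed, so their Spearman level is exactly the copula target |

Mechanics worth knowing:

- Metabolite ratios hit the target *Spearman* ρ via the Gaussian copula
  identity ρ_P = 2 sin(πρ_S/6) on the log-ratio scale.
- Censoring is a single administrative cutoff placed at the empirical
  (1 − censor_rate) quantile of the event times — independent censoring with
  an exactly controlled censoring fraction.
- Single-cell programs differ by a per-pathway-gene mean shift of
  2·noise_sd by default; the per-cell difference statistic then separates by
  11 gene-shifts against noise of √11·noise_sd, which is what makes ≥ 95%
  classification accuracy attainable at the default mixtures.
- The default single-cell compartment (4 tumors, fractions 0.9/0.8/0.7/0.2,
  T-cell counts 52/51/51/21) mirrors the published four-patient composition
  of three salvage-dominant tumors and one de-novo-dominant tumor.

What the generator does **not** emulate: count-level noise (expression is
Gaussian directly on log2 scale), gene–gene correlation beyond the planted
latent factors, batch effects, informative censoring, platform differences
between metabolome panels, doublets/ambient RNA in single cells, and real
LD-like structure in copy number. A green test therefore establishes that the
*procedures* behave as specified under their own assumptions — not that the
published cohort-level estimates are reproduced; those require the original
patient data.

## Numerical conventions

- TSV writers use `%.17g`; readers parse with correctly rounded float
  conversion, so write→read round-trips are bit-exact, and reruns of any
  stage with the same config and seed are byte-identical (manifests are
  timestamp-free).
- All randomness flows from a single integer seed through a SeedSequence
  tree; independent streams per data layer keep, e.g., the metabolome
  unchanged when only n_noise_genes changes downstream of its stream.
- Newton steps in the Cox solver are clipped at ±4 with linear predictors
  clipped at ±60 to prevent overflow on separated covariates; columns with
  vanishing information return β = 0, p = 1 rather than diverging.
- The exact Spearman permutation null enumerates all n! rank permutations
  (feasible through n = 9, the documented cut-over).

## Known limitations

- The published feature weights are not printed in the source material, so
  the four-feature published model can be *applied* only once its weights are
  supplied; the package's fitted weights are its own reconstruction of the
  supervised-PC recipe.
- Exact reproduction of the 82-gene signature list is not claimed: the
  derivation thresholds behind it are unpublished, so `derive_signature`
  exposes them as parameters.
- `loocv` is O(n²) model fits per permutation; it is intended for cohorts of
  tens to a few hundred samples, not thousands.
- Time-dependent covariates and competing risks are out of scope.
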