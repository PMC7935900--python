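# methex

Integrative scoring of tumor methionine metabolism and T-cell exhaustion in
hepatocellular carcinoma (HCC) cohorts.

Intratumoral CD8+ T cells in HCC frequently sit in an exhausted, hypofunctional
state, and tumors that rewire methionine recycling toward the salvage pathway
accumulate S-adenosylmethionine (SAM) and 5-methylthioadenosine (MTA), two
metabolites tied to that dysfunction. `methex` packages the analysis chain that
connects these layers — bulk transcriptome, tumor/non-tumor and serum
metabolome, single-cell transcriptome, per-gene copy-number summaries — for
computational oncologists who want to score new cohorts or stress-test the
methodology on simulated ones.

## What it computes

**Exhaustion score (ES).** On CD3-normalised log2 expression
(x<sub>gj</sub> − mean(CD3D, CD3E, CD3G)<sub>j</sub>, i.e. signature expression
relative to T-cell content), a supervised principal-components Cox model:
genes are screened by univariate Cox Wald tests (*p* < α, default α = 0.001),
the selected features are standardised, their first principal component is fit
in a univariate Cox model with coefficient β, and each feature receives weight
w<sub>i</sub> = β·v<sub>i</sub>/s<sub>i</sub> (loading over training SD), giving

> ES<sub>j</sub> = Σ<sub>i</sub> w<sub>i</sub> x<sub>ij</sub> − offset

with the offset fixed so the training-cohort mean ES is 0. Higher ES means
higher hazard by construction. The published four-feature model
(YARS, PKM2, TPI1, MTHFD2; offset 12.77237) can be loaded directly via
`ExhaustionScoreResults.from_weights` once its weights are supplied; PKM/PKM2
and YARS/YARS1 annotation differences are resolved automatically.

**CYT.** The cytolytic score √(GZMA·PRF1), a geometric mean on the linear
scale.

**Methionine pathway activity.** Cumulative expression of the salvage genes
(AMD1, SRM, SMS, ENOPH1, MTAP, APIP) and de novo remethylation genes (GNMT,
AHCY, BHMT, BHMT2, MTR): the salvage/de-novo *ratio* per bulk sample, the
*difference* per malignant single cell. Cells above the population-mean
difference are salvage-high; a tumor is salvage-dominant when a strict
majority of its malignant cells are salvage-high, and T-cell gene sets
(exhaustion signature, DNMT1/3A/3B) are compared between tumor groups by t
test.

**Metabolite screen.** Minimum-imputation per metabolite, tumor/non-tumor
ratios over matched pairs, Spearman correlation of each ratio with the ES
(exact permutation p for n ≤ 9), Benjamini–Hochberg adjustment, hits at
FDR < 0.05; serum MTA is normalised to serum methionine.

**Survival statistics.** Median-split stratification (ties to the low group),
Kaplan–Meier product-limit curves, Mantel–Cox log-rank tests and Cox
proportional-hazards fits (Efron or Breslow ties) with Wald CIs.

**Integration.** Per-gene copy-number/expression Pearson correlation with
amplification / deep-deletion calls at ±0.8, and the SAM/MTA-driven gene rule:
genes whose chromatin peaks are differential (FDR < 0.05, |fold change| > 1.5)
*and* significantly upregulated in salvage-dominant tumors, concordant in
direction, minus a tumor-specific exclusion list.

**Synthetic cohorts.** `generate_bulk_cohort` / `generate_single_cell` plant a
latent exhaustion level that drives signature genes and hazard, anti-correlated
salvage/de-novo programs, metabolite ratios at a configured Spearman level,
serum MTA coupled to salvage status, and two-program single-cell mixtures —
so every stage is testable against known ground truth without any download.

## Worked example

```python
import methex

cfg = methex.CohortConfig(n_samples=200, seed=1)          # planted log HR = 1.0
bundle = methex.generate_bulk_cohort(cfg)

norm = methex.cd3_normalize(bundle.bulk_expression, bundle.signature_genes)
model = methex.ExhaustionScoreModel(
    norm.loc[bundle.signature_genes], bundle.clinical, alpha=0.001
).fit()
scores = model.predict(norm)                              # per-sample ES
groups = methex.median_split(scores["ES"])
stat, p = methex.logrank_test(bundle.clinical, groups)
fit = methex.cox_fit(bundle.clinical, (groups == "high").astype(float).rename("ES_high"))
print(f"log-rank chi2={stat:.3f} (p={p:.3g}), "
      f"HR={fit.hr.iloc[0]:.3f} [{fit.ci_low.iloc[0]:.3f}, {fit.ci_high.iloc[0]:.3f}]")
```

prints

```
log-rank chi2=34.047 (p=5.38e-09), HR=2.685 [1.903, 3.789]
```

— the cross-cohort pattern the score is built for: the high-ES half of the
cohort dies faster (hazard ratio ≈ 2.7, CI excluding 1). Screening the planted
metabolome against that fitted score,

```python
ratios = methex.tumor_nontumor_ratio(
    methex.impute_min(bundle.tumor_metabolome),
    methex.impute_min(bundle.nontumor_metabolome),
)
print(methex.es_metabolite_screen(scores["ES"], ratios).head(2).round(4))
```

recovers the two planted methionine metabolites at the top of the waterfall:

```
               rho       p  n_used       q   hit
metabolite
SAM         0.3389  0.0000     200  0.0002  True
MTA         0.2654  0.0001     200  0.0147  True
```

The same chain runs from the shell: `methex simulate | score | methionine |
screen | survive | integrate | run`, each writing tab-delimited outputs plus a
JSON manifest; reruns with the same config and seed are byte-identical.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates a seeded synthetic cohort and recomputes the full pipeline from
scratch — score-model fit, median-split survival stratification, metabolite
screen, serum MTA, single-cell classification and tumor composition, and the
copy-number association — printing a summary of each computed quantity and
writing the results file.

## Layout

- `src/methex/simulate.py` — synthetic cohorts with planted truth
- `src/methex/signature.py` — signature derivation, CD3 normalisation
- `src/methex/score.py` — `ExhaustionScoreModel` / `ExhaustionScoreResults`, CYT
- `src/methex/methionine.py` — pathway scores, cell classification, dominance
- `src/methex/metabolites.py` — imputation, T/N ratios, Spearman screen, serum MTA
- `src/methex/survival.py` — median split, KM, log-rank, Cox
- `src/methex/integration.py` — CNV association, driven-gene intersection
- `src/methex/io.py`, `pipeline.py`, `cli.py` — formats, orchestration, CLI
- `docs/methods.md` — modelling assumptions and numerical choices
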