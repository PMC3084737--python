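# Methods

`mediassoc` implements the statistical chain used to decide whether a risk
variant acts on a smoking-related disease directly or indirectly through
smoking behaviour. This note records the models, the defaults and why they
are what they are, the numerical choices, and what the synthetic cohorts do
and do not establish.

## Association statistics

**Crude genotype ORs.** For a genotype dosage g versus a reference genotype,
the odds ratio is the cross-product of the 2×2 case/control table, with a
Woolf (log-OR Wald) 95% CI, `exp(ln OR ± 1.96·√(Σ 1/cell))`, and a two-sided
Wald p. Woolf intervals with no continuity correction are what reproduce
published per-genotype CIs from count tables; the Haldane 0.5-cell
correction is available behind a flag and results carry a `corrected`
marker. A zero cell without the flag is an error, never a silent infinity.

**Per-allele OR.** The additive model `logit P(case|g) = α + βg` is fitted
to the grouped counts by Newton/IRLS, initialized at β = 0 and α = the
overall log-odds, converged when the log-likelihood changes by < 1e-10
(max 100 iterations). `exp(β)` is the per-allele OR with Wald CI. Complete
separation raises `ConvergenceError` (detected as |β| > 15 or a divergent
log-likelihood) rather than returning a huge estimate. The fit is
cross-checked against an independent GLM implementation in the tests.

**Risk-allele coding.** Dosage counts risk alleles, which is a per-variant
choice, not an alphabetical one: for one of the two shipped variants the
risk allele is the major allele, so its printed genotype rows are coded
2/1/0 against the homozygous-risk reference. The model surface flags (never
silently inverts) tables whose per-allele OR direction contradicts the
case/control allele-frequency difference — a situation that occurs in one
published never-smoker row, where the reported value is the reciprocal of
what the counts give.

**Cochran–Armitage trend.** The statistic is the usual 1-df trend χ² with
the margins-conditional (multivariate hypergeometric, N−1 divisor)
variance and weights 0/1/2. Because the χ² approximation is poor on tiny
tables, the two-sided p is computed *exactly* for N ≤ 30 by enumerating the
conditional distribution of case configurations (counted with binomial
multiplicity); results carry an `exact` flag. Above N = 30 the asymptotic p
is used. The exact branch is validated against a brute-force enumeration of
subject-level label assignments.

**HWE.** 1-df χ² of observed genotype counts against p², 2pq, q² with the
allele frequency estimated from the sample; monomorphic samples return
χ² = 0 with a `monomorphic` flag. The statistic is invariant to allele
relabelling.

**Adjusted per-allele OR.** Individual-level multivariable logistic MLE
(delegated to statsmodels GLM) with dosage additive and smoking quantity
entered as the four conventional categories 0–10 (reference), 11–20, 21–30,
31+ cigarettes/day. Rows with missing covariates are removed listwise and
counted in the result flags (cohorts routinely have exposure data on only a
subset). Indicator columns that are empty in the analysed data (an
unoccupied CPD category, a single-sex cohort) are dropped with a flag;
a genuinely collinear design raises an error naming the offending columns.

**Power.** Power of the per-allele trend test by the non-central χ²
approximation: under the alternative, the control risk-allele frequency p₀
maps to a case frequency p₁ with `odds₁ = OR·odds₀`, the non-centrality is
the squared expected allelic log OR over its Woolf variance at the expected
counts. Validated against Monte-Carlo power (simulated genotype tables)
rather than against any published claim — the analytic and simulated power
agree with each other.

## Genotype–exposure analyses

Smoking intensity across genotype groups uses the tie-corrected
Kruskal–Wallis test (scipy); its rank nature makes the raw/log CPD choice
irrelevant to the test, and group means are reported raw. The per-allele
CPD effect is the least-squares trend of log CPD on dosage, back-transformed
to raw cigarettes/day at the analysed sample's mean
(`Δ = mean CPD · (exp(slope) − 1)`), because effects are conventionally
reported in raw CPD units despite log-scale testing. Heavy smoking
dichotomizes at >20 CPD (light 1–20, heavy 21+) and reports the risk-allele
frequency in each stratum plus a genotype trend test across strata. Trends
in any numeric response across genotype (age of onset, initiation,
cessation age) share one operation: a 1-df linear trend, optionally on
residuals from a linear adjustment (sex as indicator, CPD, duration).
Box–Cox exponents for covariate transformation maximize the profile
log-likelihood over λ ∈ [−2, 2] by bounded scalar optimization with
tolerance 1e-4; λ = 0 means log.

## Dose–response mediation

Excess risk follows the power law `risk ∝ (CPD + 6)² · d^4.5`, with d the
*effective smoking duration* in years. In the original formulation d is
age − 22.5 for men aged 40–79 smoking < 40 CPD; this package works in
effective duration because the mediating hypothesis is that genotype
lengthens smoking, not age. Only ratios are used, so the proportionality
constant cancels. A scenario (baseline CPD and duration, per-allele shifts)
maps to a predicted per-allele relative risk, and
`fraction_explained = ln(predicted)/ln(observed)` quantifies how much of an
observed per-allele OR the exposure pathway accounts for (≥ 1 means fully).
Model risk ratios are compared directly with case-control odds ratios under
the rare-disease approximation; this is documented, not hidden.

Baselines are explicit required inputs. The CLI default scenario — baseline
20 CPD / 30 years, +1.0 CPD and +1.0 year per allele — is an assumption:
the literature's "9% for a 1.2-CPD homozygote difference" figure is only
consistent with a baseline near 20–21 CPD, and no source states the
baseline explicitly. At these defaults the predicted per-allele relative
risk is (27/26)²·(31/30)^4.5 ≈ 1.25.

## Attributable and familial risk

Per-locus PAR is `p(OR−1)/(p(OR−1)+1)` with p the control risk-allele
frequency (the population proxy the formula defines). Loci combine as
`1 − Π(1 − PARₖ)` under multiplicative independence; this convention
reproduces the ≈30% two-locus figure from (0.36, 1.43) and (0.77, 1.32),
and per-locus values are always reported so an additive reading stays
auditable. A protective OR < 1 yields a negative PAR with a warning.

The familial relative risk attributable to a heritable binary exposure uses
a liability-threshold formalization (the cited methodology is
reference-only in the source literature; this concrete model is the
package's own testable stand-in): relatives' exposure liabilities are
standard bivariate normal with correlation r = relatedness·h², the
threshold is set by exposure prevalence, disease risk is b·RR if exposed
else b, and FRR = E[risk₁·risk₂]/E[risk]², which is independent of b. The
orthant probability comes from the bivariate normal CDF (Genz adaptive
quadrature); tests cross-check it against 10⁶-draw Monte-Carlo sampling.
Under pure additivity both sibling and parent-offspring pairs use r = h²/2;
dominance is out of scope. At h² = 0.6 and exposed-disease RR 30, the FRR
declines from ≈1.64 at 10% exposure prevalence to ≈1.40 at 25%; the
often-quoted ≈1.4 corresponds to the upper end of the 10–25% prevalence
range.

## Meta-analysis

Studies enter on the log-OR scale. From genotype counts the study effect is
the allelic 2×2 log OR (risk vs non-risk allele counts) with Woolf SE —
allelic pooling is used because published raw data are genotype frequency
tables; zero allele cells get the 0.5 correction with a flag. Fixed-effect
pooling is inverse-variance; random effects are DerSimonian–Laird
(method-of-moments, τ² clipped at 0; REML deliberately out of scope), with
Cochran's Q, I² = max(0, (Q−(k−1))/Q), and a χ²(k−1) heterogeneity p.
Egger's test regresses the standardized effect y/se on precision 1/se and
t-tests the intercept with k−2 df; if every SE is identical the design is
rank-deficient and the test degenerates, by construction, to a one-sample
t-test of the mean standardized deviation (k−1 df). Leave-one-out re-pools
k times; funnel data (log OR, SE) export losslessly to TSV at full double
precision. Sub-populations of one publication are treated as separate
studies. The pooling arithmetic is cross-checked against statsmodels'
`combine_effects` in the tests, which never substitutes for the
implementation.

## Synthetic cohorts

The generator emulates a case-control study of a smoking-related disease
under an indirect-effect causal model: genotypes at Hardy–Weinberg
proportions; smokers' CPD log-normal with the raw mean shifted by
β_cpd per allele (the log-mean shift `log1p(β·g/μ)` makes the raw-scale
mean shift exact); effective duration uniform over the age window plus
β_dur per allele; disease probability for smokers
`baseline · RR_smoking · ((CPD+6)/26)² · (d/30)^4.5 · exp(direct·g)` and
`baseline · exp(direct·g)` for never-smokers; ascertainment by rejection
sampling from a source population sized from a 20,000-subject pilot
prevalence estimate (transparent outcome-dependent sampling at desk scale,
deliberately not the faster analytic alternative). One seed drives a
`SeedSequence`-spawned sub-stream per generative stage, so adding a stage
never perturbs earlier draws and identical seeds give byte-identical CSVs.
Defaults mirror a typical cohort of this kind: population never-smoker
fraction 0.37, baseline smoker mean 18 CPD, log-scale SD 0.45 — case means
near 23 CPD and case never-smoker fractions near 5% then *emerge* from the
dose-dependent ascertainment rather than being imposed.

**The end-to-end consistency experiment** (and its test) generates cohorts
with behavioural effects only (+1.0 CPD, +1.0 year per allele, direct
effect 0) at baseline 20 CPD with ages 47.5–57.5, i.e. effective durations
uniform on 25–35 years centred on the 30-year baseline. The narrow age
window is deliberate: the point-baseline prediction
(27/26)²·(31/30)^4.5 ≈ 1.25 applies to the *marginal* per-allele risk ratio
only when the duration spread is modest, because d^4.5 is convex — a wide
spread (e.g. durations 20–40) moves the effective baseline upward and
shrinks the marginal log risk ratio by ≈7%, a model property, not an
estimation artefact. With the ±5-year window the residual convexity gap is
≈0.7% in log risk, well inside Monte-Carlo resolution at the experiment's
scale (150 replicate cohorts of 1,000 cases / 1,000 controls; disease kept
rare, prevalence < 1%, so OR ≈ RR). The never-smoker stratum of the same
cohorts carries no genotype effect by construction and its trend test
rejects at the nominal 5% rate — the computational restatement of the
indirect-effect conclusion.

What passing these tests shows: the chain genotype → exposure →
dose-response risk → observed per-allele OR is internally consistent at
realistic effect sizes. What it does not show: anything about measurement
error in self-reported smoking, population stratification, genotyping
error, differential misclassification between cases and controls, or
age/period structure in real smoking histories — none of which the
generator models.

## Numerical and interface conventions

- P-values two-sided throughout; significance language uses 0.05.
- Full double precision in all serialized output; rounding only in
  human-readable summaries and in comparisons against printed values
  (which round to the published decimals).
- JSON reports are key-sorted and carry a schema version; identical inputs
  produce byte-identical reports.
- Count/study tables are TSV, individual records CSV (case-insensitive
  enums; never-smokers with CPD flagged; malformed values reported with
  line numbers), reports JSON. No binary formats.
- `scripts/acceptance.py` recomputes the per-allele ORs and the combined
  PAR from the shipped count tables at run time.

## Known limitations

- The mediation calculation is a dose-response sufficiency argument, not a
  counterfactual mediation decomposition (no natural direct/indirect
  effects).
- The familial-risk model is a deliberately simple liability-threshold
  formalization; assortative mating, dominance and shared environment are
  ignored.
- Allelic 2×2 pooling assumes within-study HWE; per-study per-allele
  logistic pooling would differ slightly for strongly non-HWE studies.
- The exact trend p switches to asymptotic above N = 30; near the boundary
  the two can differ by a few hundredths on unbalanced tables.
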