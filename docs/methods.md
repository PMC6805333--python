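# Methods

## Model and procedure

The pipeline treats a corpus of narrative case reports as a collection of
independent Bernoulli observations per outcome. For an analysis set of n
cases and an outcome with k positive cases, the evidence that therapy
modifies the outcome is assessed by the exact one-sided binomial test of
H₀: π ≤ p₀ against π > p₀, where π is the probability that a published case
shows the modification and p₀ is a futility boundary. The default
p₀ = 0.05 mirrors phase-II futility conventions: a response rate at or below
5% is treated as indistinguishable from no effect. p-values are exact upper
tails, P(X ≥ k) for X ~ Binomial(n, p₀), computed via `scipy.stats.binom.sf`
(an independent rational-arithmetic summation oracle pins them to 1e-12 in
the tests).

Key modelling commitments, all conservative for declaring an effect:

* **Denominator invariance.** Every outcome uses the full analysis-set size n
  as denominator. An outcome not reported in a case is counted as *not
  modified* — unreported outcomes cannot generate evidence.
* **Scoring.** The strong confirmatory method requires the improvement to be
  documented (evaluation method described or quantitative measure reported);
  the weak method requires only a mention. Harm outcomes come in two shapes:
  dose-change outcomes (IRRs) count only events that forced a dose change and
  score identically under both methods; documented-event harms (antibody
  development) follow the benefit-shaped rule. The antibody rule is chosen so
  that the published strong and weak counts (both 6/44) are reproduced by the
  same flag semantics rather than a bespoke laboratory-confirmation rule.
* **Multiplicity.** Benjamini–Hochberg at q = 0.10 across the nr = 11
  outcomes. Critical values are c_r = (r/nr)·q. Ranks are *dense* over the
  sorted p-values and tied p-values (identical counts) share the minimum rank
  of their group, which assigns the smallest — most conservative — critical
  value; ties are detected by exact equality, which is safe because equal
  counts give bit-identical p-values. The default `per_rank` rule accepts an
  outcome iff its own p ≤ c_r; the orthodox step-up rule (largest sorted
  position with p ≤ c) is available as `ClassificationRule.STEP_UP` because
  the two can diverge on non-monotone configurations, though they agree on
  every corpus analyzed here (asserted in tests, with the step-up route
  cross-checked against `statsmodels.multipletests`).

## Concordance with the gold standard

The gold standard is the per-outcome SOE grade from a meta-analysis of
clinical studies, dichotomized as moderate-to-high (positive) vs
low-to-insufficient (negative); the case-report side is the
acceptable/unacceptable evidence label. Validity indices are plain
proportions from the 2×2 table with exact Clopper–Pearson intervals
(`statsmodels proportion_confint(method="beta")`); indices with an empty
margin are returned as explicitly undefined rather than NaN. Percent display
rounds halves away from zero (10/11 → 91%, 2/3 → 67%, 8/9 → 89%).

Relative agreement uses the tie-corrected Spearman coefficient: midranks
(mean rank over each tie group) of the per-outcome positive counts and of the
ordinal SOE scores (insufficient=1 … high=4), then the product-moment
correlation of the midranks. With the heavy ties in both vectors this is the
appropriate estimator; the no-tie shortcut 1 − 6Σd²/(n(n²−1)) gives 0.83
rather than the tie-corrected 0.82 on the primary data. The CI uses the
Fisher z transform with SE 1/√(n−3) and the normal quantile, defined only
for |ρ| < 1 and n > 3.

## The MPS-II fixture: a reconstruction

The published analysis prints only marginal quantities — per-outcome
positive counts in the 44-case primary set under both scoring methods, set
sizes for four analysis sets, and the sets' confusion tables and agreement
coefficients. Case-level flags were never published. The packaged corpus is
therefore a *construction* satisfying all printed marginals simultaneously;
the assignment of positives to specific cases is arbitrary and frozen
(`casemeta.mpsii.reconstruct_corpus` rebuilds it deterministically and the
shipped CSV is asserted equal to it in tests).

Two published values cannot be satisfied and are documented rather than
forced:

* **Publication totals.** 56 cases over 38 publications is arithmetically
  incompatible with the nested primary set of 44 cases over 25 publications:
  the 12 post-cutoff cases would need 13 publications. The reconstruction
  keeps all case counts (56/44/36/33) and the per-set publication counts
  (25/21/22), giving 37 total publications.
* **One inconsistent p-value.** The weak-method table prints p = 0.014 for
  quality of life at 8/44 while the strong-method table prints 0.001 for the
  same count; exact computation gives 0.0015, and the pipeline reports that.
  (Two critical values in the weak table are also printed swapped; exact
  r/nr·q values are used.) Neither discrepancy affects any classification.

Counts for the three sensitivity sets (n = 56, 36, 33) are likewise not
printed per outcome. They were fixed to reproduce the published confusion
tables exactly and to preserve the ordering/tie pattern of the primary
counts, which makes the tie-corrected ρ of each set match its published
value (0.83 for all cases, 0.82 otherwise). Congress communications carry
4 of the 6 antibody positives, so excluding them drops antibody development
below its critical value — the one published disagreement (accuracy 91%).

## Synthetic corpora

`SimulationScenario` draws, per case and outcome, improvement ~
Bernoulli(true_modification_prob); an improvement is documented at strong
level with probability `prob_strong_documentation_given_improvement`
(default 0.7), else only mentioned; a non-improvement is reported as
unchanged with probability `prob_reported_given_no_improvement` (default
0.2), else omitted. A case with no positive observation is dropped with
probability `publication_bias` — the mechanism by which observed positive
proportions exceed true rates in a literature that prefers positive
single-case results. Outcomes are independent within a case by default; an
optional logit-normal per-case severity factor (`case_severity_sd`) induces
positive dependence and is off by default because the real corpus offers no
dependence information to calibrate it. Generated corpora satisfy all
data-model invariants, and every replicate in
`operating_characteristics` gets its own child seed from a
`numpy.random.SeedSequence`, so replicate r is reproducible independently of
the replicate count.

The generator emulates counts, documentation levels, reporting gaps and
publication bias; it does not emulate narrative text, outcome correlation
structure beyond the optional severity factor, dosing heterogeneity, or
time-to-event structure. Passing operating-characteristic tests therefore
demonstrate control of the procedure under the stated sampling model, not
robustness to those unmodelled features.

Operating-characteristic runs in the test suite use 2000 replicates for the
global-null FDR check (every per-outcome rejection rate stays below
q + 3 Monte-Carlo SEs) and 1000 for the power check (a 0.45-probability
outcome is detected in >99% of replicates); the null scenario sets the
strong-documentation probability to 1 and negative-reporting to 0 so that
the scored count is exactly Binomial(n, p₀). The `analysis/05` driver
defaults to 500 replicates.

## Degenerate inputs and numerical choices

* Empty analysis sets are legal: counts are (0, 0) and downstream tests are
  simply not run; `classify_evidence` requires a non-empty outcome list and a
  shared denominator.
* `clopper_pearson_interval` with zero trials, Spearman with a constant
  vector, and Fisher-z with |ρ| = 1 or n ≤ 3 return explicit
  undefined-result values (`None`) instead of raising.
* p-value display uses "< 0.0001" below 1e-4 and three decimals otherwise;
  all arithmetic is done at full double precision.
* Dates are ISO-8601; the primary-set cutoff 2015-12-31 (the gold standard's
  search date) is inclusive. Aggregated-form cases are representable but
  excluded from every analysis set by default.
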