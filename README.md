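# casemeta

Quantitative meta-analysis of narrative case reports in rare diseases.

In diseases too rare for randomized trials, most published evidence for a
therapy lives in single-patient case reports, which evidence grading normally
treats qualitatively. `casemeta` implements a quantitative aggregation
pipeline and validates it on the corpus of 56 published case reports of males
with mucopolysaccharidosis type II (Hunter syndrome) treated with idursulfase
enzyme replacement therapy (ERT), shipped with the package as a reconstructed
fixture.

## The method

For each of 11 pre-specified outcomes, count the case reports in an analysis
set of *n* cases that show an outcome modification, under one of two scoring
rules:

* **strong confirmatory method** — an efficacy outcome counts as improved only
  if the report describes the evaluation method or gives a quantitative
  measure; infusion-related reactions (IRRs) count only when they forced an
  ERT dose change;
* **weak confirmatory method** — a mere mention of improvement suffices.

Outcomes not reported in a case are conservatively counted as not improved.
Each count k is tested one-sided against a futility boundary p₀ (default 5%):

&nbsp;&nbsp;&nbsp;&nbsp;p = P(X ≥ k), X ~ Binomial(n, p₀)

Multiplicity over the nr outcomes is controlled with Benjamini–Hochberg
critical values c_r = (r / nr)·q at FDR level q = 10%, with dense
minimum-rank ties (the conservative choice). An outcome whose p-value is at
or below its critical value lands in the **acceptable evidence** group.

The classification is then validated against an independent gold standard:
the strength-of-evidence (SOE) grades (insufficient/low/moderate/high) that a
meta-analysis of clinical studies assigned to the same outcomes. Agreement is
summarized by a 2×2 table (acceptable evidence vs moderate-to-high SOE) with
sensitivity, specificity, predictive values and accuracy (exact
Clopper–Pearson 95% CIs), and by the tie-corrected (midrank) Spearman
correlation between positive counts and ordinal SOE scores with a Fisher-z
interval.

A synthetic-corpus generator (`casemeta.simulate`) makes the assumed
data-generating process explicit — per-outcome true modification
probabilities, a documentation-level model, optional reporting of negative
outcomes, and a publication-bias mechanism that suppresses all-negative
cases — and drives operating-characteristic studies of the whole procedure.

## Worked example

```bash
casemeta classify --set primary --method strong
```

prints the primary-set evidence table (44 cases from 25 publications):

```
 rank                              outcome positives  p_value fdr_critical_value evidence_group
    1              Urinary GAGs (Moderate)     20/44 < 0.0001              0.009     acceptable
    2              Liver volume (Moderate)      8/44    0.001              0.018     acceptable
    3      Antibody development (Moderate)      6/44    0.022              0.027     acceptable
    4                6-min walk test (Low)      4/44    0.177              0.036   unacceptable
    4 Joint range of motion (Insufficient)      4/44    0.177              0.036   unacceptable
    5                Growth (height) (Low)      3/44    0.379              0.045   unacceptable
    6     Infusion-related reactions (Low)      2/44    0.653              0.055   unacceptable
    7      Pulmonary function (FVC%) (Low)      1/44    0.895              0.064   unacceptable
    8      Cardiac function (Insufficient)      0/44        1              0.073   unacceptable
    8       Quality of life (Insufficient)      0/44        1              0.073   unacceptable
    8           Sleep apnea (Insufficient)      0/44        1              0.073   unacceptable
```

Only urinary glycosaminoglycans (20/44 positive cases), liver volume (8/44)
and antibody development (6/44) beat their FDR critical values — exactly the
three outcomes the clinical-study gold standard graded moderate SOE.
`casemeta concordance` quantifies that agreement:

```
true_positives                     3
false_positives                    0
false_negatives                    0
true_negatives                     8
accuracy           100% (72 to 100%)
sensitivity        100% (29 to 100%)
specificity        100% (63 to 100%)
ppv                100% (29 to 100%)
npv                100% (63 to 100%)
spearman_rho                    0.82
spearman_rho_95ci       0.43 to 0.95
```

i.e. perfect 2×2 concordance and good relative agreement (ρ = 0.82) between
how often an outcome improved in case reports and how strongly clinical
studies supported it. `casemeta sweep` re-runs the pipeline over the four
analysis sets and over futility boundaries 1–20% (`--boundaries`), and
`casemeta simulate` estimates rejection rates on synthetic corpora.

The numbered drivers under `analysis/` run the same steps as a narrative
sequence (corpus overview → evidence tables → concordance → sensitivity →
operating characteristics) and write their tables under `results/`.

## Caveat on the fixture

Case-level flags for the MPS-II corpus were never published; the shipped
fixture is a *reconstruction* that reproduces every published marginal
(per-outcome counts in all four analysis sets, set sizes, confusion tables).
Which individual case carries which positive is arbitrary and frozen. See
`docs/methods.md` for details and for one publication-count inconsistency in
the published totals.
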