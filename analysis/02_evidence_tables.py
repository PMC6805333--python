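#!/usr/bin/env python
"""Evidence classification of the 11 outcomes, strong and weak methods.

For the 44-case primary set, tests each outcome's positive-case count
against the 5% futility boundary (one-sided exact binomial) and
classifies outcomes into acceptable/unacceptable evidence at FDR 10%.
Under the strong confirmatory method three outcomes reach acceptable
evidence (urinary GAGs, liver volume, antibody development); the weak
method adds the 6-min walk test and quality of life.  Writes
results/evidence_{strong,weak}.csv.
"""

from pathlib import Path

from casemeta import apply_analysis_set, classify_evidence, count_all_positives
from casemeta import mpsii, report
from casemeta.evidence import ClassificationConfig
from casemeta.scoring import ScoringMethod

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    corpus = mpsii.load_corpus()
    primary = apply_analysis_set(corpus, mpsii.PRIMARY_SET)
    print(primary.provenance)
    OUT.mkdir(exist_ok=True)
    for method in ScoringMethod:
        counts = count_all_positives(primary, method)
        rows = classify_evidence(counts, ClassificationConfig())
        table = report.evidence_table(rows, primary.outcomes)
        dest = OUT / f"evidence_{method.value}.csv"
        table.to_csv(dest, index=False)
        acceptable = sorted(r.outcome_id for r in rows if r.acceptable)
        print(f"\n{method.value} confirmatory method -> acceptable: {acceptable}")
        print(table.to_string(index=False))
        print(f"wrote {dest}")


if __name__ == "__main__":
    main()
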