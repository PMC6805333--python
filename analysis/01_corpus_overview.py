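#!/usr/bin/env python
"""Corpus overview: analysis-set sizes of the MPS-II case-report corpus.

Loads the packaged 56-case corpus and reports how many cases and
publications survive each analysis-set filter (primary date-cutoff set,
all cases, excluding gold-standard-overlap publications, excluding
congress communications).  Writes results/analysis_sets.csv.
"""

from pathlib import Path

import pandas as pd

from casemeta import apply_analysis_set
from casemeta import mpsii

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    corpus = mpsii.load_corpus()
    print(f"corpus: {corpus.n_cases} cases from {corpus.n_publications} publications")
    records = []
    for name, spec in mpsii.ANALYSIS_SETS.items():
        sub = apply_analysis_set(corpus, spec)
        print(" ", sub.provenance)
        records.append(
            {"analysis_set": name, "cases": sub.n_cases, "publications": sub.n_publications}
        )
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(records).to_csv(OUT / "analysis_sets.csv", index=False)
    print(f"wrote {OUT / 'analysis_sets.csv'}")


if __name__ == "__main__":
    main()
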