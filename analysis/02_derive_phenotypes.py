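#!/usr/bin/env python
"""Baseline selection and derived phenotypes.

Keeps the earliest visit of each genotyped individual, derives mean arterial
pressure (MAP = 2/3 DBP + 1/3 SBP) and the pulse gap (SBP - DBP), and writes
a descriptive table in the usual mean +/- SD / n (%) layout.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from towpath import io as tio  # noqa: E402
from towpath.phenotypes import (  # noqa: E402
    derive_phenotypes,
    descriptive_stats,
    format_descriptives,
    select_baseline,
)

FIXTURE_DIR = ROOT / "scratch" / "fixture"
RESULTS = ROOT / "results"


def main() -> None:
    cohort = tio.read_cohort_tsv(FIXTURE_DIR / "cohort.tsv")
    baseline = select_baseline(cohort, require_genotyped=True)
    derived = derive_phenotypes(baseline)
    tio.write_cohort_tsv(derived, FIXTURE_DIR / "cohort_derived.tsv")

    stats = descriptive_stats(derived)
    RESULTS.mkdir(exist_ok=True)
    stats.to_csv(RESULTS / "02_descriptives.tsv", sep="\t", index=False)

    print(f"baseline: {cohort['individual_id'].nunique()} individuals in, "
          f"{len(derived)} genotyped retained, {int(derived['bp_flagged'].sum())} flagged")
    print(format_descriptives(stats))


if __name__ == "__main__":
    main()
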