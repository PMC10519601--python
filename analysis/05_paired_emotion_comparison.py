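#!/usr/bin/env python
"""Stage 5 — within-user emotion comparison (MH vs non-MH posts).

For users with at least four ≥25-word posts in each context, compares the
per-user mean category scores between MH and non-MH posts via dependent
t-tests (Bonferroni-corrected for the five categories) with paired Cohen's
d. Expected from the planted emission rates: less positive emotion, more
anxiety, sadness, and first-person singular in MH-community posts, anger
essentially flat.
"""

from pathlib import Path

from bdforum.aggregate import read_records_tsv, select_rq2
from bdforum.pipeline import _write_rq2_tsv
from bdforum.stats import rq2_table

OUT = Path("results/analysis")


def main() -> None:
    records = read_records_tsv(OUT / "user_records.tsv")
    sample = select_rq2(records)
    table = rq2_table(sample)
    _write_rq2_tsv(table, OUT / "rq2_table.tsv")

    print(f"paired sample: {len(sample)} users with >=4 scored posts in each context")
    print(f"{'variable':<10} {'MH mean':>8} {'nonMH':>8} {'d_z':>7} {'p_bonf':>9}  interpretation")
    for row in table:
        print(f"{row.variable:<10} {row.mean_mh:>8.2f} {row.mean_nonmh:>8.2f} "
              f"{row.d_z:>7.2f} {row.p_bonf:>9.2g}  {row.interpretation}")


if __name__ == "__main__":
    main()
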