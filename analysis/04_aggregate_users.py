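#!/usr/bin/env python
"""Stage 4 — aggregate to user level and partition posting patterns.

Builds one record per cohort user (context-stratified mean scores over
≥25-word posts, activity controls, the MH-posting outcome) and computes the
posting-pattern partition: who posts only in MH communities, only outside
them, or in both, with the active-contributor (≥4 MH posts) and ≥8-post
strata.
"""

from pathlib import Path

from bdforum.aggregate import build_user_records, partition_rq1, write_partition, write_records_tsv
from bdforum.cohort import INCLUDED
from bdforum.corpus import read_attributes, read_posts
from bdforum.lexicon import default_lexicon, score_text
from bdforum.taxonomy import classify, fixture_taxonomy

OUT = Path("results/analysis")


def main() -> None:
    cohort = set()
    with open(OUT / "cohort_decisions.tsv", encoding="utf-8") as handle:
        next(handle)
        for line in handle:
            author, status, _ = line.rstrip("\n").split("\t")
            if status == INCLUDED:
                cohort.add(author)

    taxonomy = fixture_taxonomy()
    lexicon = default_lexicon()
    triples = [
        (p, classify(p.subreddit, taxonomy), score_text(p.body, lexicon))
        for p in read_posts(OUT / "corpus.jsonl")
    ]
    attributes = read_attributes(OUT / "attributes.tsv")
    records = build_user_records(cohort, triples, attributes)
    write_records_tsv(records, OUT / "user_records.tsv")

    part = partition_rq1(records)
    write_partition(part, OUT / "rq1_partition.json", OUT / "rq1_partition.tsv")
    props = part.proportions
    print(f"built {len(records)} user records")
    print(f"posting partition: {100 * props['both']:.1f}% both, "
          f"{100 * props['only_mh']:.1f}% only MH, "
          f"{100 * props['only_nonmh']:.1f}% only non-MH")
    print(f"active contributors in both contexts (>=4 posts each): {part.n_both_active}")


if __name__ == "__main__":
    main()
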