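#!/usr/bin/env python
"""Stage 2 — mine the diagnosis cohort.

Scans every author's posts for bipolar-diagnosis statements, exclusion
phrases ("not officially diagnosed", "self-diagnosed", ...) and
psychotic-disorder comorbidity statements, and decides cohort membership.
Verifies the decisions against the planted ground truth from stage 1.
"""

import json
from collections import Counter
from pathlib import Path

from bdforum.cohort import build_cohort, default_patterns, write_decisions_tsv
from bdforum.corpus import read_posts

OUT = Path("results/analysis")


def main() -> None:
    posts = list(read_posts(OUT / "corpus.jsonl"))
    cohort, decisions, summary = build_cohort(posts, default_patterns())
    write_decisions_tsv(decisions, OUT / "cohort_decisions.tsv")

    reasons = Counter(d.reason for d in decisions.values())
    print(f"corpus: {summary.n_posts} posts by {summary.n_users} users")
    print(f"included: {len(cohort)} users; decision reasons: {dict(reasons)}")

    truth = json.loads((OUT / "planted_truth.json").read_text())
    clean = {
        a for a, u in truth["users"].items()
        if not (u["has_exclusion_phrase"] or u["has_psychotic_statement"])
    }
    agreement = cohort == clean
    print(f"matches planted ground truth: {agreement}")
    if not agreement:
        raise SystemExit("cohort decisions diverge from planted truth")


if __name__ == "__main__":
    main()
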