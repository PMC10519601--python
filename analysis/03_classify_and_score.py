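#!/usr/bin/env python
"""Stage 3 — classify post contexts and score affect.

Labels every post MH / non-MH via the subreddit taxonomy and computes the
five dictionary category percentages (positive emotion, anxiety, anger,
sadness, first-person singular) plus word count per post.
"""

from pathlib import Path

from bdforum.corpus import read_posts
from bdforum.lexicon import MIN_WORDS, default_lexicon, score_text, write_scores_tsv
from bdforum.taxonomy import MH, classify, fixture_taxonomy, write_classification_tsv

OUT = Path("results/analysis")


def main() -> None:
    taxonomy = fixture_taxonomy()
    lexicon = default_lexicon()
    posts = list(read_posts(OUT / "corpus.jsonl"))

    contexts = [(p.id, p.subreddit, classify(p.subreddit, taxonomy)) for p in posts]
    write_classification_tsv(contexts, OUT / "post_contexts.tsv")
    scores = [(p.id, score_text(p.body, lexicon)) for p in posts]
    write_scores_tsv(scores, OUT / "post_scores.tsv")

    n_mh = sum(1 for _, _, c in contexts if c == MH)
    n_scored = sum(1 for _, s in scores if s.wc >= MIN_WORDS)
    print(f"classified {len(posts)} posts: {n_mh} MH, {len(posts) - n_mh} non-MH")
    print(f"{n_scored} posts pass the >= {MIN_WORDS}-word reliability filter "
          f"({100 * n_scored / len(posts):.1f}%)")


if __name__ == "__main__":
    main()
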