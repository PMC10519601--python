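#!/usr/bin/env python
"""Stage 1 — simulate the study corpus.

Generates the default synthetic forum corpus: 500 users with a self-reported
bipolar-disorder diagnosis statement each, a 76/24 split between users who do
and do not post in mental-health (MH) communities, per-context affect-token
emission rates mirroring the qualitative structure of real cohorts, and a
small rate of exclusion-phrase / psychotic-statement contamination for the
cohort filter to catch. Writes the corpus, the user-attribute table, and the
planted ground truth under results/analysis/.
"""

import json
from pathlib import Path

import numpy as np

from bdforum.corpus import write_attributes, write_posts
from bdforum.synth import SynthConfig, generate, plant_contamination

OUT = Path("results/analysis")
SEED = 11

config = SynthConfig(
    n_users=500,
    seed=SEED,
    tokens_per_post=60.0,
    p_excluded_phrase=0.05,
    p_psychotic_comorbid=0.03,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    posts, attributes, truth = generate(config)
    posts = plant_contamination(posts, truth, config, np.random.default_rng(SEED + 1))
    n = write_posts(posts, OUT / "corpus.jsonl")
    write_attributes(attributes, OUT / "attributes.tsv")
    with open(OUT / "planted_truth.json", "w", encoding="utf-8") as handle:
        json.dump(truth.to_jsonable(), handle, indent=2, sort_keys=True)
        handle.write("\n")
    n_contaminated = config.n_users - len(truth.clean_authors())
    print(f"simulated {n} posts for {config.n_users} users (seed {SEED})")
    print(f"planted contamination: {n_contaminated} users carry an exclusion or "
          f"psychotic-disorder statement")


if __name__ == "__main__":
    main()
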