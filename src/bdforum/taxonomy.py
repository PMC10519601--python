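"""Subreddit → context classification from a topic taxonomy table.

Every analysis downstream consumes a binary context per post — MH (the
community is mental-health focused) or non-MH — with an additional
bipolar-specific flag carried for descriptive summaries. The taxonomy is an
input CSV (name, up to four topic levels, is_mh, is_bd); communities absent
from the table count as non-MH, the table being the positive filter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

MH = "MH"
NON_MH = "nonMH"

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class TaxonomyEntry:
    topic_path: tuple[str, ...]
    is_mh: bool
    is_bd: bool


@dataclass
class SubredditTaxonomy:
    """Normalised-name → entry map with provenance."""

    entries: dict[str, TaxonomyEntry]
    provenance: str = "unknown"

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def mh_names(self) -> set[str]:
        return {n for n, e in self.entries.items() if e.is_mh}

    @property
    def bd_names(self) -> set[str]:
        return {n for n, e in self.entries.items() if e.is_bd}


def normalise_name(name: str) -> str:
    return name.strip().lower()


def load_taxonomy(path: str | Path) -> SubredditTaxonomy:
    """Load a taxonomy CSV (header: name,level1..level4,is_mh,is_bd).

    Names are lower-cased and trimmed; a duplicate normalised name or a
    bipolar flag without the MH flag is an error.
    """
    entries: dict[str, TaxonomyEntry] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        required = {"name", "is_mh", "is_bd"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"taxonomy header must contain {sorted(required)}")
        for row in reader:
            name = normalise_name(row["name"])
            if name in entries:
                raise ValueError(f"duplicate subreddit name after normalisation: {name!r}")
            is_mh = row["is_mh"].strip() == "1"
            is_bd = row["is_bd"].strip() == "1"
            if is_bd and not is_mh:
                raise ValueError(f"{name!r}: is_bd requires is_mh")
            topic = tuple(
                row.get(f"level{i}", "").strip()
                for i in range(1, 5)
                if row.get(f"level{i}", "").strip()
            )
            entries[name] = TaxonomyEntry(topic_path=topic, is_mh=is_mh, is_bd=is_bd)
    return SubredditTaxonomy(entries=entries, provenance=str(path))


def fixture_taxonomy() -> SubredditTaxonomy:
    """The small bundled taxonomy used by tests and the synthetic generator."""
    return load_taxonomy(_DATA_DIR / "fixture_taxonomy.csv")


def classify(subreddit: str, tax: SubredditTaxonomy) -> str:
    """``MH`` iff the normalised name is a taxonomy entry flagged MH."""
    entry = tax.entries.get(normalise_name(subreddit))
    return MH if entry is not None and entry.is_mh else NON_MH


def classify_posts(posts: Iterable, tax: SubredditTaxonomy) -> list[tuple[object, str]]:
    """Pair each post with its context; the MH/non-MH split partitions the corpus."""
    return [(post, classify(post.subreddit, tax)) for post in posts]


def write_classification_tsv(rows: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Export a per-post classification join as TSV (id, subreddit, context)."""
    n = 0
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("id\tsubreddit\tcontext\n")
        for post_id, subreddit, context in rows:
            handle.write(f"{post_id}\t{subreddit}\t{context}\n")
            n += 1
    return n
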