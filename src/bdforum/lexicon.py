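"""Dictionary-based affect scoring of post texts.

A text's score for a category is the percentage of its tokens that match the
category's word list, the operationalisation used by closed-vocabulary text
analysis tools of the LIWC family: single-post scores are read as
in-the-moment *emotion*, scores averaged over many posts as *mood*. Five
categories are carried: positive emotion (``posemo``), ``anxiety``,
``anger``, ``sadness``, and first-person singular pronouns (``i``).

Entries are literal lower-case words or stems with a trailing ``*`` wildcard
(``worri*`` matches ``worried``, ``worrying``). A token may score in several
categories, but counts at most once per category; the word-count denominator
is all tokens, dictionary or not. Texts under 25 tokens are conventionally
excluded from analysis because percentage estimates on very short texts are
unreliable (:func:`filter_min_words`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

logger = logging.getLogger(__name__)

CATEGORIES = ("posemo", "anxiety", "anger", "sadness", "i")

#: Minimum token count for a post to enter any analysis.
MIN_WORDS = 25

_DATA_DIR = Path(__file__).parent / "data"

# Tokens are whitespace-separated; leading/trailing punctuation is stripped
# while internal apostrophes survive ("don't" is one token).
_EDGE_PUNCT = re.compile(r"^[\W_]+|[\W_]+$", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lower-cased whitespace tokens with edge punctuation stripped.

    Pure-punctuation fragments are dropped; numerals count as tokens.
    Apostrophes inside a word are kept, so contractions stay intact.
    """
    tokens = []
    for raw in text.lower().split():
        tok = _EDGE_PUNCT.sub("", raw)
        if tok:
            tokens.append(tok)
    return tokens


@dataclass(frozen=True)
class CategoryScores:
    """Word count and the five category percentages for one text."""

    wc: int
    posemo: float
    anxiety: float
    anger: float
    sadness: float
    i: float

    @property
    def usable(self) -> bool:
        return self.wc > 0

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in CATEGORIES}


@dataclass
class Lexicon:
    """Affect dictionary: per-category literal words and ``*``-stems."""

    entries: dict[str, list[str]]
    version: str = "unversioned"
    _literals: dict[str, frozenset[str]] = field(init=False, repr=False)
    _stems: dict[str, tuple[str, ...]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if not self.entries.get(c)]
        if missing:
            raise ValueError(f"lexicon categories empty or absent: {missing}")
        self._literals = {}
        self._stems = {}
        for cat in CATEGORIES:
            lits, stems = [], []
            for entry in self.entries[cat]:
                if entry != entry.lower():
                    raise ValueError(f"lexicon entry not lower-case: {entry!r}")
                if "*" in entry[:-1]:
                    raise ValueError(f"wildcard only allowed in final position: {entry!r}")
                if entry.endswith("*"):
                    stems.append(entry[:-1])
                else:
                    lits.append(entry)
            self._literals[cat] = frozenset(lits)
            self._stems[cat] = tuple(stems)

    def categories_of(self, token: str) -> list[str]:
        """All categories a token scores in (literal equality or stem prefix)."""
        hits = []
        for cat in CATEGORIES:
            if token in self._literals[cat] or any(
                token.startswith(s) for s in self._stems[cat]
            ):
                hits.append(cat)
        return hits


def score_text(text: str, lexicon: Lexicon) -> CategoryScores:
    """Score one text: percentage of tokens matching each category."""
    tokens = tokenize(text)
    return score_tokens(tokens, lexicon)


def score_tokens(tokens: Sequence[str], lexicon: Lexicon) -> CategoryScores:
    """Score an already-tokenised text (tokens must be lower-case)."""
    wc = len(tokens)
    counts = dict.fromkeys(CATEGORIES, 0)
    cache: dict[str, list[str]] = {}
    for tok in tokens:
        hits = cache.get(tok)
        if hits is None:
            hits = lexicon.categories_of(tok)
            cache[tok] = hits
        for cat in hits:
            counts[cat] += 1
    if wc == 0:
        return CategoryScores(wc=0, posemo=0.0, anxiety=0.0, anger=0.0, sadness=0.0, i=0.0)
    return CategoryScores(wc=wc, **{c: 100.0 * counts[c] / wc for c in CATEGORIES})


def filter_min_words(scored, min_wc: int = MIN_WORDS):
    """Keep exactly the items whose scores report ``wc >= min_wc``.

    ``scored`` is an iterable of (item, CategoryScores) pairs; the kept pairs
    are returned as a list in input order.
    """
    return [(item, s) for item, s in scored if s.wc >= min_wc]


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a native YAML lexicon ({category: [entries]})."""
    with open(path, encoding="utf-8") as handle:
        data = yaml.safe_load(handle)
    version = data.pop("version", str(path))
    return Lexicon(entries={k: list(v) for k, v in data.items()}, version=str(version))


def default_lexicon() -> Lexicon:
    """The bundled open lexicon covering the five categories.

    A deliberately small, shippable word list; any externally licensed
    dictionary in ``.dic`` format can be substituted via :func:`read_dic`.
    """
    return load_lexicon(_DATA_DIR / "default_lexicon.yaml")


# Aliases under which the five target categories appear in common .dic files.
_DIC_ALIASES = {
    "posemo": "posemo",
    "positive_emotion": "posemo",
    "anx": "anxiety",
    "anxiety": "anxiety",
    "anger": "anger",
    "sad": "sadness",
    "sadness": "sadness",
    "i": "i",
    "ppron_i": "i",
}


def read_dic(path: str | Path) -> Lexicon:
    """Read a ``%``-delimited dictionary file, keeping the five categories.

    The format is a header block between two ``%`` lines declaring
    ``<id> <category>`` pairs, followed by ``<word> <id> <id>...`` lines.
    Categories other than the five targets are ignored (count logged);
    a word line referencing an undeclared id is an error.
    """
    with open(path, encoding="utf-8") as handle:
        lines = [ln.strip() for ln in handle]
    try:
        first = lines.index("%")
        second = lines.index("%", first + 1)
    except ValueError as exc:
        raise ValueError("dictionary file must contain a %-delimited header block") from exc

    id_to_cat: dict[str, str] = {}
    ignored_ids = 0
    for ln in lines[first + 1 : second]:
        if not ln:
            continue
        cat_id, _, name = ln.partition("\t") if "\t" in ln else ln.partition(" ")
        name = name.strip().lower()
        target = _DIC_ALIASES.get(name)
        if target is None:
            ignored_ids += 1
            id_to_cat[cat_id.strip()] = ""
        else:
            id_to_cat[cat_id.strip()] = target
    if ignored_ids:
        logger.info("ignored %d non-target categories in %s", ignored_ids, path)

    entries: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for ln in lines[second + 1 :]:
        if not ln:
            continue
        parts = ln.split()
        word, ids = parts[0].lower(), parts[1:]
        for cat_id in ids:
            if cat_id not in id_to_cat:
                raise ValueError(f"word line {word!r} references undeclared category id {cat_id}")
            cat = id_to_cat[cat_id]
            if cat and word not in entries[cat]:
                entries[cat].append(word)
    return Lexicon(entries=entries, version=str(path))


def write_scores_tsv(rows: Iterable[tuple[str, CategoryScores]], path: str | Path) -> int:
    """Export per-post scores as TSV (id, wc, five category percentages)."""
    n = 0
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("id\twc\t" + "\t".join(CATEGORIES) + "\n")
        for post_id, s in rows:
            vals = "\t".join(f"{getattr(s, c):.6g}" for c in CATEGORIES)
            handle.write(f"{post_id}\t{s.wc}\t{vals}\n")
            n += 1
    return n
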