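"""Cohort identification from self-reported diagnosis statements.

A user enters the analysis cohort when at least one of their posts contains a
bipolar-disorder diagnosis statement ("I was diagnosed with bipolar
disorder"), none of their posts contains an exclusion phrase ("not officially
diagnosed", "self-diagnosed", ...), and none reports a psychotic-disorder
diagnosis. A major depressive disorder statement does *not* exclude: a large
share of people eventually diagnosed with bipolar disorder first receive a
depression diagnosis, so only the psychotic-disorder comorbidity (a DSM-5
exclusion criterion that is not part of the typical diagnostic trajectory)
removes a user. Exclusion operates at user level — any post, any time.

Matching is case-insensitive over whitespace-normalised text, with patterns
anchored at word boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

_DATA_DIR = Path(__file__).parent / "data"

INCLUDED = "included"
EXCLUDED = "excluded"

REASON_INCLUDED = "included"
REASON_NO_INCLUSION = "no_inclusion_match"
REASON_EXCLUSION = "exclusion_pattern"
REASON_PSYCHOTIC = "psychotic_comorbidity"

_WS = re.compile(r"\s+")


def _normalise(text: str) -> str:
    return _WS.sub(" ", text).strip()


def _compile(patterns: Sequence[str]) -> list[re.Pattern]:
    return [re.compile(rf"\b(?:{p})\b", re.IGNORECASE) for p in patterns]


@dataclass
class DiagnosisPatternSet:
    """Inclusion / exclusion / other-diagnosis regular-expression patterns."""

    inclusion: list[str]
    exclusion: list[str]
    other_diagnoses: dict[str, list[str]]
    _inc: list[re.Pattern] = field(init=False, repr=False)
    _exc: list[re.Pattern] = field(init=False, repr=False)
    _other: dict[str, list[re.Pattern]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.inclusion or not self.exclusion:
            raise ValueError("inclusion and exclusion pattern lists must be non-empty")
        if "psychotic_disorder" not in self.other_diagnoses:
            raise ValueError("other_diagnoses must contain the key 'psychotic_disorder'")
        for label, pats in self.other_diagnoses.items():
            if not pats:
                raise ValueError(f"empty pattern list for diagnosis {label!r}")
        self._inc = _compile(self.inclusion)
        self._exc = _compile(self.exclusion)
        self._other = {k: _compile(v) for k, v in self.other_diagnoses.items()}


def load_patterns(path: str | Path) -> DiagnosisPatternSet:
    """Load a YAML pattern file (keys inclusion, exclusion, other_diagnoses)."""
    with open(path, encoding="utf-8") as handle:
        data = yaml.safe_load(handle)
    return DiagnosisPatternSet(
        inclusion=list(data["inclusion"]),
        exclusion=list(data["exclusion"]),
        other_diagnoses={k: list(v) for k, v in data["other_diagnoses"].items()},
    )


def default_patterns() -> DiagnosisPatternSet:
    """The shipped default pattern set (documented seed, user-replaceable)."""
    return load_patterns(_DATA_DIR / "default_patterns.yaml")


@dataclass(frozen=True)
class Statement:
    """One matched diagnosis-relevant span."""

    pattern_class: str  # inclusion | exclusion | other
    label: str  # 'bipolar', 'exclusion', or the other-diagnosis label
    span: tuple[int, int]
    text: str


def find_statements(text: str, patterns: DiagnosisPatternSet) -> list[Statement]:
    """All non-overlapping matches, case-insensitive, left-to-right.

    Each pattern class is scanned independently: an exclusion phrase is
    reported regardless of any inclusion match in the same text.
    """
    norm = _normalise(text)
    out: list[Statement] = []

    def scan(compiled: Iterable[re.Pattern], pattern_class: str, label: str) -> None:
        taken: list[tuple[int, int]] = []
        found: list[Statement] = []
        for pat in compiled:
            for m in pat.finditer(norm):
                span = m.span()
                if any(span[0] < e and s < span[1] for s, e in taken):
                    continue
                taken.append(span)
                found.append(
                    Statement(pattern_class=pattern_class, label=label, span=span, text=m.group(0))
                )
        out.extend(found)

    scan(patterns._inc, "inclusion", "bipolar")
    scan(patterns._exc, "exclusion", "exclusion")
    for label, compiled in patterns._other.items():
        scan(compiled, "other", label)
    out.sort(key=lambda s: (s.span, s.pattern_class))
    return out


@dataclass(frozen=True)
class CohortDecision:
    author: str
    status: str  # included | excluded
    reason: str
    evidence: tuple[Statement, ...]

    def __post_init__(self) -> None:
        if (self.status == EXCLUDED) != (self.reason != REASON_INCLUDED):
            raise ValueError("status=excluded iff reason != included")


def classify_user(author: str, posts: Iterable, patterns: DiagnosisPatternSet) -> CohortDecision:
    """Decide one author's cohort membership from all their posts.

    Included iff ≥1 inclusion match AND 0 exclusion matches AND 0
    psychotic-disorder matches, over the union of the author's posts.
    Order of posts is irrelevant by construction.
    """
    inclusion_hits: list[Statement] = []
    exclusion_hits: list[Statement] = []
    psychotic_hits: list[Statement] = []
    for post in posts:
        for st in find_statements(post.body, patterns):
            if st.pattern_class == "inclusion":
                inclusion_hits.append(st)
            elif st.pattern_class == "exclusion":
                exclusion_hits.append(st)
            elif st.label == "psychotic_disorder":
                psychotic_hits.append(st)
    if not inclusion_hits:
        return CohortDecision(author, EXCLUDED, REASON_NO_INCLUSION, ())
    if exclusion_hits:
        return CohortDecision(author, EXCLUDED, REASON_EXCLUSION, tuple(exclusion_hits))
    if psychotic_hits:
        return CohortDecision(author, EXCLUDED, REASON_PSYCHOTIC, tuple(psychotic_hits))
    return CohortDecision(author, INCLUDED, REASON_INCLUDED, tuple(inclusion_hits))


@dataclass(frozen=True)
class CorpusSummary:
    n_users: int
    n_posts: int
    frac_single_post_users: float


def build_cohort(
    posts: Iterable, patterns: DiagnosisPatternSet
) -> tuple[set[str], dict[str, CohortDecision], CorpusSummary]:
    """Group a corpus by author and decide membership for each.

    Returns the included author set, the per-author decisions, and a corpus
    summary (user count, post count, fraction of single-post users).
    """
    by_author: dict[str, list] = {}
    n_posts = 0
    for post in posts:
        by_author.setdefault(post.author, []).append(post)
        n_posts += 1
    decisions = {
        author: classify_user(author, author_posts, patterns)
        for author, author_posts in by_author.items()
    }
    cohort = {a for a, d in decisions.items() if d.status == INCLUDED}
    n_users = len(by_author)
    single = sum(1 for ps in by_author.values() if len(ps) == 1)
    summary = CorpusSummary(
        n_users=n_users,
        n_posts=n_posts,
        frac_single_post_users=(single / n_users) if n_users else 0.0,
    )
    return cohort, decisions, summary


def write_decisions_tsv(decisions: Mapping[str, CohortDecision], path: str | Path) -> int:
    """Export decisions as TSV (author, status, reason), authors sorted."""
    n = 0
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("author\tstatus\treason\n")
        for author in sorted(decisions):
            d = decisions[author]
            handle.write(f"{author}\t{d.status}\t{d.reason}\n")
            n += 1
    return n
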