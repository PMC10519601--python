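"""User-level aggregation: context-stratified score means and eligibility.

Each cohort author becomes one :class:`UserRecord` carrying demographic
attributes, activity controls, unfiltered per-context post counts, counts and
unweighted means of scored (≥25-word) posts per context, and the binary
MH-posting outcome. The three analyses draw their samples from these records:

* posting partition — classes on *unfiltered* counts (it precedes the
  language analysis in the pipeline);
* within-user paired comparison — users with ≥4 scored posts in each context;
* between-user regression — the paired-comparison users (outcome 1) against
  users with no MH posts at all and ≥8 scored non-MH posts (outcome 0),
  keeping only users with both age and gender assigned.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from bdforum.corpus import Post, UserAttributes
from bdforum.lexicon import CATEGORIES, CategoryScores, MIN_WORDS
from bdforum.taxonomy import MH, NON_MH

#: Minimum scored posts per context for the paired within-user comparison.
RQ2_MIN_POSTS = 4
#: Minimum scored non-MH posts for a never-MH user to enter the regression.
RQ3_MIN_POSTS = 8
#: MH-post threshold separating active contributors from lurkers.
ACTIVE_CONTRIBUTOR_MIN = 4

SECONDS_PER_DAY = 86400


@dataclass(frozen=True)
class UserRecord:
    author: str
    gender: int | None
    age: float | None
    active_days: int
    activity: float
    n_mh_all: int
    n_nonmh_all: int
    n_mh_posts: int
    n_nonmh_posts: int
    mean_mh: dict[str, float] | None
    mean_nonmh: dict[str, float] | None

    @property
    def posted_in_mh(self) -> int:
        return 1 if self.n_mh_all >= 1 else 0


def _mean_scores(scores: Sequence[CategoryScores]) -> dict[str, float] | None:
    if not scores:
        return None
    return {c: sum(getattr(s, c) for s in scores) / len(scores) for c in CATEGORIES}


def build_user_records(
    cohort: Iterable[str],
    classified_scored: Sequence[tuple[Post, str, CategoryScores]],
    attributes: Mapping[str, UserAttributes],
    min_wc: int = MIN_WORDS,
) -> list[UserRecord]:
    """One record per cohort author from their classified, scored posts.

    ``classified_scored`` holds (post, context, scores) triples for the whole
    corpus; posts of non-cohort authors are ignored. Per-context means are
    unweighted means over the author's ≥``min_wc``-word posts in that
    context. ``active_days = max(1, ceil((last-first)/1 day))`` in UTC;
    ``activity`` divides the unfiltered post total by it.
    """
    cohort = set(cohort)
    per_user: dict[str, list[tuple[Post, str, CategoryScores]]] = {a: [] for a in cohort}
    for post, context, scores in classified_scored:
        if post.author in cohort:
            per_user[post.author].append((post, context, scores))

    records = []
    for author in sorted(cohort):
        triples = per_user[author]
        if not triples:
            raise ValueError(f"cohort author {author!r} has no posts")
        times = [p.created_utc for p, _, _ in triples]
        span = max(times) - min(times)
        active_days = max(1, math.ceil(span / SECONDS_PER_DAY))
        n_mh_all = sum(1 for _, ctx, _ in triples if ctx == MH)
        n_nonmh_all = len(triples) - n_mh_all
        mh_scored = [s for _, ctx, s in triples if ctx == MH and s.wc >= min_wc]
        nonmh_scored = [s for _, ctx, s in triples if ctx == NON_MH and s.wc >= min_wc]
        attr = attributes.get(author)
        records.append(
            UserRecord(
                author=author,
                gender=attr.gender if attr else None,
                age=attr.age if attr else None,
                active_days=active_days,
                activity=len(triples) / active_days,
                n_mh_all=n_mh_all,
                n_nonmh_all=n_nonmh_all,
                n_mh_posts=len(mh_scored),
                n_nonmh_posts=len(nonmh_scored),
                mean_mh=_mean_scores(mh_scored),
                mean_nonmh=_mean_scores(nonmh_scored),
            )
        )
    return records


@dataclass(frozen=True)
class Rq1Partition:
    """Posting-pattern partition with activity strata (figure-style table)."""

    n_users: int
    n_both: int
    n_only_mh: int
    n_only_nonmh: int
    n_both_active: int  # both contexts, ≥4 posts in each
    n_only_mh_8plus: int
    n_only_nonmh_8plus: int
    n_both_under8: int  # <8 total posts, by class
    n_only_mh_under8: int
    n_only_nonmh_under8: int

    @property
    def proportions(self) -> dict[str, float]:
        return {
            "both": self.n_both / self.n_users,
            "only_mh": self.n_only_mh / self.n_users,
            "only_nonmh": self.n_only_nonmh / self.n_users,
        }

    def to_jsonable(self) -> dict:
        out = {k: getattr(self, k) for k in self.__dataclass_fields__}
        out["proportions"] = self.proportions
        return out


def partition_rq1(records: Sequence[UserRecord]) -> Rq1Partition:
    """Partition users by posting class, on unfiltered post counts."""
    if not records:
        raise ValueError("partition requires at least one user record")
    n_both = n_only_mh = n_only_nonmh = 0
    n_both_active = n_only_mh_8 = n_only_nonmh_8 = 0
    n_both_u8 = n_only_mh_u8 = n_only_nonmh_u8 = 0
    for r in records:
        total = r.n_mh_all + r.n_nonmh_all
        if r.n_mh_all >= 1 and r.n_nonmh_all >= 1:
            n_both += 1
            if r.n_mh_all >= ACTIVE_CONTRIBUTOR_MIN and r.n_nonmh_all >= ACTIVE_CONTRIBUTOR_MIN:
                n_both_active += 1
            if total < 8:
                n_both_u8 += 1
        elif r.n_mh_all >= 1:
            n_only_mh += 1
            if total >= 8:
                n_only_mh_8 += 1
            else:
                n_only_mh_u8 += 1
        else:
            n_only_nonmh += 1
            if total >= 8:
                n_only_nonmh_8 += 1
            else:
                n_only_nonmh_u8 += 1
    return Rq1Partition(
        n_users=len(records),
        n_both=n_both,
        n_only_mh=n_only_mh,
        n_only_nonmh=n_only_nonmh,
        n_both_active=n_both_active,
        n_only_mh_8plus=n_only_mh_8,
        n_only_nonmh_8plus=n_only_nonmh_8,
        n_both_under8=n_both_u8,
        n_only_mh_under8=n_only_mh_u8,
        n_only_nonmh_under8=n_only_nonmh_u8,
    )


def select_rq2(records: Sequence[UserRecord], min_posts: int = RQ2_MIN_POSTS) -> list[UserRecord]:
    """Users with ≥``min_posts`` scored posts in both contexts."""
    return [r for r in records if r.n_mh_posts >= min_posts and r.n_nonmh_posts >= min_posts]


def select_rq3(
    records: Sequence[UserRecord],
    rq2_min: int = RQ2_MIN_POSTS,
    rq3_min: int = RQ3_MIN_POSTS,
) -> list[UserRecord]:
    """The regression sample: paired-comparison users vs never-MH users.

    Outcome 1: RQ2-eligible users. Outcome 0: users with zero MH posts of
    any length and ≥``rq3_min`` scored non-MH posts. Users missing age or
    gender are dropped (listwise). Raises if only one outcome class remains.
    """
    sample = []
    for r in records:
        eligible_1 = r.n_mh_posts >= rq2_min and r.n_nonmh_posts >= rq2_min
        eligible_0 = r.n_mh_all == 0 and r.n_nonmh_posts >= rq3_min
        if not (eligible_1 or eligible_0):
            continue
        if r.age is None or r.gender is None:
            continue
        sample.append(r)
    outcomes = {r.posted_in_mh for r in sample}
    if outcomes != {0, 1}:
        raise ValueError(
            f"regression sample has a single outcome class {sorted(outcomes)}; model undefined"
        )
    return sample


def regression_frame(sample: Sequence[UserRecord]):
    """Design matrix and outcome for the regression, from non-MH means only.

    Predictors: age, gender, active_days, activity, and the five non-MH mood
    scores. Never touches MH-context means, keeping the mood measure
    comparable between outcome groups.
    """
    import pandas as pd
    import numpy as np

    rows = []
    for r in sample:
        assert r.mean_nonmh is not None
        row = {
            "age": r.age,
            "gender": float(r.gender),
            "active_days": float(r.active_days),
            "activity": r.activity,
        }
        row.update({c: r.mean_nonmh[c] for c in CATEGORIES})
        rows.append(row)
    X = pd.DataFrame(rows, index=[r.author for r in sample])
    y = np.array([r.posted_in_mh for r in sample], dtype=float)
    return X, y


def write_records_tsv(records: Sequence[UserRecord], path: str | Path) -> int:
    """Export user records as TSV, one row per user."""
    cols = [
        "author", "gender", "age", "active_days", "activity",
        "n_mh_all", "n_nonmh_all", "n_mh_posts", "n_nonmh_posts", "posted_in_mh",
    ]
    mean_cols = [f"mean_mh_{c}" for c in CATEGORIES] + [f"mean_nonmh_{c}" for c in CATEGORIES]
    n = 0
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(cols + mean_cols) + "\n")
        for r in records:
            vals = [
                r.author,
                "" if r.gender is None else str(r.gender),
                "" if r.age is None else f"{r.age:g}",
                str(r.active_days),
                f"{r.activity:.6g}",
                str(r.n_mh_all), str(r.n_nonmh_all),
                str(r.n_mh_posts), str(r.n_nonmh_posts),
                str(r.posted_in_mh),
            ]
            for means in (r.mean_mh, r.mean_nonmh):
                for c in CATEGORIES:
                    vals.append("" if means is None else f"{means[c]:.6g}")
            handle.write("\t".join(vals) + "\n")
            n += 1
    return n


def read_records_tsv(path: str | Path) -> list[UserRecord]:
    """Read back a user-record TSV written by :func:`write_records_tsv`."""
    records = []
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        idx = {name: j for j, name in enumerate(header)}
        for line in handle:
            cells = line.rstrip("\n").split("\t")
            get = lambda name: cells[idx[name]]
            mean_mh = {c: get(f"mean_mh_{c}") for c in CATEGORIES}
            mean_nonmh = {c: get(f"mean_nonmh_{c}") for c in CATEGORIES}
            records.append(
                UserRecord(
                    author=get("author"),
                    gender=int(get("gender")) if get("gender") else None,
                    age=float(get("age")) if get("age") else None,
                    active_days=int(get("active_days")),
                    activity=float(get("activity")),
                    n_mh_all=int(get("n_mh_all")),
                    n_nonmh_all=int(get("n_nonmh_all")),
                    n_mh_posts=int(get("n_mh_posts")),
                    n_nonmh_posts=int(get("n_nonmh_posts")),
                    mean_mh=None if "" in mean_mh.values() else {c: float(v) for c, v in mean_mh.items()},
                    mean_nonmh=None if "" in mean_nonmh.values() else {c: float(v) for c, v in mean_nonmh.items()},
                )
            )
    return records


def write_partition(partition: Rq1Partition, json_path: str | Path, tsv_path: str | Path) -> None:
    """Export the partition as JSON and a flat TSV."""
    with open(json_path, "w", encoding="utf-8") as handle:
        json.dump(partition.to_jsonable(), handle, indent=2, sort_keys=True)
        handle.write("\n")
    data = partition.to_jsonable()
    props = data.pop("proportions")
    with open(tsv_path, "w", encoding="utf-8") as handle:
        handle.write("quantity\tvalue\n")
        for k in sorted(data):
            handle.write(f"{k}\t{data[k]}\n")
        for k in sorted(props):
            handle.write(f"prop_{k}\t{props[k]:.6f}\n")
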