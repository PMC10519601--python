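"""Canonical data model and I/O for post corpora and user-attribute tables.

Corpora are line-delimited JSON (one post object per line), the dialect in
which Reddit dumps commonly circulate, so everything streams. A "post" covers
both submissions (thread starts) and comments; a submission's title, when
present, is folded into ``body`` with a single newline, since nothing
downstream distinguishes the two.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

#: Forum inception (2005-01-01 UTC); no valid post predates it.
SITE_EPOCH = 1104537600

_REQUIRED_FIELDS = ("id", "author", "subreddit", "created_utc")


@dataclass(frozen=True)
class Post:
    """One forum message (submission or comment)."""

    id: str
    author: str
    subreddit: str
    created_utc: int
    body: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("post id must be non-empty")
        if self.created_utc < SITE_EPOCH:
            raise ValueError(
                f"created_utc {self.created_utc} predates site inception ({SITE_EPOCH})"
            )


@dataclass(frozen=True)
class UserAttributes:
    """Demographic attributes of one author.

    ``age`` is the author's mean age over their posting history, in years.
    ``gender`` uses the upstream coding 0 = feminine, 1 = masculine.
    Either may be ``None`` when the attribute could not be assigned.
    """

    author: str
    age: float | None
    gender: int | None

    def __post_init__(self) -> None:
        if self.age is not None and not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.gender is not None and self.gender not in (0, 1):
            raise ValueError(f"gender must be 0 or 1, got {self.gender}")


class CorpusFormatError(ValueError):
    """A corpus or attribute file violates its format contract."""


def _post_from_record(record: dict, lineno: int) -> Post:
    for field in _REQUIRED_FIELDS:
        if field not in record:
            raise CorpusFormatError(f"line {lineno}: missing field {field}")
    body = record.get("body") or ""
    title = record.get("title")
    if title:
        body = f"{title}\n{body}" if body else title
    return Post(
        id=str(record["id"]),
        author=str(record["author"]),
        subreddit=str(record["subreddit"]),
        created_utc=int(record["created_utc"]),
        body=body,
    )


def read_posts(path: str | Path) -> Iterator[Post]:
    """Stream posts from a JSONL corpus in file order.

    Raises :class:`CorpusFormatError` naming the line number for malformed
    JSON and the field name for incomplete records. Lines with a missing or
    null ``body`` yield posts with empty text.
    """
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
            yield _post_from_record(record, lineno)


def write_posts(posts: Iterable[Post], path: str | Path) -> int:
    """Write posts as canonical JSONL (fixed key order); returns the count."""
    n = 0
    with open(path, "w", encoding="utf-8") as handle:
        for post in posts:
            record = {
                "id": post.id,
                "author": post.author,
                "subreddit": post.subreddit,
                "created_utc": post.created_utc,
                "body": post.body,
            }
            handle.write(json.dumps(record, ensure_ascii=False) + "\n")
            n += 1
    return n


def read_attributes(path: str | Path) -> dict[str, UserAttributes]:
    """Read the author/age/gender TSV into a map keyed by author.

    Empty cells map to missing; a duplicated author keeps the last row (with
    a logged warning); a gender outside {0, 1, empty} is an error.
    """
    out: dict[str, UserAttributes] = {}
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = ["author", "age", "gender"]
        if header != expected:
            raise CorpusFormatError(f"attribute header must be {expected}, got {header}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 3:
                raise CorpusFormatError(f"line {lineno}: expected 3 cells, got {len(cells)}")
            author, age_cell, gender_cell = cells
            age = float(age_cell) if age_cell.strip() else None
            if age is not None and math.isnan(age):
                age = None
            if gender_cell.strip() == "":
                gender: int | None = None
            elif gender_cell.strip() in ("0", "1"):
                gender = int(gender_cell)
            else:
                raise CorpusFormatError(
                    f"line {lineno}: gender must be 0, 1 or empty, got {gender_cell!r}"
                )
            if author in out:
                logger.warning("duplicate author %r at line %d; keeping last row", author, lineno)
            out[author] = UserAttributes(author=author, age=age, gender=gender)
    return out


def write_attributes(attributes: Iterable[UserAttributes], path: str | Path) -> int:
    """Write an attribute table as TSV; missing values become empty cells."""
    n = 0
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("author\tage\tgender\n")
        for attr in attributes:
            age = "" if attr.age is None else f"{attr.age:g}"
            gender = "" if attr.gender is None else str(attr.gender)
            handle.write(f"{attr.author}\t{age}\t{gender}\n")
            n += 1
    return n
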