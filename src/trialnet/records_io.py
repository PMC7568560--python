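"""Publication-record data model and corpus file I/O.

A corpus is an ordered list of :class:`PublicationRecord`, one per manuscript.
Two on-disk dialects are supported:

``jsonl``
    One JSON object per record, UTF-8, keys in a fixed order.  This is the
    primary interchange format.
``table``
    A tab-separated table with one row per (record, author-slot) pair and the
    record-level fields repeated on every row.  Convenient for spreadsheet
    inspection and for loading into a DataFrame.

Both dialects are bit-stable: writing the same records twice yields identical
bytes, and ``read(write(x)) == x`` for any valid corpus.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "AuthorSlot",
    "PublicationRecord",
    "ParsedName",
    "CorpusError",
    "MalformedNameError",
    "ValidationError",
    "parse_author_name",
    "read_corpus",
    "write_corpus",
]

WEIGHT_TOL = 1e-9


class CorpusError(ValueError):
    """Base class for corpus-level errors."""


class MalformedNameError(CorpusError):
    """Raised when an author name string does not follow the expected format."""


class ValidationError(CorpusError):
    """Raised when one or more records violate the data-model invariants.

    ``failures`` is a list of ``(record_id, field, reason)`` tuples so that a
    caller can report every offending record at once.
    """

    def __init__(self, failures: list[tuple[str, str, str]]):
        self.failures = failures
        lines = "; ".join(f"{r}:{f}: {m}" for r, f, m in failures[:10])
        more = "" if len(failures) <= 10 else f" (+{len(failures) - 10} more)"
        super().__init__(f"{len(failures)} invalid record(s): {lines}{more}")


@dataclass
class AuthorSlot:
    """One position in a manuscript's ordered author list.

    ``raw_name`` uses the MEDLINE convention ``Surname_Given`` where the given
    block is either a full first name or 1-3 initials.  ``position`` is 1-based.
    """

    raw_name: str
    position: int
    equal_contrib: bool = False


@dataclass
class PublicationRecord:
    """A single manuscript with its authorship, design and citation metadata.

    ``update_index`` counts follow-up generations: 0 marks the primary
    publication of a trial, 1 its first update, and so on.  Manuscripts that
    pool updates of several trials carry the individual update generations in
    ``pooled_update_indices``.  ``subspecialty_weights`` maps disease
    subspecialty labels to fractions summing to one; most manuscripts map to a
    single subspecialty with weight 1.0.
    """

    record_id: str
    year: int
    journal_tier: int
    randomized: bool
    update_index: int
    citations: int
    subspecialty_weights: dict[str, float]
    authors: list[AuthorSlot]
    pooled_update_indices: list[int] | None = None
    positive_trial: bool | None = None

    def validate(self, year_range: tuple[int, int] | None = None) -> list[tuple[str, str, str]]:
        """Return a list of (record_id, field, reason) invariant violations."""
        bad: list[tuple[str, str, str]] = []
        rid = self.record_id
        if not rid:
            bad.append(("<missing>", "record_id", "empty record identifier"))
            rid = "<missing>"
        if not self.authors:
            bad.append((rid, "authors", "author list is empty"))
        positions = [a.position for a in self.authors]
        if len(set(positions)) != len(positions):
            bad.append((rid, "authors", "duplicate author positions"))
        for a in self.authors:
            if not a.raw_name:
                bad.append((rid, "authors", f"empty raw_name at position {a.position}"))
        if self.update_index < 0:
            bad.append((rid, "update_index", f"negative update index {self.update_index}"))
        if self.pooled_update_indices is not None:
            if not self.pooled_update_indices:
                bad.append((rid, "pooled_update_indices", "empty pooled index list"))
            elif any(i < 0 for i in self.pooled_update_indices):
                bad.append((rid, "pooled_update_indices", "negative pooled index"))
        if self.citations < 0:
            bad.append((rid, "citations", f"negative citation count {self.citations}"))
        total = sum(self.subspecialty_weights.values())
        if not self.subspecialty_weights or not math.isclose(total, 1.0, abs_tol=WEIGHT_TOL):
            bad.append((rid, "subspecialty_weights", f"weights sum to {total!r}, expected 1"))
        if any(w < 0 for w in self.subspecialty_weights.values()):
            bad.append((rid, "subspecialty_weights", "negative weight"))
        if year_range is not None and not (year_range[0] <= self.year <= year_range[1]):
            bad.append((rid, "year", f"{self.year} outside {year_range}"))
        return bad


@dataclass(frozen=True)
class ParsedName:
    surname: str
    given: str
    initials_only: bool


def _is_initials(given: str) -> bool:
    return 1 <= len(given) <= 3 and given.isalpha() and given.isupper()


def parse_author_name(raw: str) -> ParsedName:
    """Split a ``Surname_Given`` author string into its components.

    The surname block is kept verbatim (it may contain spaces or hyphens).
    The given block is classified as initials-only iff it consists of 1-3
    uppercase letters, e.g. ``"Kantarjian_HM"`` vs ``"Rigal-Huguet_Francoise"``.

    Raises
    ------
    MalformedNameError
        If the string is empty or does not contain exactly one underscore
        separating non-empty surname and given blocks.
    """
    if not raw:
        raise MalformedNameError("empty author name")
    parts = raw.split("_")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise MalformedNameError(
            f"author name {raw!r} is not in Surname_Given format "
            "(exactly one underscore separating non-empty blocks)"
        )
    surname, given = parts
    return ParsedName(surname=surname, given=given, initials_only=_is_initials(given))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_RECORD_KEYS = (
    "record_id",
    "year",
    "journal_tier",
    "randomized",
    "update_index",
    "pooled_update_indices",
    "citations",
    "subspecialty_weights",
    "positive_trial",
)

_TABLE_COLUMNS = _RECORD_KEYS + ("author_raw_name", "author_position", "author_equal_contrib")


def _record_to_obj(rec: PublicationRecord) -> dict:
    return {
        "record_id": rec.record_id,
        "year": rec.year,
        "journal_tier": rec.journal_tier,
        "randomized": rec.randomized,
        "update_index": rec.update_index,
        "pooled_update_indices": rec.pooled_update_indices,
        "citations": rec.citations,
        "subspecialty_weights": {k: rec.subspecialty_weights[k] for k in sorted(rec.subspecialty_weights)},
        "positive_trial": rec.positive_trial,
        "authors": [
            {"raw_name": a.raw_name, "position": a.position, "equal_contrib": a.equal_contrib}
            for a in sorted(rec.authors, key=lambda a: a.position)
        ],
    }


def _record_from_obj(obj: dict) -> PublicationRecord:
    return PublicationRecord(
        record_id=obj["record_id"],
        year=int(obj["year"]),
        journal_tier=int(obj["journal_tier"]),
        randomized=bool(obj["randomized"]),
        update_index=int(obj["update_index"]),
        pooled_update_indices=(
            None if obj.get("pooled_update_indices") is None else [int(i) for i in obj["pooled_update_indices"]]
        ),
        citations=int(obj["citations"]),
        subspecialty_weights={str(k): float(v) for k, v in obj["subspecialty_weights"].items()},
        positive_trial=obj.get("positive_trial"),
        authors=[
            AuthorSlot(raw_name=a["raw_name"], position=int(a["position"]), equal_contrib=bool(a["equal_contrib"]))
            for a in obj["authors"]
        ],
    )


def _validate_all(records: Sequence[PublicationRecord], year_range: tuple[int, int] | None) -> None:
    failures: list[tuple[str, str, str]] = []
    for rec in records:
        failures.extend(rec.validate(year_range))
    if failures:
        raise ValidationError(failures)


def write_corpus(
    records: Iterable[PublicationRecord],
    path: str | Path,
    dialect: str = "jsonl",
) -> Path:
    """Write a corpus to ``path`` in the given dialect.

    Records are sorted by ``(year, record_id)`` before writing so the output is
    deterministic for a fixed input set.
    """
    path = Path(path)
    recs = sorted(records, key=lambda r: (r.year, r.record_id))
    _validate_all(recs, None)
    if dialect == "jsonl":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for rec in recs:
                fh.write(json.dumps(_record_to_obj(rec), ensure_ascii=False, separators=(",", ":")))
                fh.write("\n")
    elif dialect == "table":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_TABLE_COLUMNS)
            for rec in recs:
                obj = _record_to_obj(rec)
                base = [
                    obj["record_id"],
                    obj["year"],
                    obj["journal_tier"],
                    int(obj["randomized"]),
                    obj["update_index"],
                    "" if obj["pooled_update_indices"] is None else ",".join(map(str, obj["pooled_update_indices"])),
                    obj["citations"],
                    json.dumps(obj["subspecialty_weights"], separators=(",", ":")),
                    "" if obj["positive_trial"] is None else int(obj["positive_trial"]),
                ]
                for a in obj["authors"]:
                    writer.writerow(base + [a["raw_name"], a["position"], int(a["equal_contrib"])])
    else:
        raise ValueError(f"unknown corpus dialect {dialect!r}")
    return path


def read_corpus(
    path: str | Path,
    dialect: str = "jsonl",
    year_range: tuple[int, int] | None = None,
) -> list[PublicationRecord]:
    """Read a corpus file, validate every record, and return records sorted by
    ``(year, record_id)``.

    Raises
    ------
    ValidationError
        Listing every record whose invariants fail (weights not summing to 1,
        empty author list, duplicate positions, negative indices, ...).
    """
    path = Path(path)
    records: list[PublicationRecord] = []
    if dialect == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(_record_from_obj(json.loads(line)))
    elif dialect == "table":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            by_id: dict[str, PublicationRecord] = {}
            order: list[str] = []
            for row in reader:
                rid = row["record_id"]
                if rid not in by_id:
                    by_id[rid] = PublicationRecord(
                        record_id=rid,
                        year=int(row["year"]),
                        journal_tier=int(row["journal_tier"]),
                        randomized=bool(int(row["randomized"])),
                        update_index=int(row["update_index"]),
                        pooled_update_indices=(
                            [int(i) for i in row["pooled_update_indices"].split(",")]
                            if row["pooled_update_indices"]
                            else None
                        ),
                        citations=int(row["citations"]),
                        subspecialty_weights=json.loads(row["subspecialty_weights"]),
                        positive_trial=(None if row["positive_trial"] == "" else bool(int(row["positive_trial"]))),
                        authors=[],
                    )
                    order.append(rid)
                by_id[rid].authors.append(
                    AuthorSlot(
                        raw_name=row["author_raw_name"],
                        position=int(row["author_position"]),
                        equal_contrib=bool(int(row["author_equal_contrib"])),
                    )
                )
            records = [by_id[r] for r in order]
    else:
        raise ValueError(f"unknown corpus dialect {dialect!r}")
    records.sort(key=lambda r: (r.year, r.record_id))
    _validate_all(records, year_range)
    return records
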