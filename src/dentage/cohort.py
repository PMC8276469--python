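"""Staged-dentition cohorts: record types, delimited-text I/O, eligibility filter.

A cohort row is one scoring of one child: sex, chronological age in decimal
years, and the Demirjian stage of each of the seven lower-left permanent
mandibular teeth, FDI 31-37 (central incisor through second molar; the third
molar 38 is excluded from seven-tooth methods).  Optional ``observer_id`` /
``session`` columns allow repeat scorings of the same radiograph for
observer-agreement analyses.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

from .stages import StageCode, parse_stage

#: the seven FDI teeth a Willems-style method scores
TEETH: tuple[int, ...] = (31, 32, 33, 34, 35, 36, 37)

SEXES: tuple[str, str] = ("M", "F")

_REQUIRED_COLUMNS = ("subject_id", "sex", "chron_age") + tuple(f"t{t}" for t in TEETH)
_OPTIONAL_COLUMNS = ("observer_id", "session")


class CohortSchemaError(ValueError):
    """A cohort file lacks a required column."""


class CohortParseError(ValueError):
    """A cohort file row contains an unparseable value; message names row/column."""


@dataclass(frozen=True)
class DentitionRecord:
    """One subject's staged dentition and chronological age."""

    subject_id: str
    sex: str
    chron_age: float
    stages: Mapping[int, StageCode]
    observer_id: Optional[str] = None
    session: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not (math.isfinite(self.chron_age) and self.chron_age > 0):
            raise ValueError(f"chron_age must be finite and positive, got {self.chron_age}")
        if set(self.stages) != set(TEETH):
            raise ValueError(
                f"stages must key exactly teeth {TEETH}, got {sorted(self.stages)}"
            )
        object.__setattr__(self, "stages", dict(self.stages))

    # dict is unhashable; compare by content
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DentitionRecord):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.sex == other.sex
            and self.chron_age == other.chron_age
            and dict(self.stages) == dict(other.stages)
            and self.observer_id == other.observer_id
            and self.session == other.session
        )

    __hash__ = None  # type: ignore[assignment]

    @property
    def key(self) -> tuple[str, Optional[str], Optional[int]]:
        return (self.subject_id, self.observer_id, self.session)

    def has_missing(self) -> bool:
        return any(s is StageCode.MISSING for s in self.stages.values())

    def fully_developed(self) -> bool:
        """All seven teeth at stage H (closed apices)."""
        return all(s is StageCode.H for s in self.stages.values())


@dataclass
class Cohort:
    """An ordered collection of dentition records."""

    records: Sequence[DentitionRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.records = list(self.records)
        seen: set[tuple] = set()
        for r in self.records:
            if r.key in seen:
                raise ValueError(f"duplicate record key {r.key}")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DentitionRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return list(self.records) == list(other.records)

    def subset(self, records: Iterable[DentitionRecord], provenance: str = "") -> "Cohort":
        return Cohort(list(records), provenance or self.provenance)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per record, stages as single-character strings."""
        rows = []
        for r in self.records:
            row = {"subject_id": r.subject_id, "sex": r.sex, "chron_age": r.chron_age}
            for t in TEETH:
                row[f"t{t}"] = r.stages[t].value
            row["observer_id"] = r.observer_id
            row["session"] = r.session
            rows.append(row)
        cols = list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS)
        return pd.DataFrame(rows, columns=cols)


def _has_optional(records: Sequence[DentitionRecord]) -> bool:
    return any(r.observer_id is not None or r.session is not None for r in records)


def read_cohort(path: str | Path, delimiter: str = ",") -> Cohort:
    """Read a cohort from delimited text.

    Stage tokens are parsed case-insensitively; empty or ``NA`` cells mark an
    unscorable tooth.  Errors are addressed by row number (header = row 1) and
    column name.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing_cols = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing_cols:
            raise CohortSchemaError(
                f"{path}: missing required column(s) {', '.join(missing_cols)}"
            )
        records = []
        for lineno, row in enumerate(reader, start=2):
            records.append(_parse_row(row, lineno, path))
    return Cohort(records, provenance=str(path))


def _parse_row(row: Mapping[str, str], lineno: int, path: Path) -> DentitionRecord:
    def fail(col: str, msg: str) -> CohortParseError:
        return CohortParseError(f"{path}: row {lineno}, column {col}: {msg}")

    sex = (row["sex"] or "").strip().upper()
    if sex not in SEXES:
        raise fail("sex", f"expected M or F, got {row['sex']!r}")
    try:
        age = float(row["chron_age"])
    except (TypeError, ValueError):
        raise fail("chron_age", f"not a number: {row['chron_age']!r}") from None
    stages = {}
    for t in TEETH:
        col = f"t{t}"
        try:
            stages[t] = parse_stage(row[col] or "")
        except ValueError as exc:
            raise fail(col, str(exc)) from None
    observer = (row.get("observer_id") or "").strip() or None
    session_tok = (row.get("session") or "").strip()
    session = None
    if session_tok:
        try:
            session = int(session_tok)
        except ValueError:
            raise fail("session", f"not an integer: {session_tok!r}") from None
    try:
        return DentitionRecord(row["subject_id"], sex, age, stages, observer, session)
    except ValueError as exc:
        raise CohortParseError(f"{path}: row {lineno}: {exc}") from None


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = ",") -> None:
    """Write a cohort as delimited text in canonical column order.

    ``read_cohort(write_cohort(c)) == c``; floats use Python's shortest
    round-tripping representation so the file is byte-stable under rewrite.
    The optional observer columns are emitted only when some record sets them.
    """
    path = Path(path)
    with_opt = _has_optional(cohort.records)
    cols = list(_REQUIRED_COLUMNS) + (list(_OPTIONAL_COLUMNS) if with_opt else [])
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(cols)
        for r in cohort.records:
            row = [r.subject_id, r.sex, repr(r.chron_age)]
            row += [r.stages[t].value for t in TEETH]
            if with_opt:
                row += [r.observer_id or "", "" if r.session is None else str(r.session)]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# eligibility filter

#: exclusion reason labels
REASON_AGE = "age"
REASON_MISSING = "missing_tooth"
REASON_FULLY_DEVELOPED = "fully_developed"


@dataclass
class ExclusionLog:
    """Per-record exclusion reasons; a record may trigger several."""

    reasons: "dict[tuple, tuple[str, ...]]" = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out = {REASON_AGE: 0, REASON_MISSING: 0, REASON_FULLY_DEVELOPED: 0}
        for rs in self.reasons.values():
            for r in rs:
                out[r] += 1
        return out

    @property
    def n_excluded(self) -> int:
        return len(self.reasons)


@dataclass
class EligibilityResult:
    cohort: Cohort
    log: ExclusionLog

    def __iter__(self):  # allow `eligible, log = filter_eligible(...)`
        return iter((self.cohort, self.log))


def filter_eligible(cohort: Cohort, max_age: float = 16.0) -> EligibilityResult:
    """Apply the study's eligibility rules.

    A record is retained when (i) chronological age < ``max_age`` (strict:
    exactly ``max_age`` is excluded), (ii) none of teeth 31-37 is MISSING, and
    (iii) not all seven teeth are at stage H — a fully developed dentition
    carries no age signal below the ceiling.
    """
    if not max_age > 0:
        raise ValueError("max_age must be positive")
    kept, log = [], ExclusionLog()
    for r in cohort:
        reasons = []
        if r.chron_age >= max_age:
            reasons.append(REASON_AGE)
        if r.has_missing():
            reasons.append(REASON_MISSING)
        elif r.fully_developed():
            reasons.append(REASON_FULLY_DEVELOPED)
        if reasons:
            log.reasons[r.key] = tuple(reasons)
        else:
            kept.append(r)
    return EligibilityResult(Cohort(kept, provenance=cohort.provenance), log)
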