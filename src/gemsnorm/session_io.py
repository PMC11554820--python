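"""Reading and writing session files, normative tables and retest tables.

All files are comma-separated UTF-8 with a mandatory header row and dot
decimal separators (the instrument's web runtime emits dot decimals even in
Italian locales).  Validation is collect-all: every violation is reported so
clinical files can be triaged rather than rejected on the first fault.
Schemas are documented in ``docs/formats.md``.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import SchemaError, ValidationError
from .tasks import KNOWN_CHANNELS, Task

__all__ = [
    "SessionEvent",
    "SessionFile",
    "SessionReadResult",
    "NormativeTable",
    "read_session_csv",
    "write_session_csv",
    "read_normative_table",
    "write_normative_table",
    "read_retest_table",
    "NORMATIVE_COLUMNS",
    "TASK_COLUMNS",
]

SESSION_COLUMNS = (
    "examinee_id",
    "administration_date",
    "version",
    "task_id",
    "item_id",
    "response",
    "elapsed_s",
)

TASK_COLUMNS = tuple(t.value for t in Task)
NORMATIVE_COLUMNS = ("age", "education", "sex", "cr") + TASK_COLUMNS + ("total",)


@dataclass(frozen=True)
class SessionEvent:
    task_id: str
    item_id: str
    response: str
    elapsed_s: float


@dataclass(frozen=True)
class SessionFile:
    examinee_id: str
    administration_date: _dt.date
    version: str
    events: tuple[SessionEvent, ...]

    def task_groups(self) -> dict[str, list[SessionEvent]]:
        groups: dict[str, list[SessionEvent]] = {}
        for ev in self.events:
            groups.setdefault(ev.task_id, []).append(ev)
        return groups


@dataclass
class SessionReadResult:
    """A validated session plus the rows that failed validation."""

    session: SessionFile
    rejects: list[dict] = field(default_factory=list)
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.rejects and not self.issues


@dataclass
class NormativeTable:
    """Normative cohort rows with per-row validation issues.

    ``data`` keeps every input row (row count preserved); ``row_issues`` maps
    0-based row index to the list of violated invariants.  ``valid()`` returns
    the rows usable for fitting.
    """

    data: pd.DataFrame
    row_issues: dict[int, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def valid(self) -> pd.DataFrame:
        bad = list(self.row_issues)
        return self.data.drop(index=bad)


def _parse_date(text: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(text).strip()[:10])
    except ValueError as exc:
        raise ValidationError(f"unparseable ISO-8601 date: {text!r}") from exc


def read_session_csv(path) -> SessionReadResult:
    """Read one examinee's session file.

    Unknown task ids are collected into ``rejects`` (never silently dropped);
    structural faults (missing columns, unparseable metadata) raise.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in SESSION_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required columns: {missing}")
        rows = list(reader)
    if not rows:
        raise SchemaError(f"{path}: no rows")

    first = rows[0]
    examinee_id = first["examinee_id"]
    date = _parse_date(first["administration_date"])
    version = str(first["version"]).strip()
    if version not in ("A", "B"):
        raise ValidationError(f"{path}: version must be A or B, got {version!r}")

    events: list[SessionEvent] = []
    rejects: list[dict] = []
    issues: list[str] = []
    for i, row in enumerate(rows):
        if row["examinee_id"] != examinee_id:
            issues.append(f"row {i}: examinee_id differs from header row")
        task_id = str(row["task_id"]).strip()
        try:
            elapsed = float(row["elapsed_s"]) if row["elapsed_s"] != "" else 0.0
        except ValueError:
            rejects.append({**row, "reason": "elapsed_s not numeric"})
            continue
        if elapsed < 0:
            rejects.append({**row, "reason": "negative elapsed_s"})
            continue
        if task_id not in KNOWN_CHANNELS:
            rejects.append({**row, "reason": f"unknown task_id {task_id!r}"})
            continue
        events.append(
            SessionEvent(task_id, str(row["item_id"]), str(row["response"]),
                         elapsed)
        )
    session = SessionFile(examinee_id, date, version, tuple(events))
    return SessionReadResult(session, rejects, issues)


def write_session_csv(session: SessionFile, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SESSION_COLUMNS)
        for ev in session.events:
            writer.writerow(
                [
                    session.examinee_id,
                    session.administration_date.isoformat(),
                    session.version,
                    ev.task_id,
                    ev.item_id,
                    ev.response,
                    repr(ev.elapsed_s) if ev.elapsed_s % 1 else int(ev.elapsed_s),
                ]
            )


def _validate_normative_row(row) -> list[str]:
    problems = []
    if not row["age"] >= 18:
        problems.append(f"age {row['age']} below 18")
    if not 0 <= row["education"] <= 30:
        problems.append(f"education {row['education']} outside [0, 30]")
    if row["sex"] not in ("F", "M"):
        problems.append(f"sex {row['sex']!r} not in {{F, M}}")
    if not row["cr"] > 0:
        problems.append(f"cr {row['cr']} not positive")
    for col in TASK_COLUMNS:
        if not 0 <= row[col] <= 9:
            problems.append(f"{col} {row[col]} outside [0, 9]")
    if not 0 <= row["total"] <= 100:
        problems.append(f"total {row['total']} outside [0, 100]")
    return problems


def read_normative_table(path) -> NormativeTable:
    """Read a normative cohort table, validating every row."""
    try:
        df = pd.read_csv(path, dtype={"sex": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, header row required") from exc
    missing = [c for c in NORMATIVE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no rows")
    numeric = [c for c in NORMATIVE_COLUMNS if c != "sex"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    row_issues: dict[int, list[str]] = {}
    for i, row in df.iterrows():
        if row[numeric].isna().any():
            bad = [c for c in numeric if pd.isna(row[c])]
            row_issues[i] = [f"non-numeric or missing value in {bad}"]
            continue
        problems = _validate_normative_row(row)
        if problems:
            row_issues[i] = problems
    return NormativeTable(df, row_issues)


def write_normative_table(table, path) -> None:
    df = table.data if isinstance(table, NormativeTable) else table
    df.to_csv(path, index=False, columns=list(NORMATIVE_COLUMNS))


RETEST_COLUMNS = ("examinee_id", "version_t0", "version_t1", "interval_days",
                  "t0_total", "t1_total")


def read_retest_table(path) -> pd.DataFrame:
    """Read a baseline/retest pair table (totals-level)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, header row required") from exc
    missing = [c for c in RETEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no rows")
    bad = df[df["interval_days"] <= 0]
    if len(bad):
        raise ValidationError(
            f"{path}: non-positive interval_days in rows {list(bad.index)}"
        )
    return df
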