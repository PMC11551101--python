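"""Participant-level trial data model, CSV schema, validation and I/O.

The data model is a fixed three-visit schedule (HRQoL at weeks 0/12/24,
utilities at months 0/3/6) plus a per-participant cost ledger split into a
pre-trial window and two within-trial windows.  Missing values are explicit
(``None``), never zero, and survive a CSV round-trip as empty cells.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

ARMS = ("intervention", "control")
SEXES = ("male", "female", "unspecified")
SCORE_VISITS = ("week0", "week12", "week24")
UTILITY_VISITS = ("month0", "month3", "month6")
COST_WINDOWS = ("pretrial_12wk", "trial_0_3mo", "trial_3_6mo")
COST_COMPONENTS = ("primary_care", "medications", "hospital", "social_care", "intervention")
TRIAL_WINDOWS = ("trial_0_3mo", "trial_3_6mo")

MAX_SESSIONS_STRUCTURED = 24
MAX_SESSIONS_EDUCATION = 12

SCHEMA_VERSION = "1"


def _score_columns(prefix: str) -> list[str]:
    return [f"{prefix}_w{v.removeprefix('week')}" for v in SCORE_VISITS]


def _utility_columns() -> list[str]:
    return [f"eq5d_m{v.removeprefix('month')}" for v in UTILITY_VISITS]


def _cost_columns() -> list[str]:
    return [f"cost_{c}_{w}" for c in COST_COMPONENTS for w in COST_WINDOWS]


#: CSV header, in order.  One column per cost component and window.
CSV_COLUMNS = (
    ["participant_id", "arm", "age", "sex"]
    + _score_columns("mcs")
    + _score_columns("pcs")
    + _utility_columns()
    + _cost_columns()
    + ["completed_week24", "sessions_structured", "sessions_education", "minutes_structured"]
)

_SCORE_COL = {("mcs", v): f"mcs_w{v.removeprefix('week')}" for v in SCORE_VISITS}
_SCORE_COL.update({("pcs", v): f"pcs_w{v.removeprefix('week')}" for v in SCORE_VISITS})
_UTILITY_COL = {v: f"eq5d_m{v.removeprefix('month')}" for v in UTILITY_VISITS}


class SchemaError(ValueError):
    """Raised when a CSV header does not match the documented schema."""


class ValidationError(ValueError):
    """Raised when record- or dataset-level invariants are violated."""


@dataclass
class CostLedger:
    """Cost components (GBP) per analysis window.

    ``windows`` maps window label -> {component -> amount or None}.  The
    ``intervention`` component is never missing and is 0 for control
    records and for every pre-trial window.
    """

    windows: dict[str, dict[str, float | None]]
    imputed: set[tuple[str, str]] = field(default_factory=set)

    @classmethod
    def empty(cls) -> "CostLedger":
        return cls(windows={w: {c: (0.0 if c == "intervention" else None) for c in COST_COMPONENTS} for w in COST_WINDOWS})

    def get(self, window: str, component: str) -> float | None:
        return self.windows[window][component]

    def set(self, window: str, component: str, value: float | None) -> None:
        self.windows[window][component] = value

    def copy(self) -> "CostLedger":
        return CostLedger(
            windows={w: dict(comps) for w, comps in self.windows.items()},
            imputed=set(self.imputed),
        )

    def validate(self, participant_id: str, arm: str) -> None:
        for w in COST_WINDOWS:
            if w not in self.windows:
                raise ValidationError(f"{participant_id}: missing cost window {w!r}")
            for c in COST_COMPONENTS:
                v = self.windows[w].get(c)
                if v is not None and v < 0:
                    raise ValidationError(f"{participant_id}: negative cost in {c}/{w}: {v}")
            iv = self.windows[w]["intervention"]
            if iv is None:
                raise ValidationError(f"{participant_id}: intervention cost may not be missing ({w})")
        if self.windows["pretrial_12wk"]["intervention"] != 0:
            raise ValidationError(f"{participant_id}: pre-trial intervention cost must be 0")
        if arm == "control":
            for w in COST_WINDOWS:
                if self.windows[w]["intervention"] != 0:
                    raise ValidationError(f"{participant_id}: control record has nonzero intervention cost in {w}")


@dataclass
class ParticipantRecord:
    participant_id: str
    arm: str
    age: float
    sex: str = "unspecified"
    mcs: dict[str, float | None] = field(default_factory=lambda: dict.fromkeys(SCORE_VISITS))
    pcs: dict[str, float | None] = field(default_factory=lambda: dict.fromkeys(SCORE_VISITS))
    eq5d: dict[str, float | None] = field(default_factory=lambda: dict.fromkeys(UTILITY_VISITS))
    costs: CostLedger = field(default_factory=CostLedger.empty)
    completed_week24: bool = False
    sessions_structured: int = 0
    sessions_education: int = 0
    minutes_structured: float = 0.0
    #: provenance of imputed outcome cells, e.g. {("mcs", "week24")}
    imputed: set[tuple[str, str]] = field(default_factory=set)

    def copy(self) -> "ParticipantRecord":
        return replace(
            self,
            mcs=dict(self.mcs),
            pcs=dict(self.pcs),
            eq5d=dict(self.eq5d),
            costs=self.costs.copy(),
            imputed=set(self.imputed),
        )

    def outcome_values(self, outcome: str) -> dict[str, float | None]:
        if outcome == "mcs":
            return self.mcs
        if outcome == "pcs":
            return self.pcs
        if outcome == "eq5d":
            return self.eq5d
        raise ValueError(f"unknown outcome {outcome!r}")

    def is_observed(self, outcome: str, visit: str) -> bool:
        """True if the cell holds a genuinely observed (non-imputed) value."""
        return (
            self.outcome_values(outcome).get(visit) is not None
            and (outcome, visit) not in self.imputed
        )

    def validate(self) -> None:
        pid = self.participant_id
        if not pid:
            raise ValidationError("empty participant_id")
        if self.arm not in ARMS:
            raise ValidationError(f"{pid}: arm must be one of {ARMS}, got {self.arm!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"{pid}: sex must be one of {SEXES}, got {self.sex!r}")
        if not self.age > 0:
            raise ValidationError(f"{pid}: age must be > 0, got {self.age}")
        for label, d, visits in (("mcs", self.mcs, SCORE_VISITS), ("pcs", self.pcs, SCORE_VISITS), ("eq5d", self.eq5d, UTILITY_VISITS)):
            if set(d) != set(visits):
                raise ValidationError(f"{pid}: {label} visits must be exactly {visits}")
        for v in self.eq5d.values():
            if v is not None and v > 1.0:
                raise ValidationError(f"{pid}: utility above 1.0: {v}")
        if not 0 <= self.sessions_structured <= MAX_SESSIONS_STRUCTURED:
            raise ValidationError(f"{pid}: sessions_structured out of range: {self.sessions_structured}")
        if not 0 <= self.sessions_education <= MAX_SESSIONS_EDUCATION:
            raise ValidationError(f"{pid}: sessions_education out of range: {self.sessions_education}")
        if self.minutes_structured < 0:
            raise ValidationError(f"{pid}: minutes_structured negative")
        self.costs.validate(pid, self.arm)

    def is_analyzable(self, outcome: str = "mcs") -> bool:
        base_visit = "week0" if outcome in ("mcs", "pcs") else "month0"
        return self.outcome_values(outcome)[base_visit] is not None


@dataclass
class TrialDataset:
    records: list[ParticipantRecord]
    currency_year: str = "2021/2022"
    horizon_years: float = 0.5
    allocation_seed: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    def copy(self) -> "TrialDataset":
        return TrialDataset(
            records=[r.copy() for r in self.records],
            currency_year=self.currency_year,
            horizon_years=self.horizon_years,
            allocation_seed=self.allocation_seed,
        )

    def arm(self, arm: str) -> list[ParticipantRecord]:
        return [r for r in self.records if r.arm == arm]

    def validate(self) -> None:
        if self.horizon_years <= 0:
            raise ValidationError(f"horizon_years must be > 0, got {self.horizon_years}")
        seen: set[str] = set()
        for r in self.records:
            r.validate()
            if r.participant_id in seen:
                raise ValidationError(f"duplicate participant_id {r.participant_id!r}")
            seen.add(r.participant_id)
        arms = {r.arm for r in self.records}
        if arms != set(ARMS):
            raise ValidationError(f"both arms must be represented, found {sorted(arms)}")

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-participant view for analysis."""
        rows = [_record_to_row(r) for r in self.records]
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        for col in df.columns:
            if col not in ("participant_id", "arm", "sex", "completed_week24"):
                df[col] = pd.to_numeric(df[col])
        df["completed_week24"] = df["completed_week24"] == "true"
        return df


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    return repr(float(value))


def _record_to_row(r: ParticipantRecord) -> dict[str, str]:
    row = {
        "participant_id": r.participant_id,
        "arm": r.arm,
        "age": _fmt(r.age),
        "sex": r.sex,
        "completed_week24": "true" if r.completed_week24 else "false",
        "sessions_structured": str(r.sessions_structured),
        "sessions_education": str(r.sessions_education),
        "minutes_structured": _fmt(r.minutes_structured),
    }
    for (outcome, visit), col in _SCORE_COL.items():
        row[col] = _fmt(getattr(r, outcome)[visit])
    for visit, col in _UTILITY_COL.items():
        row[col] = _fmt(r.eq5d[visit])
    for c in COST_COMPONENTS:
        for w in COST_WINDOWS:
            row[f"cost_{c}_{w}"] = _fmt(r.costs.get(w, c))
    return row


def _parse_float(cell: str, row_id: str, column: str) -> float | None:
    cell = cell.strip()
    if cell == "" or cell.upper() == "NA":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise ValidationError(f"row {row_id!r}, column {column!r}: not a number: {cell!r}") from exc


def read_trial_csv(path: str | Path, schema_version: str = SCHEMA_VERSION) -> TrialDataset:
    """Read and validate a trial CSV.

    Empty cells (or the sentinel ``NA``) become explicit missing values.
    The header must match the documented schema exactly.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        if header != CSV_COLUMNS:
            expected, got = set(CSV_COLUMNS), set(header)
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            detail = []
            if missing:
                detail.append(f"missing columns {missing}")
            if extra:
                detail.append(f"unexpected columns {extra}")
            if not detail:
                detail.append("columns out of order")
            raise SchemaError(f"{path}: header mismatch: " + "; ".join(detail))
        records = []
        for raw in reader:
            if not raw:
                continue
            row = dict(zip(CSV_COLUMNS, raw))
            pid = row["participant_id"]
            rec = ParticipantRecord(
                participant_id=pid,
                arm=row["arm"],
                age=_parse_float(row["age"], pid, "age") or 0.0,
                sex=row["sex"],
                completed_week24=row["completed_week24"].strip().lower() == "true",
                sessions_structured=int(row["sessions_structured"] or 0),
                sessions_education=int(row["sessions_education"] or 0),
                minutes_structured=_parse_float(row["minutes_structured"], pid, "minutes_structured") or 0.0,
            )
            for (outcome, visit), col in _SCORE_COL.items():
                getattr(rec, outcome)[visit] = _parse_float(row[col], pid, col)
            for visit, col in _UTILITY_COL.items():
                rec.eq5d[visit] = _parse_float(row[col], pid, col)
            for c in COST_COMPONENTS:
                for w in COST_WINDOWS:
                    col = f"cost_{c}_{w}"
                    val = _parse_float(row[col], pid, col)
                    if val is not None and val < 0:
                        raise ValidationError(f"row {pid!r}, column {col!r}: negative cost {val}")
                    if c == "intervention" and val is None:
                        val = 0.0
                    rec.costs.set(w, c, val)
            records.append(rec)
    ds = TrialDataset(records=records)
    ds.validate()
    return ds


def write_trial_csv(dataset: TrialDataset, path: str | Path) -> Path:
    """Write a validated dataset; missing values become empty cells."""
    dataset.validate()
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in dataset.records:
            row = _record_to_row(r)
            writer.writerow([row[c] for c in CSV_COLUMNS])
    return path
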