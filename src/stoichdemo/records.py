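"""Domain records and delimited-text I/O.

Single source of truth for the four table schemas the pipeline consumes
and emits: the individual event log, the serial-transfer census table,
the morphometry table and the elemental-composition table. All files
are UTF-8 comma-separated text with a header row and fixed column
order; readers validate every stated invariant and report offending
rows by number.

Event times are hours from the focal individual's birth; census time is
integer days. The chemostat replicate is the true unit of replication
and is carried on every record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

EGG_FATES = ("hatched", "died", "male", "unresolved")
END_REASONS = (
    "death",
    "censored_male_egg",
    "censored_horizon",
    "completed_k_neonates",
)
EVENT_TYPES = (
    "hatch",
    "egg_laid",
    "egg_hatched",
    "egg_died",
    "male_egg",
    "death",
    "censored",
)

EVENT_LOG_COLUMNS = [
    "individual_id",
    "clone",
    "treatment",
    "chemostat_replicate",
    "event_type",
    "event_time_h",
    "egg_index",
    "detail",
]
CENSUS_COLUMNS = [
    "unit_id",
    "clone",
    "treatment",
    "chemostat_replicate",
    "day",
    "n_start",
    "n_end",
]
MORPHOMETRY_COLUMNS = [
    "individual_id",
    "clone",
    "treatment",
    "chemostat_replicate",
    "body_length_um",
    "body_width_um",
    "egg_length_um",
    "egg_width_um",
    "maturation_interval_h",
]
ELEMENTAL_COLUMNS = [
    "sample_id",
    "clone",
    "treatment",
    "chemostat_replicate",
    "organism",
    "c_mass_ug",
    "n_mass_ug",
    "p_mass_ug",
    "n_individuals",
]
ALGAL_CP_COLUMNS = [
    "treatment",
    "chemostat_replicate",
    "occasion",
    "molar_cp",
]


class ValidationError(ValueError):
    """Schema or invariant violation; message lists every offending row."""


@dataclass
class EggEvent:
    """One egg of one mother: when laid, and how it resolved."""

    egg_index: int
    lay_time: float
    fate: str = "unresolved"
    fate_time: float | None = None

    def validate(self) -> None:
        if self.fate not in EGG_FATES:
            raise ValidationError(f"unknown egg fate {self.fate!r}")
        if self.fate == "unresolved":
            if self.fate_time is not None:
                raise ValidationError("unresolved egg must have no fate_time")
        else:
            if self.fate_time is None:
                raise ValidationError(f"{self.fate} egg requires fate_time")
            if self.fate_time < self.lay_time:
                raise ValidationError(
                    f"egg {self.egg_index}: fate_time {self.fate_time} "
                    f"precedes lay_time {self.lay_time}"
                )


@dataclass
class IndividualRecord:
    """One experimental animal's observed timeline.

    ``birth_time`` is the origin of the age axis (usually 0);
    ``end_time`` is when monitoring stopped, with ``end_reason``
    explaining why. Eggs are ordered by lay time with consecutive
    indices from 1.
    """

    individual_id: str
    clone: str
    treatment: str
    chemostat_replicate: str
    birth_time: float
    end_time: float
    end_reason: str
    eggs: list[EggEvent] = field(default_factory=list)

    def validate(self) -> None:
        if self.end_reason not in END_REASONS:
            raise ValidationError(f"unknown end_reason {self.end_reason!r}")
        if self.end_time < self.birth_time:
            raise ValidationError(
                f"{self.individual_id}: end_time precedes birth_time"
            )
        for i, egg in enumerate(self.eggs, start=1):
            if egg.egg_index != i:
                raise ValidationError(
                    f"{self.individual_id}: egg indices not consecutive from 1"
                )
            if not (self.birth_time < egg.lay_time <= self.end_time):
                raise ValidationError(
                    f"{self.individual_id}: egg {i} lay_time {egg.lay_time} "
                    f"outside ({self.birth_time}, {self.end_time}]"
                )
            egg.validate()

    @property
    def died(self) -> bool:
        return self.end_reason == "death"


@dataclass
class CensusSeries:
    """Daily serial-transfer counts for one culture unit.

    Each observation is ``(day, N0, Nt)``: the day index, the count the
    unit was re-seeded with at the start of the 24-h period and the
    count at its end.
    """

    unit_id: str
    clone: str
    treatment: str
    chemostat_replicate: str
    observations: list[tuple[int, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        days = [d for d, _, _ in self.observations]
        if any(b >= a for a, b in zip(days[1:], days[:-1])):
            raise ValidationError(f"{self.unit_id}: days not strictly increasing")
        for day, n0, nt in self.observations:
            if n0 < 0 or nt < 0:
                raise ValidationError(f"{self.unit_id} day {day}: negative count")


# ---------------------------------------------------------------------------
# event log

def records_to_events(records: Iterable[IndividualRecord]) -> pd.DataFrame:
    """Flatten individual records into the event-log table."""
    rows = []
    for rec in records:
        base = (rec.individual_id, rec.clone, rec.treatment, rec.chemostat_replicate)
        rows.append((*base, "hatch", rec.birth_time, "", ""))
        for egg in rec.eggs:
            rows.append((*base, "egg_laid", egg.lay_time, egg.egg_index, ""))
            if egg.fate == "hatched":
                rows.append((*base, "egg_hatched", egg.fate_time, egg.egg_index, ""))
            elif egg.fate == "died":
                rows.append((*base, "egg_died", egg.fate_time, egg.egg_index, ""))
            elif egg.fate == "male":
                rows.append((*base, "male_egg", egg.fate_time, egg.egg_index, ""))
        terminal = "death" if rec.end_reason == "death" else "censored"
        rows.append((*base, terminal, rec.end_time, "", rec.end_reason))
    df = pd.DataFrame(rows, columns=EVENT_LOG_COLUMNS)
    return df.sort_values(
        ["individual_id", "event_time_h"], kind="stable"
    ).reset_index(drop=True)


def events_to_records(events: pd.DataFrame, strict: bool = True) -> list[IndividualRecord]:
    """Reassemble validated :class:`IndividualRecord` objects from an event table."""
    problems: list[str] = []
    records: list[IndividualRecord] = []
    for ind_id, grp in events.groupby("individual_id", sort=True):
        grp = grp.sort_values("event_time_h", kind="stable")
        meta = grp.iloc[0]
        birth = grp[grp.event_type == "hatch"]
        terminal = grp[grp.event_type.isin(["death", "censored"])]
        if len(birth) != 1 or len(terminal) != 1:
            problems.append(
                f"individual {ind_id}: needs exactly one hatch and one terminal event"
            )
            continue
        birth_time = float(birth.iloc[0].event_time_h)
        end_row = terminal.iloc[0]
        end_time = float(end_row.event_time_h)
        if end_row.event_type == "death":
            end_reason = "death"
        else:
            end_reason = str(end_row.detail) or "censored_horizon"
        eggs: dict[int, EggEvent] = {}
        for _, row in grp[grp.event_type == "egg_laid"].iterrows():
            idx = int(row.egg_index)
            eggs[idx] = EggEvent(idx, float(row.event_time_h))
        fate_map = {"egg_hatched": "hatched", "egg_died": "died", "male_egg": "male"}
        for ev, fate in fate_map.items():
            for _, row in grp[grp.event_type == ev].iterrows():
                idx = int(row.egg_index)
                if idx not in eggs:
                    problems.append(
                        f"individual {ind_id}: {ev} for egg {idx} with no egg_laid row"
                    )
                    continue
                eggs[idx].fate = fate
                eggs[idx].fate_time = float(row.event_time_h)
        rec = IndividualRecord(
            individual_id=str(ind_id),
            clone=str(meta.clone),
            treatment=str(meta.treatment),
            chemostat_replicate=str(meta.chemostat_replicate),
            birth_time=birth_time,
            end_time=end_time,
            end_reason=end_reason,
            eggs=[eggs[i] for i in sorted(eggs)],
        )
        try:
            rec.validate()
        except ValidationError as exc:
            problems.append(f"individual {ind_id}: {exc}")
            continue
        records.append(rec)
    if problems:
        msg = "; ".join(problems)
        if strict:
            raise ValidationError(msg)
        logger.warning("dropped invalid individuals: %s", msg)
    return records


def write_event_log(records: Iterable[IndividualRecord], path) -> None:
    records_to_events(records).to_csv(path, index=False)


def read_event_log(path, strict: bool = True) -> list[IndividualRecord]:
    """Read and validate an event log; see :data:`EVENT_LOG_COLUMNS`.

    With ``strict`` (default) any invariant violation raises a
    :class:`ValidationError` naming every offending row or individual;
    in lenient mode bad individuals are dropped and logged.
    """
    df = pd.read_csv(path, dtype={"detail": "string"}, keep_default_na=False)
    missing = [c for c in EVENT_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"event log missing columns: {missing}")
    bad_types = df[~df.event_type.isin(EVENT_TYPES)]
    if len(bad_types):
        rows = ", ".join(str(i + 2) for i in bad_types.index)  # header is line 1
        msg = f"unknown event_type on file line(s) {rows}"
        if strict:
            raise ValidationError(msg)
        logger.warning(msg)
        df = df[df.event_type.isin(EVENT_TYPES)]
    return events_to_records(df, strict=strict)


# ---------------------------------------------------------------------------
# census

def census_to_frame(series: Iterable[CensusSeries]) -> pd.DataFrame:
    rows = [
        (s.unit_id, s.clone, s.treatment, s.chemostat_replicate, day, n0, nt)
        for s in series
        for day, n0, nt in s.observations
    ]
    return pd.DataFrame(rows, columns=CENSUS_COLUMNS)


def write_census(series: Iterable[CensusSeries], path) -> None:
    census_to_frame(series).to_csv(path, index=False)


def read_census(path, strict: bool = True) -> list[CensusSeries]:
    df = pd.read_csv(path)
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"census table missing columns: {missing}")
    if df.empty:
        logger.warning("census file %s has a header but no rows", path)
        return []
    dupes = df.duplicated(subset=["unit_id", "day"], keep=False)
    if dupes.any():
        rows = ", ".join(str(i + 2) for i in df.index[dupes])
        msg = f"duplicate (unit_id, day) on file line(s) {rows}"
        if strict:
            raise ValidationError(msg)
        logger.warning(msg)
        df = df[~df.duplicated(subset=["unit_id", "day"], keep="first")]
    out: list[CensusSeries] = []
    problems: list[str] = []
    for unit_id, grp in df.groupby("unit_id", sort=True):
        grp = grp.sort_values("day")
        meta = grp.iloc[0]
        s = CensusSeries(
            unit_id=str(unit_id),
            clone=str(meta.clone),
            treatment=str(meta.treatment),
            chemostat_replicate=str(meta.chemostat_replicate),
            observations=[
                (int(r.day), int(r.n_start), int(r.n_end)) for _, r in grp.iterrows()
            ],
        )
        try:
            s.validate()
        except ValidationError as exc:
            problems.append(str(exc))
            continue
        out.append(s)
    if problems:
        msg = "; ".join(problems)
        if strict:
            raise ValidationError(msg)
        logger.warning("dropped invalid census units: %s", msg)
    return out


# ---------------------------------------------------------------------------
# simple frame-backed tables

def _read_table(path, columns: Sequence[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} table missing columns: {missing}")
    return df


def read_morphometry(path) -> pd.DataFrame:
    df = _read_table(path, MORPHOMETRY_COLUMNS, "morphometry")
    dims = ["body_length_um", "body_width_um", "egg_length_um", "egg_width_um"]
    bad = df[(df[dims] <= 0).any(axis=1) & df[dims].notna().all(axis=1)]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad.index)
        raise ValidationError(f"non-positive dimension on file line(s) {rows}")
    return df


def read_elemental(path) -> pd.DataFrame:
    df = _read_table(path, ELEMENTAL_COLUMNS, "elemental")
    bad = df[(df[["c_mass_ug", "n_mass_ug", "p_mass_ug"]] < 0).any(axis=1)
             | (df.n_individuals < 1)]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad.index)
        raise ValidationError(f"invalid elemental row on file line(s) {rows}")
    return df


def read_algal_cp(path) -> pd.DataFrame:
    df = _read_table(path, ALGAL_CP_COLUMNS, "algal C:P")
    bad = df[df.molar_cp <= 0]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad.index)
        raise ValidationError(f"non-positive molar C:P on file line(s) {rows}")
    return df


def write_tables(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write named DataFrames as ``<name>.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written
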