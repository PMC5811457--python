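"""Age-classed survivorship/fecundity schedules and life-history traits.

The life table is built on a fixed age-class grid (default 2 h, the
observation resolution). ``lx`` is the fraction of individuals known
alive entering class x among those not yet right-censored: censored
animals (male-egg producers, horizon-truncated) simply leave the risk
set, deaths stay in the denominator. ``mx`` counts neonates *hatched*
in class x per individual at risk there, so egg mortality reduces
fecundity exactly as it reduces population growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import IndividualRecord


@dataclass
class AgeSchedule:
    """Survivorship (lx) and fecundity (mx) on a uniform age grid.

    ``x`` holds class midpoints in hours; ``truncated`` flags schedules
    from cohorts whose monitoring ended at a fixed horizon rather than
    at the reproductive stopping rule.
    """

    age_class_width: float
    x: np.ndarray
    lx: np.ndarray
    mx: np.ndarray
    n_individuals: int
    truncated: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.lx = np.asarray(self.lx, dtype=float)
        self.mx = np.asarray(self.mx, dtype=float)
        if not (len(self.x) == len(self.lx) == len(self.mx)):
            raise ValueError("x, lx, mx must have equal length")
        if np.any((self.lx < 0) | (self.lx > 1)):
            raise ValueError("lx must lie in [0, 1]")
        if np.any(np.diff(self.lx) > 1e-12):
            raise ValueError("lx must be non-increasing")
        if np.any(self.mx < 0):
            raise ValueError("mx must be non-negative")

    @property
    def x_days(self) -> np.ndarray:
        return self.x / 24.0

    @property
    def net_reproductive_rate(self) -> float:
        """R0 = sum lx*mx, lifetime offspring per individual."""
        return float(np.sum(self.lx * self.mx))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_h": self.x, "lx": self.lx, "mx": self.mx}
        )


@dataclass
class LifeHistoryTraits:
    """Per-individual traits extracted from one record."""

    individual_id: str
    treatment: str
    chemostat_replicate: str
    age_at_first_egg: float | None
    development_times: dict[int, float] = field(default_factory=dict)
    egg_production_rate: float | None = None
    died: bool = False
    eggs_total: int = 0
    eggs_died: int = 0


def build_schedule(
    records: Sequence[IndividualRecord],
    age_class_width: float = 2.0,
    denominator: str = "survivors",
) -> AgeSchedule:
    """Build the lx/mx schedule for a cohort.

    ``denominator`` selects the mx convention: ``"survivors"`` (default)
    divides hatched neonates in a class by individuals at risk there;
    ``"initial"`` divides by the starting cohort size.
    """
    if not records:
        raise ValueError("cannot build a schedule from zero records")
    if age_class_width <= 0:
        raise ValueError("age_class_width must be > 0")
    if denominator not in ("survivors", "initial"):
        raise ValueError("denominator must be 'survivors' or 'initial'")
    w = age_class_width

    end_ages = [r.end_time - r.birth_time for r in records]
    if max(end_ages) <= 0:
        raise ValueError("all individuals censored at birth")
    n_classes = int(math.floor(max(end_ages) / w)) + 1
    starts = np.arange(n_classes) * w

    death_age = np.array([
        (r.end_time - r.birth_time) if r.died else math.inf for r in records
    ])
    censor_age = np.array([
        math.inf if r.died else (r.end_time - r.birth_time) for r in records
    ])

    # alive & under observation entering class j
    alive = (death_age[None, :] > starts[:, None]) & (
        censor_age[None, :] >= starts[:, None]
    )
    n_alive = alive.sum(axis=1)
    # risk set for lx: everyone not censored before the class start
    in_risk = (censor_age[None, :] >= starts[:, None]) | np.isfinite(
        death_age[None, :]
    )
    n_risk = in_risk.sum(axis=1)
    if n_risk[0] == 0:
        raise ValueError("empty risk set at birth")
    with np.errstate(invalid="ignore"):
        lx = np.where(n_risk > 0, n_alive / np.maximum(n_risk, 1), 0.0)

    hatches = np.zeros(n_classes)
    for r in records:
        for egg in r.eggs:
            if egg.fate == "hatched":
                age = egg.fate_time - r.birth_time
                j = int(math.floor(round(age / w, 9)))
                if j >= n_classes:  # hatch at the final boundary
                    j = n_classes - 1
                hatches[j] += 1
    if denominator == "survivors":
        mx = np.where(n_alive > 0, hatches / np.maximum(n_alive, 1), 0.0)
    else:
        mx = hatches / len(records)

    truncated = any(r.end_reason == "censored_horizon" for r in records)
    return AgeSchedule(
        age_class_width=w,
        x=starts + w / 2.0,
        lx=lx,
        mx=mx,
        n_individuals=len(records),
        truncated=truncated,
    )


def extract_traits(record: IndividualRecord) -> LifeHistoryTraits:
    """Per-individual life-history traits.

    The egg production rate is total eggs laid divided by the span from
    first to last lay time; it requires at least two laying events and
    is otherwise flagged unavailable (None). Development times are
    reported per hatched egg.
    """
    lays = [e.lay_time for e in record.eggs]
    age_first = lays[0] - record.birth_time if lays else None
    dev = {
        e.egg_index: e.fate_time - e.lay_time
        for e in record.eggs
        if e.fate == "hatched"
    }
    rate = None
    if len(lays) >= 2 and lays[-1] > lays[0]:
        rate = len(lays) / (lays[-1] - lays[0])
    resolved = [e for e in record.eggs if e.fate in ("hatched", "died")]
    return LifeHistoryTraits(
        individual_id=record.individual_id,
        treatment=record.treatment,
        chemostat_replicate=record.chemostat_replicate,
        age_at_first_egg=age_first,
        development_times=dev,
        egg_production_rate=rate,
        died=record.died,
        eggs_total=len(record.eggs),
        eggs_died=sum(1 for e in record.eggs if e.fate == "died"),
    )


def traits_table(records: Iterable[IndividualRecord]) -> pd.DataFrame:
    """Trait table with one row per individual."""
    rows = []
    for rec in records:
        t = extract_traits(rec)
        first_dev = t.development_times.get(1)
        rows.append({
            "individual_id": t.individual_id,
            "treatment": t.treatment,
            "chemostat_replicate": t.chemostat_replicate,
            "age_at_first_egg_h": t.age_at_first_egg,
            "first_egg_development_h": first_dev,
            "mean_egg_development_h": (
                float(np.mean(list(t.development_times.values())))
                if t.development_times else None
            ),
            "egg_production_rate_per_h": t.egg_production_rate,
            "died": t.died,
            "eggs_total": t.eggs_total,
            "eggs_died": t.eggs_died,
        })
    return pd.DataFrame(rows)


def mortality_summary(records: Sequence[IndividualRecord]) -> pd.DataFrame:
    """Per-treatment individual and egg mortality, in percent (1 d.p.).

    Egg mortality excludes male and unresolved eggs from the
    denominator; with zero resolved eggs it is flagged unavailable.
    """
    if not records:
        raise ValueError("no records")
    rows = []
    by_treatment: dict[str, list[IndividualRecord]] = {}
    for r in records:
        by_treatment.setdefault(r.treatment, []).append(r)
    for treatment, recs in sorted(by_treatment.items()):
        n = len(recs)
        deaths = sum(1 for r in recs if r.died)
        resolved = died = 0
        for r in recs:
            for e in r.eggs:
                if e.fate in ("hatched", "died"):
                    resolved += 1
                    died += e.fate == "died"
        rows.append({
            "treatment": treatment,
            "n_individuals": n,
            "individual_mortality_pct": round(100.0 * deaths / n, 1),
            "n_resolved_eggs": resolved,
            "egg_mortality_pct": (
                round(100.0 * died / resolved, 1) if resolved else None
            ),
        })
    return pd.DataFrame(rows)
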