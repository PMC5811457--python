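"""Individual-based generator for feeding-trial data.

Produces the four inputs the analysis consumes — individual event logs,
serial-transfer census series, morphometric measurements and elemental
composition tables — under the statistical structure the downstream
estimators assume.

The observation process mirrors the trial protocol: latent event times
are continuous, but every event is *discovered* at the first scheduled
check at or after it happens, so reported times sit on the 2-hour
observation grid (rounded up). Monitoring of an individual ends at the
earliest of: its death, the laying of a male egg (right-censoring), the
hatching of the k-th neonate (HP and LP+P arms), or the fixed horizon
(62 h in the LP arm, where development is too slow for the k-neonate
rule).

Randomness: one master seed deterministically spawns an independent
substream per experimental unit, keyed by (stream, treatment,
replicate, unit index). Subsetting the design therefore never changes
the data of a retained unit.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .config import (
    CLONES,
    DEFAULT_CLONE_RATE_OFFSETS,
    TREATMENTS,
    ConfigurationError,
    DesignConfig,
    TreatmentParams,
)
from .records import CensusSeries, EggEvent, IndividualRecord

import pandas as pd

# substream tags: keep unit keys disjoint across the three generators
_STREAM_INDIVIDUALS = 1
_STREAM_CENSUS = 2
_STREAM_MORPHO = 3
_STREAM_ELEMENTAL = 4
_STREAM_ALGAL = 5

#: individuals pooled per elemental sample
ELEMENTAL_POOL_SIZE = 150


def _unit_rng(seed: int, stream: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, *key]))


def _pos_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gaussian truncated at zero (redraw); degenerate to the mean at sd=0."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    return max(mean, 1e-9)  # pragma: no cover - pathological sd/mean ratio


def _grid_up(t: float, width: float) -> float:
    """First check at or after latent time t."""
    return math.ceil(round(t / width, 9)) * width


def _check_params(
    design: DesignConfig, params: Mapping[str, TreatmentParams]
) -> list[str]:
    design.validate()
    labels = list(params)
    for label in labels:
        if label not in TREATMENTS:
            raise ConfigurationError(f"unknown treatment label {label!r}")
        params[label].validate()
    return labels


def simulate_individuals(
    design: DesignConfig,
    params: Mapping[str, TreatmentParams],
    seed: int,
) -> list[IndividualRecord]:
    """Simulate the life-table experiment.

    Returns one :class:`IndividualRecord` per design cell
    (treatments x chemostat replicates x individuals); the default
    three-arm design yields 225 records. All reported times are
    multiples of ``design.observation_interval``.
    """
    labels = _check_params(design, params)
    records = []
    for t_idx, label in enumerate(labels):
        p = params[label]
        for rep in range(1, design.n_chemostat_replicates + 1):
            for ind in range(1, design.n_individuals_per_replicate + 1):
                rng = _unit_rng(seed, _STREAM_INDIVIDUALS, t_idx, rep, ind)
                rec = _simulate_one(design, p, rng,
                                    individual_id=f"{label}-r{rep}-i{ind:03d}",
                                    replicate=f"chemo{rep}")
                records.append(rec)
    return records


def _simulate_one(
    design: DesignConfig,
    p: TreatmentParams,
    rng: np.random.Generator,
    individual_id: str,
    replicate: str,
    clone: str = "D12",
) -> IndividualRecord:
    w = design.observation_interval
    use_horizon = p.treatment_label == "LP"
    cap = design.lp_horizon if use_horizon else design.max_horizon

    # latent death time: per-check Bernoulli hazard -> geometric over checks
    p_check = 1.0 - (1.0 - p.adult_hazard) ** w
    death = rng.geometric(p_check) * w if p_check > 0 else math.inf

    # latent laying schedule up to death or the horizon cap
    lays: list[float] = []
    t = _pos_normal(rng, p.maturation_time_mean, p.maturation_time_sd)
    while t <= min(death, cap):
        lays.append(t)
        t += _pos_normal(rng, p.inter_egg_interval_mean, p.inter_egg_interval_sd)

    # egg fates in lay order; observed (grid) times throughout
    eggs: list[EggEvent] = []
    male_obs = math.inf
    for lay in lays:
        lay_obs = _grid_up(lay, w)
        idx = len(eggs) + 1
        if rng.random() < p.male_egg_prob:
            eggs.append(EggEvent(idx, lay_obs, "male", lay_obs))
            male_obs = lay_obs
            break  # monitoring stops at the male egg: later lays unobserved
        dev = _pos_normal(rng, p.egg_development_time_mean, p.egg_development_time_sd)
        fate = "died" if rng.random() < p.egg_mortality_prob else "hatched"
        eggs.append(EggEvent(idx, lay_obs, fate, _grid_up(lay + dev, w)))

    # end of monitoring: earliest applicable rule
    death_obs = death if math.isfinite(death) else math.inf  # already on grid
    hatch_times = sorted(e.fate_time for e in eggs if e.fate == "hatched")
    kth = (hatch_times[design.k_neonates - 1]
           if not use_horizon and len(hatch_times) >= design.k_neonates
           else math.inf)
    horizon = cap if use_horizon else design.max_horizon
    candidates = [
        (death_obs, "death"),
        (male_obs, "censored_male_egg"),
        (kth, "completed_k_neonates"),
        (horizon, "censored_horizon"),
    ]
    end_time, end_reason = min(candidates, key=lambda c: c[0])

    kept: list[EggEvent] = []
    for egg in eggs:
        if egg.lay_time > end_time:
            break
        if egg.fate_time is not None and egg.fate_time > end_time:
            egg = EggEvent(egg.egg_index, egg.lay_time, "unresolved", None)
        kept.append(egg)

    rec = IndividualRecord(
        individual_id=individual_id,
        clone=clone,
        treatment=p.treatment_label,
        chemostat_replicate=replicate,
        birth_time=0.0,
        end_time=float(end_time),
        end_reason=end_reason,
        eggs=kept,
    )
    rec.validate()
    return rec


def simulate_census(
    design: DesignConfig,
    params: Mapping[str, TreatmentParams],
    seed: int,
    clone_rate_offsets: Mapping[str, float] | None = None,
) -> list[CensusSeries]:
    """Simulate the serial-transfer census experiment.

    Each unit restarts every day from ``census_seed_count`` individuals;
    the day's end count is lognormal around the configured exponential
    growth rate, so the expected daily log-ratio equals that rate. The
    default design (3 clones x 3 treatments x 5 replicates) yields 45
    series of ``census_days`` observations.
    """
    labels = _check_params(design, params)
    if design.census_days < 2:
        raise ConfigurationError("census_days must be >= 2")
    if clone_rate_offsets is None:
        clone_rate_offsets = DEFAULT_CLONE_RATE_OFFSETS
    clones = CLONES[: design.n_clones]
    out = []
    for c_idx, clone in enumerate(clones):
        offset = clone_rate_offsets.get(clone, 0.0)
        for t_idx, label in enumerate(labels):
            p = params[label]
            rate = p.census_growth_rate + offset
            for rep in range(1, design.n_chemostat_replicates + 1):
                rng = _unit_rng(seed, _STREAM_CENSUS, c_idx, t_idx, rep)
                obs = []
                n0 = design.census_seed_count
                for day in range(1, design.census_days + 1):
                    log_ratio = rate + (
                        rng.normal(0.0, p.census_log_sd) if p.census_log_sd > 0 else 0.0
                    )
                    nt = max(0, round(n0 * math.exp(log_ratio)))
                    obs.append((day, n0, int(nt)))
                s = CensusSeries(
                    unit_id=f"{clone}-{label}-r{rep}",
                    clone=clone,
                    treatment=label,
                    chemostat_replicate=f"chemo{rep}",
                    observations=obs,
                )
                s.validate()
                out.append(s)
    return out


def simulate_composition_tables(
    design: DesignConfig,
    params: Mapping[str, TreatmentParams],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the morphometry, rotifer-elemental and algal C:P tables.

    Morphometry follows the shortened life-table design (treatments x
    replicates x ``n_individuals_morphometry``; 75 rows by default).
    One elemental row is produced per clone x treatment x replicate,
    each a pooled sample of 150 animals. Algal molar C:P is drawn per
    treatment x replicate x sampling occasion around the configured
    centre, with per-batch dispersion implied by the configured standard
    error of the treatment mean (sd = se * sqrt(replicates x occasions)).
    """
    labels = _check_params(design, params)

    morpho_rows = []
    for t_idx, label in enumerate(labels):
        p = params[label]
        for rep in range(1, design.n_chemostat_replicates + 1):
            for ind in range(1, design.n_individuals_morphometry + 1):
                rng = _unit_rng(seed, _STREAM_MORPHO, t_idx, rep, ind)
                maturation = _pos_normal(rng, p.maturation_time_mean,
                                         p.maturation_time_sd)
                morpho_rows.append((
                    f"{label}-r{rep}-m{ind:02d}", "D12", label, f"chemo{rep}",
                    _pos_normal(rng, p.body_length_mean, p.body_length_sd),
                    _pos_normal(rng, p.body_width_mean, p.body_width_sd),
                    _pos_normal(rng, p.egg_length_mean, p.egg_length_sd),
                    _pos_normal(rng, p.egg_width_mean, p.egg_width_sd),
                    math.ceil(maturation),  # checked hourly in this experiment
                ))
    morphometry = pd.DataFrame(morpho_rows, columns=[
        "individual_id", "clone", "treatment", "chemostat_replicate",
        "body_length_um", "body_width_um", "egg_length_um", "egg_width_um",
        "maturation_interval_h",
    ])

    elem_rows = []
    clones = CLONES[: design.n_elemental_clones]
    cv = 0.05  # within-treatment coefficient of variation of pooled masses
    for c_idx, clone in enumerate(clones):
        for t_idx, label in enumerate(labels):
            p = params[label]
            for rep in range(1, design.n_chemostat_replicates + 1):
                rng = _unit_rng(seed, _STREAM_ELEMENTAL, c_idx, t_idx, rep)
                elem_rows.append((
                    f"{clone}-{label}-r{rep}", clone, label, f"chemo{rep}",
                    "rotifer",
                    _pos_normal(rng, p.rotifer_c_mass, cv * p.rotifer_c_mass),
                    _pos_normal(rng, p.rotifer_n_mass, cv * p.rotifer_n_mass),
                    _pos_normal(rng, p.rotifer_p_mass, cv * p.rotifer_p_mass),
                    ELEMENTAL_POOL_SIZE,
                ))
    elemental = pd.DataFrame(elem_rows, columns=[
        "sample_id", "clone", "treatment", "chemostat_replicate", "organism",
        "c_mass_ug", "n_mass_ug", "p_mass_ug", "n_individuals",
    ])

    algal_rows = []
    n_batches = design.n_chemostat_replicates * design.n_algal_occasions
    for t_idx, label in enumerate(labels):
        p = params[label]
        batch_sd = p.algal_cp_se * math.sqrt(n_batches)
        for rep in range(1, design.n_chemostat_replicates + 1):
            for occ in range(1, design.n_algal_occasions + 1):
                rng = _unit_rng(seed, _STREAM_ALGAL, t_idx, rep, occ)
                algal_rows.append((
                    label, f"chemo{rep}", occ,
                    _pos_normal(rng, p.algal_cp_mean, batch_sd),
                ))
    algal = pd.DataFrame(algal_rows, columns=[
        "treatment", "chemostat_replicate", "occasion", "molar_cp",
    ])
    return morphometry, elemental, algal
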