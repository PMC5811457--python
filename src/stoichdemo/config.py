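"""Treatment parameters and experimental-design configuration.

The three food-quality arms of a P-supplementation trial are labelled
``HP`` (P-replete algae), ``LP`` (P-limited algae) and ``LP+P``
(P-limited algae spiked with inorganic phosphate just before feeding).
:class:`TreatmentParams` carries everything the individual-based
generator needs for one arm; :class:`DesignConfig` carries the design
dimensions (treatments x chemostat replicates x individuals, census
layout, observation grid).

Defaults reproduce the canonical trial layout: 3 treatments x 5
chemostat replicates x 15 individuals for the life table (225 units),
3 clones x 3 treatments x 5 replicates for the census experiment
(45 units), 5 individuals per replicate for morphometrics (75 units),
a 2-hour observation grid, and per-arm monitoring rules (HP and LP+P
until the fourth neonate, LP for a fixed 62 h).
"""

from __future__ import annotations

import configparser
import dataclasses
import io
from dataclasses import dataclass, field

TREATMENTS = ("HP", "LP", "LP+P")

#: clones used in the census experiment (two lake-derived lineages plus one
#: from a second lake); the life-table experiment uses the first only.
CLONES = ("D12", "D61", "E1")


class ConfigurationError(ValueError):
    """Raised when a design or parameter set violates its invariants."""


@dataclass
class TreatmentParams:
    """Generator parameters for one food-quality treatment.

    Times are hours, linear dimensions micrometres, masses micrograms
    per pooled elemental sample, and ``algal_cp_*`` dimensionless molar
    ratios. ``adult_hazard`` is a per-hour death probability;
    ``egg_mortality_prob`` applies once per (female) egg at laying.
    """

    treatment_label: str
    maturation_time_mean: float
    maturation_time_sd: float
    inter_egg_interval_mean: float
    inter_egg_interval_sd: float
    egg_development_time_mean: float
    egg_development_time_sd: float
    egg_mortality_prob: float
    adult_hazard: float
    male_egg_prob: float
    body_length_mean: float
    body_length_sd: float
    body_width_mean: float
    body_width_sd: float
    egg_length_mean: float
    egg_length_sd: float
    egg_width_mean: float
    egg_width_sd: float
    algal_cp_mean: float
    algal_cp_se: float
    rotifer_c_mass: float
    rotifer_n_mass: float
    rotifer_p_mass: float
    #: configured true per-day exponential growth rate for the census model
    census_growth_rate: float = 0.0
    #: lognormal sd of the daily census log-ratio
    census_log_sd: float = 0.15

    def validate(self) -> None:
        for name in ("egg_mortality_prob", "male_egg_prob", "adult_hazard"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        positive = (
            "maturation_time_mean",
            "inter_egg_interval_mean",
            "egg_development_time_mean",
            "body_length_mean",
            "body_width_mean",
            "egg_length_mean",
            "egg_width_mean",
            "algal_cp_mean",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        nonneg = (
            "maturation_time_sd",
            "inter_egg_interval_sd",
            "egg_development_time_sd",
            "body_length_sd",
            "body_width_sd",
            "egg_length_sd",
            "egg_width_sd",
            "algal_cp_se",
            "census_log_sd",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass
class DesignConfig:
    """Design dimensions shared by all simulated experiments."""

    n_chemostat_replicates: int = 5
    n_individuals_per_replicate: int = 15
    n_individuals_morphometry: int = 5
    n_clones: int = 3
    n_elemental_clones: int = 2
    observation_interval: float = 2.0  # hours between checks
    k_neonates: int = 4               # HP / LP+P stopping rule
    lp_horizon: float = 62.0          # hours, LP stopping rule
    max_horizon: float = 240.0        # hard cap on any unit, hours
    census_days: int = 22
    census_seed_count: int = 10
    n_algal_occasions: int = 5        # C:P sampling occasions per replicate
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_chemostat_replicates,
            self.n_individuals_per_replicate,
            self.n_individuals_morphometry,
            self.n_clones,
            self.n_elemental_clones,
            self.k_neonates,
            self.census_seed_count,
            self.n_algal_occasions,
        )
        if any(c < 1 for c in counts):
            raise ConfigurationError("all design counts must be >= 1")
        if self.observation_interval <= 0:
            raise ConfigurationError("observation_interval must be > 0")
        if self.census_days < 2:
            raise ConfigurationError("census_days must be >= 2")
        if self.lp_horizon <= 0 or self.max_horizon <= 0:
            raise ConfigurationError("monitoring horizons must be > 0")


def default_params() -> dict[str, TreatmentParams]:
    """Default per-treatment parameters.

    Trait means follow the treatment ordering of the trial (HP fastest /
    largest, LP slowest, LP+P intermediate, with egg size and first-egg
    development time tracking LP instead); algal C:P centres are the
    measured 112 / 631 / 113 with their standard errors. Absolute life
    history values are illustrative since the source data report them
    graphically only.
    """
    hp = TreatmentParams(
        treatment_label="HP",
        maturation_time_mean=22.0, maturation_time_sd=2.0,
        inter_egg_interval_mean=4.0, inter_egg_interval_sd=0.8,
        egg_development_time_mean=12.0, egg_development_time_sd=1.2,
        egg_mortality_prob=0.0,
        adult_hazard=0.0,
        male_egg_prob=0.02,
        body_length_mean=240.0, body_length_sd=12.0,
        body_width_mean=150.0, body_width_sd=8.0,
        egg_length_mean=110.0, egg_length_sd=6.0,
        egg_width_mean=85.0, egg_width_sd=4.0,
        algal_cp_mean=112.0, algal_cp_se=2.6,
        rotifer_c_mass=15.0, rotifer_n_mass=3.5, rotifer_p_mass=0.387,
        census_growth_rate=0.80,
    )
    lpp = TreatmentParams(
        treatment_label="LP+P",
        maturation_time_mean=26.0, maturation_time_sd=2.4,
        inter_egg_interval_mean=6.0, inter_egg_interval_sd=1.2,
        egg_development_time_mean=14.5, egg_development_time_sd=1.4,
        egg_mortality_prob=0.0,
        adult_hazard=0.00035,
        male_egg_prob=0.02,
        body_length_mean=238.6, body_length_sd=12.0,
        body_width_mean=149.1, body_width_sd=8.0,
        egg_length_mean=121.9, egg_length_sd=6.0,
        egg_width_mean=94.2, egg_width_sd=4.5,
        algal_cp_mean=113.0, algal_cp_se=2.7,
        rotifer_c_mass=17.19, rotifer_n_mass=3.85, rotifer_p_mass=0.419,
        census_growth_rate=0.66,
    )
    lp = TreatmentParams(
        treatment_label="LP",
        maturation_time_mean=38.0, maturation_time_sd=3.5,
        inter_egg_interval_mean=11.2, inter_egg_interval_sd=2.0,
        egg_development_time_mean=14.7, egg_development_time_sd=1.4,
        egg_mortality_prob=0.231,
        adult_hazard=0.00134,
        male_egg_prob=0.02,
        body_length_mean=228.2, body_length_sd=12.0,
        body_width_mean=142.7, body_width_sd=8.0,
        egg_length_mean=123.1, egg_length_sd=6.0,
        egg_width_mean=95.1, egg_width_sd=4.5,
        algal_cp_mean=631.0, algal_cp_se=14.9,
        rotifer_c_mass=10.35, rotifer_n_mass=2.5, rotifer_p_mass=0.132,
        census_growth_rate=0.495,
    )
    return {"HP": hp, "LP": lp, "LP+P": lpp}


#: additive per-clone offsets on the census growth rate (per day); clones
#: differ measurably in the trial but share the treatment response pattern.
DEFAULT_CLONE_RATE_OFFSETS = {"D12": 0.03, "D61": 0.0, "E1": -0.03}


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings with documented defaults."""

    design: DesignConfig = field(default_factory=DesignConfig)
    params: dict[str, TreatmentParams] = field(default_factory=default_params)
    age_class_width: float = 2.0        # hours, matches the observation grid
    solver_tol: float = 1e-10           # Euler-Lotka residual tolerance
    solver_bracket: tuple[float, float] = (-5.0, 5.0)  # per day
    census_window: int = 16             # final scored days used for the mean
    n_boot: int = 1000
    scenario_tolerance_pct: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        self.design.validate()
        for label, p in self.params.items():
            if p.treatment_label != label:
                raise ConfigurationError(
                    f"params key {label!r} does not match label {p.treatment_label!r}"
                )
            p.validate()
        if self.age_class_width <= 0:
            raise ConfigurationError("age_class_width must be > 0")
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")


# ---------------------------------------------------------------------------
# flat key-value config file (INI sections: [design], [pipeline], one block
# per treatment); every field is overridable, omitted keys keep defaults.

def _to_configparser(cfg: PipelineConfig) -> configparser.ConfigParser:
    cp = configparser.ConfigParser()
    cp["design"] = {
        k: repr(v) for k, v in dataclasses.asdict(cfg.design).items()
    }
    cp["pipeline"] = {
        "age_class_width": repr(cfg.age_class_width),
        "solver_tol": repr(cfg.solver_tol),
        "solver_bracket_low": repr(cfg.solver_bracket[0]),
        "solver_bracket_high": repr(cfg.solver_bracket[1]),
        "census_window": repr(cfg.census_window),
        "n_boot": repr(cfg.n_boot),
        "scenario_tolerance_pct": repr(cfg.scenario_tolerance_pct),
        "seed": repr(cfg.seed),
    }
    for label, p in cfg.params.items():
        d = dataclasses.asdict(p)
        d.pop("treatment_label")
        cp[f"treatment:{label}"] = {k: repr(v) for k, v in d.items()}
    return cp


def write_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        _to_configparser(cfg).write(fh)


def _coerce(value: str, like):
    if isinstance(like, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(like, int):
        return int(value)
    if isinstance(like, float):
        return float(value)
    return value


def read_config(path) -> PipelineConfig:
    cp = configparser.ConfigParser()
    with open(path, encoding="utf-8") as fh:
        cp.read_file(fh)
    cfg = PipelineConfig()
    if cp.has_section("design"):
        for k, v in cp["design"].items():
            if not hasattr(cfg.design, k):
                raise ConfigurationError(f"unknown design key {k!r}")
            setattr(cfg.design, k, _coerce(v, getattr(cfg.design, k)))
    if cp.has_section("pipeline"):
        sec = cp["pipeline"]
        for k in ("age_class_width", "solver_tol", "scenario_tolerance_pct"):
            if k in sec:
                setattr(cfg, k, float(sec[k]))
        for k in ("census_window", "n_boot", "seed"):
            if k in sec:
                setattr(cfg, k, int(sec[k]))
        lo = float(sec.get("solver_bracket_low", cfg.solver_bracket[0]))
        hi = float(sec.get("solver_bracket_high", cfg.solver_bracket[1]))
        cfg.solver_bracket = (lo, hi)
    for section in cp.sections():
        if not section.startswith("treatment:"):
            continue
        label = section.split(":", 1)[1]
        if label not in cfg.params:
            raise ConfigurationError(f"unknown treatment label {label!r}")
        p = cfg.params[label]
        for k, v in cp[section].items():
            if not hasattr(p, k):
                raise ConfigurationError(f"unknown parameter {k!r} for {label}")
            setattr(p, k, _coerce(v, getattr(p, k)))
    cfg.validate()
    return cfg


def config_to_string(cfg: PipelineConfig) -> str:
    buf = io.StringIO()
    _to_configparser(cfg).write(buf)
    return buf.getvalue()
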