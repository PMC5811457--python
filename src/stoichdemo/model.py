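"""Model/results interface for a three-arm P-supplementation trial.

:class:`FeedingTrial` bundles the four raw inputs (individual event
records, census series, morphometry, elemental composition) with the
analysis configuration; :meth:`FeedingTrial.fit` runs the full
pipeline — life-table schedules, intrinsic and census growth rates,
stoichiometric summaries, and the direct/indirect decomposition with
bootstrap intervals — and returns a :class:`TrialResults` whose
``summary()`` prints the trait-by-trait report.

Typical use::

    trial = FeedingTrial.from_simulation(seed=1)
    res = trial.fit()
    print(res.summary())
    res.decomposition_table

Trait means are always computed per chemostat replicate first (the
true unit of replication) and only then averaged per treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import demography, lifetable, morphometrics, stoichiometry
from .config import TREATMENTS, DesignConfig, PipelineConfig, TreatmentParams
from .decomposition import (
    DecompositionResult,
    UndefinedComponentError,
    bootstrap_components,
    classify_scenario,
    decompose,
    decomposition_table,
)
from .records import CensusSeries, IndividualRecord
from .simulate import (
    simulate_census,
    simulate_composition_tables,
    simulate_individuals,
)

#: trait -> (orientation, survival-convention flag)
TRAIT_REGISTRY: dict[str, tuple[str, bool]] = {
    "population_growth_rate": ("benefit", False),
    "intrinsic_growth_rate": ("benefit", False),
    "somatic_growth_rate": ("benefit", False),
    "age_at_first_egg": ("cost", False),
    "first_egg_development_time": ("cost", False),
    "egg_production_rate": ("benefit", False),
    "egg_mortality": ("cost", True),
    "body_volume": ("benefit", False),
    "first_egg_volume": ("benefit", False),
    "rotifer_cp_ratio": ("cost", False),
    "rotifer_c_content": ("benefit", False),
    "rotifer_p_content": ("benefit", False),
}


class FeedingTrial:
    """A P-supplementation feeding trial ready to be analysed.

    Parameters
    ----------
    records
        Individual life-table records (may be empty).
    census
        Serial-transfer census series (may be empty).
    morphometry, elemental, algal_cp
        The corresponding measurement tables (may be None).
    config
        Pipeline settings; defaults reproduce the canonical design.
    """

    def __init__(
        self,
        records: Sequence[IndividualRecord] = (),
        census: Sequence[CensusSeries] = (),
        morphometry: pd.DataFrame | None = None,
        elemental: pd.DataFrame | None = None,
        algal_cp: pd.DataFrame | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        self.records = list(records)
        self.census = list(census)
        self.morphometry = morphometry
        self.elemental = elemental
        self.algal_cp = algal_cp
        self.config = config or PipelineConfig()
        self.config.validate()

    @classmethod
    def from_simulation(
        cls, config: PipelineConfig | None = None, seed: int | None = None
    ) -> "FeedingTrial":
        """Generate a complete trial from the individual-based simulator."""
        cfg = config or PipelineConfig()
        if seed is not None:
            cfg.seed = seed
        cfg.validate()
        records = simulate_individuals(cfg.design, cfg.params, cfg.seed)
        census = simulate_census(cfg.design, cfg.params, cfg.seed)
        morpho, elem, algal = simulate_composition_tables(
            cfg.design, cfg.params, cfg.seed
        )
        return cls(records, census, morpho, elem, algal, cfg)

    @classmethod
    def from_files(
        cls,
        event_log=None,
        census=None,
        morphometry=None,
        elemental=None,
        algal_cp=None,
        config: PipelineConfig | None = None,
        strict: bool = True,
    ) -> "FeedingTrial":
        """Build a trial from the delimited-text tables."""
        from . import records as rio

        return cls(
            rio.read_event_log(event_log, strict=strict) if event_log else (),
            rio.read_census(census, strict=strict) if census else (),
            rio.read_morphometry(morphometry) if morphometry else None,
            rio.read_elemental(elemental) if elemental else None,
            rio.read_algal_cp(algal_cp) if algal_cp else None,
            config,
        )

    # ------------------------------------------------------------------
    def fit(self, n_boot: int | None = None, seed: int | None = None) -> "TrialResults":
        """Run the full analysis; deterministic for fixed config and seed."""
        cfg = self.config
        n_boot = cfg.n_boot if n_boot is None else n_boot
        seed = cfg.seed if seed is None else seed

        rep_rows: list[dict] = []  # tidy: treatment, replicate, trait, value

        traits_df = pd.DataFrame()
        mortality = pd.DataFrame()
        schedules: dict[tuple[str, str], lifetable.AgeSchedule] = {}
        growth_rows: list[dict] = []

        if self.records:
            traits_df = lifetable.traits_table(self.records)
            mortality = lifetable.mortality_summary(self.records)
            for (treatment, rep), grp in traits_df.groupby(
                ["treatment", "chemostat_replicate"]
            ):
                for trait, col in (
                    ("age_at_first_egg", "age_at_first_egg_h"),
                    ("first_egg_development_time", "first_egg_development_h"),
                    ("egg_production_rate", "egg_production_rate_per_h"),
                ):
                    vals = grp[col].dropna()
                    if len(vals):
                        rep_rows.append(dict(
                            treatment=treatment, chemostat_replicate=rep,
                            trait=trait, value=float(vals.mean()),
                        ))
                died = int(grp.eggs_died.sum())
                n_resolved = self._resolved_eggs(treatment, rep)
                if n_resolved:
                    rep_rows.append(dict(
                        treatment=treatment, chemostat_replicate=rep,
                        trait="egg_mortality", value=died / n_resolved,
                    ))
            # replicate-level schedules and intrinsic rates
            by_rep: dict[tuple[str, str], list[IndividualRecord]] = {}
            for r in self.records:
                by_rep.setdefault((r.treatment, r.chemostat_replicate), []).append(r)
            for (treatment, rep), recs in sorted(by_rep.items()):
                sched = lifetable.build_schedule(recs, cfg.age_class_width)
                schedules[(treatment, rep)] = sched
                try:
                    est = demography.euler_lotka_r(
                        sched, tol=cfg.solver_tol, bracket=cfg.solver_bracket
                    )
                except demography.NoReproductionError:
                    continue
                growth_rows.append(dict(
                    unit_id=f"{treatment}-{rep}", clone="D12",
                    treatment=treatment, chemostat_replicate=rep,
                    method="euler_lotka", r_per_day=est.r,
                    residual=est.residual, truncated=est.truncated,
                ))
                rep_rows.append(dict(
                    treatment=treatment, chemostat_replicate=rep,
                    trait="intrinsic_growth_rate", value=est.r,
                ))

        if self.census:
            census_unit = []
            for s in self.census:
                est = demography.census_growth_rate(s, window=cfg.census_window)
                census_unit.append(dict(
                    unit_id=s.unit_id, clone=s.clone, treatment=s.treatment,
                    chemostat_replicate=s.chemostat_replicate,
                    method="census", r_per_day=est.r,
                    residual=None, truncated=False,
                ))
            growth_rows.extend(census_unit)
            cdf = pd.DataFrame(census_unit)
            for (treatment, rep), grp in cdf.groupby(
                ["treatment", "chemostat_replicate"]
            ):
                rep_rows.append(dict(
                    treatment=treatment, chemostat_replicate=rep,
                    trait="population_growth_rate",
                    value=float(grp.r_per_day.mean()),
                ))

        morpho_df = None
        if self.morphometry is not None and len(self.morphometry):
            morpho_df = morphometrics.morphometry_summary(self.morphometry)
            for (treatment, rep), grp in morpho_df.groupby(
                ["treatment", "chemostat_replicate"]
            ):
                for trait, col in (
                    ("body_volume", "body_volume_um3"),
                    ("first_egg_volume", "egg_volume_um3"),
                    ("somatic_growth_rate", "somatic_growth_um3_per_h"),
                ):
                    rep_rows.append(dict(
                        treatment=treatment, chemostat_replicate=rep,
                        trait=trait, value=float(grp[col].mean()),
                    ))

        elem_df = None
        if self.elemental is not None and len(self.elemental):
            elem_df = stoichiometry.elemental_summary(self.elemental)
            for (treatment, rep), grp in elem_df.groupby(
                ["treatment", "chemostat_replicate"]
            ):
                for trait, col in (
                    ("rotifer_cp_ratio", "molar_cp"),
                    ("rotifer_c_content", "c_per_individual_ug"),
                    ("rotifer_p_content", "p_per_individual_ug"),
                ):
                    rep_rows.append(dict(
                        treatment=treatment, chemostat_replicate=rep,
                        trait=trait, value=float(grp[col].mean()),
                    ))

        algal_summary = None
        if self.algal_cp is not None and len(self.algal_cp):
            g = self.algal_cp.groupby("treatment").molar_cp
            algal_summary = pd.DataFrame({
                "mean_cp": g.mean(),
                "se_cp": g.sem(),
                "n_batches": g.size(),
            }).reset_index()

        replicate_traits = pd.DataFrame(
            rep_rows, columns=["treatment", "chemostat_replicate", "trait", "value"]
        )

        results: list[DecompositionResult] = []
        for i, trait in enumerate(TRAIT_REGISTRY):
            orientation, as_survival = TRAIT_REGISTRY[trait]
            sub = replicate_traits[replicate_traits.trait == trait]
            if sub.empty or set(sub.treatment) != set(TREATMENTS):
                continue
            rep_means = {
                t: sub[sub.treatment == t].value.to_numpy() for t in TREATMENTS
            }
            means = {t: float(v.mean()) for t, v in rep_means.items()}
            try:
                res = decompose(means, orientation, trait, as_survival)
            except UndefinedComponentError:
                continue
            classify_scenario(res, cfg.scenario_tolerance_pct)
            if all(len(v) >= 2 for v in rep_means.values()):
                try:
                    res.ci = bootstrap_components(
                        rep_means, orientation, n_boot=n_boot,
                        seed=seed + i, as_survival=as_survival,
                    )
                except (ValueError, UndefinedComponentError):
                    pass
            results.append(res)

        return TrialResults(
            model=self,
            traits_individual=traits_df,
            replicate_traits=replicate_traits,
            mortality=mortality,
            schedules=schedules,
            growth_rates=pd.DataFrame(growth_rows),
            morphometry=morpho_df,
            elemental=elem_df,
            algal_summary=algal_summary,
            decomposition=results,
        )

    def _resolved_eggs(self, treatment: str, replicate: str) -> int:
        n = 0
        for r in self.records:
            if r.treatment == treatment and r.chemostat_replicate == replicate:
                n += sum(1 for e in r.eggs if e.fate in ("hatched", "died"))
        return n


@dataclass
class TrialResults:
    """Fitted quantities, uncertainties and report tables for one trial."""

    model: FeedingTrial
    traits_individual: pd.DataFrame
    replicate_traits: pd.DataFrame
    mortality: pd.DataFrame
    schedules: dict
    growth_rates: pd.DataFrame
    morphometry: pd.DataFrame | None
    elemental: pd.DataFrame | None
    algal_summary: pd.DataFrame | None
    decomposition: list[DecompositionResult]

    @property
    def decomposition_table(self) -> pd.DataFrame:
        return decomposition_table(self.decomposition)

    def treatment_means(self, trait: str) -> pd.Series:
        """Replicate-first treatment means for one trait."""
        sub = self.replicate_traits[self.replicate_traits.trait == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present in this fit")
        return sub.groupby("treatment").value.mean()

    def tables(self) -> dict[str, pd.DataFrame]:
        """All report tables, named as written by ``save``."""
        out = {
            "replicate_traits": self.replicate_traits,
            "growth_rates": self.growth_rates,
            "decomposition": self.decomposition_table,
        }
        if len(self.mortality):
            out["mortality"] = self.mortality
        if len(self.traits_individual):
            out["individual_traits"] = self.traits_individual
        if self.morphometry is not None:
            out["morphometry"] = self.morphometry
        if self.elemental is not None:
            out["elemental"] = self.elemental
        if self.algal_summary is not None:
            out["algal_cp_summary"] = self.algal_summary
        return out

    def save(self, out_dir) -> list:
        from .records import write_tables

        return write_tables(self.tables(), out_dir)

    def summary(self) -> str:
        """Human-readable report of means, rates and the decomposition."""
        lines = ["P-supplementation trial analysis", "=" * 34, ""]
        if len(self.mortality):
            lines += ["Mortality (per treatment)",
                      self.mortality.to_string(index=False), ""]
        if len(self.growth_rates):
            g = (self.growth_rates
                 .groupby(["method", "treatment"]).r_per_day
                 .agg(["mean", "sem", "count"]).reset_index())
            lines += ["Growth rates (per day)", g.to_string(index=False), ""]
        if self.algal_summary is not None:
            lines += ["Algal molar C:P",
                      self.algal_summary.to_string(index=False), ""]
        if self.decomposition:
            lines += ["Direct/indirect decomposition (relative differences, %)",
                      self.decomposition_table.to_string(index=False), ""]
        return "\n".join(lines)

    def plot_trait(self, trait: str, ax=None):
        """Treatment mean +/- 2 SE of replicate means for one trait."""
        import matplotlib.pyplot as plt

        sub = self.replicate_traits[self.replicate_traits.trait == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present in this fit")
        if ax is None:
            _, ax = plt.subplots()
        order = [t for t in TREATMENTS if t in set(sub.treatment)]
        means = [sub[sub.treatment == t].value.mean() for t in order]
        ses = [sub[sub.treatment == t].value.sem() for t in order]
        ax.errorbar(range(len(order)), means,
                    yerr=[2 * s for s in ses], fmt="o", capsize=4)
        ax.set_xticks(range(len(order)), order)
        ax.set_ylabel(trait)
        ax.set_xlabel("food quality treatment")
        return ax
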