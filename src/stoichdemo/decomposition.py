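"""Direct/indirect decomposition of food-quality effects.

The three-arm P-supplementation contrast splits a trait's response to
P-limited food into:

* an **indirect** (non-stoichiometric) component, the relative
  difference between the supplemented arm and the P-replete arm,
  ``100 * (LP+P - HP) / HP`` — P content is equal, so any difference
  reflects the algae's P-limited growth history;
* a **direct** (stoichiometric) component, the relative difference
  between the P-limited and supplemented arms,
  ``100 * (LP - LP+P) / (LP+P)`` — growth history is shared, so any
  difference reflects elemental P content itself.

Mortality-type traits (cost-oriented proportions) are decomposed on
survival = 1 - mortality: a zero-mortality baseline otherwise makes
the relative difference undefined.

Scenario labels follow the three canonical response patterns: I (purely
direct), III (purely indirect), II (both substantial), judged against a
tolerance in percentage points.

Uncertainty comes from a percentile bootstrap over chemostat
replicates — the true unit of replication — resampled with replacement
within each treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TREATMENT_KEYS = ("HP", "LP", "LP+P")


class UndefinedComponentError(ZeroDivisionError):
    """A reference mean of zero makes a relative difference undefined."""


@dataclass
class DecompositionResult:
    """Direct and indirect components of one trait's treatment response."""

    trait: str
    orientation: str                  # "benefit" or "cost"
    mean_HP: float
    mean_LP: float
    mean_LPP: float
    indirect_pct: float
    direct_pct: float
    survival_convention: bool = False
    scenario: str | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def _components(
    m_hp: float, m_lp: float, m_lpp: float, as_survival: bool
) -> tuple[float, float]:
    if as_survival:
        m_hp, m_lp, m_lpp = 1.0 - m_hp, 1.0 - m_lp, 1.0 - m_lpp
    if m_hp == 0 or m_lpp == 0:
        raise UndefinedComponentError(
            "zero reference mean; for mortality-type traits decompose on survival"
        )
    indirect = 100.0 * (m_lpp - m_hp) / m_hp
    direct = 100.0 * (m_lp - m_lpp) / m_lpp
    return indirect, direct


def decompose(
    means: Mapping[str, float],
    orientation: str = "benefit",
    trait: str = "trait",
    as_survival: bool = False,
) -> DecompositionResult:
    """Split a trait's treatment response into indirect and direct parts.

    ``means`` maps the three treatment labels to trait means (replicate
    averages). With ``as_survival`` the means are proportions on [0, 1]
    read as mortalities and decomposed on 1 - mortality.
    """
    if orientation not in ("benefit", "cost"):
        raise ValueError("orientation must be 'benefit' or 'cost'")
    missing = [k for k in TREATMENT_KEYS if k not in means]
    if missing:
        raise ValueError(f"missing treatment means: {missing}")
    m_hp, m_lp, m_lpp = (float(means[k]) for k in TREATMENT_KEYS)
    if as_survival and not all(0.0 <= m <= 1.0 for m in (m_hp, m_lp, m_lpp)):
        raise ValueError("survival-convention traits must lie in [0, 1]")
    indirect, direct = _components(m_hp, m_lp, m_lpp, as_survival)
    return DecompositionResult(
        trait=trait,
        orientation=orientation,
        mean_HP=m_hp,
        mean_LP=m_lp,
        mean_LPP=m_lpp,
        indirect_pct=indirect,
        direct_pct=direct,
        survival_convention=as_survival,
    )


def classify_scenario(
    result: DecompositionResult, tolerance_pct: float = 5.0
) -> str:
    """Label the response pattern.

    ``I``: only the direct component exceeds the tolerance (P content
    explains the whole response); ``III``: only the indirect component
    does; ``II``: both do; ``no effect``: neither does.
    """
    i, d = abs(result.indirect_pct), abs(result.direct_pct)
    if i <= tolerance_pct and d > tolerance_pct:
        label = "I"
    elif d <= tolerance_pct and i > tolerance_pct:
        label = "III"
    elif i > tolerance_pct and d > tolerance_pct:
        label = "II"
    else:
        label = "no effect"
    result.scenario = label
    return label


def bootstrap_components(
    replicate_means: Mapping[str, Sequence[float]],
    orientation: str = "benefit",
    n_boot: int = 1000,
    seed: int = 0,
    as_survival: bool = False,
    ci_level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CIs for both components.

    Chemostat replicates are resampled with replacement independently
    within each treatment; each resample is averaged and decomposed.
    Resamples with an undefined component are skipped.
    """
    arrays = {}
    for k in TREATMENT_KEYS:
        vals = np.asarray(replicate_means[k], dtype=float)
        if len(vals) < 2:
            raise ValueError(f"need >= 2 replicates per treatment, {k} has {len(vals)}")
        arrays[k] = vals
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    ind = np.empty(n_boot)
    dire = np.empty(n_boot)
    kept = 0
    for _ in range(n_boot):
        means = {
            k: float(np.mean(rng.choice(v, size=len(v), replace=True)))
            for k, v in arrays.items()
        }
        try:
            i, d = _components(
                means["HP"], means["LP"], means["LP+P"], as_survival
            )
        except UndefinedComponentError:
            continue
        ind[kept], dire[kept] = i, d
        kept += 1
    if kept == 0:
        raise UndefinedComponentError("all bootstrap resamples undefined")
    alpha = (1.0 - ci_level) / 2.0
    q = [100.0 * alpha, 100.0 * (1.0 - alpha)]
    lo_i, hi_i = np.percentile(ind[:kept], q)
    lo_d, hi_d = np.percentile(dire[:kept], q)
    return {
        "indirect": (float(lo_i), float(hi_i)),
        "direct": (float(lo_d), float(hi_d)),
    }


def decomposition_table(results: Sequence[DecompositionResult]) -> pd.DataFrame:
    """Long-format report: one row per trait x effect source."""
    rows = []
    for res in results:
        for source, pct in (("Indirect", res.indirect_pct), ("Direct", res.direct_pct)):
            key = source.lower()
            lo, hi = res.ci.get(key, (None, None))
            rows.append({
                "trait": res.trait,
                "contrast": "(LP+P)-HP" if source == "Indirect" else "LP-(LP+P)",
                "effect_source": source,
                "relative_difference_pct": round(pct, 1),
                "ci_low_pct": None if lo is None else round(lo, 1),
                "ci_high_pct": None if hi is None else round(hi, 1),
                "scenario": res.scenario,
            })
    return pd.DataFrame(rows)
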