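"""Population growth-rate estimators.

Two routes to r:

* the intrinsic rate of increase from a life-table schedule, as the
  unique root of the discrete Euler-Lotka equation
  ``1 = sum_x lx * mx * exp(-r * x)`` (ages at class midpoints,
  converted to days so r is per day);
* the realised exponential rate from a serial-transfer census, as the
  mean of daily log-ratios ``ln(Nt) - ln(N0)`` over a scoring window
  (by default the final 16 scored days, where growth has stabilised).

The Euler-Lotka left-hand side is strictly decreasing in r whenever
some lx*mx > 0, so bracketed root finding (Brent, with automatic
bracket expansion) is exact up to the residual tolerance; the sign law
r > 0 <=> R0 > 1 holds by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .lifetable import AgeSchedule
from .records import CensusSeries


class NoReproductionError(ValueError):
    """Schedule has R0 = 0; the intrinsic rate is undefined (-inf)."""


@dataclass
class GrowthEstimate:
    """A per-day growth rate with its provenance and diagnostics."""

    r: float
    method: str  # "euler_lotka" or "census"
    residual: float | None = None          # |sum lx*mx*e^(-r x) - 1|
    window: tuple[int, int] | None = None  # first/last scored day
    per_day_rates: np.ndarray | None = None
    n_excluded_days: int = 0
    truncated: bool = False


def euler_lotka_r(
    schedule: AgeSchedule,
    tol: float = 1e-10,
    bracket: tuple[float, float] = (-5.0, 5.0),
    max_expansions: int = 60,
) -> GrowthEstimate:
    """Solve the Euler-Lotka equation for the intrinsic rate r (per day).

    Raises :class:`NoReproductionError` when the schedule has no
    reproduction (R0 = 0); expands the bracket geometrically if the
    root lies outside it.
    """
    x = schedule.x_days
    lxmx = schedule.lx * schedule.mx
    r0 = float(lxmx.sum())
    if r0 <= 0:
        raise NoReproductionError("schedule has zero net reproduction")
    # zero-fecundity classes contribute nothing; dropping them lets the
    # sum be evaluated in log space, which keeps the solver stable even
    # for tiny lx*mx whose root would overflow exp in linear arithmetic
    keep = lxmx > 0
    x, lxmx = x[keep], lxmx[keep]
    log_lxmx = np.log(lxmx)

    def g(r: float) -> float:
        # log of the Euler-Lotka sum; same sign and root as the sum - 1
        return float(logsumexp(log_lxmx - r * x))

    lo, hi = bracket
    glo, ghi = g(lo), g(hi)
    # g is decreasing: need g(lo) > 0 > g(hi)
    n = 0
    while glo < 0 and n < max_expansions:
        lo *= 2.0
        glo = g(lo)
        n += 1
    while ghi > 0 and n < max_expansions:
        hi *= 2.0
        ghi = g(hi)
        n += 1
    if not (glo >= 0 >= ghi):
        raise ValueError(
            f"could not bracket the Euler-Lotka root within [{lo}, {hi}]"
        )
    root = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    residual = abs(math.exp(g(root)) - 1.0)
    if residual > tol:
        raise ValueError(f"solver residual {residual} exceeds tolerance {tol}")
    return GrowthEstimate(
        r=float(root),
        method="euler_lotka",
        residual=residual,
        truncated=schedule.truncated,
    )


def census_growth_rate(
    series: CensusSeries,
    window: int = 16,
) -> GrowthEstimate:
    """Mean daily exponential rate over the final ``window`` scored days.

    Each day contributes ``ln(Nt) - ln(N0)`` per 24 h; days with
    ``Nt = 0`` are flagged and excluded from the mean but counted in
    ``n_excluded_days``. A day with ``N0 = 0`` cannot be scored at all.
    """
    obs = sorted(series.observations)
    if window < 1 or window > len(obs):
        raise ValueError(
            f"window of {window} days outside series of {len(obs)} days"
        )
    scored = obs[-window:]
    rates = []
    excluded = 0
    for day, n0, nt in scored:
        if n0 <= 0:
            raise ValueError(f"{series.unit_id} day {day}: N0 = 0 in window")
        if nt == 0:
            excluded += 1
            continue
        rates.append(math.log(nt) - math.log(n0))
    if not rates:
        raise ValueError(f"{series.unit_id}: no scorable days in window")
    return GrowthEstimate(
        r=float(np.mean(rates)),
        method="census",
        window=(scored[0][0], scored[-1][0]),
        per_day_rates=np.asarray(rates),
        n_excluded_days=excluded,
    )
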