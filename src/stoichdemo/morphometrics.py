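"""Volumes from linear dimensions, and somatic growth rates.

Body volume treats the animal as a cylinder-like solid of revolution,
``Vb = pi * Lb * (Wb/2)^2``; eggs are ellipsoids,
``Ve = (4/3) * pi * (Le/2) * (We/2)^2``. Somatic growth is the volume
gained between the first egg (starting size) and the body at first
reproduction, per hour of maturation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def body_volume(length_um: float, width_um: float) -> float:
    """pi * L * (W/2)^2, in cubic micrometres."""
    if np.any(np.asarray(length_um) <= 0) or np.any(np.asarray(width_um) <= 0):
        raise ValueError("body dimensions must be strictly positive")
    return math.pi * length_um * (width_um / 2.0) ** 2


def egg_volume(length_um: float, width_um: float) -> float:
    """Ellipsoid volume (4/3) * pi * (L/2) * (W/2)^2, in cubic micrometres."""
    if np.any(np.asarray(length_um) <= 0) or np.any(np.asarray(width_um) <= 0):
        raise ValueError("egg dimensions must be strictly positive")
    return (4.0 / 3.0) * math.pi * (length_um / 2.0) * (width_um / 2.0) ** 2


def somatic_growth_rate(
    body_volume_um3: float,
    first_egg_volume_um3: float,
    maturation_interval_h: float,
) -> float:
    """(Vb - Ve_first) / maturation time, in um^3 per hour.

    A negative rate (egg larger than adult) is returned as-is; callers
    decide whether to flag it.
    """
    if maturation_interval_h <= 0:
        raise ValueError("maturation interval must be > 0")
    return (body_volume_um3 - first_egg_volume_um3) / maturation_interval_h


def morphometry_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Add derived volumes and somatic growth rate to a morphometry table.

    Rows missing an egg measurement get the replicate-mean egg volume
    substituted (flagged in ``egg_volume_imputed``) so per-replicate
    means stay estimable.
    """
    df = table.copy()
    df["body_volume_um3"] = math.pi * df.body_length_um * (df.body_width_um / 2) ** 2
    ve = (4.0 / 3.0) * math.pi * (df.egg_length_um / 2) * (df.egg_width_um / 2) ** 2
    df["egg_volume_um3"] = ve
    df["egg_volume_imputed"] = df.egg_volume_um3.isna()
    fill = df.groupby(["treatment", "chemostat_replicate"])[
        "egg_volume_um3"
    ].transform("mean")
    df["egg_volume_um3"] = df.egg_volume_um3.fillna(fill)
    df["somatic_growth_um3_per_h"] = (
        df.body_volume_um3 - df.egg_volume_um3
    ) / df.maturation_interval_h
    return df
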