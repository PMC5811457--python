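"""Molar elemental ratios and per-individual composition.

Ratios follow the ecological-stoichiometry convention: moles of the
first element per mole of the second, computed from masses via atomic
masses C 12.011, N 14.007, P 30.974 (g/mol, 5 significant figures).
"""

from __future__ import annotations

import pandas as pd

ATOMIC_MASS = {"C": 12.011, "N": 14.007, "P": 30.974}


def molar_ratio(mass_a: float, mass_b: float, element_a: str, element_b: str) -> float:
    """Molar a:b ratio from masses of two elements (any common mass unit)."""
    for el in (element_a, element_b):
        if el not in ATOMIC_MASS:
            raise ValueError(f"unsupported element {el!r}; expected C, N or P")
    if mass_b <= 0:
        raise ZeroDivisionError(
            f"molar ratio undefined: {element_b} mass must be > 0"
        )
    if mass_a < 0:
        raise ValueError("masses must be non-negative")
    return (mass_a / ATOMIC_MASS[element_a]) / (mass_b / ATOMIC_MASS[element_b])


def per_individual_content(sample: pd.Series | dict) -> dict:
    """Per-animal C, N, P masses from a pooled elemental sample."""
    s = dict(sample)
    n = int(s["n_individuals"])
    if n < 1:
        raise ValueError("n_individuals must be >= 1")
    out = {k: s[k] for k in s if k not in ("c_mass_ug", "n_mass_ug", "p_mass_ug")}
    out["c_per_individual_ug"] = s["c_mass_ug"] / n
    out["n_per_individual_ug"] = s["n_mass_ug"] / n
    out["p_per_individual_ug"] = s["p_mass_ug"] / n
    return out


def elemental_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample molar ratios and per-individual contents."""
    df = table.copy()
    df["molar_cp"] = [
        molar_ratio(c, p, "C", "P") for c, p in zip(df.c_mass_ug, df.p_mass_ug)
    ]
    df["molar_cn"] = [
        molar_ratio(c, n, "C", "N") for c, n in zip(df.c_mass_ug, df.n_mass_ug)
    ]
    df["c_per_individual_ug"] = df.c_mass_ug / df.n_individuals
    df["n_per_individual_ug"] = df.n_mass_ug / df.n_individuals
    df["p_per_individual_ug"] = df.p_mass_ug / df.n_individuals
    return df
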