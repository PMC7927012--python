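"""Period life tables and mortality indicators.

A period life table follows a synthetic cohort of ``radix`` newborns through
a single calendar year's age-specific death probabilities ``q_x``.  From the
table we compute three indicators: remaining life expectancy ``e_x``, the
modal age at death ``M`` (the adult age with the largest synthetic-cohort
death count), and the Gini index of lifespan inequality derived from the
Lorenz curve of the distribution of ages at death.

Conventions
-----------
* The table is closed by forcing ``q`` at the last age ``omega`` to 1, so the
  cohort is extinct at ``omega + 1``.
* Those dying within an age interval are assumed to live half of it, at every
  age (``L_x = l_x - 0.5 d_x``); the fraction is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeriodLifeTable",
    "LorenzCurve",
    "build_period_table",
    "life_expectancy",
    "modal_age",
    "lorenz_points",
    "gini_index",
]

#: youngest age eligible as a modal age at death (infant/child mortality
#: excluded: the mode is searched over ages strictly above 5).
MIN_MODAL_AGE = 6


@dataclass(frozen=True)
class PeriodLifeTable:
    """One year's synthetic-cohort life table over contiguous ages 0..omega."""

    ages: np.ndarray
    q: np.ndarray        # death probability per age, q[omega] == 1
    l: np.ndarray        # survivors at exact age x
    d_table: np.ndarray  # synthetic-cohort deaths in [x, x+1)
    L: np.ndarray        # person-years lived in [x, x+1)
    T: np.ndarray        # person-years lived at and above x
    e: np.ndarray        # remaining life expectancy at x
    radix: float = 100_000.0

    @property
    def omega(self) -> int:
        return int(self.ages[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "q": self.q, "l": self.l, "d": self.d_table,
             "L": self.L, "T": self.T, "e": self.e}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class LorenzCurve:
    """Lorenz curve of the lifespan distribution.

    ``f[x]`` is the proportion of the cohort dead before age x; ``g[x]`` is
    the share of the cohort's total person-years that was lived by those
    decedents.  Both include a terminal point (1, 1) at extinction.
    """

    f: np.ndarray
    g: np.ndarray


def read_table_csv(path) -> PeriodLifeTable:
    """Read a life table written by :meth:`PeriodLifeTable.to_csv`."""
    df = pd.read_csv(path)
    return PeriodLifeTable(
        ages=df["age"].to_numpy(),
        q=df["q"].to_numpy(float),
        l=df["l"].to_numpy(float),
        d_table=df["d"].to_numpy(float),
        L=df["L"].to_numpy(float),
        T=df["T"].to_numpy(float),
        e=df["e"].to_numpy(float),
        radix=float(df["l"].iloc[0]),
    )


def build_period_table(
    q, radix: float = 100_000.0, interval_fraction: float = 0.5
) -> PeriodLifeTable:
    """Build a period life table from a death-probability vector.

    Parameters
    ----------
    q
        Death probabilities for contiguous integer ages ``0..omega``.  The
        last entry is forced to 1 (closure of the table).
    radix
        Size of the synthetic cohort at age 0.
    interval_fraction
        Fraction of the age interval lived by those dying within it.

    Raises
    ------
    ValueError
        If ``q`` is empty, has fewer than 2 ages, or lies outside [0, 1].
    """
    q = np.asarray(q, dtype=float).copy()
    if q.ndim != 1 or q.size == 0:
        raise ValueError("q must be a non-empty 1-D vector")
    if np.any(q < 0) or np.any(q > 1) or not np.all(np.isfinite(q)):
        raise ValueError("death probabilities must lie in [0, 1]")
    if radix <= 0:
        raise ValueError("radix must be positive")
    q[-1] = 1.0

    omega = q.size - 1
    ages = np.arange(omega + 1)
    # survivorship recursion l[x+1] = l[x] (1 - q[x])
    l = radix * np.concatenate([[1.0], np.cumprod(1.0 - q[:-1])])
    d = l * q
    L = l - (1.0 - interval_fraction) * d
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / np.where(l > 0, l, 1.0), np.nan)
    return PeriodLifeTable(ages=ages, q=q, l=l, d_table=d, L=L, T=T, e=e,
                           radix=float(radix))


def life_expectancy(table: PeriodLifeTable, x: int = 0) -> float:
    """Remaining life expectancy ``e_x = T_x / l_x`` at integer age ``x``."""
    if not 0 <= x <= table.omega:
        raise ValueError(f"age {x} outside table range 0..{table.omega}")
    if table.l[x] <= 0:
        raise ValueError(f"life expectancy undefined at age {x}: l[x] = 0")
    return float(table.T[x] / table.l[x])


def modal_age(table: PeriodLifeTable) -> int:
    """Modal age at death: the age above 5 with the most cohort deaths.

    Ties are broken toward the smallest qualifying age.
    """
    if table.omega < MIN_MODAL_AGE:
        raise ValueError(
            f"modal age needs ages beyond {MIN_MODAL_AGE - 1}; "
            f"table ends at {table.omega}"
        )
    adult = table.d_table[MIN_MODAL_AGE:]
    return MIN_MODAL_AGE + int(np.argmax(adult))


def lorenz_points(table: PeriodLifeTable) -> LorenzCurve:
    """Lorenz curve points of the lifespan distribution.

    ``f_x = 1 - l_x / l_0`` and ``g_x = (T_0 - T_x - x l_x) / T_0`` for
    ``x = 0..omega``; the terminal point (1, 1), reached at extinction one
    interval past ``omega``, is appended.
    """
    if table.T[0] <= 0:
        raise ValueError("degenerate table: no person-years lived")
    x = table.ages.astype(float)
    f = 1.0 - table.l / table.l[0]
    g = (table.T[0] - table.T - x * table.l) / table.T[0]
    f = np.append(f, 1.0)
    g = np.append(g, 1.0)
    return LorenzCurve(f=f, g=g)


def gini_index(table: PeriodLifeTable) -> float:
    """Gini index of lifespan inequality.

    Discrete Lorenz-curve estimator: the ratio of ``sum(f_x - g_x)`` to
    ``sum(f_x)`` with both sums over ages ``0..omega-1``.  0 means everyone
    dies at the same age; values approach 1 when deaths concentrate at birth
    with a single survivor to ``omega``.
    """
    curve = lorenz_points(table)
    omega = table.omega
    f = curve.f[:omega]  # x = 0..omega-1
    g = curve.g[:omega]
    denom = float(np.sum(f))
    if denom == 0.0:
        warnings.warn(
            "all mass survives to the last age: Lorenz curve degenerates to "
            "the diagonal; returning Gini = 0",
            RuntimeWarning,
        )
        return 0.0
    return float(np.sum(f - g) / denom)
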