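"""Synthetic mortality surfaces with known Lee-Carter/cohort structure.

The generator emulates the shape of a national male mortality surface: an
age profile with high infant mortality declining through childhood and a
Gompertz-like exponential rise at adult ages, positive age loadings
concentrated at young ages, a period index following a random walk with
downward drift (steadily improving mortality), an optional small second
bilinear component, and an optional smooth bounded cohort effect.  Death
counts are binomial given exposures, or beta-binomial when an
overdispersion factor phi > 1 is requested, matching the quasi-binomial
variance phi E q (1 - q).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .forecast import IndicatorCurveSet
from .lc_models import ModelParams, MortalitySurface, logit_clip

__all__ = ["ScenarioSpec", "make_params", "simulate_deaths",
           "make_scenario_surface", "make_fanova_fixture"]

# stylized death-probability schedule q*_x = c1 exp(-c2 x) + c3 exp(c4 x),
# capped below 0.7: infant decline plus Gompertz rise
SCHEDULE = (0.004, 0.6, 5e-5, 0.085)
Q_CAP = 0.7


@dataclass
class ScenarioSpec:
    """Default study scenario: ages 0-99 x 20 years, E = 1e5 per cell.

    The full 0-99 age range is kept so that remaining life expectancy at 65
    is defined; parameter-recovery studies use smaller grids.
    """

    ages: int = 100
    years: int = 20
    family: str = "LC1"
    drift: float = -0.8        # k random-walk drift, logit units per year
    sigma_k: float = 0.3       # k innovation SD
    exposure: float = 1e5      # per-cell exposure (scalar or per-age profile)
    dispersion: float = 1.0    # variance inflation phi >= 1
    seed: int = 0
    first_year: int = 1993
    gamma_amplitude: float = 0.2
    exposure_profile: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.dispersion < 1:
            raise ValueError("dispersion must be >= 1")


def make_params(A: int, T: int, family: str = "LC1", seed: int = 0,
                drift: float = -0.8, sigma_k: float = 0.3,
                first_year: int = 1993, gamma_amplitude: float = 0.2
                ) -> ModelParams:
    """Ground-truth parameters for a synthetic surface.

    ``a_x`` is the logit of the stylized schedule; ``b_x`` is positive and
    proportional to 1/(x+5) (mortality improvement loaded on the young),
    normalized to sum 1; ``k_t`` is a realized random walk with drift shifted
    to k[t0] = 0.  LC2 adds a small second component; H1 adds a sinusoidal
    cohort effect of the given amplitude whose period equals the year-window
    length, so it averages out over any T consecutive cohorts.
    """
    if A < 10 or T < 10:
        raise ValueError("need at least a 10 x 10 grid")
    rng = np.random.default_rng(seed)
    x = np.arange(A)
    c1, c2, c3, c4 = SCHEDULE
    q_star = np.minimum(c1 * np.exp(-c2 * x) + c3 * np.exp(c4 * x), Q_CAP)
    a = logit_clip(q_star)

    b = 1.0 / (x + 5.0)
    b = b / b.sum()

    k = np.concatenate([[0.0], np.cumsum(drift + sigma_k * rng.standard_normal(T - 1))])
    k -= k[0]  # t0 = first year

    B = b[None, :]
    K = k[None, :]
    gamma = None
    weights = None
    cohort_years = None
    if family == "LC2":
        # small second component: loading contrast young vs old, slow wave
        b2 = np.cos(np.pi * x / (A - 1))
        b2 = b2 / np.abs(b2).sum() * 0.5
        b2 = b2 - (b2.sum() - 1.0) / A  # normalize sum to 1 keeping the shape
        k2 = 0.05 * np.cumsum(rng.standard_normal(T))
        k2 -= k2[0]
        B = np.vstack([b, b2])
        K = np.vstack([k, k2])
    elif family == "H1":
        ncoh = A + T - 1
        c = np.arange(ncoh)
        gamma = gamma_amplitude * np.sin(2 * np.pi * c / T)
        weights = np.ones(ncoh)
        weights[:5] = 0.0
        weights[-5:] = 0.0
        cohort_years = first_year - (A - 1) + c
    elif family != "LC1":
        raise ValueError(f"unknown family {family!r}")

    return ModelParams(family=family, a=a, B=B, K=K, t0=first_year,
                       gamma=gamma, cohort_weights=weights,
                       cohort_years=cohort_years)


def _true_q(params: ModelParams, A: int, T: int) -> np.ndarray:
    eta = params.a[:, None] + np.einsum("ia,it->at", params.B, params.K)
    if params.gamma is not None:
        x = np.arange(A)[:, None]
        t = np.arange(T)[None, :]
        eta = eta + params.gamma[(A - 1) - x + t]
    return expit(eta)


def simulate_deaths(params: ModelParams, exposure_profile, dispersion: float = 1.0,
                    seed: int | np.random.Generator = 0,
                    first_year: int | None = None) -> MortalitySurface:
    """Draw a death-count surface from the true probabilities.

    ``exposure_profile`` is a scalar, a per-age vector, or a full A x T
    matrix of exposures.  With ``dispersion`` phi = 1 counts are binomial;
    with phi > 1 they are beta-binomial with mean E q and variance
    phi E q (1 - q) (mixing parameter rho = (phi - 1)/(E - 1) per cell).
    """
    if dispersion < 1:
        raise ValueError("dispersion must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A, T = params.a.size, params.K.shape[1]
    q = _true_q(params, A, T)
    E = np.broadcast_to(np.asarray(exposure_profile, float).reshape(-1, 1)
                        if np.ndim(exposure_profile) == 1
                        else np.asarray(exposure_profile, float), (A, T)).copy()
    E_int = np.round(E).astype(np.int64)
    if dispersion == 1.0:
        d = rng.binomial(E_int, q).astype(float)
    else:
        rho = (dispersion - 1.0) / np.maximum(E_int - 1, 1)
        s = 1.0 / rho - 1.0  # alpha + beta of the mixing Beta
        alpha = np.maximum(q * s, 1e-12)
        beta = np.maximum((1.0 - q) * s, 1e-12)
        p = rng.beta(alpha, beta)
        d = rng.binomial(E_int, p).astype(float)
    first = params.t0 if first_year is None else first_year
    ages = np.arange(A)
    years = first + np.arange(T)
    return MortalitySurface(ages=ages, years=years, E=E_int.astype(float), d=d)


def make_scenario_surface(spec: ScenarioSpec) -> tuple[MortalitySurface, ModelParams]:
    """Generate the study scenario: ground-truth parameters plus one surface draw."""
    params = make_params(spec.ages, spec.years, spec.family, seed=spec.seed,
                         drift=spec.drift, sigma_k=spec.sigma_k,
                         first_year=spec.first_year,
                         gamma_amplitude=spec.gamma_amplitude)
    expo = spec.exposure_profile if spec.exposure_profile is not None else spec.exposure
    surface = simulate_deaths(params, expo, spec.dispersion,
                              seed=np.random.default_rng(spec.seed + 1))
    return surface, params


def make_fanova_fixture(effect_model: float = 0.0, effect_sample: float = 0.0,
                        effect_interaction: float = 0.0, N: int = 10,
                        H: int = 20, noise_sd: float = 1.0,
                        seed: int | np.random.Generator = 0,
                        indicator: str = "e0") -> IndicatorCurveSet:
    """Curve fixture generated exactly from the two-way functional decomposition.

    Curves are m(t) + f_mod(t) + g_sam(t) + h_mod,sam(t) + noise with smooth
    sinusoidal effect functions scaled by the given effect sizes (in units of
    the iid Gaussian curve noise SD).  Zero effects give exchangeable cells.
    """
    if N < 2 or H < 2:
        raise ValueError("need N >= 2 and H >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, H)
    m = 80.0 + 2.0 * t  # overall trend, life-expectancy-like scale
    models = ("LC1", "LC2", "H1")
    sources = ("RLC1", "RLC2", "RH1")
    # zero-sum smooth contrasts across the three levels
    level_shape = {0: np.sin(np.pi * t), 1: np.cos(np.pi * t), 2: None}
    cells = {}
    for i, mod in enumerate(models):
        f = _level_effect(i, t) * effect_model * noise_sd
        for j, sam in enumerate(sources):
            g = _level_effect(j, t) * effect_sample * noise_sd
            h = _level_effect(i, t) * _level_effect(j, t)[::-1] \
                * effect_interaction * noise_sd
            mean = m + f + g + h
            cells[(mod, sam)] = mean[None, :] + noise_sd * rng.standard_normal((N, H))
    years = 2013 + np.arange(H)
    return IndicatorCurveSet(indicator=indicator, horizon_years=years,
                             cells=cells, N=N)


def _level_effect(level: int, t: np.ndarray) -> np.ndarray:
    """Smooth level contrasts summing to zero across the three levels."""
    base = [np.sin(np.pi * t) + 0.5, -np.cos(np.pi * t) - 0.2]
    base.append(-(base[0] + base[1]))
    return base[level]
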