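"""Index projection and indicator confidence intervals.

The period indices ``k_t`` (and the cohort series ``gamma_c`` for the H1
model) are projected with univariate ARIMA processes chosen by an AICc grid
search over low orders (the Box-Jenkins workhorse orders).  The model is fit
on the manually differenced series, with a constant (drift) allowed at
d = 1; forecasts are conditional means integrated back to the level of the
series.  Uncertainty in the indicator forecasts comes from the bootstrap
refits, not from ARIMA innovation noise, so the intervals isolate parameter
error; an option adds innovation noise for sensitivity analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.arima.model import ARIMA

from . import lifetable
from .lc_models import ModelParams, predictor_matrix
from scipy.special import expit

__all__ = [
    "ArimaSpec",
    "IndicatorCurveSet",
    "select_arima",
    "fit_arima",
    "forecast_index",
    "forecast_gamma",
    "project_probabilities",
    "indicator_curves",
    "percentile_ci",
    "INDICATORS",
]

INDICATORS = ("e0", "e65", "modal", "gini")


@dataclass
class ArimaSpec:
    """A fitted ARIMA(p, d, q) (+ drift) specification for one index series."""

    p: int
    d: int
    q: int
    drift: bool = False
    ar: np.ndarray = field(default_factory=lambda: np.zeros(0))
    ma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    const: float = 0.0          # constant of the differenced series (drift)
    sigma2: float = 0.0
    aicc: float = np.nan

    @property
    def order(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)

    @property
    def n_fitted(self) -> int:
        # AR + MA + drift + innovation variance
        return self.p + self.q + int(self.drift) + 1

    def to_json(self, path=None) -> str:
        obj = {"p": self.p, "d": self.d, "q": self.q, "drift": self.drift,
               "ar": self.ar.tolist(), "ma": self.ma.tolist(),
               "const": self.const, "sigma2": self.sigma2,
               "aicc": None if not np.isfinite(self.aicc) else self.aicc}
        text = json.dumps(obj)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _difference(series: np.ndarray, d: int) -> np.ndarray:
    for _ in range(d):
        series = np.diff(series)
    return series


def fit_arima(series, p: int, d: int, q: int, drift: bool = False) -> ArimaSpec:
    """Fit ARIMA(p,d,q) by Gaussian ML on the differenced series.

    ``drift`` adds a constant to the d-times differenced series (only
    meaningful for d >= 1; for d = 0 it is the series mean).
    """
    series = np.asarray(series, float)
    z = _difference(series, d)
    n = z.size
    if n < 3:
        raise ValueError("series too short after differencing")
    if np.allclose(z, z[0]):
        # degenerate: constant differences (e.g. an exactly linear series)
        spec = ArimaSpec(p=0, d=d, q=0, drift=True, const=float(z[0]), sigma2=0.0)
        spec.aicc = -np.inf
        if z.std() == 0 and (p, q) != (0, 0):
            warnings.warn("zero-variance differenced series: returning pure "
                          "drift spec", RuntimeWarning)
        return spec
    if (p, q) == (0, 0):
        # closed form: random walk (with drift) on the level scale
        c = float(z.mean()) if drift else 0.0
        resid = z - c
        sigma2 = float(np.mean(resid ** 2))
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        spec = ArimaSpec(p=0, d=d, q=0, drift=drift, const=c, sigma2=sigma2)
    else:
        trend = "c" if drift else "n"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ARIMA(z, order=(p, 0, q), trend=trend).fit()
        # trend "c" in statsmodels is the process mean of the differenced series
        spec = ArimaSpec(
            p=p, d=d, q=q, drift=drift,
            ar=np.asarray(res.arparams, float), ma=np.asarray(res.maparams, float),
            const=float(res.params[0]) if drift else 0.0,
            sigma2=float(res.params[-1]),
        )
        ll = float(res.llf)
    m = spec.n_fitted
    spec.aicc = float(-2.0 * ll + 2.0 * m * (n / max(n - m - 1, 1e-9)))
    return spec


def select_arima(series, orders=None, d_values=(1, 2),
                 drift_when_d1: bool = True) -> ArimaSpec:
    """AICc grid search over low ARIMA orders (default p, q in {0, 1, 2}).

    Drift is tried (with and without) when d = 1; d = 2 specs carry no
    constant.  Returns the minimum-AICc specification.
    """
    series = np.asarray(series, float)
    if orders is None:
        orders = [(p, q) for p in range(3) for q in range(3)]
    best = None
    for d in d_values:
        if series.size - d < 8:
            continue
        for (p, q) in orders:
            drift_opts = (False, True) if (d == 1 and drift_when_d1) else (False,)
            for drift in drift_opts:
                try:
                    spec = fit_arima(series, p, d, q, drift)
                except Exception:
                    continue
                if best is None or spec.aicc < best.aicc:
                    best = spec
    if best is None:
        raise ValueError("no ARIMA candidate could be fitted "
                         "(series too short after differencing?)")
    return best


def forecast_index(spec: ArimaSpec, series, horizon: int,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Conditional-mean forecast of the next ``horizon`` values of the series.

    With ``rng`` given, Gaussian innovation noise is simulated instead
    (sensitivity option); by default forecasts are deterministic so that
    interval width reflects bootstrap parameter error only.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    series = np.asarray(series, float)
    z = _difference(series, spec.d)
    mu = spec.const  # process mean of the differenced series (0 without drift)
    zc = z - mu
    resid = _arma_residuals(zc, spec.ar, spec.ma)
    zfut = np.empty(horizon)
    hist = list(zc)
    eps = list(resid)
    for hstep in range(horizon):
        val = 0.0
        for i, phi in enumerate(spec.ar):
            val += phi * (hist[-1 - i] if len(hist) > i else 0.0)
        for j, th in enumerate(spec.ma):
            idx = len(eps) - 1 - j
            if idx >= 0:  # future shocks are appended as zeros
                val += th * eps[idx]
        shock = 0.0
        if rng is not None:
            shock = rng.normal(0.0, np.sqrt(max(spec.sigma2, 0.0)))
            val += shock
        hist.append(val)
        eps.append(shock)
        zfut[hstep] = val + mu
    # integrate back to the level of the series
    out = zfut
    for lvl in range(spec.d, 0, -1):
        tail = _difference(series, lvl - 1)[-1]
        out = tail + np.cumsum(out)
    return out


def _arma_residuals(zc: np.ndarray, ar: np.ndarray, ma: np.ndarray) -> np.ndarray:
    """One-step-ahead residuals of a mean-centered ARMA recursion."""
    n = zc.size
    eps = np.zeros(n)
    for t in range(n):
        pred = 0.0
        for i, phi in enumerate(ar):
            if t - 1 - i >= 0:
                pred += phi * zc[t - 1 - i]
        for j, th in enumerate(ma):
            if t - 1 - j >= 0:
                pred += th * eps[t - 1 - j]
        eps[t] = zc[t] - pred
    return eps


def forecast_gamma(gamma: np.ndarray, horizon: int,
                   spec: ArimaSpec | None = None) -> np.ndarray:
    """Extend a cohort-effect series across unestimated and future cohorts.

    ``gamma`` spans the surface's cohorts with NaN for the zero-weight
    (unestimated) leading/trailing entries.  An ARIMA process fitted on the
    estimated stretch forecasts the trailing unestimated cohorts plus the
    ``horizon`` new cohorts born after the data window, so every (age, future
    year) cell has a cohort effect.  Leading unestimated cohorts (never
    needed once the fitting window exceeds their span) are filled with the
    first estimated value.  Returns the extended series of length
    ``len(gamma) + horizon``.
    """
    gamma = np.asarray(gamma, float)
    est = np.flatnonzero(np.isfinite(gamma))
    if est.size == 0:
        raise ValueError("no estimated cohort effects")
    first, last = est[0], est[-1]
    series = gamma[first:last + 1]
    if not np.all(np.isfinite(series)):
        raise ValueError("estimated cohort stretch must be contiguous")
    n_ahead = (len(gamma) - 1 - last) + horizon
    if spec is None:
        if series.size >= 8 + 1:
            spec = select_arima(series, d_values=(1,))
        else:
            warnings.warn("cohort series too short for order selection; "
                          "using a random walk with drift", RuntimeWarning)
            spec = fit_arima(series, 0, 1, 0, drift=True)
    ext = forecast_index(spec, series, n_ahead) if n_ahead > 0 else np.zeros(0)
    out = np.empty(len(gamma) + horizon)
    out[:first] = series[0]
    out[first:last + 1] = series
    out[last + 1:] = ext
    return out


def project_probabilities(params: ModelParams, k_future: np.ndarray,
                          future_years: np.ndarray, ages: np.ndarray,
                          gamma_extended: np.ndarray | None = None,
                          cohort_years: np.ndarray | None = None) -> np.ndarray:
    """Forecast death probabilities q_hat over (ages x future years).

    ``k_future`` is (r, H).  For H1, ``gamma_extended`` must cover every
    cohort year - age reached by the grid (indexed by ``cohort_years``).
    """
    k_future = np.atleast_2d(np.asarray(k_future, float))
    H = k_future.shape[1]
    eta = params.a[:, None] + np.einsum("ia,ih->ah", params.B, k_future)
    if params.family == "H1":
        if gamma_extended is None or cohort_years is None:
            raise ValueError("H1 projection needs the extended cohort effects")
        coh = future_years[None, :] - np.asarray(ages)[:, None]
        idx = coh - cohort_years[0]
        if idx.min() < 0 or idx.max() >= len(gamma_extended) \
                or not np.all(np.isfinite(gamma_extended[idx])):
            raise ValueError("incomplete cohort-effect forecast for the grid")
        eta = eta + gamma_extended[idx]
    return expit(eta)


def indicator_curves(q_future: np.ndarray, radix: float = 100_000.0,
                     indicators=INDICATORS) -> dict[str, np.ndarray]:
    """Evaluate mortality indicators year by year on a forecast q surface.

    Each column of ``q_future`` (ages x H) is built into a period life table;
    returns H-vectors for the requested indicators among life expectancy at
    birth and at 65, the modal age at death, and the Gini index.  ``e65``
    requires the age range to reach 65.
    """
    H = q_future.shape[1]
    if "e65" in indicators and q_future.shape[0] <= 65:
        raise ValueError("e65 needs ages beyond 65; drop it for short tables")
    out = {name: np.empty(H) for name in indicators}
    for h in range(H):
        table = lifetable.build_period_table(q_future[:, h], radix=radix)
        if "e0" in out:
            out["e0"][h] = lifetable.life_expectancy(table, 0)
        if "e65" in out:
            out["e65"][h] = lifetable.life_expectancy(table, 65)
        if "modal" in out:
            out["modal"][h] = lifetable.modal_age(table)
        if "gini" in out:
            out["gini"][h] = lifetable.gini_index(table)
    return out


@dataclass
class IndicatorCurveSet:
    """Replicate indicator curves for every (fitting model, residual source) cell.

    ``cells`` maps (model, source) -> array of shape (N, H).
    """

    indicator: str
    horizon_years: np.ndarray
    cells: dict[tuple[str, str], np.ndarray]
    N: int

    def __post_init__(self):
        H = len(self.horizon_years)
        for key, arr in self.cells.items():
            if arr.shape != (self.N, H):
                raise ValueError(f"cell {key}: expected shape {(self.N, H)}, "
                                 f"got {arr.shape}")

    @property
    def models(self) -> list[str]:
        return sorted({m for m, _ in self.cells})

    @property
    def sources(self) -> list[str]:
        return sorted({s for _, s in self.cells})

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All curves stacked (n_curves x H) with model and source labels."""
        curves, ms, ss = [], [], []
        for (m, s), arr in sorted(self.cells.items()):
            curves.append(arr)
            ms += [m] * arr.shape[0]
            ss += [s] * arr.shape[0]
        return np.vstack(curves), np.array(ms), np.array(ss)


def percentile_ci(curves: np.ndarray, probs=(0.025, 0.975)
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise bootstrap percentile interval over N replicate curves (N x H)."""
    curves = np.atleast_2d(np.asarray(curves, float))
    if curves.shape[0] < 2:
        warnings.warn("fewer than 2 replicates: degenerate interval", RuntimeWarning)
        return curves[0].copy(), curves[0].copy()
    lower = np.quantile(curves, probs[0], axis=0)
    upper = np.quantile(curves, probs[1], axis=0)
    return lower, upper
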