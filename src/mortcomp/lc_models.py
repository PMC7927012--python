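"""Lee-Carter-family mortality models on the logit scale.

Three models for an age x year surface of death probabilities ``q_xt``,
with death counts ``d_xt`` treated as (quasi-)binomial given exposures
``E_xt``:

* ``LC1`` — logit q_xt = a_x + b_x k_t
* ``LC2`` — logit q_xt = a_x + b_x^(1) k_t^(1) + b_x^(2) k_t^(2)
* ``H1``  — logit q_xt = a_x + b_x k_t + gamma_{t-x}  (cohort effect)

Point estimates maximize the binomial log-likelihood (quasi-binomial ML
coincides with binomial ML; overdispersion only scales the variance and is
reported as the Pearson dispersion ``phi``).  Estimation is by block
coordinate ascent with Newton steps and step halving, which is monotone in
the deviance.  Identifiability is fixed by the gauge ``k^(i)[t0] = 0`` and
``sum_x b_x^(i) = 1`` with ``t0`` the first year of the fitting period.

``H1`` is fitted in two stages for robustness: ``a_x`` is frozen at the
per-age mean of the observed logits, then ``b``, ``k`` and ``gamma`` are
estimated with ``a`` as an offset.  Cohorts with fewer than a handful of
observed cells (the first and last five) get weight zero and are excluded
from the likelihood; their ``gamma`` is reported missing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "MortalitySurface",
    "ModelParams",
    "logit_clip",
    "init_svd",
    "fit_lc",
    "fit_h1",
    "model_deviance",
    "fitted_deaths",
    "predictor_matrix",
    "binomial_deviance",
]

EPS_CLIP = 1e-8
N_ZERO_WEIGHT = 5  # leading and trailing cohorts excluded from the H1 likelihood


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class MortalitySurface:
    """Rectangular mortality surface: ages in rows, calendar years in columns."""

    ages: np.ndarray   # contiguous integers, length A
    years: np.ndarray  # contiguous integers, length T
    E: np.ndarray      # exposure-to-risk per cell, A x T
    d: np.ndarray      # death count per cell (may be non-integer), A x T

    def __post_init__(self):
        A, T = len(self.ages), len(self.years)
        for name in ("E", "d"):
            arr = getattr(self, name)
            if arr.shape != (A, T):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(A, T)}")
        if np.any(np.diff(self.ages) != 1) or np.any(np.diff(self.years) != 1):
            raise ValueError("ages and years must be contiguous integer grids")
        if np.any(self.E < 0):
            raise ValueError("exposures must be non-negative")
        if np.any(self.d < -1e-9) or np.any(self.d > self.E * (1 + 1e-9) + 1e-9):
            raise ValueError("death counts must satisfy 0 <= d <= E")

    @property
    def shape(self) -> tuple[int, int]:
        return self.E.shape

    @property
    def q(self) -> np.ndarray:
        """Crude death probabilities d/E (0 where E = 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.E > 0, self.d / np.where(self.E > 0, self.E, 1.0), 0.0)

    def with_deaths(self, d: np.ndarray) -> "MortalitySurface":
        return MortalitySurface(self.ages, self.years, self.E, d)

    @property
    def n_cohorts(self) -> int:
        return len(self.ages) + len(self.years) - 1

    def cohort_index(self) -> np.ndarray:
        """Cell -> cohort position 0..A+T-2 (cohort year = first year - oldest age + index)."""
        A, T = self.shape
        x = np.arange(A)[:, None]
        t = np.arange(T)[None, :]
        return (A - 1) - x + t

    def cohort_years(self) -> np.ndarray:
        first = int(self.years[0]) - int(self.ages[-1])
        return first + np.arange(self.n_cohorts)


@dataclass
class ModelParams:
    """Fitted parameters of one of the three models.

    ``B`` and ``K`` are stacked as (r, A) and (r, T).  ``gamma`` spans the
    A+T-1 cohorts (NaN where the cohort weight is zero); it is None for the
    LC models.
    """

    family: str                      # "LC1" | "LC2" | "H1"
    a: np.ndarray
    B: np.ndarray
    K: np.ndarray
    t0: int                          # reference year with k[t0] = 0
    gamma: np.ndarray | None = None
    cohort_weights: np.ndarray | None = None
    cohort_years: np.ndarray | None = None
    dispersion: float = np.nan
    fit_trace: np.ndarray | None = field(default=None, repr=False, compare=False)
    converged: bool = True

    @property
    def rank(self) -> int:
        return self.B.shape[0]

    def n_params(self, A: int, T: int) -> int:
        """Raw parameter count by the conventional tally (constraints not deducted)."""
        if self.family == "H1":
            return A + T + A + (T + A - 1)
        return A + self.rank * T + self.rank * A

    def to_json(self, path=None) -> str:
        obj = {
            "family": self.family,
            "t0": int(self.t0),
            "a": self.a.tolist(),
            "B": self.B.tolist(),
            "K": self.K.tolist(),
            "gamma": (
                {str(int(c)): float(g)
                 for c, g in zip(self.cohort_years, self.gamma)
                 if np.isfinite(g)}
                if self.gamma is not None else None
            ),
            "dispersion": None if not np.isfinite(self.dispersion) else float(self.dispersion),
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "ModelParams":
        try:
            obj = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                obj = json.load(fh)
        gamma = cohort_years = weights = None
        if obj.get("gamma") is not None:
            items = sorted((int(c), v) for c, v in obj["gamma"].items())
            est_years = np.array([c for c, _ in items])
            # reconstruct the full cohort axis with the standard 5/5 zero weights
            cohort_years = np.arange(est_years[0] - N_ZERO_WEIGHT,
                                     est_years[-1] + N_ZERO_WEIGHT + 1)
            gamma = np.full(len(cohort_years), np.nan)
            gamma[N_ZERO_WEIGHT:len(cohort_years) - N_ZERO_WEIGHT] = [v for _, v in items]
            weights = np.isfinite(gamma).astype(float)
        return cls(
            family=obj["family"], t0=obj["t0"],
            a=np.asarray(obj["a"], float),
            B=np.asarray(obj["B"], float), K=np.asarray(obj["K"], float),
            gamma=gamma, cohort_weights=weights, cohort_years=cohort_years,
            dispersion=np.nan if obj.get("dispersion") is None else obj["dispersion"],
        )


# ---------------------------------------------------------------------------
# elementary pieces


def logit_clip(q, eps: float = EPS_CLIP) -> np.ndarray:
    """Elementwise logit after clipping probabilities into [eps, 1-eps]."""
    q = np.clip(np.asarray(q, float), eps, 1.0 - eps)
    return np.log(q / (1.0 - q))


def binomial_deviance(d, dhat, E, mask=None) -> float:
    """Total binomial deviance 2*sum[d ln(d/dhat) + (E-d) ln((E-d)/(E-dhat))].

    Uses the convention 0*ln(0) = 0.  ``mask`` selects cells included in the
    likelihood.
    """
    d = np.asarray(d, float)
    dhat = np.asarray(dhat, float)
    E = np.asarray(E, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(d > 0, d * np.log(d / dhat), 0.0)
        t2 = np.where(E - d > 0, (E - d) * np.log((E - d) / (E - dhat)), 0.0)
    cell = 2.0 * (t1 + t2)
    if mask is not None:
        cell = np.where(mask, cell, 0.0)
    return float(np.sum(cell))


def predictor_matrix(params: ModelParams, surface: MortalitySurface,
                     fill_gamma: bool = True) -> np.ndarray:
    """Linear predictor a_x + sum_i b_x^(i) k_t^(i) [+ gamma_{t-x}] on the surface grid.

    For H1, missing (zero-weight) cohort effects are filled by the nearest
    estimated cohort's value when ``fill_gamma`` is true, so the predictor is
    defined on every cell; those cells remain outside the likelihood.
    """
    eta = params.a[:, None] + np.einsum("ia,it->at", params.B, params.K)
    if params.gamma is not None:
        g = params.gamma
        if fill_gamma:
            g = _fill_nearest(g)
        eta = eta + g[surface.cohort_index()]
    return eta


def _fill_nearest(v: np.ndarray) -> np.ndarray:
    """Fill NaNs at the ends of a vector with the nearest finite value."""
    v = v.copy()
    idx = np.flatnonzero(np.isfinite(v))
    if idx.size == 0:
        raise ValueError("no finite values to fill from")
    v[: idx[0]] = v[idx[0]]
    v[idx[-1] + 1:] = v[idx[-1]]
    # interior NaNs (not produced by the standard weighting) -> interpolate
    bad = ~np.isfinite(v)
    if bad.any():
        v[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(~bad), v[~bad])
    return v


def fitted_deaths(params: ModelParams, surface: MortalitySurface) -> np.ndarray:
    """Fitted death counts d_hat = E * expit(predictor)."""
    return surface.E * expit(predictor_matrix(params, surface))


def h1_mask(surface: MortalitySurface) -> np.ndarray:
    """Boolean mask of cells in the H1 likelihood (weight-1 cohorts only)."""
    ci = surface.cohort_index()
    ncoh = surface.n_cohorts
    w = np.ones(ncoh, bool)
    w[:N_ZERO_WEIGHT] = False
    w[ncoh - N_ZERO_WEIGHT:] = False
    return w[ci]


# ---------------------------------------------------------------------------
# initial values


def init_svd(surface: MortalitySurface, r: int = 1, eps: float = EPS_CLIP) -> ModelParams:
    """SVD starting values: a = per-age mean logit, (B, K) from the top-r
    singular triplets of the centered logit surface, rescaled to the gauge."""
    A, T = surface.shape
    if A < 3 or T < 3 or r > min(A, T):
        raise ValueError("surface too small for SVD initialization")
    Z = logit_clip(surface.q, eps)
    a = Z.mean(axis=1)
    C = Z - a[:, None]
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    B = np.zeros((r, A))
    K = np.zeros((r, T))
    scale = np.abs(s[0]) if s.size else 0.0
    for i in range(r):
        if s[i] <= 1e-12 * max(scale, 1.0):
            warnings.warn("rank-deficient surface: component "
                          f"{i + 1} set to zero", RuntimeWarning)
            B[i] = 1.0 / A
            continue
        u, v = U[:, i], Vt[i]
        S = u.sum()
        if abs(S) < 1e-12:  # pathological gauge: fall back to sign of max |u|
            S = u[np.argmax(np.abs(u))]
        B[i] = u / S
        K[i] = s[i] * v * S
    params = ModelParams(family=f"LC{r}", a=a, B=B, K=K, t0=int(surface.years[0]))
    _shift_k_to_t0(params, t0_idx=0)
    return params


def _shift_k_to_t0(params: ModelParams, t0_idx: int) -> None:
    """Absorb b^(i) k^(i)[t0] into a so that k^(i)[t0] = 0 (fit-preserving)."""
    for i in range(params.rank):
        k0 = params.K[i, t0_idx]
        params.a += params.B[i] * k0
        params.K[i] -= k0


# ---------------------------------------------------------------------------
# coordinate-ascent machinery


def _halving_update(apply_step, dev_old, dev_fn, max_halvings: int = 30):
    """Apply a Newton block step with step halving until deviance does not increase."""
    frac = 1.0
    for _ in range(max_halvings):
        apply_step(frac)
        dev_new = dev_fn()
        if dev_new <= dev_old * (1 + 1e-12) + 1e-12:
            return dev_new
        apply_step(-frac)  # roll back
        frac *= 0.5
    return dev_old


def _check_identifiable(surface: MortalitySurface, mask: np.ndarray) -> None:
    if not mask.any():
        raise ValueError("no cells with positive exposure")
    if np.any(~mask.any(axis=1)) or np.any(~mask.any(axis=0)):
        bad_rows = np.flatnonzero(~mask.any(axis=1))
        bad_cols = np.flatnonzero(~mask.any(axis=0))
        raise ValueError(
            "unidentifiable cells: every age and year needs at least one "
            f"cell with positive exposure (ages {bad_rows.tolist()}, "
            f"year columns {bad_cols.tolist()})"
        )


def fit_lc(surface: MortalitySurface, r: int = 1, t0: int | None = None,
           tol: float = 1e-8, max_sweeps: int = 500) -> ModelParams:
    """Fit LC1 (r=1) or LC2 (r=2) by quasi-binomial maximum likelihood.

    Alternates Newton updates of the per-age block (a_x, b_x^(1..r)) and the
    per-year block (k_t^(1..r)), each with step halving against the deviance,
    until the relative deviance change drops below ``tol``.  The gauge
    ``k[t0] = 0``, ``sum b = 1`` is applied after convergence via an SVD of
    the fitted bilinear term (fit-preserving).
    """
    if r not in (1, 2):
        raise ValueError("r must be 1 or 2")
    A, T = surface.shape
    t0 = int(surface.years[0]) if t0 is None else int(t0)
    t0_idx = int(t0 - surface.years[0])
    if not 0 <= t0_idx < T:
        raise ValueError(f"t0={t0} outside the fitting years")
    mask = surface.E > 0
    _check_identifiable(surface, mask)

    params = init_svd(surface, r)
    params.t0 = t0
    a, B, K = params.a, params.B, params.K
    d, E = surface.d, surface.E
    w_mask = mask.astype(float)

    def dev() -> float:
        eta = a[:, None] + np.einsum("ia,it->at", B, K)
        return binomial_deviance(d, E * expit(eta), E, mask)

    trace = [dev()]
    converged = False
    for _ in range(max_sweeps):
        dev_sweep_start = trace[-1]

        # --- per-age joint (a_x, b_x) Newton block
        eta = a[:, None] + np.einsum("ia,it->at", B, K)
        p = expit(eta)
        s = (d - E * p) * w_mask
        w = E * p * (1 - p) * w_mask
        X = np.concatenate([np.ones((1, T)), K], axis=0)     # (r+1, T)
        G = np.einsum("it,jt,at->aij", X, X, w)              # A x (r+1) x (r+1)
        rhs = np.einsum("it,at->ai", X, s)
        G += 1e-10 * (1.0 + np.trace(G, axis1=1, axis2=2))[:, None, None] * np.eye(r + 1)
        step = np.linalg.solve(G, rhs[:, :, None])[:, :, 0]  # A x (r+1)

        def apply_ab(frac, step=step):
            a[:] += frac * step[:, 0]
            B[:] += frac * step[:, 1:].T

        dcur = _halving_update(apply_ab, trace[-1], dev)

        # --- per-year k block
        eta = a[:, None] + np.einsum("ia,it->at", B, K)
        p = expit(eta)
        s = (d - E * p) * w_mask
        w = E * p * (1 - p) * w_mask
        Zc = B                                               # (r, A)
        G = np.einsum("ix,jx,xt->tij", Zc, Zc, w)            # T x r x r
        rhs = np.einsum("ix,xt->ti", Zc, s)
        G += 1e-10 * (1.0 + np.trace(G, axis1=1, axis2=2))[:, None, None] * np.eye(r)
        step_k = np.linalg.solve(G, rhs[:, :, None])[:, :, 0]  # T x r

        def apply_k(frac, step_k=step_k):
            K[:] += frac * step_k.T

        dcur = _halving_update(apply_k, dcur, dev)
        trace.append(dcur)

        if dev_sweep_start - dcur < tol * max(dev_sweep_start, 1e-10) or dcur < 1e-10:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fit_lc did not converge in {max_sweeps} sweeps; last deviance "
            f"changes: {np.diff(trace[-5:]).tolist()}", RuntimeWarning)

    _gauge_fix_lc(params, t0_idx)
    params.fit_trace = np.asarray(trace)
    params.converged = converged
    params.dispersion = _pearson_dispersion(surface, params, mask)
    return params


def _gauge_fix_lc(params: ModelParams, t0_idx: int) -> None:
    """Rotate (B, K) to the SVD gauge and shift k to k[t0] = 0.

    Pure gauge: the fitted bilinear term B^T K is reproduced exactly, so the
    deviance is unchanged.
    """
    M = np.einsum("ia,it->at", params.B, params.K)
    r = params.rank
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    for i in range(r):
        u, v = U[:, i], Vt[i]
        S = u.sum()
        if abs(S) < 1e-12:
            S = u[np.argmax(np.abs(u))]
        params.B[i] = u / S
        params.K[i] = s[i] * v * S
    _shift_k_to_t0(params, t0_idx)


def _pearson_dispersion(surface: MortalitySurface, params: ModelParams,
                        mask: np.ndarray) -> float:
    A, T = surface.shape
    dhat = fitted_deaths(params, surface)
    p = dhat / np.where(surface.E > 0, surface.E, 1.0)
    var = surface.E * p * (1 - p)
    ok = mask & (var > 0)
    x2 = float(np.sum((surface.d[ok] - dhat[ok]) ** 2 / var[ok]))
    df = int(ok.sum()) - params.n_params(A, T)
    if df <= 0:
        warnings.warn("non-positive residual degrees of freedom; "
                      "dispersion undefined", RuntimeWarning)
        return np.nan
    return x2 / df


def fit_h1(surface: MortalitySurface, t0: int | None = None,
           tol: float = 1e-8, max_sweeps: int = 500,
           b_floor: float = 1e-6) -> ModelParams:
    """Two-stage fit of the cohort model H1.

    Stage 1 freezes ``a_x`` at the per-age mean of the clipped observed
    logits.  Stage 2 maximizes the weighted quasi-binomial likelihood over
    ``b``, ``k`` and ``gamma`` with ``a`` as offset; cells belonging to the
    first/last five cohorts carry weight zero.  Constraints: ``k[t0] = 0``
    (the t0 entry is pinned during optimization), ``sum b = 1`` (gauge
    renormalization compensated in k) and ``b > 0`` (negative updates clipped
    to ``b_floor``).
    """
    A, T = surface.shape
    t0 = int(surface.years[0]) if t0 is None else int(t0)
    t0_idx = int(t0 - surface.years[0])
    mask = (surface.E > 0) & h1_mask(surface)
    _check_identifiable(surface, mask)

    ncoh = surface.n_cohorts
    ci = surface.cohort_index()
    w_coh = np.ones(ncoh)
    w_coh[:N_ZERO_WEIGHT] = 0.0
    w_coh[ncoh - N_ZERO_WEIGHT:] = 0.0
    if not (w_coh > 0).any():
        raise ValueError("no cohorts left with positive weight")

    Z = logit_clip(surface.q)
    obs = surface.E > 0
    a = np.where(obs.any(axis=1),
                 (Z * obs).sum(axis=1) / np.maximum(obs.sum(axis=1), 1), 0.0)

    # start from the SVD of the residual logits (a as offset)
    C = (Z - a[:, None]) * obs
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    b = U[:, 0].copy()
    if b.sum() < 0:
        b = -b
    b = np.clip(b, b_floor, None)
    k = s[0] * Vt[0] * U[:, 0].sum()
    b = b / b.sum()
    k = k - k[t0_idx]
    gamma = np.zeros(ncoh)

    d, E = surface.d, surface.E
    w_mask = mask.astype(float)
    free_k = np.arange(T) != t0_idx
    ci_flat = ci.ravel()

    def dev() -> float:
        eta = a[:, None] + np.outer(b, k) + gamma[ci]
        return binomial_deviance(d, E * expit(eta), E, mask)

    trace = [dev()]
    converged = False
    for _ in range(max_sweeps):
        dev_sweep_start = trace[-1]
        b_prev, k_prev, g_prev = b.copy(), k.copy(), gamma.copy()

        # --- per-age b update (1-D Newton per age)
        eta = a[:, None] + np.outer(b, k) + gamma[ci]
        p = expit(eta)
        s_r = (d - E * p) * w_mask
        w = E * p * (1 - p) * w_mask
        num = s_r @ k
        den = w @ (k ** 2) + 1e-12
        step_b = num / den

        def apply_b(frac, step_b=step_b):
            b[:] += frac * step_b

        dcur = _halving_update(apply_b, trace[-1], dev)
        # enforce b > 0 then renormalize (gauge-compensated in k)
        if np.any(b < b_floor):
            b[:] = np.clip(b, b_floor, None)
        S = b.sum()
        b[:] = b / S
        k[:] = k * S
        dcur = dev()

        # --- per-year k update (t0 pinned at 0)
        eta = a[:, None] + np.outer(b, k) + gamma[ci]
        p = expit(eta)
        s_r = (d - E * p) * w_mask
        w = E * p * (1 - p) * w_mask
        num = b @ s_r
        den = (b ** 2) @ w + 1e-12
        step_k = np.where(free_k, num / den, 0.0)

        def apply_k(frac, step_k=step_k):
            k[:] += frac * step_k

        dcur = _halving_update(apply_k, dcur, dev)

        # --- per-cohort gamma update (cohorts are disjoint cell sets)
        eta = a[:, None] + np.outer(b, k) + gamma[ci]
        p = expit(eta)
        s_r = ((d - E * p) * w_mask).ravel()
        w = (E * p * (1 - p) * w_mask).ravel()
        num = np.bincount(ci_flat, weights=s_r, minlength=ncoh)
        den = np.bincount(ci_flat, weights=w, minlength=ncoh) + 1e-12
        step_g = np.where(w_coh > 0, num / den, 0.0)

        def apply_g(frac, step_g=step_g):
            gamma[:] += frac * step_g

        dcur = _halving_update(apply_g, dcur, dev)

        # the near-flat direction (cohort trend vs period trend) makes plain
        # alternation crawl; extrapolate along the whole sweep's displacement
        db, dk, dg = b - b_prev, k - k_prev, gamma - g_prev
        alpha = 1.0
        while alpha <= 512:
            b[:] += alpha * db
            k[:] += alpha * dk
            gamma[:] += alpha * dg
            ok = not np.any(b <= 0)
            d_try = dev() if ok else np.inf
            if ok and d_try < dcur:
                dcur = d_try
                alpha *= 2
            else:
                b[:] -= alpha * db
                k[:] -= alpha * dk
                gamma[:] -= alpha * dg
                break
        if np.any(b < b_floor):
            b[:] = np.clip(b, b_floor, None)
            S = b.sum()
            b[:] = b / S
            k[:] = k * S
            dcur = dev()
        trace.append(dcur)

        if dev_sweep_start - dcur < tol * max(dev_sweep_start, 1e-10) or dcur < 1e-10:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fit_h1 did not converge in {max_sweeps} sweeps; last deviance "
            f"changes: {np.diff(trace[-5:]).tolist()}", RuntimeWarning)

    gamma_out = np.where(w_coh > 0, gamma, np.nan)
    params = ModelParams(
        family="H1", a=a, B=b[None, :], K=k[None, :], t0=t0,
        gamma=gamma_out, cohort_weights=w_coh,
        cohort_years=surface.cohort_years(),
        fit_trace=np.asarray(trace), converged=converged,
    )
    params.dispersion = _pearson_dispersion(surface, params, mask)
    return params


def model_deviance(surface: MortalitySurface, params: ModelParams
                   ) -> tuple[float, int, float]:
    """(total deviance, raw parameter count, Pearson dispersion) of a fit.

    The deviance sums squared deviance residuals over the cells in the
    model's likelihood (weight-1 cohorts only for H1).
    """
    A, T = surface.shape
    if params.a.shape != (A,):
        raise ValueError("parameter/surface shape mismatch")
    mask = surface.E > 0
    if params.family == "H1":
        mask = mask & h1_mask(surface)
    dhat = fitted_deaths(params, surface)
    devi = binomial_deviance(surface.d, dhat, surface.E, mask)
    return devi, params.n_params(A, T), _pearson_dispersion(surface, params, mask)


# ---------------------------------------------------------------------------
# surface CSV I/O (ages in the first column, years as the remaining headers)


def _read_matrix_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if df.columns[0] != "age":
        raise ValueError(f"{path}: first column must be 'age'")
    ages = df["age"].to_numpy(int)
    try:
        years = np.array([int(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: year headers must be integers") from exc
    M = df.iloc[:, 1:].to_numpy(float)
    if np.any(np.diff(ages) != 1):
        raise ValueError(f"{path}: ages must be contiguous")
    if np.any(np.diff(years) != 1):
        raise ValueError(f"{path}: years must be contiguous")
    if np.isnan(M).any():
        bad = np.argwhere(np.isnan(M))[0]
        raise ValueError(f"{path}: missing value at age row {bad[0]}, year column {bad[1]}")
    return ages, years, M


def read_surface(E_path=None, d_path=None, q_path=None) -> MortalitySurface:
    """Read a surface from CSV matrices: exposures plus deaths, or exposures plus
    crude probabilities (deaths reconstructed as q*E)."""
    if E_path is None or (d_path is None and q_path is None):
        raise ValueError("need an exposure file plus a deaths or probability file")
    ages, years, E = _read_matrix_csv(E_path)
    if d_path is not None:
        ages2, years2, d = _read_matrix_csv(d_path)
    else:
        ages2, years2, q = _read_matrix_csv(q_path)
        d = q * E
    if not (np.array_equal(ages, ages2) and np.array_equal(years, years2)):
        raise ValueError("grids of the input files disagree")
    return MortalitySurface(ages=ages, years=years, E=E, d=d)


def write_surface(surface: MortalitySurface, E_path, d_path) -> None:
    for M, path in ((surface.E, E_path), (surface.d, d_path)):
        df = pd.DataFrame(M, columns=[str(y) for y in surface.years])
        df.insert(0, "age", surface.ages)
        df.to_csv(path, index=False, float_format="%.17g")
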