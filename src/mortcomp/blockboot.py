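"""Residual block bootstrap for mortality surfaces.

The fitted model leaves an age x year array of deviance residuals that is
typically dependent along ages, years and cohort diagonals.  To propagate
parameter uncertainty while retaining that local dependence, the residual
array is resampled in contiguous rectangular blocks: the target array is
tiled by non-overlapping ``height x width`` blocks (ages x years, truncated
at the edges), and each tile is filled with the same-shaped rectangle lying
to the southeast of an anchor cell drawn uniformly among positions where the
rectangle fits inside the original array.  Resampled residuals are then
inverted through the deviance-residual definition back to pseudo death
counts, which are refitted to give a bootstrap replicate of the parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResidualMatrix",
    "BlockSpec",
    "deviance_residuals",
    "resample_blocks",
    "invert_to_deaths",
    "residual_correlogram",
]


@dataclass(frozen=True)
class ResidualMatrix:
    """Deviance residuals per cell with a likelihood-inclusion mask.

    ``r`` is NaN on masked-out cells (e.g. the zero-weight cohorts of H1).
    """

    r: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.r.shape != self.mask.shape:
            raise ValueError("residuals and mask must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape


@dataclass(frozen=True)
class BlockSpec:
    """Block geometry (ages x years) and RNG seed for one resampling."""

    height: int
    width: int
    seed: int | np.random.SeedSequence | None = None

    def validate(self, shape: tuple[int, int]) -> None:
        A, T = shape
        if not (1 <= self.height <= A and 1 <= self.width <= T):
            raise ValueError(
                f"block {self.height}x{self.width} invalid for a {A}x{T} array")


def deviance_residuals(d: np.ndarray, dhat: np.ndarray, E: np.ndarray,
                       mask: np.ndarray | None = None) -> ResidualMatrix:
    """Signed deviance residuals of the (quasi-)binomial fit.

    r = sign(d - dhat) * sqrt(2[d ln(d/dhat) + (E-d) ln((E-d)/(E-dhat))]),
    with 0*ln(0) = 0.  Cells where dhat is 0 or E (degenerate fit) are
    flagged out of the mask and set missing.
    """
    d = np.asarray(d, float)
    dhat = np.asarray(dhat, float)
    E = np.asarray(E, float)
    if mask is None:
        mask = np.ones_like(d, bool)
    mask = mask.copy()
    degenerate = mask & ((dhat <= 0) | (dhat >= E))
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} cells have fitted deaths at the "
                      "boundary; residuals set missing", RuntimeWarning)
        mask &= ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(d > 0, d * np.log(d / dhat), 0.0)
        t2 = np.where(E - d > 0, (E - d) * np.log((E - d) / (E - dhat)), 0.0)
    dev = np.maximum(2.0 * (t1 + t2), 0.0)
    r = np.sign(d - dhat) * np.sqrt(dev)
    r = np.where(mask, r, np.nan)
    return ResidualMatrix(r=r, mask=mask)


def resample_blocks(res: ResidualMatrix, spec: BlockSpec,
                    rng: np.random.Generator | None = None) -> ResidualMatrix:
    """One block-bootstrap resample of the residual array.

    The target grid is tiled by non-overlapping blocks anchored at the
    top-left corner; edge blocks are truncated.  Each target block of
    effective size h' x w' is filled by the h' x w' rectangle southeast of an
    anchor drawn uniformly among all positions where it fits; anchors are
    independent across blocks.
    """
    spec.validate(res.shape)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    A, T = res.shape
    h, w = spec.height, spec.width
    out = np.empty((A, T))
    for i0 in range(0, A, h):
        hh = min(h, A - i0)
        for j0 in range(0, T, w):
            ww = min(w, T - j0)
            ai = rng.integers(0, A - hh + 1)
            aj = rng.integers(0, T - ww + 1)
            out[i0:i0 + hh, j0:j0 + ww] = res.r[ai:ai + hh, aj:aj + ww]
    return ResidualMatrix(r=out, mask=np.isfinite(out))


def invert_to_deaths(rhat: ResidualMatrix, dhat: np.ndarray, E: np.ndarray,
                     tol_bits: int = 60, warn_nonfinite: bool = True) -> np.ndarray:
    """Invert resampled residuals to pseudo death counts.

    Per cell, solves h(d) = 2[d ln(d/dhat) + (E-d) ln((E-d)/(E-dhat))] = rhat^2
    for d on the side of dhat indicated by sign(rhat).  h is convex with
    minimum 0 at dhat, so bisection on [dhat, E] (positive residual) or
    [0, dhat] converges; if rhat^2 exceeds h at the boundary the count is
    clipped to E or 0.  Output counts are real-valued.
    """
    dhat = np.asarray(dhat, float)
    E = np.asarray(E, float)
    r = rhat.r
    bad = rhat.mask & ~np.isfinite(r)
    if bad.any() and warn_nonfinite:
        warnings.warn(f"{int(bad.sum())} non-finite resampled residuals; "
                      "cells set to the fitted count", RuntimeWarning)
    target = np.where(np.isfinite(r), r, 0.0) ** 2
    sign = np.sign(np.where(np.isfinite(r), r, 0.0))

    def h(d):
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(d > 0, d * np.log(d / dhat), 0.0)
            t2 = np.where(E - d > 0, (E - d) * np.log((E - d) / (E - dhat)), 0.0)
        return 2.0 * (t1 + t2)

    lo = np.where(sign >= 0, dhat, 0.0)
    hi = np.where(sign >= 0, E, dhat)
    # boundary clipping: if even the extreme count cannot reach rhat^2
    h_extreme = h(np.where(sign >= 0, E, 0.0))
    clip = target >= h_extreme
    for _ in range(tol_bits):
        mid = 0.5 * (lo + hi)
        too_small = h(mid) < target
        # moving away from dhat increases h; direction depends on the sign
        go_up = too_small == (sign >= 0)
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
    d_new = 0.5 * (lo + hi)
    d_new = np.where(clip, np.where(sign >= 0, E, 0.0), d_new)
    d_new = np.where(target == 0.0, dhat, d_new)
    return np.clip(d_new, 0.0, E)


def residual_correlogram(res: ResidualMatrix, max_lag_age: int,
                         max_lag_year: int) -> np.ndarray:
    """Sample autocorrelation of the residual field on a lag grid.

    Returns an array of shape (max_lag_age + 1, 2*max_lag_year + 1) indexed
    by (age lag 0..max_lag_age, year lag -max_lag_year..max_lag_year); entry
    (0, center) is 1.  Negative year lags at positive age lags distinguish
    cohort-diagonal from anti-diagonal dependence.
    """
    A, T = res.shape
    if max_lag_age >= A or max_lag_year >= T:
        raise ValueError("lags must be smaller than the array dimensions")
    r = np.where(res.mask, res.r, np.nan)
    mu = np.nanmean(r)
    v = np.nanvar(r)
    if v == 0 or not np.isfinite(v):
        raise ValueError("zero-variance residuals: correlation undefined")
    r0 = r - mu
    out = np.empty((max_lag_age + 1, 2 * max_lag_year + 1))
    for dx in range(max_lag_age + 1):
        for j, dt in enumerate(range(-max_lag_year, max_lag_year + 1)):
            a = r0[: A - dx, :]
            b = r0[dx:, :]
            if dt >= 0:
                a2, b2 = a[:, : T - dt], b[:, dt:]
            else:
                a2, b2 = a[:, -dt:], b[:, : T + dt]
            prod = a2 * b2
            out[dx, j] = np.nanmean(prod) / v
    return out
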