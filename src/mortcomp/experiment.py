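"""End-to-end 3 x 3 model-comparison experiment.

For each *residual source* S (a model fitted to the data), the deviance
residuals of S are block-resampled and inverted to pseudo death counts; each
*fitting model* M is then refitted on those counts, its indices projected
with ARIMA, and the four mortality indicators evaluated over the forecast
horizon.  Crossing the three sources with the three models gives nine cells
of N replicate indicator curves each, from which percentile confidence
intervals and the random-projection functional ANOVA are computed.

ARIMA orders are selected once per fitting model on the original fit and
held fixed across replicates (coefficients are refitted per replicate), so
bootstrap variation reflects parameter error rather than order-selection
churn.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import blockboot, fanova, forecast
from .blockboot import BlockSpec, ResidualMatrix
from .forecast import INDICATORS, ArimaSpec, IndicatorCurveSet
from .lc_models import (MortalitySurface, ModelParams, fit_h1, fit_lc,
                        fitted_deaths, h1_mask, read_surface, write_surface)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "default_block_sizes", "read_surface", "write_surface"]

log = logging.getLogger("mortcomp")

MODELS = ("LC1", "LC2", "H1")

# reference block geometry on a 100-age x 22-year surface: 3x9 for the LC
# sources and 3x14 for the cohort-model source (ages x years)
REFERENCE_BLOCKS = {"LC1": (3, 9), "LC2": (3, 9), "H1": (3, 14)}
REFERENCE_SHAPE = (100, 22)


def default_block_sizes(A: int, T: int) -> dict[str, tuple[int, int]]:
    """Reference block sizes, scaled proportionally for smaller surfaces."""
    out = {}
    for src, (h, w) in REFERENCE_BLOCKS.items():
        # round half up so a 50% scale of an odd extent does not collapse
        hh = max(1, min(A, int(h * A / REFERENCE_SHAPE[0] + 0.5)))
        ww = max(1, min(T, int(w * T / REFERENCE_SHAPE[1] + 0.5)))
        out[src] = (hh, ww)
    return out


@dataclass
class ExperimentConfig:
    """Configuration of one crossed bootstrap experiment."""

    models: tuple[str, ...] = MODELS            # fitting models
    sources: tuple[str, ...] = MODELS           # residual sources
    n_replicates: int = 50
    horizon: int = 20
    block_sizes: dict[str, tuple[int, int]] | None = None  # per source
    indicators: tuple[str, ...] = INDICATORS
    k1_order: tuple[int, int, int] = (0, 1, 0)  # classical random walk + drift
    k1_drift: bool = True
    n_projections: int = 30
    alpha: float = 0.05
    seed: int = 0
    radix: float = 100_000.0
    max_failure_frac: float = 0.10
    out_dir: str | None = None

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        for m in tuple(self.models) + tuple(self.sources):
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        """Read a flat ``key = value`` config file (lists comma-separated)."""
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        kwargs = {}
        casts = {f.name: f.type for f in fields(cls)}
        for key, val in kv.items():
            if key not in casts:
                raise ValueError(f"unknown config key {key!r}")
            if key in ("models", "sources", "indicators"):
                kwargs[key] = tuple(v.strip() for v in val.split(","))
            elif key in ("n_replicates", "horizon", "n_projections", "seed"):
                kwargs[key] = int(val)
            elif key in ("alpha", "radix", "max_failure_frac"):
                kwargs[key] = float(val)
            elif key == "k1_order":
                kwargs[key] = tuple(int(v) for v in val.split(","))
            elif key == "k1_drift":
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif key == "block_sizes":
                # format: LC1:3x9,LC2:3x9,H1:3x14
                bs = {}
                for item in val.split(","):
                    name, geom = item.split(":")
                    h, w = geom.lower().split("x")
                    bs[name.strip()] = (int(h), int(w))
                kwargs[key] = bs
            else:
                kwargs[key] = val
        return cls(**kwargs)


@dataclass
class ExperimentResult:
    """All artifacts of one experiment run."""

    curvesets: dict[str, IndicatorCurveSet]          # per indicator
    intervals: pd.DataFrame                          # indicator, model, source, year, lower, upper
    fanova: dict[str, fanova.FanovaResult]           # per indicator
    fits: dict[str, ModelParams]                     # original fits per model
    arima: dict[str, dict[str, ArimaSpec]]           # per model, per index series
    n_failed: int = 0

    def curves_frame(self) -> pd.DataFrame:
        rows = []
        for name, cs in self.curvesets.items():
            for (m, s), arr in sorted(cs.cells.items()):
                for rep in range(arr.shape[0]):
                    for h, year in enumerate(cs.horizon_years):
                        rows.append((name, m, s, rep, int(year), arr[rep, h]))
        return pd.DataFrame(
            rows, columns=["indicator", "model", "residual_source",
                           "replicate", "year", "value"])

    def fanova_frame(self) -> pd.DataFrame:
        return pd.concat([r.to_frame() for r in self.fanova.values()],
                         ignore_index=True)

    def pairwise_frame(self) -> pd.DataFrame:
        frames = []
        for name, r in self.fanova.items():
            if r.pairwise is not None:
                frames.append(r.pairwise.assign(indicator=name))
        return pd.concat(frames, ignore_index=True)


def _fit_model(surface: MortalitySurface, family: str) -> ModelParams:
    if family == "H1":
        return fit_h1(surface)
    return fit_lc(surface, r=1 if family == "LC1" else 2)


def _select_orders(params: ModelParams, config: ExperimentConfig
                   ) -> dict[str, ArimaSpec]:
    """Box-Jenkins order selection on the original fit's index series."""
    specs = {}
    p, d, q = config.k1_order
    specs["k1"] = forecast.fit_arima(params.K[0], p, d, q, drift=config.k1_drift)
    if params.rank > 1:
        specs["k2"] = forecast.select_arima(params.K[1])
    if params.gamma is not None:
        est = params.gamma[np.isfinite(params.gamma)]
        specs["gamma"] = forecast.select_arima(est)
    return specs


def _forecast_curves(params: ModelParams, surface: MortalitySurface,
                     orders: dict[str, ArimaSpec], config: ExperimentConfig
                     ) -> dict[str, np.ndarray]:
    """Refit ARIMA coefficients at fixed orders and evaluate the indicators."""
    H = config.horizon
    k_future = np.empty((params.rank, H))
    for i in range(params.rank):
        spec0 = orders["k1" if i == 0 else "k2"]
        spec = forecast.fit_arima(params.K[i], spec0.p, spec0.d, spec0.q,
                                  drift=spec0.drift)
        k_future[i] = forecast.forecast_index(spec, params.K[i], H)
    gamma_ext = None
    if params.gamma is not None:
        spec0 = orders["gamma"]
        est = params.gamma[np.isfinite(params.gamma)]
        spec = forecast.fit_arima(est, spec0.p, spec0.d, spec0.q, drift=spec0.drift)
        gamma_ext = forecast.forecast_gamma(params.gamma, H, spec=spec)
    future_years = surface.years[-1] + 1 + np.arange(H)
    cohort_years = None
    if params.gamma is not None:
        cohort_years = np.arange(surface.cohort_years()[0],
                                 surface.cohort_years()[0] + len(gamma_ext))
    q_fut = forecast.project_probabilities(
        params, k_future, future_years, surface.ages,
        gamma_extended=gamma_ext, cohort_years=cohort_years)
    return forecast.indicator_curves(q_fut, radix=config.radix,
                                     indicators=config.indicators)


def run_experiment(surface: MortalitySurface, config: ExperimentConfig
                   ) -> ExperimentResult:
    """Run the crossed (fitting model x residual source) bootstrap experiment."""
    A, T = surface.shape
    if "e65" in config.indicators and A <= 65:
        log.warning("age range ends at %d: dropping the e65 indicator",
                    surface.ages[-1])
        config = replace(config, indicators=tuple(
            i for i in config.indicators if i != "e65"))
    blocks = dict(default_block_sizes(A, T))
    if config.block_sizes:
        blocks.update(config.block_sizes)

    needed = sorted(set(config.models) | set(config.sources),
                    key=MODELS.index)
    log.info("fitting %s on the observed surface", needed)
    fits = {m: _fit_model(surface, m) for m in needed}
    arima_orders = {m: _select_orders(fits[m], config) for m in config.models}

    source_resid: dict[str, tuple[ResidualMatrix, np.ndarray]] = {}
    for srcname in config.sources:
        params = fits[srcname]
        dhat = fitted_deaths(params, surface)
        mask = surface.E > 0
        if params.family == "H1":
            mask = mask & h1_mask(surface)
        res = blockboot.deviance_residuals(surface.d, dhat, surface.E, mask)
        source_resid[srcname] = (res, dhat)

    N = config.n_replicates
    raw_curves: dict[tuple[str, str], dict[str, list]] = {
        (m, "R" + s): {ind: [] for ind in config.indicators}
        for m in config.models for s in config.sources}
    n_failed = 0
    for srcname in config.sources:
        res, dhat = source_resid[srcname]
        bh, bw = blocks[srcname]
        for rep in range(N):
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, MODELS.index(srcname), rep)))
            try:
                rhat = blockboot.resample_blocks(
                    res, BlockSpec(bh, bw), rng=rng)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    d_new = blockboot.invert_to_deaths(rhat, dhat, surface.E)
                # cells outside the source's likelihood keep the observed counts
                d_new = np.where(res.mask, d_new, surface.d)
                boot_surface = surface.with_deaths(d_new)
                for m in config.models:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        refit = _fit_model(boot_surface, m)
                        curves = _forecast_curves(refit, surface,
                                                  arima_orders[m], config)
                    for ind in config.indicators:
                        raw_curves[(m, "R" + srcname)][ind].append(curves[ind])
                log.debug("source %s replicate %d done", srcname, rep)
            except Exception as exc:  # noqa: BLE001 - replicate-level fault barrier
                n_failed += 1
                log.warning("source %s replicate %d failed: %s", srcname, rep, exc)
    total = len(config.sources) * N
    if n_failed > config.max_failure_frac * total:
        raise RuntimeError(
            f"{n_failed}/{total} bootstrap replicates failed "
            f"(> {config.max_failure_frac:.0%})")

    # balance the design: truncate every cell to the smallest replicate count
    n_used = min(len(v[config.indicators[0]]) for v in raw_curves.values())
    future_years = surface.years[-1] + 1 + np.arange(config.horizon)
    curvesets = {}
    for ind in config.indicators:
        cells = {key: np.asarray(raw_curves[key][ind][:n_used])
                 for key in raw_curves}
        curvesets[ind] = IndicatorCurveSet(
            indicator=ind, horizon_years=future_years, cells=cells, N=n_used)

    rows = []
    for ind, cs in curvesets.items():
        for (m, s), arr in sorted(cs.cells.items()):
            lower, upper = forecast.percentile_ci(arr)
            for h, year in enumerate(future_years):
                rows.append((ind, m, s, int(year), lower[h], upper[h]))
    intervals = pd.DataFrame(
        rows, columns=["indicator", "model", "residual_source", "year",
                       "lower", "upper"])

    fanova_results = {}
    can_test = (len(set(config.models)) == 3 and len(set(config.sources)) == 3
                and n_used >= 2)
    if can_test:
        for i, ind in enumerate(config.indicators):
            fanova_results[ind] = fanova.fanova_test(
                curvesets[ind], K=config.n_projections, alpha=config.alpha,
                seed=np.random.default_rng(
                    np.random.SeedSequence((config.seed, 97, i))))

    result = ExperimentResult(curvesets=curvesets, intervals=intervals,
                              fanova=fanova_results, fits=fits,
                              arima=arima_orders, n_failed=n_failed)
    if config.out_dir:
        _write_outputs(result, surface, config)
    return result


def _write_outputs(result: ExperimentResult, surface: MortalitySurface,
                   config: ExperimentConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_surface(surface, out / "exposures.csv", out / "deaths.csv")
    result.curves_frame().to_csv(out / "indicator_curves.csv", index=False)
    result.intervals.to_csv(out / "indicator_intervals.csv", index=False)
    if result.fanova:
        result.fanova_frame().to_csv(out / "fanova_decisions.csv", index=False)
        result.pairwise_frame().to_csv(out / "fanova_pairwise.csv", index=False)
    for name, params in result.fits.items():
        params.to_json(out / f"fit_{name}.json")
    for name, specs in result.arima.items():
        for idx, spec in specs.items():
            spec.to_json(out / f"arima_{name}_{idx}.json")
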