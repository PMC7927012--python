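"""Two-way functional ANOVA of indicator curves by random projections.

Each observation is a curve (an indicator trajectory over the forecast
horizon) in a balanced two-factor design: fitting model x residual source,
N replicate curves per cell.  Curves are projected onto K random directions
drawn as standard Brownian motion on the grid; each projection yields a
scalar response analyzed by an ordinary balanced two-way fixed-effects
ANOVA.  The K per-hypothesis p-values are combined with the false discovery
rate rule min_i(K p_(i) / i), giving one combined p-value per hypothesis
(model main effect, sample main effect, interaction).  Pairwise level
comparisons pool over the other factor and use one-way ANOVAs per
projection, combined the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .forecast import IndicatorCurveSet

__all__ = [
    "FanovaResult",
    "project_curves",
    "brownian_directions",
    "two_way_anova",
    "one_way_anova",
    "fdr_combine",
    "fanova_test",
    "pairwise_comparisons",
]


@dataclass
class FanovaResult:
    """Combined p-values and decisions of the random-projection test."""

    indicator: str
    p_model: float
    p_sample: float
    p_interaction: float
    K: int
    alpha: float
    pairwise: pd.DataFrame | None = None  # factor, level_a, level_b, p, p_adjusted, reject

    @property
    def reject_model(self) -> bool:
        return self.p_model < self.alpha

    @property
    def reject_sample(self) -> bool:
        return self.p_sample < self.alpha

    @property
    def reject_interaction(self) -> bool:
        return self.p_interaction < self.alpha

    def to_frame(self) -> pd.DataFrame:
        """Flat table mirroring a rejection summary (hypothesis, p, decision)."""
        rows = [
            ("model", self.p_model, self.reject_model),
            ("sample", self.p_sample, self.reject_sample),
            ("model:sample", self.p_interaction, self.reject_interaction),
        ]
        return pd.DataFrame(rows, columns=["hypothesis", "p", "reject"]) \
            .assign(indicator=self.indicator)


def brownian_directions(H: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """K standard-Brownian-motion directions on an H-point grid (K x H).

    Cumulative sums of iid standard normals scaled by 1/sqrt(H), the usual
    direction law of the random-projection test for functional data.
    """
    return np.cumsum(rng.standard_normal((K, H)) / np.sqrt(H), axis=1)


def project_curves(curves: np.ndarray, K: int,
                   seed: int | np.random.Generator | None = None,
                   directions: np.ndarray | None = None) -> np.ndarray:
    """Project curves (n x H) onto K shared random directions -> (n x K)."""
    curves = np.atleast_2d(np.asarray(curves, float))
    if directions is None:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        directions = brownian_directions(curves.shape[1], K, rng)
    if directions.shape[1] != curves.shape[1]:
        raise ValueError("direction grid does not match the curve grid")
    return curves @ directions.T


def two_way_anova(y: np.ndarray, factor_a: np.ndarray, factor_b: np.ndarray
                  ) -> dict[str, tuple[float, float]]:
    """Balanced two-way fixed-effects ANOVA.

    Returns {"A": (F, p), "B": (F, p), "AB": (F, p)}.  Requires a balanced
    design with at least two replicates per cell.  A fully degenerate input
    (zero effect and zero error sums of squares) gives p = 1 by convention.
    """
    y = np.asarray(y, float)
    a_levels, a_idx = np.unique(factor_a, return_inverse=True)
    b_levels, b_idx = np.unique(factor_b, return_inverse=True)
    I, J = len(a_levels), len(b_levels)
    counts = np.zeros((I, J), int)
    np.add.at(counts, (a_idx, b_idx), 1)
    if counts.min() != counts.max():
        raise ValueError("design must be balanced")
    n = counts[0, 0]
    if n < 2:
        raise ValueError("need at least two replicates per cell")
    N = y.size

    grand = y.mean()
    cell_mean = np.zeros((I, J))
    np.add.at(cell_mean, (a_idx, b_idx), y)
    cell_mean /= n
    a_mean = cell_mean.mean(axis=1)
    b_mean = cell_mean.mean(axis=0)

    ss_a = n * J * np.sum((a_mean - grand) ** 2)
    ss_b = n * I * np.sum((b_mean - grand) ** 2)
    ss_ab = n * np.sum((cell_mean - a_mean[:, None] - b_mean[None, :] + grand) ** 2)
    ss_err = np.sum((y - cell_mean[a_idx, b_idx]) ** 2)
    df_a, df_b = I - 1, J - 1
    df_ab = df_a * df_b
    df_err = N - I * J

    def f_p(ss, df):
        if ss_err <= 0:
            if ss <= 0:
                return 0.0, 1.0  # fully degenerate data
            return np.inf, 0.0
        F = (ss / df) / (ss_err / df_err)
        return float(F), float(stats.f.sf(F, df, df_err))

    return {"A": f_p(ss_a, df_a), "B": f_p(ss_b, df_b), "AB": f_p(ss_ab, df_ab)}


def one_way_anova(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Balanced one-way ANOVA F test; degenerate data give p = 1."""
    y = np.asarray(y, float)
    levels, idx = np.unique(groups, return_inverse=True)
    I = len(levels)
    grand = y.mean()
    means = np.array([y[idx == i].mean() for i in range(I)])
    ns = np.array([(idx == i).sum() for i in range(I)])
    ss_between = np.sum(ns * (means - grand) ** 2)
    ss_within = np.sum((y - means[idx]) ** 2)
    df_b, df_w = I - 1, y.size - I
    if ss_within <= 0:
        return (0.0, 1.0) if ss_between <= 0 else (np.inf, 0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(F), float(stats.f.sf(F, df_b, df_w))


def fdr_combine(pvals) -> float:
    """False-discovery-rate combination of K projection p-values.

    With order statistics p_(1) <= ... <= p_(K), returns
    min(1, min_i K p_(i) / i).
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    K = p.size
    ranked = np.sort(p)
    return float(min(1.0, np.min(K * ranked / np.arange(1, K + 1))))


def fanova_test(curveset: IndicatorCurveSet, K: int = 30, alpha: float = 0.05,
                seed: int | np.random.Generator | None = None,
                with_pairwise: bool = True) -> FanovaResult:
    """Random-projection functional ANOVA of an indicator curve set.

    Tests the model main effect, the sample (residual-source) main effect
    and their interaction on the balanced models x sources x N design.  The
    same K Brownian directions are shared by all hypotheses and by the
    pairwise comparisons so the results are internally consistent.
    """
    curves, models, sources = curveset.stacked()
    n_cells = len(set(zip(models, sources)))
    if n_cells != len(set(models)) * len(set(sources)):
        raise ValueError("design must be fully crossed")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    directions = brownian_directions(curves.shape[1], K, rng)
    proj = project_curves(curves, K, directions=directions)  # n x K

    p_mod = np.empty(K)
    p_sam = np.empty(K)
    p_int = np.empty(K)
    for k in range(K):
        res = two_way_anova(proj[:, k], models, sources)
        p_mod[k], p_sam[k], p_int[k] = res["A"][1], res["B"][1], res["AB"][1]

    result = FanovaResult(
        indicator=curveset.indicator,
        p_model=fdr_combine(p_mod),
        p_sample=fdr_combine(p_sam),
        p_interaction=fdr_combine(p_int),
        K=K, alpha=alpha,
    )
    if with_pairwise:
        frames = [
            _pairwise_from_projections(proj, models, "model", alpha),
            _pairwise_from_projections(proj, sources, "sample", alpha),
        ]
        result.pairwise = pd.concat(frames, ignore_index=True)
    return result


def pairwise_comparisons(curveset: IndicatorCurveSet, factor: str = "model",
                         K: int = 30, alpha: float = 0.05,
                         seed: int | np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Pairwise level comparisons for one factor, pooled over the other.

    For each level pair a one-way ANOVA is run per projection and combined
    by the FDR rule.  Benjamini-Hochberg-adjusted p-values across the pairs
    are also reported; the default decision uses the raw combined p.
    """
    if factor not in ("model", "sample"):
        raise ValueError("factor must be 'model' or 'sample'")
    curves, models, sources = curveset.stacked()
    labels = models if factor == "model" else sources
    if len(set(labels)) < 2:
        raise ValueError("factor needs at least two levels")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    directions = brownian_directions(curves.shape[1], K, rng)
    proj = project_curves(curves, K, directions=directions)
    return _pairwise_from_projections(proj, labels, factor, alpha)


def _pairwise_from_projections(proj: np.ndarray, labels: np.ndarray,
                               factor: str, alpha: float) -> pd.DataFrame:
    levels = sorted(set(labels))
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            keep = (labels == levels[i]) | (labels == levels[j])
            sub = proj[keep]
            grp = labels[keep]
            pk = np.array([one_way_anova(sub[:, k], grp)[1]
                           for k in range(proj.shape[1])])
            rows.append((factor, levels[i], levels[j], fdr_combine(pk)))
    df = pd.DataFrame(rows, columns=["factor", "level_a", "level_b", "p"])
    df["p_adjusted"] = _benjamini_hochberg(df["p"].to_numpy())
    df["reject"] = df["p"] < alpha
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values across a small family of tests."""
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
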