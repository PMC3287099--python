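"""Variance-components analysis of electrode sampling strategies.

Two questions are asked of a cohort of tumors sampled with needle
electrodes.  First, how much of the variability of an oxygenation
assessment is sampling noise within a tumor rather than genuine
between-tumor difference — and how does that share shrink as tracks are
added?  Second, how much variability is attributable to the choice of
estimation method (hypoxic-area image analysis vs pooled electrode
readings) under each placement strategy?

Components are estimated by ANOVA method-of-moments (expected mean
squares, negative estimates truncated at zero), the classical
variance-components approach; no iterative fitting is involved.

The within-vs-between percentage is reported on the scale of a *tumor-
level assessment*: the within-tumor component enters as the sampling
variance of a per-tumor mean, sigma_w^2 / n0, where n0 is the effective
per-tumor reading count.  With k tracks of m readings this behaves like
sigma_w^2/(k m), which is what gives the percentage its characteristic
decrease with additional tracks and the diminishing return beyond 5-6
tracks.  The raw component ratio (no 1/n scaling, constant in k in
expectation) is available via ``scale="reading"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .electrode import make_plan, sample, hp_from_readings
from .hypoxia import hypoxic_area_fraction

__all__ = [
    "VarianceDecomposition",
    "MethodComparison",
    "InsufficientDataError",
    "within_between",
    "between_methods",
    "variance_vs_tracks",
    "strategy_method_variance",
    "normality_check",
]


class InsufficientDataError(ValueError):
    """Fewer groups or readings than the decomposition requires."""


@dataclass(frozen=True)
class VarianceDecomposition:
    """One-way random-effects decomposition of cohort readings."""

    var_within: float
    var_between: float
    pct_total_within: float
    n_groups: int
    n0: float  # effective per-group sample size (unbalanced-design constant)
    degenerate: bool = False
    n_tracks: int | None = None
    strategy: str | None = None


@dataclass(frozen=True)
class MethodComparison:
    """Tumor x method (two-way, one observation per cell) decomposition."""

    var_method: float
    var_tumor: float
    ms_residual: float
    pct_total_method: float
    n_tumors: int
    degenerate: bool = False


def within_between(
    groups: Sequence[np.ndarray],
    scale: Literal["mean", "reading"] = "mean",
) -> VarianceDecomposition:
    """Within- and between-tumor variance components from pooled readings.

    ``groups`` holds one array of readings per tumor (>= 2 tumors, each
    with >= 2 readings).  Components come from the one-way random-effects
    expected mean squares with the standard unbalanced-design constant n0.
    The percentage of total variance is 100 * W / (W + var_between) where
    W = var_within / n0 for ``scale="mean"`` (the default; variance of a
    tumor-level mean) or W = var_within for ``scale="reading"``.

    A fully degenerate cohort (all readings identical) returns percentage
    0 with the degenerate flag set.
    """
    groups = [np.asarray(grp, dtype=float).ravel() for grp in groups]
    T = len(groups)
    if T < 2:
        raise InsufficientDataError("need at least 2 tumors")
    sizes = np.array([g.size for g in groups])
    if (sizes < 2).any():
        raise InsufficientDataError("every tumor needs at least 2 readings")
    N = int(sizes.sum())
    grand = float(np.concatenate(groups).mean())
    means = np.array([g.mean() for g in groups])
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ms_within = ss_within / (N - T)
    ms_between = ss_between / (T - 1)
    n0 = (N - float((sizes**2).sum()) / N) / (T - 1)
    var_within = ms_within
    var_between = max(0.0, (ms_between - ms_within) / n0)
    w = var_within / n0 if scale == "mean" else var_within
    total = w + var_between
    if total == 0.0:
        return VarianceDecomposition(0.0, 0.0, 0.0, T, n0, degenerate=True)
    return VarianceDecomposition(var_within, var_between, 100.0 * w / total, T, n0)


def between_methods(
    hp_area: Sequence[float] | Mapping[object, float],
    hp_electrode: Sequence[float] | Mapping[object, float],
) -> MethodComparison:
    """Between-methods vs between-tumors variance share.

    ``hp_area`` and ``hp_electrode`` give each tumor's hypoxic fraction as
    estimated by the area method and the electrode method (same tumors,
    same order; mappings must share keys).  A two-factor tumor x method
    mean-square decomposition (one observation per cell, no interaction
    term) yields the method and tumor components; the result is
    100 * Var(method) / (Var(tumor) + Var(method)).
    """
    if isinstance(hp_area, Mapping) or isinstance(hp_electrode, Mapping):
        if not (isinstance(hp_area, Mapping) and isinstance(hp_electrode, Mapping)):
            raise ValueError("pass both estimates as mappings or both as sequences")
        if set(hp_area) != set(hp_electrode):
            raise ValueError("the two methods cover different tumor sets")
        keys = sorted(hp_area, key=repr)
        a = np.array([hp_area[k] for k in keys], dtype=float)
        b = np.array([hp_electrode[k] for k in keys], dtype=float)
    else:
        a = np.asarray(hp_area, dtype=float)
        b = np.asarray(hp_electrode, dtype=float)
        if a.shape != b.shape:
            raise ValueError("the two methods cover different tumor sets")
    T = a.size
    if T < 2:
        raise InsufficientDataError("need at least 2 tumors")
    grand = float((a.sum() + b.sum()) / (2 * T))
    method_means = np.array([a.mean(), b.mean()])
    tumor_means = (a + b) / 2.0
    ss_method = T * float(((method_means - grand) ** 2).sum())  # df = 1
    ss_tumor = 2.0 * float(((tumor_means - grand) ** 2).sum())  # df = T-1
    ss_total = float(((a - grand) ** 2).sum() + ((b - grand) ** 2).sum())
    ss_resid = max(0.0, ss_total - ss_method - ss_tumor)  # df = T-1
    ms_method = ss_method / 1.0
    ms_tumor = ss_tumor / (T - 1)
    ms_resid = ss_resid / (T - 1)
    var_method = max(0.0, (ms_method - ms_resid) / T)
    var_tumor = max(0.0, (ms_tumor - ms_resid) / 2.0)
    total = var_method + var_tumor
    if total == 0.0:
        return MethodComparison(0.0, 0.0, ms_resid, 0.0, T, degenerate=True)
    return MethodComparison(
        var_method, var_tumor, ms_resid, 100.0 * var_method / total, T
    )


def _derive_seed(seed: int, *parts: int) -> int:
    ss = np.random.SeedSequence([seed, *parts])
    return int(ss.generate_state(1)[0] % (2**31))


def variance_vs_tracks(
    fields: Sequence[tuple],
    strategy: str,
    max_tracks: int,
    n_readings: int = 25,
    step_mm: float = 0.2,
    replicates: int = 1,
    seed: int = 0,
    arc_deg: tuple[float, float] = (60.0, 120.0),
    scale: Literal["mean", "reading"] = "mean",
) -> pd.DataFrame:
    """Within-tumor variance share as a function of the number of tracks.

    ``fields`` is a cohort of ``(domain, K)`` pairs (converged oxygen
    fields).  For k = 1..max_tracks every tumor is sampled with a k-track
    plan and the cohort readings decomposed; random-strategy plans use the
    first k tracks of a ``max_tracks`` plan (incremental insertion) and
    are averaged over ``replicates`` seeded repeats.  Deterministic
    strategies are computed once.

    Returns a DataFrame with columns ``n_tracks`` and ``pct_total_within``.
    """
    if max_tracks < 2:
        raise ValueError("max_tracks must be >= 2")
    n_reps = replicates if strategy == "random" else 1
    acc = np.zeros(max_tracks)
    for rep in range(n_reps):
        full_plans = None
        if strategy == "random":
            full_plans = [
                make_plan(strategy, max_tracks, dom, seed=_derive_seed(seed, rep, i),
                          step_mm=step_mm, n_readings=n_readings)
                for i, (dom, _K) in enumerate(fields)
            ]
        for k in range(1, max_tracks + 1):
            groups = []
            for i, (dom, K) in enumerate(fields):
                if strategy == "random":
                    plan = full_plans[i]
                    from .electrode import SamplingPlan

                    plan_k = SamplingPlan(strategy, plan.tracks[:k], plan.seed)
                else:
                    plan_k = make_plan(strategy, k, dom, step_mm=step_mm,
                                       n_readings=n_readings, arc_deg=arc_deg)
                rs = sample(plan_k, K, dom.geometry, tumor_mask=dom.tumor_mask)
                groups.append(rs.values)
            acc[k - 1] += within_between(groups, scale=scale).pct_total_within
    return pd.DataFrame(
        {"n_tracks": np.arange(1, max_tracks + 1), "pct_total_within": acc / n_reps}
    )


def strategy_method_variance(
    fields: Sequence[tuple],
    strategies: Sequence[str] = ("uniform", "random", "half_radial", "full_radial"),
    n_tracks: int = 6,
    threshold: float = 5.0,
    n_readings: int = 25,
    step_mm: float = 0.2,
    replicates: int = 1,
    seed: int = 0,
    arc_deg: tuple[float, float] = (60.0, 120.0),
) -> dict[str, float]:
    """Between-methods variance share per placement strategy.

    For each strategy, each tumor's hypoxic fraction at ``threshold`` is
    estimated by the area method and by pooled electrode readings; the
    two-way decomposition's method share is averaged over ``replicates``
    (random strategy only; the rest are deterministic).
    """
    out: dict[str, float] = {}
    for strat in strategies:
        n_reps = replicates if strat == "random" else 1
        pcts = []
        for rep in range(n_reps):
            hp_a, hp_e = [], []
            for i, (dom, K) in enumerate(fields):
                plan = make_plan(
                    strat, n_tracks, dom,
                    seed=_derive_seed(seed, rep, i) if strat == "random" else None,
                    step_mm=step_mm, n_readings=n_readings, arc_deg=arc_deg,
                )
                rs = sample(plan, K, dom.geometry, tumor_mask=dom.tumor_mask)
                hp_a.append(hypoxic_area_fraction(K, dom.tumor_mask, threshold))
                hp_e.append(hp_from_readings(rs, float(K.max()), [threshold])[threshold])
            pcts.append(between_methods(hp_a, hp_e).pct_total_method)
        out[strat] = float(np.mean(pcts))
    return out


def normality_check(groups: Sequence[np.ndarray]) -> dict:
    """Advisory normality diagnostics of within-tumor residuals.

    Residuals are readings minus their tumor mean, pooled across tumors;
    summarized by skewness, excess kurtosis and the D'Agostino-Pearson
    omnibus statistic.  Never raises on non-normality — the caller decides
    whether the variance analysis is trustworthy.
    """
    resid = np.concatenate(
        [np.asarray(g, float).ravel() - np.mean(g) for g in groups]
    )
    if resid.size < 20 or np.allclose(resid, resid[0]):
        return {
            "skewness": float("nan"),
            "excess_kurtosis": float("nan"),
            "statistic": float("nan"),
            "pvalue": float("nan"),
            "n": int(resid.size),
            "degenerate": True,
        }
    stat, p = stats.normaltest(resid)
    return {
        "skewness": float(stats.skew(resid)),
        "excess_kurtosis": float(stats.kurtosis(resid)),
        "statistic": float(stat),
        "pvalue": float(p),
        "n": int(resid.size),
        "degenerate": False,
    }
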