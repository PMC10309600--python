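"""Minimal filter-sheet estimation by Monte-Carlo simulation and regression.

How many filter sheets must a 1-hour sampling session use so that the DNA
yield reliably reaches a target (default 10 ng)? The estimator:

1. estimate the per-sheet yield rate ``lambda_hat`` (ng/sheet) from training
   sessions;
2. for each candidate sheet count ``k`` simulate ``n_sim`` total-yield values
   (default 100) from a Poisson model of the per-sheet concentration;
3. compute the lower bound of a one-tailed confidence interval (default 90%,
   t-quantile with ``ci_df`` degrees of freedom, default 40 for a 41-session
   training set) of the simulated values at each ``k``;
4. regress the lower bounds on ``k`` and report the smallest integer sheet
   count whose regression line reaches the target yield.

The Poisson family operates on counts at ``poisson_scale`` counts per ng
(default 100, i.e. 0.01 ng resolution); gamma and bootstrap families are
dispersion-faithful alternatives. An observed per-sheet dispersion of zero is
treated as the noiseless limit in every family: simulated totals collapse to
``k * lambda_hat`` and the estimate is exactly ``ceil(target / lambda_hat)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
from scipy import stats

from .exceptions import (
    EmptyInputError,
    GridExceededError,
    InsufficientSampleError,
    NonInformativeRegressionError,
    ParameterDomainError,
)
from .yield_performance import YieldDataset

__all__ = [
    "EffortConfig",
    "EffortEstimate",
    "fit_per_sheet",
    "simulate_totals",
    "ci_lower_bound",
    "estimate_min_sheets",
    "SheetEffortModel",
    "EffortResults",
]

SIM_FAMILIES = ("scaled_poisson", "gamma", "bootstrap")
BOUND_MODES = ("mean_se", "mean_sd", "empirical_quantile")


@dataclass(frozen=True)
class EffortConfig:
    """Configuration of the minimal-sheet simulation estimator.

    ``ci_df=None`` resolves at fit time to ``n_train - 1``.
    """

    target_yield_ng: float = 10.0
    confidence: float = 0.90
    n_sim: int = 100
    ci_df: Optional[int] = None
    sheet_grid: tuple = tuple(range(1, 201))
    sim_family: str = "scaled_poisson"
    poisson_scale: float = 100.0
    bound_mode: str = "mean_sd"
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.5 < self.confidence < 1.0:
            raise ParameterDomainError(
                f"confidence must be in (0.5, 1), got {self.confidence}"
            )
        if self.n_sim < 2:
            raise ParameterDomainError(f"n_sim must be >= 2, got {self.n_sim}")
        if not self.target_yield_ng > 0:
            raise ParameterDomainError(
                f"target_yield_ng must be > 0, got {self.target_yield_ng}"
            )
        if not self.poisson_scale > 0:
            raise ParameterDomainError(
                f"poisson_scale must be > 0, got {self.poisson_scale}"
            )
        if self.sim_family not in SIM_FAMILIES:
            raise ValueError(f"sim_family must be one of {SIM_FAMILIES}")
        if self.bound_mode not in BOUND_MODES:
            raise ValueError(f"bound_mode must be one of {BOUND_MODES}")


@dataclass(frozen=True)
class EffortEstimate:
    """Result of the minimal-sheet estimation."""

    min_sheets: int
    crossing_k: float  # exact intersection abscissa on the regression line
    slope: float  # ng per sheet
    intercept: float  # ng
    r_squared: float
    lower_bounds: Dict[int, float]
    lambda_hat: float
    dispersion: float
    config: EffortConfig


def fit_per_sheet(records) -> tuple[float, float]:
    """Per-sheet yield rate and dispersion: mean and sd of ng/sheet values."""
    if isinstance(records, YieldDataset):
        per_sheet = records.per_sheet_yields
    else:
        per_sheet = np.asarray(records, dtype=float)
    if per_sheet.size == 0:
        raise EmptyInputError("no training records supplied")
    if per_sheet.size < 2:
        raise InsufficientSampleError("need at least 2 training records")
    lam = float(np.mean(per_sheet))
    disp = float(np.std(per_sheet, ddof=1))
    if disp <= 1e-12 * max(1.0, abs(lam)):  # snap float noise to the exact limit
        disp = 0.0
    return lam, disp


def simulate_totals(
    k_sheets: int,
    lambda_hat: float,
    cfg: EffortConfig,
    rng: np.random.Generator,
    *,
    dispersion: float = None,
    per_sheet_values=None,
) -> np.ndarray:
    """Simulate ``cfg.n_sim`` total yields (ng) for a ``k_sheets``-sheet session.

    scaled_poisson draws Poisson(poisson_scale * k * lambda) / poisson_scale;
    gamma matches mean ``k*lambda`` and variance ``k*dispersion**2``;
    bootstrap sums ``k`` resampled observed per-sheet yields. Dispersion 0 is
    the noiseless limit: all totals equal ``k * lambda``.
    """
    if lambda_hat < 0:
        raise ParameterDomainError(f"lambda_hat must be >= 0, got {lambda_hat}")
    if k_sheets < 1:
        raise ParameterDomainError(f"k_sheets must be >= 1, got {k_sheets}")
    n = cfg.n_sim
    mean_total = k_sheets * lambda_hat
    if dispersion == 0.0 or lambda_hat == 0.0:
        return np.full(n, mean_total)
    if cfg.sim_family == "scaled_poisson":
        return rng.poisson(cfg.poisson_scale * mean_total, size=n) / cfg.poisson_scale
    if cfg.sim_family == "gamma":
        if dispersion is None:
            raise ParameterDomainError("gamma family requires a dispersion estimate")
        var_total = k_sheets * dispersion**2
        shape = mean_total**2 / var_total
        scale = var_total / mean_total
        return rng.gamma(shape, scale, size=n)
    if per_sheet_values is None:
        raise ParameterDomainError("bootstrap family requires per_sheet_values")
    per_sheet = np.asarray(per_sheet_values, dtype=float)
    draws = rng.choice(per_sheet, size=(n, k_sheets), replace=True)
    return draws.sum(axis=1)


def ci_lower_bound(values, confidence: float, ci_df: int, bound_mode: str = "mean_sd") -> float:
    """Lower bound of the one-tailed confidence interval of simulated yields.

    mean_se: mean - t * sd/sqrt(n); mean_sd: mean - t * sd (a per-observation
    style bound); empirical_quantile: the (1 - confidence) sample quantile.
    """
    x = np.asarray(values, dtype=float)
    if not 0.0 < confidence < 1.0:
        raise ParameterDomainError(f"confidence must be in (0, 1), got {confidence}")
    if bound_mode not in BOUND_MODES:
        raise ValueError(f"bound_mode must be one of {BOUND_MODES}")
    if bound_mode == "empirical_quantile":
        if x.size < 10:
            raise InsufficientSampleError("empirical_quantile needs n >= 10")
        return float(np.quantile(x, 1.0 - confidence))
    if x.size < 2:
        raise InsufficientSampleError("mean_se/mean_sd need n >= 2")
    m = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    tq = float(stats.t.ppf(confidence, ci_df))
    if bound_mode == "mean_se":
        return m - tq * sd / math.sqrt(x.size)
    return m - tq * sd


def _rng_for_k(seed: int, k: int) -> np.random.Generator:
    # keyed to the sheet count itself, so results do not depend on grid order
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))


def estimate_min_sheets(records, cfg: EffortConfig = EffortConfig()) -> EffortEstimate:
    """Run the full simulation/regression estimator.

    For each sheet count ``k`` in ``cfg.sheet_grid``: simulate totals, take
    the one-tailed lower confidence bound; then OLS of bound on ``k``; the
    estimate is the smallest integer at or above the regression line's
    crossing with the target yield.
    """
    lam, disp = fit_per_sheet(records)
    per_sheet = (
        records.per_sheet_yields
        if isinstance(records, YieldDataset)
        else np.asarray(records, dtype=float)
    )
    ci_df = cfg.ci_df if cfg.ci_df is not None else per_sheet.size - 1
    ks = np.array(sorted(cfg.sheet_grid), dtype=int)
    bounds = np.empty(ks.size)
    for i, k in enumerate(ks):
        totals = simulate_totals(
            int(k), lam, cfg, _rng_for_k(cfg.rng_seed, int(k)),
            dispersion=disp, per_sheet_values=per_sheet,
        )
        bounds[i] = ci_lower_bound(totals, cfg.confidence, ci_df, cfg.bound_mode)

    reg = stats.linregress(ks.astype(float), bounds)
    slope, intercept = float(reg.slope), float(reg.intercept)
    if not slope > 0:
        raise NonInformativeRegressionError(
            f"regression slope {slope:.4g} is not positive; no target crossing"
        )
    crossing = (cfg.target_yield_ng - intercept) / slope
    min_sheets = max(1, math.ceil(crossing - 1e-9))
    if min_sheets > ks.max():
        raise GridExceededError(
            f"target {cfg.target_yield_ng} ng unreachable within the sheet grid "
            f"(extrapolated crossing at k = {crossing:.1f})",
            extrapolated_k=crossing,
        )
    return EffortEstimate(
        min_sheets=int(min_sheets),
        crossing_k=float(crossing),
        slope=slope,
        intercept=intercept,
        r_squared=float(reg.rvalue) ** 2,
        lower_bounds={int(k): float(b) for k, b in zip(ks, bounds)},
        lambda_hat=lam,
        dispersion=disp,
        config=replace(cfg, ci_df=ci_df),
    )


class SheetEffortModel:
    """Statsmodels-style wrapper around :func:`estimate_min_sheets`.

    ``data`` is a :class:`YieldDataset` or a sequence of per-sheet yields
    (ng/sheet) from the training sessions.
    """

    def __init__(self, data, config: EffortConfig = EffortConfig()):
        self.data = data
        self.config = config

    @classmethod
    def from_dataframe(cls, df, config: EffortConfig = EffortConfig()):
        return cls(YieldDataset.from_dataframe(df), config)

    def fit(self, seed: Optional[int] = None) -> "EffortResults":
        cfg = self.config if seed is None else replace(self.config, rng_seed=seed)
        return EffortResults(self, estimate_min_sheets(self.data, cfg))


class EffortResults:
    """Fitted minimal-sheet estimate with its regression diagnostics."""

    def __init__(self, model: SheetEffortModel, estimate: EffortEstimate):
        self.model = model
        self.estimate = estimate

    @property
    def min_sheets(self) -> int:
        return self.estimate.min_sheets

    def lower_bound_table(self):
        import pandas as pd

        e = self.estimate
        return pd.DataFrame(
            {"k_sheets": list(e.lower_bounds), "lower_bound_ng": list(e.lower_bounds.values())}
        )

    def summary(self) -> str:
        e = self.estimate
        c = e.config
        return "\n".join(
            [
                "Minimal filter-sheet estimate (Poisson simulation + regression)",
                "=" * 63,
                f"per-sheet rate lambda (ng/sheet)   {e.lambda_hat:>10.4f}",
                f"per-sheet dispersion (ng/sheet)    {e.dispersion:>10.4f}",
                f"target yield (ng)                  {c.target_yield_ng:>10.2f}",
                f"one-tailed confidence              {c.confidence:>10.2f}",
                f"simulations per sheet count        {c.n_sim:>10d}",
                f"CI degrees of freedom              {c.ci_df:>10d}",
                f"bound mode / family                {c.bound_mode:>10s} / {c.sim_family}",
                "-" * 63,
                f"regression slope (ng/sheet)        {e.slope:>10.4f}",
                f"regression intercept (ng)          {e.intercept:>10.4f}",
                f"R-squared                          {e.r_squared:>10.4f}",
                f"exact crossing (sheets)            {e.crossing_k:>10.2f}",
                f"minimal sheets                     {e.min_sheets:>10d}",
            ]
        )
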