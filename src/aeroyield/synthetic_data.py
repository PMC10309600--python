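"""Seeded generators of synthetic pilot data for the whole pipeline.

Three generators with known ground truth make every analysis stage testable
without any field campaign:

* :func:`gen_yields` — per-session DNA yields drawn from a requested skew-t
  (right-skewed, heavy-tailed, truncated below at 0 by rejection);
* :func:`gen_air_quality` — correlated positive PM covariates plus derived
  temperature/humidity variables, with a *planted* log-linear effect of
  chosen covariates on yield, returned alongside the data for recovery tests;
* :func:`gen_gel` — gel images with bands of known intensity at known
  rectangles over a noisy background.

Every generator is a pure function of its spec (seed included): the same
spec gives a bit-identical dataset. Presets named ``"sheetA-like"`` etc.
emulate the *structure* of the study's pilot tables (sampler mix, sample
sizes, plausible yield scales); they are synthetic stand-ins, explicitly not
the study's measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import skewt
from .exceptions import FeasibilityError, ParameterDomainError
from .gel_quant import GelImage, Rectangle
from .skewt import MomentSummary, SkewTDirectParams
from .yield_performance import YieldDataset, YieldRecord

__all__ = [
    "YieldGenSpec",
    "AirGenSpec",
    "gen_yields",
    "gen_air_quality",
    "gen_gel",
    "YIELD_PRESETS",
    "AIR_PRESETS",
    "yield_preset",
    "air_preset",
]


@dataclass(frozen=True)
class YieldGenSpec:
    """Specification of a synthetic per-session yield table."""

    cp: Optional[MomentSummary] = None
    dp: Optional[SkewTDirectParams] = None
    n_sessions: int = 48
    n_sheets: int = 27
    sampler_label: str = "AirDNA"
    location: str = "indoor"
    duration_h: float = 1.0
    floor_ng: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_sessions < 1:
            raise ParameterDomainError(f"n_sessions must be >= 1, got {self.n_sessions}")
        if (self.cp is None) == (self.dp is None):
            raise ParameterDomainError("specify exactly one of cp or dp")


@dataclass(frozen=True)
class AirGenSpec:
    """Specification of a synthetic air-quality covariate table.

    The eight sampled variables (six PM bins, AT, RH) are drawn from a
    correlated Gaussian — adjacent PM size bins correlate at
    ``pm_adjacent_corr ** |i-j|`` — then clipped to physical ranges. Dew
    point and wet-bulb temperature are derived from AT and RH so that
    dp <= wb <= at always holds. Yield is log-linear in the standardized
    covariates: ``log y = log(base_yield_ng) + sum(effects_j * z_j) + noise``.
    """

    n_records: int = 66
    means: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    sds: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SDS))
    pm_adjacent_corr: float = 0.8
    effects: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    noise_sd: float = 0.6
    base_yield_ng: float = 10.0
    hour_proportions: Tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    rng_seed: int = 0


_PM_VARS = ["pm_0_3", "pm_0_5", "pm_1_0", "pm_2_5", "pm_5_0", "pm_10"]
_SAMPLED_VARS = _PM_VARS + ["at", "rh"]

# plausible low-biomass indoor environment: particle-counter counts per bin,
# tropical indoor temperature and mid-range humidity
_DEFAULT_MEANS = {
    "pm_0_3": 25000.0, "pm_0_5": 8000.0, "pm_1_0": 1500.0,
    "pm_2_5": 400.0, "pm_5_0": 120.0, "pm_10": 60.0,
    "at": 27.0, "rh": 55.0,
}
_DEFAULT_SDS = {
    "pm_0_3": 8000.0, "pm_0_5": 3000.0, "pm_1_0": 600.0,
    "pm_2_5": 180.0, "pm_5_0": 60.0, "pm_10": 30.0,
    "at": 2.0, "rh": 10.0,
}
# planted signal concentrated on the finest PM bins (the fraction carrying
# most bioaerosol surface area), on the log-yield scale
_DEFAULT_EFFECTS = {"pm_0_3": 0.8, "pm_0_5": 0.7, "pm_1_0": 0.6}


def gen_yields(spec: YieldGenSpec) -> YieldDataset:
    """Draw a per-session yield table from the requested skew-t.

    Values below ``floor_ng`` are redrawn (rejection, capped at 1000 attempts
    per draw) rather than clamped, avoiding a point mass at the floor.
    """
    dp = spec.dp if spec.dp is not None else skewt.cp_to_dp(spec.cp)
    rng = np.random.default_rng(spec.rng_seed)
    draws = skewt.st_rvs(dp, spec.n_sessions, rng)
    for _ in range(1000):  # rejection, not clamping: no point mass at the floor
        bad = draws < spec.floor_ng
        if not bad.any():
            break
        draws[bad] = skewt.st_rvs(dp, int(bad.sum()), rng)
    else:
        raise FeasibilityError(
            f"rejection sampling failed: {spec.floor_ng} ng floor rejects "
            "essentially all mass of the requested distribution"
        )
    records = [
        YieldRecord(
            sampler_label=spec.sampler_label,
            session_id=f"{spec.sampler_label}-{i + 1:03d}",
            duration_h=spec.duration_h,
            n_sheets=spec.n_sheets,
            total_yield_ng=float(draws[i]),
            location=spec.location,
        )
        for i in range(spec.n_sessions)
    ]
    return YieldDataset(records)


def _pm_correlation(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def gen_air_quality(spec: AirGenSpec) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Generate covariate records plus the ground-truth effect vector."""
    rng = np.random.default_rng(spec.rng_seed)
    p = len(_SAMPLED_VARS)
    corr = np.eye(p)
    corr[:6, :6] = _pm_correlation(6, spec.pm_adjacent_corr)
    # Toeplitz power correlation is positive definite for |rho| < 1
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((spec.n_records, p)) @ chol.T

    df = pd.DataFrame(index=range(spec.n_records))
    for j, name in enumerate(_SAMPLED_VARS):
        df[name] = spec.means[name] + spec.sds[name] * z[:, j]
    for name in _PM_VARS:
        df[name] = df[name].clip(lower=0.0)
    df["rh"] = df["rh"].clip(0.0, 100.0)
    # Lawrence dew-point approximation and a crude wet-bulb interpolation,
    # plus 0.2 degC instrument jitter; clipped so dp <= wb <= at always holds
    dp_t = df["at"] - (100.0 - df["rh"]) / 5.0 + 0.2 * rng.standard_normal(spec.n_records)
    df["dp"] = np.minimum(dp_t, df["at"])
    wb_t = df["at"] - (df["at"] - df["dp"]) / 3.0 + 0.2 * rng.standard_normal(spec.n_records)
    df["wb"] = np.clip(wb_t, df["dp"], df["at"])

    effects = {name: float(spec.effects.get(name, 0.0)) for name in _SAMPLED_VARS}
    lin = np.zeros(spec.n_records)
    for j, name in enumerate(_SAMPLED_VARS):
        lin += effects[name] * z[:, j]
    log_yield = math.log(spec.base_yield_ng) + lin + spec.noise_sd * rng.standard_normal(
        spec.n_records
    )
    df["yield_ng"] = np.exp(log_yield)

    props = np.asarray(spec.hour_proportions, dtype=float)
    props = props / props.sum()
    counts = np.floor(props * spec.n_records).astype(int)
    counts[0] += spec.n_records - counts.sum()
    hours = np.repeat(["H1", "H2", "H3"], counts)
    df["hour_index"] = rng.permutation(hours)
    cols = _PM_VARS + ["at", "rh", "dp", "wb", "hour_index", "yield_ng"]
    return df[cols], effects


def gen_gel(
    lane_means: Sequence[float],
    noise_sd: float = 1.0,
    shape: Tuple[int, int] = (120, 400),
    rng_seed: int = 0,
    *,
    band_shape: Tuple[int, int] = (20, 30),
    background: float = 5.0,
    groups: Optional[Sequence[str]] = None,
) -> Tuple[GelImage, List[Rectangle]]:
    """Synthesize a gel image with bands of known mean intensity.

    Each lane gets one rectangular band whose interior intensity is exactly
    ``lane_means[i]`` plus Gaussian camera noise; the rest of the image sits
    at ``background``. Quantifying the returned rectangles recovers
    ``lane_means`` to within ~3 * noise_sd / sqrt(band area).
    """
    lane_means = np.asarray(lane_means, dtype=float)
    if np.any(lane_means < 0):
        raise ParameterDomainError("lane means must be >= 0")
    n_lanes = lane_means.size
    h, w = shape
    bh, bw = band_shape
    if n_lanes * bw > w:
        raise ParameterDomainError(
            f"{n_lanes} lanes of width {bw} do not fit in image width {w}"
        )
    rng = np.random.default_rng(rng_seed)
    img = np.full(shape, background)
    gap = (w - n_lanes * bw) // (n_lanes + 1)
    row0 = (h - bh) // 2
    rects = []
    for i, mean in enumerate(lane_means):
        col0 = gap + i * (bw + gap)
        img[row0 : row0 + bh, col0 : col0 + bw] = mean
        rects.append(Rectangle(row_start=row0, col_start=col0, height=bh, width=bw))
    if noise_sd > 0:
        img = img + noise_sd * rng.standard_normal(shape)
    img = np.clip(img, 0.0, None)
    return GelImage(img, lane_annotations=tuple(groups) if groups else None), rects


# --- Presets ---------------------------------------------------------------
# Plausible emulations of the study's pilot-table *structure* (sampler mix,
# sample sizes, yield scale). Parameters are stated choices, not the study's
# measurements.

YIELD_PRESETS: Dict[str, Dict[str, YieldGenSpec]] = {
    # 6 + 6 one-sheet sessions: filter sampler vs cyclonic sampler, sub-ng yields
    "sheetA-like": {
        "MD8": YieldGenSpec(
            cp=MomentSummary(0.26, 0.05, 0.5, 0.5),
            n_sessions=6, n_sheets=1, sampler_label="MD8", rng_seed=101,
        ),
        "Coriolis": YieldGenSpec(
            cp=MomentSummary(0.11, 0.06, 0.5, 0.5),
            n_sessions=6, n_sheets=1, sampler_label="Coriolis", rng_seed=102,
        ),
    },
    # 41 one-sheet training sessions for the effort estimator
    "sheetB-like": {
        "MD8": YieldGenSpec(
            cp=MomentSummary(0.20, 0.12, 1.2, 2.5),
            n_sessions=41, n_sheets=1, sampler_label="MD8", rng_seed=103,
        ),
    },
    # 48 + 48 indoor sessions: 27-sheet fan sampler vs one-sheet filter sampler
    "sheetC-like": {
        "AirDNA": YieldGenSpec(
            cp=MomentSummary(18.0, 12.0, 1.5, 4.0),
            n_sessions=48, n_sheets=27, sampler_label="AirDNA", rng_seed=104,
        ),
        "MD8": YieldGenSpec(
            cp=MomentSummary(0.20, 0.12, 1.2, 2.5),
            n_sessions=48, n_sheets=1, sampler_label="MD8", rng_seed=105,
        ),
    },
    # 16 + 16 outdoor sessions; outdoors is richer in biomass
    "sheetD-like": {
        "AirDNA": YieldGenSpec(
            cp=MomentSummary(30.0, 16.0, 1.2, 3.0),
            n_sessions=16, n_sheets=27, sampler_label="AirDNA",
            location="outdoor", rng_seed=106,
        ),
        "MD8": YieldGenSpec(
            cp=MomentSummary(0.9, 0.5, 1.2, 2.5),
            n_sessions=16, n_sheets=1, sampler_label="MD8",
            location="outdoor", rng_seed=107,
        ),
    },
}

AIR_PRESETS: Dict[str, AirGenSpec] = {
    # 66 sessions with the planted fine-PM signal
    "sheetE-like": AirGenSpec(n_records=66, rng_seed=108),
}


def yield_preset(name: str, *, rng_seed: Optional[int] = None) -> Dict[str, YieldGenSpec]:
    """Named yield-table preset; optional seed override (offset per sampler)."""
    from dataclasses import replace

    if name not in YIELD_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(YIELD_PRESETS)}")
    specs = YIELD_PRESETS[name]
    if rng_seed is None:
        return dict(specs)
    return {
        label: replace(s, rng_seed=rng_seed + i) for i, (label, s) in enumerate(specs.items())
    }


def air_preset(name: str, *, rng_seed: Optional[int] = None) -> AirGenSpec:
    from dataclasses import replace

    if name not in AIR_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(AIR_PRESETS)}")
    spec = AIR_PRESETS[name]
    return spec if rng_seed is None else replace(spec, rng_seed=rng_seed)
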