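"""Discriminating yield-sufficient sampling sessions from air quality.

Sessions are labelled *sufficient* when their DNA yield reaches the
metabarcoding threshold (default 10 ng, inclusive). Ten air-quality
covariates — six particulate-matter size bins (PM0.3 … PM10), ambient
temperature (AT), relative humidity (RH), dew point (DP) and wet-bulb
temperature (WB) — are standardized (centred, unit sd) and a Fisher linear
discriminant ``w ∝ S_pooled^{-1} (mean_suff - mean_insuff)`` is fitted.

Variable importance follows the model-free filter convention: each
covariate's own ROC AUC against the label, folded as ``max(AUC, 1 - AUC)``
and rescaled 0–100 across variables. The model's discriminating power is
reported as the ROC AUC of the discriminant scores (resubstitution, 5-fold
CV or leave-one-out). Hour strata (H1/H2/H3) fit independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .exceptions import DegenerateLabelsError, DegenerateSampleError, SchemaError

__all__ = [
    "AIR_VARIABLES",
    "LdaModel",
    "ImportanceReport",
    "label_sufficiency",
    "fit_lda",
    "roc_auc",
    "variable_importance",
    "AirQualityLDA",
    "LDAResults",
]

AIR_VARIABLES = [
    "pm_0_3", "pm_0_5", "pm_1_0", "pm_2_5", "pm_5_0", "pm_10",
    "at", "rh", "dp", "wb",
]

_RIDGE = 1e-8


@dataclass(frozen=True)
class LdaModel:
    """Fitted Fisher LDA in standardized covariate space."""

    variable_names: tuple
    centers: np.ndarray
    scales: np.ndarray
    class_means: tuple  # (insufficient, sufficient), standardized space
    w: np.ndarray
    priors: tuple
    decision_threshold: float

    def standardize(self, X) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.centers) / self.scales

    def scores(self, X) -> np.ndarray:
        """Discriminant scores; higher means more likely sufficient."""
        return self.standardize(X) @ self.w

    def predict(self, X) -> np.ndarray:
        return (self.scores(X) >= self.decision_threshold).astype(int)


@dataclass(frozen=True)
class ImportanceReport:
    """Per-variable folded ROC AUCs and 0–100 scaled importances."""

    variable_names: tuple
    raw_auc: Dict[str, float]
    importance: Dict[str, float]
    model_auc: Optional[float] = None
    hour_index: Optional[str] = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": list(self.variable_names),
                "hour": self.hour_index,
                "raw_auc": [self.raw_auc[v] for v in self.variable_names],
                "importance": [self.importance[v] for v in self.variable_names],
            }
        )


def label_sufficiency(records, threshold_ng: float = 10.0) -> np.ndarray:
    """Binary labels: 1 where yield >= threshold (inclusive boundary)."""
    if isinstance(records, pd.DataFrame):
        if "yield_ng" not in records.columns:
            raise SchemaError("missing required field 'yield_ng'")
        y = records["yield_ng"].to_numpy(dtype=float)
    else:
        y = np.asarray(records, dtype=float)
    labels = (y >= threshold_ng).astype(int)
    if labels.min() == labels.max():
        warnings.warn(
            f"all sessions on one side of the {threshold_ng} ng threshold: "
            "single-class label set",
            stacklevel=2,
        )
    return labels


def _check_two_classes(labels: np.ndarray, min_per_class: int = 1) -> None:
    vals, counts = np.unique(labels, return_counts=True)
    if vals.size != 2:
        raise DegenerateLabelsError(
            f"need exactly 2 classes, got {vals.size} ({vals.tolist()})"
        )
    if counts.min() < min_per_class:
        raise DegenerateLabelsError(
            f"each class needs >= {min_per_class} members, got counts {counts.tolist()}"
        )


def _solve_discriminant(pooled_cov: np.ndarray, dmu: np.ndarray) -> np.ndarray:
    """w = S^{-1} dmu, ridging the diagonal if S is singular."""
    try:
        return np.linalg.solve(pooled_cov, dmu)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; applying ridge regularisation")
        return np.linalg.solve(pooled_cov + _RIDGE * np.eye(len(dmu)), dmu)


def fit_lda(covariates, labels, variable_names: Optional[Sequence[str]] = None) -> LdaModel:
    """Standardize covariates and fit the two-class Fisher discriminant."""
    if isinstance(covariates, pd.DataFrame):
        variable_names = variable_names or list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        variable_names = variable_names or [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(labels).astype(int)
    _check_two_classes(y, min_per_class=2)

    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    if np.any(scales == 0):
        bad = [variable_names[j] for j in np.flatnonzero(scales == 0)]
        raise DegenerateSampleError(f"constant column(s) after standardisation: {bad}")
    Z = (X - centers) / scales

    z0, z1 = Z[y == 0], Z[y == 1]
    m0, m1 = z0.mean(axis=0), z1.mean(axis=0)
    n0, n1 = len(z0), len(z1)
    pooled = ((n0 - 1) * np.cov(z0, rowvar=False) + (n1 - 1) * np.cov(z1, rowvar=False)) / (
        n0 + n1 - 2
    )
    pooled = np.atleast_2d(pooled)
    w = _solve_discriminant(pooled, m1 - m0)
    threshold = 0.5 * float((m0 + m1) @ w)
    return LdaModel(
        variable_names=tuple(variable_names),
        centers=centers,
        scales=scales,
        class_means=(m0, m1),
        w=w,
        priors=(0.5, 0.5),
        decision_threshold=threshold,
    )


def roc_auc(scores, labels) -> float:
    """ROC AUC in the Mann-Whitney formulation, ties counted half.

    Equals P(score_pos > score_neg) + 0.5 * P(score_pos = score_neg) over all
    positive-negative pairs.
    """
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def variable_importance(
    covariates,
    labels,
    variable_names: Optional[Sequence[str]] = None,
    *,
    model_auc: Optional[float] = None,
    hour_index: Optional[str] = None,
) -> ImportanceReport:
    """Filter-style importance: per-variable folded ROC AUC scaled 0–100."""
    if isinstance(covariates, pd.DataFrame):
        variable_names = variable_names or list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        variable_names = variable_names or [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(labels).astype(int)
    _check_two_classes(y, min_per_class=2)

    folded = {}
    for j, name in enumerate(variable_names):
        a = roc_auc(X[:, j], y)
        folded[name] = max(a, 1.0 - a)
    vals = np.array(list(folded.values()))
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        warnings.warn("all variables equally discriminative; importance set to 100")
        scaled = {name: 100.0 for name in folded}
    else:
        scaled = {name: 100.0 * (v - lo) / (hi - lo) for name, v in folded.items()}
    return ImportanceReport(
        variable_names=tuple(variable_names),
        raw_auc=folded,
        importance=scaled,
        model_auc=model_auc,
        hour_index=hour_index,
    )


class AirQualityLDA:
    """Statsmodels-style LDA of yield sufficiency on air-quality covariates.

    Parameters
    ----------
    covariates : DataFrame or 2-D array of air-quality variables.
    yields_or_labels : per-session DNA yields (ng) or binary labels.
    threshold_ng : sufficiency threshold applied when yields are given.
    """

    def __init__(self, covariates, yields_or_labels, *, threshold_ng: float = 10.0,
                 variable_names: Optional[Sequence[str]] = None):
        if isinstance(covariates, pd.DataFrame):
            self.variable_names = list(variable_names or covariates.columns)
            self.exog = covariates[self.variable_names].to_numpy(dtype=float)
        else:
            self.exog = np.asarray(covariates, dtype=float)
            self.variable_names = list(
                variable_names or [f"x{j}" for j in range(self.exog.shape[1])]
            )
        yv = np.asarray(yields_or_labels, dtype=float)
        if set(np.unique(yv)) <= {0.0, 1.0}:
            self.labels = yv.astype(int)
        else:
            self.labels = label_sufficiency(yv, threshold_ng)
        self.threshold_ng = threshold_ng

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, threshold_ng: float = 10.0,
                       variable_names: Optional[Sequence[str]] = None):
        """Build from a table with covariate columns plus ``yield_ng``.

        Rows with missing covariates or yield are dropped (count warned).
        """
        names = list(variable_names or [v for v in AIR_VARIABLES if v in df.columns])
        missing = [c for c in names + ["yield_ng"] if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        sub = df[names + ["yield_ng"]]
        kept = sub.dropna()
        if len(kept) < len(sub):
            warnings.warn(f"dropped {len(sub) - len(kept)} row(s) with missing values")
        return cls(kept[names], kept["yield_ng"].to_numpy(), threshold_ng=threshold_ng,
                   variable_names=names)

    @classmethod
    def fit_by_hour(cls, df: pd.DataFrame, *, threshold_ng: float = 10.0,
                    **fit_kw) -> Dict[str, "LDAResults"]:
        """Fit one model per hour_index stratum (H1/H2/H3), independently."""
        if "hour_index" not in df.columns:
            raise SchemaError("missing required column(s): ['hour_index']")
        out = {}
        for hour, grp in df.groupby("hour_index", sort=True):
            model = cls.from_dataframe(grp.drop(columns=["hour_index"]),
                                       threshold_ng=threshold_ng)
            out[str(hour)] = model.fit(hour_index=str(hour), **fit_kw)
        return out

    def fit(self, *, hour_index: Optional[str] = None) -> "LDAResults":
        model = fit_lda(self.exog, self.labels, self.variable_names)
        return LDAResults(self, model, hour_index=hour_index)


class LDAResults:
    """Fitted discriminant, importance report and AUC diagnostics."""

    def __init__(self, model: AirQualityLDA, lda: LdaModel, hour_index=None):
        self.model = model
        self.lda = lda
        self.hour_index = hour_index
        self.nobs = len(model.labels)

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.lda.w, index=self.model.variable_names)

    def auc(self, scheme: str = "resubstitution", seed: int = 0) -> float:
        """Model ROC AUC under resubstitution, 5-fold CV or leave-one-out."""
        X, y = self.model.exog, self.model.labels
        if scheme == "resubstitution":
            return roc_auc(self.lda.scores(X), y)
        if scheme == "cv5":
            splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        elif scheme == "loo":
            splitter = LeaveOneOut()
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        scores = np.empty(len(y), dtype=float)
        for train, test in splitter.split(X, y):
            m = fit_lda(X[train], y[train], self.model.variable_names)
            scores[test] = m.scores(X[test])
        return roc_auc(scores, y)

    def importance(self) -> ImportanceReport:
        return variable_importance(
            self.model.exog,
            self.model.labels,
            self.model.variable_names,
            model_auc=self.auc("resubstitution"),
            hour_index=self.hour_index,
        )

    def summary(self) -> str:
        rep = self.importance()
        lines = [
            "Air-quality LDA of yield sufficiency",
            "=" * 52,
            f"n sessions {self.nobs}   sufficient {int(self.model.labels.sum())}"
            f"   threshold {self.model.threshold_ng} ng",
            f"model ROC AUC (resubstitution)  {rep.model_auc:.3f}",
            "-" * 52,
            f"{'variable':<10s}{'w':>10s}{'raw AUC':>10s}{'importance':>12s}",
        ]
        for j, name in enumerate(self.model.variable_names):
            lines.append(
                f"{name:<10s}{self.lda.w[j]:>10.3f}{rep.raw_auc[name]:>10.3f}"
                f"{rep.importance[name]:>12.1f}"
            )
        return "\n".join(lines)
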