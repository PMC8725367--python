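"""The 0-100 disability metric and environment-adjusted performance.

Logit abilities are linearly transformed to a user-friendly 0 (lowest
disability) to 100 (highest disability) range.  Performance scores are then
adjusted with a random-forest regression of performance on capacity plus
environmental factors, so that the final distribution reflects functioning
as shaped by the environment; the adjusted predictions feed the severity
cut-offs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .pcm import ItemParams, estimate_abilities

logger = logging.getLogger("mdsmetrics")

__all__ = [
    "TransformAnchors",
    "AdjustmentResult",
    "to_0_100",
    "from_0_100",
    "anchors_from_items",
    "fit_adjustment",
]


@dataclass(frozen=True)
class TransformAnchors:
    """Logit locations mapped to 0 and 100 on the reporting scale."""

    theta_low: float
    theta_high: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta_low) and np.isfinite(self.theta_high)):
            raise ValueError("anchors must be finite")
        if self.theta_low >= self.theta_high:
            raise ValueError("theta_low must be below theta_high")


def to_0_100(theta, anchors: TransformAnchors):
    """Affine map from logits to the 0-100 metric, clipped to the range."""
    theta = np.asarray(theta, dtype=float)
    s = 100.0 * (theta - anchors.theta_low) / (anchors.theta_high - anchors.theta_low)
    out = np.clip(s, 0.0, 100.0)
    return float(out) if out.ndim == 0 else out


def from_0_100(score, anchors: TransformAnchors):
    """Inverse of :func:`to_0_100` on the open anchor interval."""
    score = np.asarray(score, dtype=float)
    th = anchors.theta_low + (score / 100.0) * (anchors.theta_high - anchors.theta_low)
    return float(th) if th.ndim == 0 else th


def anchors_from_items(items: Sequence[ItemParams]) -> TransformAnchors:
    """Anchor 0 and 100 at the abilities of the minimum and maximum raw score.

    Uses the weighted-likelihood (finite) estimates for a zero and a perfect
    raw score on the full calibrated bank, so the endpoints are attainable
    and depend only on the item bank, not on the sample at hand.
    """
    full = pd.DataFrame(
        {it.name: [0.0, float(it.n_categories - 1)] for it in items},
        index=["_zero", "_max"],
    )
    # strip category maps: anchors are defined on the fitted coding
    plain = [
        ItemParams(name=it.name, difficulty=it.difficulty, thresholds=it.thresholds.copy())
        for it in items
    ]
    est = estimate_abilities(full, plain)
    return TransformAnchors(
        theta_low=float(est.loc["_zero", "theta"]),
        theta_high=float(est.loc["_max", "theta"]),
    )


# ---------------------------------------------------------------------------
# Random-forest adjustment
# ---------------------------------------------------------------------------

@dataclass
class AdjustmentResult:
    scores: pd.DataFrame        # capacity_score, raw_performance_score, adjusted_performance_score
    oob_r2: float               # out-of-bag R^2 of the full model
    oob_r2_capacity_only: float # out-of-bag R^2 of the nested capacity-only model
    feature_names: list
    settings: dict


def _encode_env(env: pd.DataFrame) -> pd.DataFrame:
    """Ordinal covariates enter as integers, categoricals as one-of-K."""
    cols = []
    for c in env.columns:
        s = env[c]
        if s.dtype.kind in "biufc":
            cols.append(s.astype(float))
        else:
            cols.append(pd.get_dummies(s, prefix=c, dtype=float))
    return pd.concat(cols, axis=1)


def fit_adjustment(
    performance: pd.Series,
    capacity: pd.Series,
    env: pd.DataFrame,
    *,
    seed: int,
    n_estimators: int = 500,
    min_samples_leaf: int = 5,
    max_features: int | None = None,
    min_persons: int = 100,
    score_bounds: tuple[float, float] = (0.0, 100.0),
) -> AdjustmentResult:
    """Adjust performance for environment with a random-forest regression.

    Performance (0-100) is regressed on capacity (0-100) and the
    environmental covariates; the model's predictions are the adjusted
    performance scores.  A nested capacity-only forest is fitted with the
    same settings so the environmental contribution is visible as the gain
    in out-of-bag R^2.  Output is deterministic for a fixed seed.
    """
    if env.shape[1] < 1:
        raise ValueError("at least one environmental covariate is required")
    idx = performance.index.intersection(capacity.index).intersection(env.index)
    n = len(idx)
    if n < min_persons:
        raise ValueError(
            f"adjustment refused: {n} persons < configured minimum {min_persons}"
        )
    y = performance.loc[idx].to_numpy(dtype=float)
    Xenv = _encode_env(env.loc[idx])
    X = pd.concat([capacity.loc[idx].rename("capacity_score"), Xenv], axis=1)
    p = X.shape[1]
    mf = max_features if max_features is not None else max(1, math.ceil(p / 3))

    def _forest(features: pd.DataFrame, mfeat: int) -> RandomForestRegressor:
        rf = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features=mfeat,
            min_samples_leaf=min_samples_leaf,
            oob_score=True,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
        rf.fit(features.to_numpy(), y)
        return rf

    rf_full = _forest(X, mf)
    rf_cap = _forest(X[["capacity_score"]], 1)

    adjusted = np.clip(rf_full.predict(X.to_numpy()), *score_bounds)
    scores = pd.DataFrame(
        {
            "capacity_score": capacity.loc[idx],
            "raw_performance_score": performance.loc[idx],
            "adjusted_performance_score": adjusted,
        },
        index=idx,
    )
    return AdjustmentResult(
        scores=scores,
        oob_r2=float(rf_full.oob_score_),
        oob_r2_capacity_only=float(rf_cap.oob_score_),
        feature_names=list(X.columns),
        settings={
            "n_estimators": n_estimators,
            "max_features": mf,
            "min_samples_leaf": min_samples_leaf,
            "seed": seed,
        },
    )
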