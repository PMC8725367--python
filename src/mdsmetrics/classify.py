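"""Severity classification and disaggregation on the adjusted 0-100 metric.

WHO's suggested cut-offs are distribution-based: with M the sample mean and
S one standard deviation of the adjusted performance score,

    no        score < M - S, or score = 0
    mild      M - S  < score < M
    moderate  M      < score < M + S
    severe    score >= M + S

A score of exactly zero is always "no disability" regardless of the
cut-offs.  The published rules use strict inequalities at the two interior
boundaries; here a score exactly on a boundary joins the higher-severity
side (consistent with the ">=" that defines severe), which is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("mdsmetrics")

__all__ = [
    "LEVELS",
    "CutoffSet",
    "derive_cutoffs",
    "classify",
    "prevalence",
    "disaggregate",
    "distribution_histogram",
    "plot_distribution",
]

LEVELS = ["no", "mild", "moderate", "severe"]


@dataclass(frozen=True)
class CutoffSet:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mean) and np.isfinite(self.sd)):
            raise ValueError("cutoff mean and sd must be finite")
        if self.sd <= 0:
            raise ValueError("cutoff sd must be positive")

    @property
    def lower(self) -> float:
        return self.mean - self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.sd

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "lower": self.lower, "upper": self.upper}


def derive_cutoffs(scores, weights=None) -> CutoffSet:
    """Sample mean +/- 1 SD cut-offs from adjusted performance scores.

    Unweighted: SD uses the n-1 divisor.  Weighted: weighted mean and
    population-style weighted SD (weights normalised to sum 1); the
    convention is recorded in the output metadata of the pipeline.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if np.unique(x).size < 2:
        raise ValueError("cut-offs undefined: need at least 2 distinct scores")
    if weights is None:
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != np.asarray(scores, dtype=float).shape or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative, same length, positive sum")
        w = w / w.sum()
        xs = np.asarray(scores, dtype=float)
        mean = float(np.sum(w * xs))
        sd = float(np.sqrt(np.sum(w * (xs - mean) ** 2)))
    if sd <= 0:
        raise ValueError("cut-offs undefined: zero score dispersion")
    return CutoffSet(mean=mean, sd=sd)


def classify(scores, cutoffs: CutoffSet, *, boundary_side: str = "higher") -> pd.DataFrame:
    """Assign each 0-100 score to a severity level.

    ``boundary_side='higher'`` (default) sends a score exactly at M-S to
    mild and exactly at M to moderate; ``'lower'`` sends them to the less
    severe side.  Severe is always ``score >= M + S``; a score of 0 is
    always "no".
    """
    s = pd.Series(scores, dtype=float)
    x = s.to_numpy()
    if np.any(~np.isfinite(x)) or np.any(x < 0) or np.any(x > 100):
        raise ValueError("scores must lie in [0, 100]")
    if boundary_side not in {"higher", "lower"}:
        raise ValueError("boundary_side must be 'higher' or 'lower'")
    lo, mid, hi = cutoffs.lower, cutoffs.mean, cutoffs.upper
    level = np.empty(x.size, dtype=object)
    if boundary_side == "higher":
        level[x < lo] = "no"
        level[(x >= lo) & (x < mid)] = "mild"
        level[(x >= mid) & (x < hi)] = "moderate"
    else:
        level[x <= lo] = "no"
        level[(x > lo) & (x <= mid)] = "mild"
        level[(x > mid) & (x < hi)] = "moderate"
    level[x >= hi] = "severe"
    level[x == 0.0] = "no"
    out = pd.DataFrame(
        {
            "adjusted_performance_score": x,
            "level": pd.Categorical(level, categories=LEVELS, ordered=True),
        },
        index=s.index,
    )
    return out


def prevalence(records: pd.DataFrame, weights=None) -> pd.Series:
    """Proportion of persons at each severity level (sums to 1)."""
    lv = records["level"]
    if weights is None:
        out = lv.value_counts(normalize=True).reindex(LEVELS).fillna(0.0)
    else:
        w = pd.Series(np.asarray(weights, dtype=float), index=records.index)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        out = w.groupby(lv, observed=False).sum().reindex(LEVELS).fillna(0.0) / w.sum()
    out.name = "prevalence"
    out.index.name = "level"
    return out.astype(float)


def disaggregate(
    indicator: pd.Series,
    records: pd.DataFrame,
    *,
    min_n: int = 30,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Per-severity-level summary of a survey indicator with normal CIs.

    For a binary indicator the estimate is the proportion; for a numeric
    indicator the mean.  Levels with fewer than ``min_n`` observations are
    flagged as low-count; empty levels get no estimate.
    """
    from scipy.stats import norm

    ind = indicator.loc[indicator.index.intersection(records.index)].astype(float)
    z = norm.ppf(0.5 + conf_level / 2)
    rows = []
    for lev in LEVELS:
        vals = ind.loc[records.index[records["level"] == lev]].dropna()
        n = int(vals.size)
        if n == 0:
            rows.append((lev, 0, np.nan, np.nan, np.nan, True))
            continue
        est = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append((lev, n, est, est - z * se, est + z * se, n < min_n))
    out = pd.DataFrame(
        rows, columns=["level", "n", "estimate", "ci_low", "ci_high", "low_count"]
    ).set_index("level")
    return out


def distribution_histogram(
    scores, cutoffs: CutoffSet, bin_width: float = 5.0
) -> tuple[pd.DataFrame, dict]:
    """Bin the adjusted scores over [0, 100] and locate the cut-off lines.

    Bins tile [0, 100]; the last bin includes 100 so frequencies sum to the
    number of scores.  Returns (bins DataFrame, cut-off positions for the
    three severity boundaries).
    """
    x = np.asarray(scores, dtype=float)
    if bin_width <= 0 or bin_width > 100:
        raise ValueError("bin_width must lie in (0, 100]")
    n_bins = int(np.ceil(100.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 100.0)
    counts, _ = np.histogram(x, bins=edges)
    hist = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts.astype(int)}
    )
    lines = {"lower": cutoffs.lower, "mean": cutoffs.mean, "upper": cutoffs.upper}
    return hist, lines


def plot_distribution(hist: pd.DataFrame, lines: dict, path=None):
    """Bar plot of the score distribution with dashed severity cut-off lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    widths = hist["bin_end"] - hist["bin_start"]
    ax.bar(hist["bin_start"], hist["count"], width=widths, align="edge",
           color="#4878a8", edgecolor="white")
    for name, xpos in lines.items():
        ax.axvline(xpos, linestyle="--", color="black", linewidth=1)
    ax.set_xlabel("Adjusted performance score (0 = no problems, 100 = severe problems)")
    ax.set_ylabel("Frequency")
    ax.set_xlim(0, 100)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
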