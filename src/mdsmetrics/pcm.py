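"""Partial credit model (polytomous Rasch) calibration and person measurement.

The partial credit model (PCM) locates persons and item response categories
on a common logit continuum.  For an item with ordered categories
``0 … m`` and step parameters ``b_1 … b_m`` (``b_k = delta + tau_k``, the
item difficulty plus the k-th centred threshold), the probability that a
person with ability ``theta`` responds in category ``x`` is

    P(x | theta) = exp( sum_{k<=x} (theta - b_k) ) / sum_h exp( sum_{k<=h} (theta - b_k) )

with the empty sum equal to zero.  Each threshold ``delta + tau_k`` is the
latent location at which categories ``k-1`` and ``k`` are equally likely.

Estimation is a two-stage scheme: item step parameters by alternating joint
maximum likelihood (persons profiled out iteratively, extreme scorers
excluded), with the standard ``(K-1)/K`` correction applied to the centred
item parameters to remove the leading JML bias; person abilities afterwards
by Warm's weighted likelihood (WLE), which yields finite estimates for
zero and perfect raw scores.  Higher ability means higher disability on the
MDS scales, so functioning well maps to negative logits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

logger = logging.getLogger("mdsmetrics")

__all__ = [
    "ItemParams",
    "PCMFit",
    "ConvergenceReport",
    "category_probabilities",
    "fit_pcm",
    "estimate_abilities",
]


# ---------------------------------------------------------------------------
# Item parameters
# ---------------------------------------------------------------------------

@dataclass
class ItemParams:
    """Calibration of a single polytomous item.

    ``difficulty`` is the item location delta (logits); ``thresholds`` are
    the centred category thresholds tau_k (sum to zero), so the absolute
    threshold locations are ``difficulty + thresholds``.
    """

    name: str
    difficulty: float
    thresholds: np.ndarray
    se_difficulty: float = float("nan")
    se_thresholds: np.ndarray | None = None
    category_map: dict[int, int] | None = None  # original code -> fitted code

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.ndim != 1 or self.thresholds.size < 1:
            raise ValueError(f"item {self.name!r}: thresholds must be a 1-d vector")
        if not np.all(np.isfinite(self.thresholds)):
            raise ValueError(f"item {self.name!r}: thresholds must be finite")
        if self.se_thresholds is not None:
            self.se_thresholds = np.asarray(self.se_thresholds, dtype=float)

    @property
    def n_categories(self) -> int:
        return self.thresholds.size + 1

    @property
    def steps(self) -> np.ndarray:
        """Absolute step locations delta + tau_k, k = 1..m."""
        return self.difficulty + self.thresholds

    @classmethod
    def from_steps(cls, name: str, steps: np.ndarray, **kw) -> "ItemParams":
        steps = np.asarray(steps, dtype=float)
        delta = float(steps.mean())
        return cls(name=name, difficulty=delta, thresholds=steps - delta, **kw)

    def to_dict(self) -> dict:
        d = {
            "item": self.name,
            "difficulty": float(self.difficulty),
            "thresholds": [float(t) for t in self.thresholds],
            "se_difficulty": float(self.se_difficulty),
            "se_thresholds": (
                None if self.se_thresholds is None else [float(s) for s in self.se_thresholds]
            ),
        }
        if self.category_map is not None:
            d["category_map"] = {str(k): int(v) for k, v in self.category_map.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ItemParams":
        cmap = d.get("category_map")
        return cls(
            name=d["item"],
            difficulty=float(d["difficulty"]),
            thresholds=np.asarray(d["thresholds"], dtype=float),
            se_difficulty=float(d.get("se_difficulty", float("nan"))),
            se_thresholds=(
                None if d.get("se_thresholds") is None
                else np.asarray(d["se_thresholds"], dtype=float)
            ),
            category_map=None if cmap is None else {int(k): int(v) for k, v in cmap.items()},
        )


# ---------------------------------------------------------------------------
# Closed-form category probabilities and moments
# ---------------------------------------------------------------------------

def pcm_probabilities(theta: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Category probabilities for an array of abilities.

    Parameters
    ----------
    theta : (T,) array of abilities in logits.
    steps : (m,) absolute step parameters of one item.

    Returns
    -------
    (T, m+1) array of probabilities over categories 0..m, rows summing to 1.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    steps = np.asarray(steps, dtype=float)
    z = theta[:, None] - steps[None, :]                       # (T, m)
    cum = np.concatenate([np.zeros((theta.size, 1)), np.cumsum(z, axis=1)], axis=1)
    cum -= cum.max(axis=1, keepdims=True)                     # overflow guard
    p = np.exp(cum)
    p /= p.sum(axis=1, keepdims=True)
    return p


def category_probabilities(theta: float, item: ItemParams) -> np.ndarray:
    """PCM probability vector over categories 0..m at a single ability.

    Raises ``ValueError`` for non-finite theta.
    """
    theta = float(theta)
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    return pcm_probabilities(np.array([theta]), item.steps)[0]


def _moments(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean, variance, and third/fourth central moments of the category score."""
    m1 = p.shape[1] - 1
    x = np.arange(m1 + 1, dtype=float)
    mean = p @ x
    d = x[None, :] - mean[:, None]
    var = np.einsum("tc,tc->t", p, d**2)
    mu3 = np.einsum("tc,tc->t", p, d**3)
    mu4 = np.einsum("tc,tc->t", p, d**4)
    return mean, var, mu3, mu4


# ---------------------------------------------------------------------------
# Response-matrix preparation
# ---------------------------------------------------------------------------

def _validate_matrix(data: pd.DataFrame) -> np.ndarray:
    if not isinstance(data, pd.DataFrame):
        raise TypeError("response matrix must be a pandas DataFrame (persons x items)")
    if data.shape[1] < 2:
        raise ValueError("response matrix needs at least 2 items")
    X = data.to_numpy(dtype=float, copy=True)
    obs = ~np.isnan(X)
    vals = X[obs]
    if vals.size == 0:
        raise ValueError("response matrix contains no observed responses")
    if np.any(vals < 0) or np.any(vals != np.round(vals)):
        raise ValueError("responses must be non-negative integer category codes (or missing)")
    if int((obs.any(axis=1)).sum()) < 2:
        raise ValueError("response matrix needs at least 2 persons with data")
    return X


def _collapse_categories(X: np.ndarray, names: Sequence[str]):
    """Recode each item to consecutive observed categories 0..m'.

    Unobserved (null) categories are collapsed out; the original-to-fitted
    index map is retained.  Items with fewer than 2 observed categories are
    excluded.  Returns (X recoded, kept column indices, m per kept item,
    category maps, warnings list).
    """
    kept, m_list, maps, warns = [], [], [], []
    Xr = X.copy()
    for j, name in enumerate(names):
        col = X[:, j]
        obs = np.unique(col[~np.isnan(col)]).astype(int)
        if obs.size < 2:
            warns.append(f"item {name!r} excluded: fewer than 2 observed categories")
            logger.warning(warns[-1])
            continue
        cmap = {int(orig): k for k, orig in enumerate(obs)}
        if obs.size != obs.max() + 1 or obs.min() != 0:
            warns.append(
                f"item {name!r}: null categories collapsed, map {cmap}"
            )
            logger.warning(warns[-1])
        lut = np.full(obs.max() + 1, -1.0)
        lut[obs] = np.arange(obs.size, dtype=float)
        mask = ~np.isnan(col)
        Xr[mask, j] = lut[col[mask].astype(int)]
        kept.append(j)
        m_list.append(obs.size - 1)
        maps.append(cmap if len(cmap) != obs.size or obs.min() != 0 or obs.size != obs.max() + 1 else None)
    if len(kept) < 2:
        raise ValueError("fewer than 2 estimable items after screening")
    return Xr[:, kept], kept, np.array(m_list), maps, warns


def _group_persons(mask: np.ndarray, score: np.ndarray):
    """Group persons by (answered-item set, raw score); theta is a function
    of that pair only (raw-score sufficiency on a fixed item set)."""
    keys = {}
    g_of = np.empty(mask.shape[0], dtype=int)
    gmask, gscore = [], []
    for i in range(mask.shape[0]):
        key = (mask[i].tobytes(), int(score[i]))
        g = keys.get(key)
        if g is None:
            g = len(keys)
            keys[key] = g
            gmask.append(mask[i])
            gscore.append(score[i])
        g_of[i] = g
    return g_of, np.asarray(gmask), np.asarray(gscore, dtype=float)


# ---------------------------------------------------------------------------
# JML item estimation
# ---------------------------------------------------------------------------

def _expected_and_var(theta_g: np.ndarray, steps_list, gmask: np.ndarray):
    """Summed expected score and variance over each group's answered items."""
    G = theta_g.size
    E = np.zeros(G)
    V = np.zeros(G)
    for j, b in enumerate(steps_list):
        rows = gmask[:, j]
        if not rows.any():
            continue
        p = pcm_probabilities(theta_g[rows], b)
        mean, var, _, _ = _moments(p)
        E[rows] += mean
        V[rows] += var
    return E, V


def _solve_theta_ml(theta_g, gscore, gmask, steps_list, tol=1e-10, max_iter=100):
    """Vectorised damped Newton for per-group ML abilities (non-extreme)."""
    theta = theta_g.copy()
    for _ in range(max_iter):
        E, V = _expected_and_var(theta, steps_list, gmask)
        f = gscore - E
        step = np.clip(f / np.maximum(V, 1e-12), -1.0, 1.0)
        theta += step
        if np.max(np.abs(step)) < tol:
            break
    return theta


def _solve_theta_wle(theta_g, gscore, gmask, steps_list, tol=1e-10, max_iter=100):
    """Vectorised damped Newton for per-group Warm-weighted abilities."""
    th = theta_g.copy()
    for _ in range(max_iter):
        f, V = _wle_equation(th, gscore, gmask, steps_list)
        step = np.clip(f / np.maximum(V, 1e-12), -1.0, 1.0)
        th += step
        if np.max(np.abs(step)) < tol:
            break
    return th


def _item_counts(Xc, g_of, use_person, m, j):
    """(G x m_j+1) response counts per theta group for one item."""
    valid = use_person & ~np.isnan(Xc[:, j])
    C = np.zeros((g_of.max() + 1, m[j] + 1))
    np.add.at(C, (g_of[valid], Xc[valid, j].astype(int)), 1.0)
    return C


def _item_grad_hess(b, theta, C):
    """Gradient and Hessian of the item log-likelihood in step parameters.

    d logP(x)/d b_k = -1{x>=k} + P(X>=k); the Hessian is minus the covariance
    matrix of the indicator vector (1{X>=k})_k, hence negative definite.
    """
    p = pcm_probabilities(theta, b)                # (T, m+1)
    Pge = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]   # (T, m): P(X>=k), k=1..m
    N = C.sum(axis=1)
    nge = np.cumsum(C[:, ::-1], axis=1)[:, ::-1][:, 1:]   # observed counts >= k
    grad = (-nge + N[:, None] * Pge).sum(axis=0)
    m_ = b.size
    kk = np.maximum(np.arange(m_)[:, None], np.arange(m_)[None, :])
    # E[1{X>=k}1{X>=l}] = P(X>=max(k,l))
    H = -np.einsum("t,tkl->kl", N, Pge[:, kk] - Pge[:, :, None] * Pge[:, None, :])
    ll = float(np.sum(C * np.log(np.maximum(p, 1e-300))))
    return grad, H, ll


def _update_item(b, theta_g, C, tol=1e-10, max_iter=60):
    """Newton maximisation of one item's likelihood given group abilities."""
    rows = C.sum(axis=1) > 0
    th, Cs = theta_g[rows], C[rows]
    b = b.copy()
    for _ in range(max_iter):
        grad, H, _ = _item_grad_hess(b, th, Cs)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / np.maximum(-np.diag(H), 1e-8)
        nrm = np.max(np.abs(step))
        if nrm > 1.0:
            step *= 1.0 / nrm
        b -= step
        if nrm < tol:
            break
    return b


@dataclass
class ConvergenceReport:
    converged: bool
    n_iterations: int
    max_param_change: float
    final_gradient_norm: float
    loglik_trace: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    n_persons_used: int = 0
    n_extreme: int = 0

    def to_dict(self) -> dict:
        return {
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "max_param_change": float(self.max_param_change),
            "final_gradient_norm": float(self.final_gradient_norm),
            "loglik_trace": [float(v) for v in self.loglik_trace],
            "warnings": list(self.warnings),
            "n_persons_used": int(self.n_persons_used),
            "n_extreme": int(self.n_extreme),
        }


@dataclass
class PCMFit:
    items: list
    report: ConvergenceReport

    def item(self, name: str) -> ItemParams:
        for it in self.items:
            if it.name == name:
                return it
        raise KeyError(name)

    @property
    def difficulties(self) -> pd.Series:
        return pd.Series({it.name: it.difficulty for it in self.items}, name="difficulty")

    def to_records(self) -> list:
        return [it.to_dict() for it in self.items]


def fit_pcm(
    data: pd.DataFrame,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
    bias_correction: bool = True,
) -> PCMFit:
    """Calibrate item difficulties and thresholds from an ordinal matrix.

    ``data`` is persons x items with integer category codes starting at 0
    and NaN for missing.  Missing responses contribute nothing to the
    likelihood (ignorable missingness).  The fitted difficulties are centred
    to mean zero (identification constraint).  Items with a single observed
    category are excluded with a warning; unobserved middle categories are
    collapsed out with the index map kept on the item.
    """
    X = _validate_matrix(data)
    names = [str(c) for c in data.columns]
    Xc, kept, m, maps, warns = _collapse_categories(X, names)
    kept_names = [names[j] for j in kept]
    J = len(kept)

    mask = ~np.isnan(Xc)
    answered = mask.any(axis=1)
    if not answered.all():
        warns.append(f"{int((~answered).sum())} all-missing persons ignored in calibration")
        logger.warning(warns[-1])
    score = np.nansum(Xc, axis=1)
    pmax = mask @ m
    extreme = (score <= 0) | (score >= pmax)
    use = answered & ~extreme
    if use.sum() < 2:
        raise ValueError("fewer than 2 non-extreme persons; cannot calibrate")

    g_of_all, gmask, gscore = _group_persons(mask[use], score[use])
    g_of = np.full(Xc.shape[0], -1, dtype=int)
    g_of[use] = g_of_all

    # initial values: log count ratios for steps, score logit for theta
    steps_list = []
    for j in range(J):
        col = Xc[use, j]
        col = col[~np.isnan(col)]
        cnt = np.bincount(col.astype(int), minlength=m[j] + 1) + 0.5
        steps_list.append(np.log(cnt[:-1] / cnt[1:]))
    gpmax = gmask @ m
    theta_g = np.log((gscore + 0.5) / (gpmax - gscore + 0.5))

    C_list = [_item_counts(Xc, g_of, use, m, j) for j in range(J)]

    trace: list[float] = []
    change = np.inf
    it_count = 0
    for it_count in range(1, max_iter + 1):
        theta_g = _solve_theta_ml(theta_g, gscore, gmask, steps_list, tol=min(tol, 1e-8))
        prev = np.concatenate(steps_list)
        for j in range(J):
            steps_list[j] = _update_item(steps_list[j], theta_g, C_list[j])
        # recentre: mean item difficulty identically zero
        c = float(np.mean([b.mean() for b in steps_list]))
        steps_list = [b - c for b in steps_list]
        theta_g = theta_g - c
        ll = sum(_item_grad_hess(b, theta_g, C)[2] for b, C in zip(steps_list, C_list))
        trace.append(ll)
        change = float(np.max(np.abs(np.concatenate(steps_list) - prev)))
        if change < tol:
            break
    converged = change < tol
    if not converged:
        warns.append(f"JML did not converge in {max_iter} iterations (last change {change:.2e})")
        logger.warning(warns[-1])

    # refinement: re-profile persons with Warm-weighted (rather than plain ML)
    # abilities and let the item parameters settle against them.  This damps
    # the outward threshold bias that plain JML carries before the (K-1)/K
    # correction is applied.
    for _ in range(100):
        theta_g = _solve_theta_wle(theta_g, gscore, gmask, steps_list)
        prev = np.concatenate(steps_list)
        for j in range(J):
            steps_list[j] = _update_item(steps_list[j], theta_g, C_list[j])
        c = float(np.mean([b.mean() for b in steps_list]))
        steps_list = [b - c for b in steps_list]
        theta_g = theta_g - c
        if float(np.max(np.abs(np.concatenate(steps_list) - prev))) < tol:
            break

    grad_norm = 0.0
    for b, C in zip(steps_list, C_list):
        g, _, _ = _item_grad_hess(b, theta_g, C)
        grad_norm = max(grad_norm, float(np.max(np.abs(g))))

    if bias_correction and J > 1:
        shrink = (J - 1) / J
        steps_list = [b * shrink for b in steps_list]
        theta_g = theta_g * shrink
    c = float(np.mean([b.mean() for b in steps_list]))
    steps_list = [b - c for b in steps_list]
    theta_g = theta_g - c

    # standard errors from the per-item observed information at the final
    # ability distribution; delta method for the (difficulty, thresholds)
    # re-parameterisation of the steps
    items: list[ItemParams] = []
    for j in range(J):
        b, C = steps_list[j], C_list[j]
        _, H, _ = _item_grad_hess(b, theta_g, C)
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov = np.full((m[j], m[j]), np.nan)
        mm = m[j]
        A = np.vstack([np.full(mm, 1.0 / mm), np.eye(mm) - 1.0 / mm])
        covp = A @ cov @ A.T
        se = np.sqrt(np.maximum(np.diag(covp), 0.0))
        items.append(
            ItemParams.from_steps(
                kept_names[j],
                b,
                se_difficulty=float(se[0]),
                se_thresholds=se[1:],
                category_map=maps[j],
            )
        )
    # exact sum-zero after rounding noise
    dmean = float(np.mean([it.difficulty for it in items]))
    for it in items:
        it.difficulty -= dmean

    report = ConvergenceReport(
        converged=converged,
        n_iterations=it_count,
        max_param_change=change,
        final_gradient_norm=grad_norm,
        loglik_trace=trace,
        warnings=warns,
        n_persons_used=int(use.sum()),
        n_extreme=int((answered & extreme).sum()),
    )
    return PCMFit(items=items, report=report)


# ---------------------------------------------------------------------------
# Person ability estimation (Warm's weighted likelihood)
# ---------------------------------------------------------------------------

def _wle_equation(theta, gscore, gmask, steps_list):
    """r - sum E_j(theta) + sum mu3_j / (2 sum Var_j): zero at the WLE."""
    G = np.atleast_1d(theta).size
    E = np.zeros(G)
    V = np.zeros(G)
    M3 = np.zeros(G)
    th = np.atleast_1d(theta)
    for j, b in enumerate(steps_list):
        rows = gmask[:, j]
        if not rows.any():
            continue
        p = pcm_probabilities(th[rows], b)
        mean, var, mu3, _ = _moments(p)
        E[rows] += mean
        V[rows] += var
        M3[rows] += mu3
    return gscore - E + M3 / (2.0 * np.maximum(V, 1e-300)), V


def _recode_with_maps(data: pd.DataFrame, items: Sequence[ItemParams]) -> np.ndarray:
    X = data[[it.name for it in items]].to_numpy(dtype=float, copy=True)
    for j, it in enumerate(items):
        if it.category_map:
            col = X[:, j]
            msk = ~np.isnan(col)
            lut = {k: float(v) for k, v in it.category_map.items()}
            X[msk, j] = [lut[int(v)] for v in col[msk]]
    return X


def estimate_abilities(
    data: pd.DataFrame,
    items: Sequence[ItemParams],
    *,
    method: str = "wle",
) -> pd.DataFrame:
    """Estimate each respondent's ability (logits) with its standard error.

    Uses Warm's weighted likelihood by default, giving finite abilities for
    zero and perfect raw scores so every respondent can be placed on the
    0-100 metric and classified.  Persons with no observed responses are
    excluded with a warning.  Returns a DataFrame indexed by person with
    columns raw_score, theta, se, extreme.
    """
    if method not in {"wle", "mle"}:
        raise ValueError("method must be 'wle' or 'mle'")
    missing_items = [it.name for it in items if it.name not in data.columns]
    if missing_items:
        raise ValueError(f"data lacks calibrated items: {missing_items}")
    X = _recode_with_maps(data, items)
    m = np.array([it.n_categories - 1 for it in items])
    mask = ~np.isnan(X)
    answered = mask.any(axis=1)
    if not answered.all():
        logger.warning(
            "%d persons with no observed responses excluded from ability estimation",
            int((~answered).sum()),
        )
    Xu = X[answered]
    masku = mask[answered]
    score = np.nansum(Xu, axis=1)
    pmax = masku @ m
    extreme = (score <= 0) | (score >= pmax)

    g_of, gmask, gscore = _group_persons(masku, score)
    steps_list = [it.steps for it in items]

    gpmax = gmask @ m
    theta_g = np.log((gscore + 0.5) / (gpmax - gscore + 0.5))
    if method == "mle":
        # ML is infinite at extremes; fall back to WLE there
        nonx = (gscore > 0) & (gscore < gpmax)
        theta_g[nonx] = _solve_theta_ml(
            theta_g[nonx], gscore[nonx], gmask[nonx], steps_list
        )
        solve_rows = ~nonx
    else:
        solve_rows = np.ones(theta_g.size, dtype=bool)

    if solve_rows.any():
        idx = np.flatnonzero(solve_rows)
        th = theta_g[idx]
        gm = gmask[idx]
        gs = gscore[idx]
        for _ in range(200):
            f, V = _wle_equation(th, gs, gm, steps_list)
            step = np.clip(f / np.maximum(V, 1e-8), -0.7, 0.7)
            th += step
            if np.max(np.abs(step)) < 1e-10:
                break
        # brentq fallback for any group the damped Newton left unsettled
        f, _ = _wle_equation(th, gs, gm, steps_list)
        span = float(np.abs(np.concatenate(steps_list)).max()) + 15.0
        for t in np.flatnonzero(np.abs(f) > 1e-6):
            fn = lambda x: _wle_equation(
                np.array([x]), gs[t : t + 1], gm[t : t + 1], steps_list
            )[0][0]
            try:
                th[t] = brentq(fn, -span, span, xtol=1e-12)
            except ValueError:
                pass  # keep Newton value; equation has no sign change in span
        theta_g[idx] = th

    _, V = _wle_equation(theta_g, gscore, gmask, steps_list)
    se_g = 1.0 / np.sqrt(np.maximum(V, 1e-300))

    out = pd.DataFrame(
        {
            "raw_score": score.astype(int),
            "theta": theta_g[g_of],
            "se": se_g[g_of],
            "extreme": extreme,
        },
        index=data.index[answered],
    )
    out.index.name = data.index.name or "person"
    return out


def expected_scores(theta: np.ndarray, items: Sequence[ItemParams]) -> np.ndarray:
    """(n_persons, n_items) expected category scores under the PCM."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    out = np.empty((theta.size, len(items)))
    for j, it in enumerate(items):
        out[:, j] = _moments(pcm_probabilities(theta, it.steps))[0]
    return out


def residual_moments(theta: np.ndarray, items: Sequence[ItemParams]):
    """Expected score, variance, and 3rd/4th central moments per person-item."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    J = len(items)
    E = np.empty((theta.size, J))
    V = np.empty_like(E)
    M3 = np.empty_like(E)
    M4 = np.empty_like(E)
    for j, it in enumerate(items):
        E[:, j], V[:, j], M3[:, j], M4[:, j] = _moments(
            pcm_probabilities(theta, it.steps)
        )
    return E, V, M3, M4
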