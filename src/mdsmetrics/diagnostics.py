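"""Psychometric quality evidence for a calibrated scale.

Covers the evidence battery reported for national disability-survey
calibrations: Person Separation Index (PSI) reliability, targeting of the
item bank against the person distribution (the half-logit centering rule),
residual-based item fit, local dependence, residual-PCA dimensionality with
a person-level subset comparison, and differential item functioning (DIF)
by two-way ANOVA of standardized residuals.

All diagnostic cut-offs live in :class:`DiagnosticSettings`, since none of
them is fixed by theory; they are reported alongside results.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.proportion import proportion_confint

from .pcm import ItemParams, residual_moments, estimate_abilities, _recode_with_maps

import logging

logger = logging.getLogger("mdsmetrics")

__all__ = [
    "DiagnosticSettings",
    "TargetingJudgment",
    "ScaleDiagnostics",
    "compute_psi",
    "targeting_summary",
    "centering_judgment",
    "standardized_residuals",
    "item_fit",
    "local_dependence",
    "dimensionality",
    "dif_analysis",
    "diagnose_scale",
]

HALF_LOGIT = 0.5  # the tolerable centering offset, in logits


@dataclass
class DiagnosticSettings:
    """Cut-offs and knobs for the diagnostic battery (all configurable)."""

    fit_flag_threshold: float = 2.5        # |standardized fit residual| above -> misfit
    min_item_observations: int = 20        # fewer -> low-information warning
    local_dependence_margin: float = 0.2   # corr > mean off-diag + margin -> flagged
    dif_n_class_intervals: int = 5         # equal-count ability strata
    dif_alpha: float = 0.05                # before Bonferroni across items
    dim_alpha: float = 0.05                # person-level paired comparison
    dim_accept_proportion: float = 0.05    # unidimensional if CI reaches below this
    min_subset_items: int = 3              # items per loading subset for the test

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

def compute_psi(persons: pd.DataFrame) -> float:
    """Person Separation Index: share of ability variance not due to error.

    PSI = (Var(theta_hat) - mean(se^2)) / Var(theta_hat), floored at 0.
    ``persons`` is the output of :func:`~mdsmetrics.pcm.estimate_abilities`
    (columns ``theta`` and ``se``).
    """
    theta = np.asarray(persons["theta"], dtype=float)
    se = np.asarray(persons["se"], dtype=float)
    ok = np.isfinite(theta) & np.isfinite(se)
    theta, se = theta[ok], se[ok]
    if theta.size < 2:
        raise ValueError("PSI needs at least 2 persons with finite estimates")
    var = float(np.var(theta, ddof=1))
    if var <= 0:
        logger.warning("zero ability variance; PSI set to 0")
        return 0.0
    psi = (var - float(np.mean(se**2))) / var
    return float(min(max(psi, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Targeting
# ---------------------------------------------------------------------------

@dataclass
class TargetingJudgment:
    centering_offset: float  # |mean ability - mean difficulty|, logits
    well_targeted: bool


def centering_judgment(offset: float) -> TargetingJudgment:
    """Apply the half-logit rule to a mean offset from zero (logits)."""
    off = abs(float(offset))
    return TargetingJudgment(centering_offset=off, well_targeted=off < HALF_LOGIT)


def targeting_summary(
    items: Sequence[ItemParams], persons: pd.DataFrame
) -> tuple[dict, TargetingJudgment]:
    """Item/person location summary and the half-logit targeting judgment.

    Because calibration centres mean item difficulty at zero, the offset is
    carried by the person side: a well-targeted scale has mean person
    ability within half a logit of the (zero) mean item difficulty.
    """
    if len(items) == 0 or len(persons) == 0:
        raise ValueError("targeting needs non-empty item and person lists")
    deltas = np.array([it.difficulty for it in items])
    locations = np.concatenate([it.steps for it in items])
    theta = np.asarray(persons["theta"], dtype=float)
    theta = theta[np.isfinite(theta)]
    summary = {
        "mean_item_difficulty": float(deltas.mean()),
        "sd_item_difficulty": float(deltas.std(ddof=1)) if deltas.size > 1 else 0.0,
        "mean_person_ability": float(theta.mean()),
        "sd_person_ability": float(theta.std(ddof=1)) if theta.size > 1 else 0.0,
        "threshold_range": (float(locations.min()), float(locations.max())),
    }
    offset = summary["mean_person_ability"] - summary["mean_item_difficulty"]
    return summary, centering_judgment(offset)


# ---------------------------------------------------------------------------
# Residuals and item fit
# ---------------------------------------------------------------------------

def _nonextreme(persons: pd.DataFrame) -> pd.DataFrame:
    """Residual analyses use non-extreme scorers only: a zero or perfect raw
    score pins the person estimate to the data, leaving no usable residual."""
    if "extreme" in persons.columns:
        return persons.loc[~persons["extreme"].astype(bool)]
    return persons


def _residual_parts(data, items, persons):
    """Observed codes and estimation-adjusted conditional moments.

    The raw model variance V overstates the dispersion of residuals taken
    at the person's own ability estimate; the first-order correction
    deflates it by the item's share of the test information,
    ``V_adj = V (1 - V / I_person)``.
    """
    sub = data.loc[persons.index]
    X = _recode_with_maps(sub, items)
    theta = np.asarray(persons["theta"], dtype=float)
    E, V, M3, M4 = residual_moments(theta, items)
    obs = ~np.isnan(X)
    info = np.where(obs, V, 0.0).sum(axis=1)
    shrink = 1.0 - V / np.maximum(info[:, None], 1e-300)
    shrink = np.clip(shrink, 1e-6, 1.0)
    V_adj = V * shrink
    M4_adj = M4 * shrink**2
    return X, E, V_adj, M4_adj, obs


def standardized_residuals(
    data: pd.DataFrame,
    items: Sequence[ItemParams],
    persons: pd.DataFrame,
    *,
    drop_extreme: bool = True,
) -> pd.DataFrame:
    """Person-by-item standardized residuals (x - E)/sqrt(V_adj) under the PCM.

    Rows are restricted to (by default non-extreme) persons present in
    ``persons``; missing responses stay missing.  The variance is adjusted
    for the ability-estimation effect (see :func:`item_fit`).
    """
    if drop_extreme:
        persons = _nonextreme(persons)
    X, E, V_adj, _, _ = _residual_parts(data, items, persons)
    with np.errstate(invalid="ignore"):
        Z = (X - E) / np.sqrt(V_adj)
    return pd.DataFrame(Z, index=persons.index, columns=[it.name for it in items])


def item_fit(
    data: pd.DataFrame,
    items: Sequence[ItemParams],
    persons: pd.DataFrame,
    settings: DiagnosticSettings | None = None,
) -> pd.DataFrame:
    """Residual-based fit statistics per item.

    Reports outfit and infit mean squares plus their standardized forms
    (Wilson-Hilferty cube-root transformation, using the exact conditional
    residual moments under the fitted model).  ``fit_residual`` is the
    standardized outfit; items with |fit_residual| above the configured
    threshold are flagged as misfitting — large positive values indicate
    underfit (noise/miscoding), large negative values overfit (Guttman-like
    over-discrimination).
    """
    settings = settings or DiagnosticSettings()
    persons = _nonextreme(persons)
    X, E, V, M4, obs = _residual_parts(data, items, persons)
    D2 = np.where(obs, (X - E) ** 2, 0.0)
    Vs = np.where(obs, V, 0.0)
    n_obs = obs.sum(axis=0)

    rows = []
    for j, it in enumerate(items):
        n = int(n_obs[j])
        if n < 2:
            rows.append((it.name, n, *([np.nan] * 4), False, True))
            continue
        v = Vs[obs[:, j], j]
        d2 = D2[obs[:, j], j]
        m4 = M4[obs[:, j], j]
        # outfit: mean squared standardized residual
        u = float(np.mean(d2 / v))
        qu2 = float(np.sum(m4 / v**2 - 1.0)) / n**2
        zu = _wilson_hilferty(u, qu2)
        # infit: information-weighted mean square
        w = float(np.sum(d2) / np.sum(v))
        qw2 = float(np.sum(m4 - v**2)) / float(np.sum(v)) ** 2
        zw = _wilson_hilferty(w, qw2)
        low_info = n < settings.min_item_observations
        if low_info:
            logger.warning("item %r: only %d observations; fit statistic is low-information", it.name, n)
        rows.append(
            (it.name, n, u, zu, w, zw, abs(zu) > settings.fit_flag_threshold, low_info)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "item", "n_obs", "outfit_msq", "fit_residual",
            "infit_msq", "infit_z", "misfit", "low_information",
        ],
    ).set_index("item")
    return out


def _wilson_hilferty(msq: float, q2: float) -> float:
    """Standardize a mean-square fit statistic to an approximate N(0,1)."""
    if q2 <= 0 or not np.isfinite(q2):
        return float("nan")
    q = np.sqrt(q2)
    return float((msq ** (1.0 / 3.0) - 1.0) * 3.0 / q + q / 3.0)


# ---------------------------------------------------------------------------
# Local dependence
# ---------------------------------------------------------------------------

def local_dependence(
    data: pd.DataFrame,
    items: Sequence[ItemParams],
    persons: pd.DataFrame,
    settings: DiagnosticSettings | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise correlations of standardized residuals, with flagged pairs.

    A pair is flagged when its residual correlation exceeds the mean
    off-diagonal correlation by the configured margin — a relative cut that
    is robust to the small negative bias Rasch residual correlations carry.
    Returns (correlation matrix, flagged pairs).  A single item gives an
    empty matrix.
    """
    settings = settings or DiagnosticSettings()
    if len(items) < 2:
        return pd.DataFrame(index=[it.name for it in items],
                            columns=[it.name for it in items], dtype=float), []
    Z = standardized_residuals(data, items, persons)
    corr = Z.corr(min_periods=2)
    vals = corr.to_numpy(copy=True)
    np.fill_diagonal(vals, np.nan)
    mean_off = float(np.nanmean(vals))
    cut = mean_off + settings.local_dependence_margin
    flagged = []
    names = list(corr.columns)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            r = vals[a, b]
            if np.isfinite(r) and r > cut:
                flagged.append((names[a], names[b], float(r)))
    return corr, flagged


# ---------------------------------------------------------------------------
# Dimensionality
# ---------------------------------------------------------------------------

def dimensionality(
    data: pd.DataFrame,
    items: Sequence[ItemParams],
    persons: pd.DataFrame,
    settings: DiagnosticSettings | None = None,
) -> dict:
    """Residual principal-component check of unidimensionality.

    The residual correlation matrix is eigen-decomposed; items are split by
    the sign of their loading on the first component, abilities are
    re-estimated on each subset, and each person's pair of estimates is
    compared with a z-test.  The scale is accepted as unidimensional when
    the binomial confidence interval for the proportion of significantly
    different pairs reaches down to the acceptance proportion (default 5%).
    """
    settings = settings or DiagnosticSettings()
    Z = standardized_residuals(data, items, persons)
    corr = Z.corr(min_periods=2).fillna(0.0)
    eigvals, eigvecs = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    first = eigvecs[:, 0]
    if first.sum() < 0:
        first = -first
    result = {
        "first_eigenvalue": float(eigvals[0]),
        "proportion_variance": float(eigvals[0] / eigvals.sum()),
        "loadings": dict(zip(corr.columns, map(float, first))),
    }
    pos = [it for it, l in zip(items, first) if l >= 0]
    neg = [it for it, l in zip(items, first) if l < 0]
    if len(pos) < settings.min_subset_items or len(neg) < settings.min_subset_items:
        logger.warning(
            "dimensionality subset test skipped: need >= %d items per loading subset",
            settings.min_subset_items,
        )
        result.update({"test_performed": False, "unidimensional": None})
        return result
    est_pos = estimate_abilities(data.loc[persons.index], pos)
    est_neg = estimate_abilities(data.loc[persons.index], neg)
    common = est_pos.index.intersection(est_neg.index)
    a, b = est_pos.loc[common], est_neg.loc[common]
    z = (a["theta"] - b["theta"]) / np.sqrt(a["se"] ** 2 + b["se"] ** 2)
    from scipy.stats import norm

    crit = norm.ppf(1 - settings.dim_alpha / 2)
    sig = (np.abs(z) > crit).to_numpy()
    n = int(sig.size)
    k = int(sig.sum())
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    result.update(
        {
            "test_performed": True,
            "n_compared": n,
            "proportion_significant": k / n,
            "ci": (float(lo), float(hi)),
            "unidimensional": bool(lo <= settings.dim_accept_proportion),
        }
    )
    return result


# ---------------------------------------------------------------------------
# Differential item functioning
# ---------------------------------------------------------------------------

def dif_analysis(
    data: pd.DataFrame,
    items: Sequence[ItemParams],
    persons: pd.DataFrame,
    factors: pd.DataFrame,
    settings: DiagnosticSettings | None = None,
) -> pd.DataFrame:
    """Two-way ANOVA DIF screen of standardized residuals.

    For each item and person factor, residuals are modelled by factor level
    and ability class interval (equal-count strata).  The factor main
    effect tests uniform DIF, the interaction non-uniform DIF.  P-values
    are Bonferroni-adjusted across items within each factor.
    """
    settings = settings or DiagnosticSettings()
    Z = standardized_residuals(data, items, persons)
    theta = persons["theta"]
    n_bins = settings.dif_n_class_intervals
    strata = pd.qcut(theta.rank(method="first"), q=n_bins, labels=False)

    rows = []
    for fac in factors.columns:
        g = factors.loc[persons.index, fac]
        levels = g.dropna().unique()
        if len(levels) < 2:
            raise ValueError(f"factor {fac!r} has fewer than 2 levels; DIF contrast undefined")
        for it in items:
            df = pd.DataFrame(
                {"resid": Z[it.name], "grp": g.astype("category"), "cls": strata}
            ).dropna()
            model = smf.ols("resid ~ C(grp) * C(cls)", data=df).fit()
            an = sm.stats.anova_lm(model, typ=2)
            p_uni = float(an.loc["C(grp)", "PR(>F)"])
            p_non = float(an.loc["C(grp):C(cls)", "PR(>F)"])
            rows.append((it.name, fac, p_uni, p_non))
    out = pd.DataFrame(rows, columns=["item", "factor", "p_uniform", "p_nonuniform"])
    k = len(items)
    out["p_uniform_adj"] = np.minimum(out["p_uniform"] * k, 1.0)
    out["p_nonuniform_adj"] = np.minimum(out["p_nonuniform"] * k, 1.0)
    out["uniform_dif"] = out["p_uniform_adj"] < settings.dif_alpha
    out["nonuniform_dif"] = out["p_nonuniform_adj"] < settings.dif_alpha
    return out


# ---------------------------------------------------------------------------
# Bundled report
# ---------------------------------------------------------------------------

@dataclass
class ScaleDiagnostics:
    psi: float
    targeting: dict
    targeting_judgment: TargetingJudgment
    item_fit: pd.DataFrame
    residual_correlations: pd.DataFrame
    flagged_pairs: list
    dimensionality: dict
    dif: pd.DataFrame | None
    settings: DiagnosticSettings

    def to_dict(self) -> dict:
        return {
            "psi": self.psi,
            "targeting": {
                **self.targeting,
                "centering_offset": self.targeting_judgment.centering_offset,
                "well_targeted": self.targeting_judgment.well_targeted,
            },
            "item_fit": self.item_fit.reset_index().to_dict(orient="records"),
            "residual_correlations": self.residual_correlations.round(6).to_dict(),
            "flagged_pairs": [list(p) for p in self.flagged_pairs],
            "dimensionality": self.dimensionality,
            "dif": None if self.dif is None else self.dif.to_dict(orient="records"),
            "settings": self.settings.to_dict(),
        }

    def summary(self) -> str:
        t = self.targeting
        lines = [
            f"PSI (reliability)          : {self.psi:.3f}",
            f"Item difficulty mean (SD)  : {t['mean_item_difficulty']:.2f} ({t['sd_item_difficulty']:.2f})",
            f"Person ability mean (SD)   : {t['mean_person_ability']:.2f} ({t['sd_person_ability']:.2f})",
            f"Threshold range            : {t['threshold_range'][0]:.2f}; {t['threshold_range'][1]:.2f}",
            f"Centering offset (logits)  : {self.targeting_judgment.centering_offset:.2f}"
            f" -> {'well targeted' if self.targeting_judgment.well_targeted else 'off target'}",
            f"Misfitting items           : {int(self.item_fit['misfit'].sum())} / {len(self.item_fit)}",
            f"Locally dependent pairs    : {len(self.flagged_pairs)}",
        ]
        d = self.dimensionality
        if d.get("test_performed"):
            lines.append(
                f"Unidimensionality          : {'accepted' if d['unidimensional'] else 'rejected'}"
                f" ({d['proportion_significant']:.1%} persons differ)"
            )
        if self.dif is not None:
            lines.append(
                f"Items with uniform DIF     : {int(self.dif['uniform_dif'].sum())}"
            )
        return "\n".join(lines)


def diagnose_scale(
    data: pd.DataFrame,
    items: Sequence[ItemParams],
    persons: pd.DataFrame,
    factors: pd.DataFrame | None = None,
    settings: DiagnosticSettings | None = None,
) -> ScaleDiagnostics:
    """Run the full diagnostic battery for one calibrated scale."""
    settings = settings or DiagnosticSettings()
    psi = compute_psi(persons)
    targeting, judgment = targeting_summary(items, persons)
    fit = item_fit(data, items, persons, settings)
    corr, flagged = local_dependence(data, items, persons, settings)
    dim = dimensionality(data, items, persons, settings)
    dif = None
    if factors is not None and len(factors.columns) > 0:
        dif = dif_analysis(data, items, persons, factors, settings)
    return ScaleDiagnostics(
        psi=psi,
        targeting=targeting,
        targeting_judgment=judgment,
        item_fit=fit,
        residual_correlations=corr,
        flagged_pairs=flagged,
        dimensionality=dim,
        dif=dif,
        settings=settings,
    )
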