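"""Synthetic Model-Disability-Survey-like data with known generating truth.

Generates ordinal capacity and performance responses from the same partial
credit model used in estimation, so every downstream stage (calibration,
reliability, targeting, adjustment, classification) has a recoverable
ground truth.  Capacity ability is drawn from a normal latent distribution;
performance ability is a correlated draw shifted by environmental
covariates (assistance, devices, attitudes), mirroring the ICF view that
realized functioning is capacity filtered through the environment.

The defaults emulate the published national calibrations: 15 five-category
items with difficulties spanning -2..+2 logits (threshold locations about
-3.5..+3.5), person ability centred below zero (populations function better
than the scale midpoint), and a capacity-performance correlation of 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pcm import ItemParams, pcm_probabilities

__all__ = ["GeneratingSpec", "SyntheticDataset", "simulate_survey", "default_item_bank"]


def default_item_bank(n_items: int = 15, n_categories: int = 5) -> list[ItemParams]:
    """Evenly spaced item bank: difficulties -2..+2, symmetric thresholds."""
    if n_items < 2 or n_categories < 2:
        raise ValueError("need at least 2 items and 2 categories")
    difficulties = np.linspace(-2.0, 2.0, n_items)
    difficulties -= difficulties.mean()
    m = n_categories - 1
    tau = np.linspace(-1.5, 1.5, m) if m > 1 else np.zeros(1)
    tau -= tau.mean()
    return [
        ItemParams(name=f"item{j + 1:02d}", difficulty=float(d), thresholds=tau.copy())
        for j, d in enumerate(difficulties)
    ]


# covariate distributions: name -> ("binary", p) or ("ordinal", n_levels, p)
# where the ordinal variable is Binomial(n_levels - 1, p)
_DEFAULT_COVARIATES: dict[str, tuple] = {
    "assistive_devices": ("binary", 0.25),
    "personal_assistance": ("binary", 0.15),
    "attitudes_of_others": ("ordinal", 5, 0.4),
    "social_support": ("ordinal", 5, 0.5),
    "sex": ("binary", 0.5),
    "age_group": ("ordinal", 5, 0.5),
}

_DEFAULT_ENV_EFFECTS: dict[str, float] = {
    # logits of extra disability in performance per unit of the covariate
    "assistive_devices": 0.6,
    "attitudes_of_others": 0.25,
}


@dataclass(frozen=True)
class GeneratingSpec:
    """Generating parameters for one synthetic survey."""

    n_persons: int = 2000
    ability_mean: float = -1.0
    ability_sd: float = 1.2
    items: tuple = tuple(default_item_bank())
    env_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ENV_EFFECTS)
    )
    covariates: Mapping[str, tuple] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATES)
    )
    capacity_performance_corr: float = 0.8
    missing_rate: float = 0.02
    employment_gap: float = 0.8  # logit drop in P(employed) per performance logit
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ValueError("invalid spec: n_persons must be a positive count")
        if not (np.isfinite(self.ability_mean) and np.isfinite(self.ability_sd)):
            raise ValueError("invalid spec: ability_mean/ability_sd must be finite")
        if self.ability_sd <= 0:
            raise ValueError("invalid spec: ability_sd must be > 0")
        if not self.items or len(self.items) < 1:
            raise ValueError("invalid spec: at least one item required")
        for it in self.items:
            if it.n_categories < 2:
                raise ValueError(f"invalid spec: item {it.name!r} needs >= 2 categories")
            if not np.all(np.isfinite(it.thresholds)):
                raise ValueError(f"invalid spec: item {it.name!r} thresholds not finite")
        if not -1.0 <= self.capacity_performance_corr <= 1.0:
            raise ValueError("invalid spec: capacity_performance_corr must lie in [-1, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("invalid spec: missing_rate must lie in [0, 1)")
        for name, eff in self.env_effects.items():
            if not name or not np.isfinite(eff):
                raise ValueError("invalid spec: env_effects must be named and finite")
            if name not in self.covariates:
                raise ValueError(f"invalid spec: env effect {name!r} has no covariate")


@dataclass
class SyntheticDataset:
    capacity_responses: pd.DataFrame
    performance_responses: pd.DataFrame
    covariates: pd.DataFrame
    true_abilities: pd.DataFrame
    spec_used: GeneratingSpec


def _covariate_mean(dist: tuple) -> float:
    if dist[0] == "binary":
        return float(dist[1])
    if dist[0] == "ordinal":
        return float((dist[1] - 1) * dist[2])
    raise ValueError(f"unknown covariate family {dist[0]!r}")


def _draw_covariate(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    if dist[0] == "binary":
        return rng.binomial(1, dist[1], size=n).astype(float)
    if dist[0] == "ordinal":
        return rng.binomial(dist[1] - 1, dist[2], size=n).astype(float)
    raise ValueError(f"unknown covariate family {dist[0]!r}")


def _draw_responses(
    rng: np.random.Generator,
    theta: np.ndarray,
    items: Sequence[ItemParams],
    missing_rate: float,
) -> pd.DataFrame:
    n = theta.size
    out = np.empty((n, len(items)))
    for j, it in enumerate(items):
        p = pcm_probabilities(theta, it.steps)
        u = rng.random(n)
        out[:, j] = (u[:, None] > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1)
    if missing_rate > 0:
        out[rng.random(out.shape) < missing_rate] = np.nan
    return pd.DataFrame(out, columns=[it.name for it in items])


def simulate_survey(spec: GeneratingSpec) -> SyntheticDataset:
    """Draw one synthetic survey from the generating PCM.

    Performance ability is built from capacity ability via its correlation,
    plus centred environmental shifts; responses are then drawn from the
    closed-form PCM category distribution at each latent ability.  Missing
    entries are injected completely at random.  Identical spec (including
    seed) gives identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_persons
    persons = pd.Index([f"P{i + 1:06d}" for i in range(n)], name="person")

    theta_cap = rng.normal(spec.ability_mean, spec.ability_sd, size=n)
    rho = spec.capacity_performance_corr
    z = rng.normal(size=n)
    theta_perf = (
        spec.ability_mean
        + rho * (theta_cap - spec.ability_mean)
        + spec.ability_sd * np.sqrt(max(0.0, 1.0 - rho**2)) * z
    )

    cov = pd.DataFrame(
        {name: _draw_covariate(rng, dist, n) for name, dist in spec.covariates.items()},
        index=persons,
    )
    for name, eff in spec.env_effects.items():
        theta_perf = theta_perf + eff * (
            cov[name].to_numpy() - _covariate_mean(spec.covariates[name])
        )

    # employment indicator with a built-in disability gap, for disaggregation
    p_emp = 1.0 / (1.0 + np.exp(-(0.5 - spec.employment_gap * (theta_perf - spec.ability_mean))))
    cov["employed"] = rng.binomial(1, p_emp).astype(float)

    cap = _draw_responses(rng, theta_cap, spec.items, spec.missing_rate)
    perf = _draw_responses(rng, theta_perf, spec.items, spec.missing_rate)
    cap.index = persons
    perf.index = persons

    truth = pd.DataFrame(
        {"theta_capacity": theta_cap, "theta_performance": theta_perf}, index=persons
    )
    return SyntheticDataset(
        capacity_responses=cap,
        performance_responses=perf,
        covariates=cov,
        true_abilities=truth,
        spec_used=spec,
    )
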