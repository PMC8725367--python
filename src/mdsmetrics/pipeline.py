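"""End-to-end pipeline: simulate -> calibrate -> diagnose -> score -> adjust
-> classify -> disaggregate, with a manifest for reproducibility.

A single global seed feeds per-stage derived seeds (via ``SeedSequence``)
so stages are individually re-runnable and a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics as diag
from . import io as mio
from . import metric, synth
from .classify import (
    classify as classify_scores,
    derive_cutoffs,
    disaggregate,
    distribution_histogram,
    prevalence,
)
from .pcm import fit_pcm, estimate_abilities

logger = logging.getLogger("mdsmetrics")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STAGES = ["simulate", "calibrate", "diagnose", "score", "adjust", "classify", "disaggregate"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Settings for one pipeline run.

    Either ``simulate`` is set (synthetic run) or the three input paths
    are given.  ``dif_factors``, ``indicator`` and ``env_covariates`` name
    columns of the covariate table.
    """

    out_dir: str = "mds_run"
    seed: int = 0
    simulate: dict | None = None              # GeneratingSpec overrides, or None
    capacity_path: str | None = None
    performance_path: str | None = None
    covariates_path: str | None = None
    codebook: dict | None = None
    env_covariates: list = field(
        default_factory=lambda: [
            "assistive_devices", "personal_assistance",
            "attitudes_of_others", "social_support",
        ]
    )
    dif_factors: list = field(default_factory=lambda: ["sex"])
    indicator: str = "employed"
    weights_column: str | None = None
    estimation: dict = field(default_factory=dict)       # fit_pcm kwargs
    adjustment: dict = field(default_factory=dict)       # fit_adjustment kwargs
    diagnostics: dict = field(default_factory=dict)      # DiagnosticSettings kwargs
    classification: dict = field(default_factory=dict)   # boundary_side etc.
    bin_width: float = 5.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("capacity_path", "performance_path", "covariates_path"):
                if getattr(self, name) is None:
                    raise ValueError(f"config invalid: {name} required when not simulating")
        if self.seed is None:
            raise ValueError("config invalid: a seed is required (stochastic stages run)")


def _make_spec(cfg: PipelineConfig, seed: int) -> synth.GeneratingSpec:
    overrides = dict(cfg.simulate or {})
    overrides.setdefault("seed", seed)
    if "items" in overrides and overrides["items"] is not None:
        overrides["items"] = tuple(
            it if isinstance(it, synth.ItemParams) else synth.ItemParams(
                name=it["name"],
                difficulty=float(it["difficulty"]),
                thresholds=np.asarray(it["thresholds"], dtype=float),
            )
            for it in overrides["items"]
        )
    return synth.GeneratingSpec(**overrides)


def _load_inputs(cfg: PipelineConfig, out: Path, seed: int):
    if cfg.simulate is not None:
        ds = synth.simulate_survey(_make_spec(cfg, seed))
        mio.write_table(ds.capacity_responses, out / "capacity.csv")
        mio.write_table(ds.performance_responses, out / "performance.csv")
        mio.write_table(ds.covariates, out / "covariates.csv")
        mio.write_table(ds.true_abilities, out / "truth.csv")
        return ds.capacity_responses, ds.performance_responses, ds.covariates
    cap = mio.read_survey_table(cfg.capacity_path, cfg.codebook)
    perf = mio.read_survey_table(cfg.performance_path, cfg.codebook)
    cov = pd.read_csv(cfg.covariates_path, index_col=0)
    return cap, perf, cov


def _check_columns(cfg: PipelineConfig, cov: pd.DataFrame) -> None:
    wanted = list(cfg.env_covariates) + list(cfg.dif_factors) + [cfg.indicator]
    if cfg.weights_column:
        wanted.append(cfg.weights_column)
    missing = [c for c in wanted if c not in cov.columns]
    if missing:
        raise ValueError(f"covariate table lacks configured columns: {missing}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and return the manifest (also written to disk).

    Fails fast on config errors before any computation; a stage failure
    raises :class:`PipelineError` naming the stage, keeps partial outputs,
    and leaves a FAILED marker file in the output directory.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(cfg.seed).spawn(len(STAGES))]
    stage_seed = dict(zip(STAGES, seeds))
    stages_done: list[dict] = []
    current = "validate"
    try:
        cap, perf, cov = _load_inputs(cfg, out, stage_seed["simulate"])
        _check_columns(cfg, cov)
        current = "simulate"
        stages_done.append({"stage": "simulate", "status": "completed",
                            "rows": int(len(cap)),
                            "note": "synthetic" if cfg.simulate is not None else "loaded from files"})

        current = "calibrate"
        fit_cap = fit_pcm(cap, **cfg.estimation)
        fit_perf = fit_pcm(perf, **cfg.estimation)
        mio.write_calibration(fit_cap.items, out / "calib_capacity.json")
        mio.write_calibration(fit_perf.items, out / "calib_performance.json")
        persons_cap = estimate_abilities(cap, fit_cap.items)
        persons_perf = estimate_abilities(perf, fit_perf.items)
        mio.write_table(persons_cap, out / "persons_capacity.csv")
        mio.write_table(persons_perf, out / "persons_performance.csv")
        stages_done.append({"stage": "calibrate", "status": "completed",
                            "rows": int(len(persons_cap)),
                            "converged": bool(fit_cap.report.converged and fit_perf.report.converged)})

        current = "diagnose"
        settings = diag.DiagnosticSettings(**cfg.diagnostics)
        factors = cov[cfg.dif_factors] if cfg.dif_factors else None
        rep_cap = diag.diagnose_scale(cap, fit_cap.items, persons_cap, factors, settings)
        rep_perf = diag.diagnose_scale(perf, fit_perf.items, persons_perf, factors, settings)
        mio.write_json(rep_cap.to_dict(), out / "diagnostics_capacity.json")
        mio.write_json(rep_perf.to_dict(), out / "diagnostics_performance.json")
        stages_done.append({"stage": "diagnose", "status": "completed",
                            "psi_capacity": rep_cap.psi, "psi_performance": rep_perf.psi})

        current = "score"
        anchors_cap = metric.anchors_from_items(fit_cap.items)
        anchors_perf = metric.anchors_from_items(fit_perf.items)
        common = persons_cap.index.intersection(persons_perf.index)
        scores = pd.DataFrame(
            {
                "capacity_score": metric.to_0_100(persons_cap.loc[common, "theta"], anchors_cap),
                "performance_score": metric.to_0_100(persons_perf.loc[common, "theta"], anchors_perf),
            },
            index=common,
        )
        mio.write_table(scores, out / "scores.csv")
        stages_done.append({"stage": "score", "status": "completed", "rows": int(len(scores))})

        current = "adjust"
        adj_kwargs = dict(cfg.adjustment)
        adj_kwargs.setdefault("seed", stage_seed["adjust"])
        adj = metric.fit_adjustment(
            scores["performance_score"],
            scores["capacity_score"],
            cov.loc[common, cfg.env_covariates],
            **adj_kwargs,
        )
        mio.write_table(adj.scores, out / "adjusted.csv")
        stages_done.append({"stage": "adjust", "status": "completed",
                            "oob_r2": adj.oob_r2,
                            "oob_r2_capacity_only": adj.oob_r2_capacity_only})

        current = "classify"
        weights = cov.loc[common, cfg.weights_column] if cfg.weights_column else None
        cut = derive_cutoffs(adj.scores["adjusted_performance_score"], weights)
        records = classify_scores(
            adj.scores["adjusted_performance_score"], cut, **cfg.classification
        )
        prev = prevalence(records, weights)
        hist, lines = distribution_histogram(
            records["adjusted_performance_score"], cut, cfg.bin_width
        )
        mio.write_table(records, out / "levels.csv")
        mio.write_table(prev.to_frame(), out / "prevalence.csv")
        mio.write_table(hist, out / "histogram.csv", index=False)
        mio.write_json({"cutoffs": cut.to_dict(), "lines": lines,
                        "sd_convention": "weighted population SD" if weights is not None else "unweighted, n-1"},
                       out / "cutoffs.json")
        stages_done.append({"stage": "classify", "status": "completed",
                            "prevalence": {k: float(v) for k, v in prev.items()}})

        current = "disaggregate"
        table = disaggregate(cov.loc[common, cfg.indicator], records)
        mio.write_table(table, out / "disaggregation.csv")
        stages_done.append({"stage": "disaggregate", "status": "completed",
                            "indicator": cfg.indicator})
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        (out / "FAILED").write_text(f"stage: {current}\nerror: {exc}\n")
        stages_done.append({"stage": current, "status": "failed", "error": str(exc)})
        manifest = mio.build_manifest(out, stages_done, _settings_dict(cfg), cfg.seed)
        mio.write_json(manifest, out / "manifest.json")
        raise PipelineError(current, exc) from exc

    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    manifest = mio.build_manifest(out, stages_done, _settings_dict(cfg), cfg.seed)
    mio.write_json(manifest, out / "manifest.json")
    return manifest


def _settings_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d.get("simulate") and "items" in (d["simulate"] or {}):
        d["simulate"] = {k: v for k, v in d["simulate"].items() if k != "items"}
        d["simulate"]["items"] = "custom bank (omitted from manifest)"
    return d
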