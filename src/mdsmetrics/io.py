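"""Reading and writing survey tables, calibrations, and run manifests.

Plain CSV for tabular data (header row, one row per respondent, empty cell
for missing), YAML codebooks declaring each item's category count, and JSON
for calibrations and diagnostic reports.  All writers use a fixed float
format so identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .pcm import ItemParams

__all__ = [
    "read_survey_table",
    "write_table",
    "read_codebook",
    "write_calibration",
    "read_calibration",
    "write_json",
    "build_manifest",
]

FLOAT_FORMAT = "%.17g"  # full double precision: write/read round-trips exactly


def write_table(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    df.to_csv(path, float_format=FLOAT_FORMAT, index=index)
    return path


def read_codebook(path) -> dict:
    """Load a YAML codebook: {items: {name: n_categories}, covariates: [...]}."""
    with open(path) as fh:
        cb = yaml.safe_load(fh)
    if not isinstance(cb, dict) or "items" not in cb:
        raise ValueError("codebook must be a mapping with an 'items' section")
    return cb


def read_survey_table(path, codebook: Mapping | None = None) -> pd.DataFrame:
    """Read a persons-x-items response CSV, validated against a codebook.

    The first column is the person identifier (must be unique); empty cells
    become missing.  When a codebook is given, its item columns must all be
    present and every observed code must lie in {0 .. n_categories-1}; a
    violation is rejected naming the offending row and column.
    """
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated person identifiers: {dups[:5]}")
    if codebook is not None:
        items = codebook["items"]
        missing_cols = [c for c in items if c not in df.columns]
        if missing_cols:
            raise ValueError(f"codebook items absent from file: {missing_cols}")
        for col, ncat in items.items():
            vals = df[col].dropna()
            bad = vals[(vals < 0) | (vals > ncat - 1) | (vals != np.round(vals))]
            if len(bad):
                row = bad.index[0]
                raise ValueError(
                    f"out-of-range code {bad.iloc[0]!r} at row {row!r}, column {col!r}"
                    f" (allowed 0..{ncat - 1})"
                )
        df = df[list(items)]
    return df


def write_calibration(items: Sequence[ItemParams], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump([it.to_dict() for it in items], fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def read_calibration(path) -> list[ItemParams]:
    with open(path) as fh:
        records = json.load(fh)
    return [ItemParams.from_dict(r) for r in records]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, cls=_NumpyEncoder, allow_nan=True)
        fh.write("\n")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(outdir, stages: list, settings: dict, seed: int) -> dict:
    """Manifest of a pipeline run: versions, seed, stages, file hashes."""
    import sklearn
    import scipy

    from . import __version__

    outdir = Path(outdir)
    files = sorted(
        p for p in outdir.iterdir()
        if p.is_file() and p.suffix in {".csv", ".json"} and p.name != "manifest.json"
    )
    return {
        "package": {"name": "mdsmetrics", "version": __version__},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "seed": seed,
        "settings": settings,
        "stages": stages,
        "files": {p.name: _sha256(p) for p in files},
    }
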