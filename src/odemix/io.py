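"""Reading and writing snapshot tables, manifests and fit results.

The on-disk snapshot format is a TSV/CSV table with one row per measured
cell and header columns ``condition`` (string), ``time`` (float), optional
stimulus columns (``stimulus`` and/or ``dose``) and one observable column
(default ``value``).  Writing uses a canonical float format so that a
write -> read -> write cycle is byte-stable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import SnapshotDataset

__all__ = ["read_snapshots", "write_snapshots", "read_mat_snapshots",
           "write_manifest", "read_manifest", "write_fit_result"]

_FLOAT_FMT = "%.10g"


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_snapshots(path, value_col: str = "value",
                   require_positive: bool = False) -> SnapshotDataset:
    """Load a snapshot table; validates schema and finiteness.

    ``require_positive`` enforces strictly positive measurements (hard
    error listing offending rows), as needed before any log-normal
    analysis.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("condition", "time", value_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df[[c for c in ("condition", "time", value_col) if c in df]].isna().any().any():
        raise ValueError(f"{path}: missing values in required columns")
    if not np.all(np.isfinite(df[value_col].to_numpy(dtype=float))):
        raise ValueError(f"{path}: non-finite values in column {value_col!r}")
    if require_positive:
        bad = df.index[df[value_col] <= 0].tolist()
        if bad:
            raise ValueError(
                f"{path}: non-positive measurements (log-normal analysis) "
                f"at rows {bad[:10]}"
            )
    return SnapshotDataset.from_dataframe(df, value_col=value_col)


def write_snapshots(data: SnapshotDataset, path, value_col: str = "value"):
    """Write the canonical snapshot table (stable ordering and formatting)."""
    path = Path(path)
    df = data.to_dataframe(value_col=value_col)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT)
    return path


def read_mat_snapshots(path, value_key: str = "y") -> SnapshotDataset:
    """Best-effort reader for MATLAB ``.mat`` snapshot containers.

    Expects struct arrays with fields ``t`` (time vector) and ``y``
    (cells x times matrix) per experiment, the layout used by MATLAB
    ODE-MM toolboxes.  Optional; absence of such files never blocks any
    analysis in this package.
    """
    from scipy.io import loadmat

    raw = loadmat(path, squeeze_me=True, struct_as_record=False)
    snapshots = {}
    conditions = {}
    for name, obj in raw.items():
        if name.startswith("__"):
            continue
        items = np.atleast_1d(obj)
        for idx, rec in enumerate(items):
            if not hasattr(rec, "t") or not hasattr(rec, value_key):
                continue
            cond = f"{name}{idx + 1}" if items.size > 1 else name
            times = np.atleast_1d(rec.t).astype(float)
            y = np.atleast_2d(getattr(rec, value_key)).astype(float)
            if y.shape[0] == times.size and y.shape[1] != times.size:
                y = y.T
            for k, t in enumerate(times):
                col = y[:, k]
                snapshots[(cond, float(t))] = col[np.isfinite(col)]
            rec_cond = {}
            for key in ("u", "dose", "stimulus"):
                if hasattr(rec, key):
                    rec_cond["dose" if key != "stimulus" else key] = float(
                        np.atleast_1d(getattr(rec, key))[0])
            conditions[cond] = rec_cond
    if not snapshots:
        raise ValueError(f"{path}: no snapshot structs with fields "
                         f"'t' and {value_key!r} found")
    return SnapshotDataset(snapshots=snapshots, conditions=conditions)


# ---------------------------------------------------------------------------
# structured text artefacts
# ---------------------------------------------------------------------------


def write_manifest(manifest: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return Path(path)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_fit_result(fit, spec, path):
    """Serialise a FitResult with its parameter names to YAML."""
    doc = fit.to_dict()
    doc["param_names"] = list(spec.param_names)
    doc["parameters"] = {n: float(v)
                         for n, v in zip(spec.param_names, fit.theta)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return Path(path)
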