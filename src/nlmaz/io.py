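"""File I/O: fixed CSV dialects, parameter files, reports, run headers.

Column names carry their units (``ce_mid_ng_ml`` etc.) and are validated
strictly — ambiguous unit-less files are rejected rather than guessed.
Every writer emits a comment header (lines starting with ``#``) holding
the package version, the seed and link choices in force, and SHA-256
hashes of any declared inputs, so each output is traceable to its run.
Numeric columns are written with 17 significant digits, making the
write/read round trip lossless at double precision.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import nlmaz
from nlmaz.fitting import FIT_PARAM_NAMES, FitResult, binarize
from nlmaz.surface import SurfaceParameters, params_to_dict

__all__ = [
    "OBSERVATION_COLUMNS",
    "DOSE_COLUMNS",
    "read_observations",
    "write_observations",
    "read_doses",
    "write_doses",
    "write_fit_result",
    "write_validation_report",
    "file_sha256",
]

OBSERVATION_COLUMNS = [
    "patient_id",
    "time_min",
    "ce_mid_ng_ml",
    "ce_alf_ng_ml",
    "ce_prop_ug_ml",
    "moaas",
]
DOSE_COLUMNS = ["patient_id", "drug", "amount", "amount_unit", "time_min", "duration_min"]
_DRUGS = ("midazolam", "alfentanil", "propofol")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _header_lines(meta: dict | None) -> str:
    base = {"package": f"nlmaz {nlmaz.__version__}"}
    base.update(meta or {})
    return "".join(f"# {k}: {v}\n" for k, v in base.items())


def _write_csv(df: pd.DataFrame, path, meta: dict | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_csv(path) -> pd.DataFrame:
    # round_trip parser: exact IEEE round trip of the %.17g writer output
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def read_observations(path) -> pd.DataFrame:
    """Observation table with unit-checked columns and a derived lor flag."""
    df = _read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: empty observation file")
    _require(df, OBSERVATION_COLUMNS, path)
    for col in ("ce_mid_ng_ml", "ce_alf_ng_ml", "ce_prop_ug_ml"):
        vals = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(f"{path}: column {col} must be finite and >= 0")
    lor = np.array([binarize(s) for s in df["moaas"]])
    if "lor" in df.columns:
        if not np.array_equal(df["lor"].to_numpy(dtype=int), lor):
            raise ValueError(f"{path}: lor column inconsistent with moaas scores")
    else:
        df["lor"] = lor
    return df


def write_observations(
    df: pd.DataFrame, path, params: SurfaceParameters | None = None, meta: dict | None = None
) -> None:
    """Write observations (plus predicted_p and lor when params given)."""
    out = df.copy()
    if "lor" not in out.columns:
        out["lor"] = [binarize(s) for s in out["moaas"]]
    if params is not None:
        from nlmaz.surface import effect_many

        out["predicted_p"] = effect_many(
            out["ce_mid_ng_ml"], out["ce_alf_ng_ml"], out["ce_prop_ug_ml"], params
        )
    _write_csv(out, path, meta)


def read_doses(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require(df, DOSE_COLUMNS, path)
    bad = set(df["drug"]) - set(_DRUGS)
    if bad:
        raise ValueError(f"{path}: unknown drug(s) {sorted(bad)}")
    bad_units = set(df["amount_unit"]) - {"mg", "ug"}
    if bad_units:
        raise ValueError(f"{path}: unknown amount_unit(s) {sorted(bad_units)}")
    if (df["amount"] < 0).any() or (df["duration_min"] < 0).any():
        raise ValueError(f"{path}: amounts and durations must be >= 0")
    return df


def write_doses(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_csv(df[DOSE_COLUMNS], path, meta)


def write_fit_result(result: FitResult, path, meta: dict | None = None) -> None:
    """Parameter-table-layout YAML: estimate (+ SE/RSE) per parameter."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = {}
    full = params_to_dict(result.params)
    for name in FIT_PARAM_NAMES:
        entry = {"estimate": float(full[name])}
        if name not in result.estimates:
            entry["fixed"] = True
        if result.se is not None and name in result.se:
            entry["se"] = result.se[name]
            rse = result.rse[name]
            entry["rse"] = "inf" if not np.isfinite(rse) else float(rse)
        table[name] = entry
    doc = {
        "parameters": table,
        "links": {
            k: v for k, v in full.items() if k.startswith("link") or k == "single_drug_reduction"
        },
        "neg2ll": result.neg2ll,
        "n_obs": result.n_obs,
        "n_patients": result.n_patients,
        "converged": result.converged,
        "at_boundary": sorted(k for k, v in result.at_boundary.items() if v),
        "n_boot_failed": result.n_boot_failed,
        "seed": result.seed,
    }
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        yaml.safe_dump(doc, fh, sort_keys=False)
    if result.bootstrap_table is not None:
        _write_csv(result.bootstrap_table, path.with_suffix(".bootstrap.csv"), meta)


def write_validation_report(report, prefix, meta: dict | None = None) -> None:
    """Metrics YAML plus ROC-points and per-observation prediction CSVs."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "n_obs": report.n_obs,
        "accuracy_percent": report.accuracy,
        "auc": report.auc,
        "auc_ci95": list(report.auc_ci),
    }
    with open(prefix.with_suffix(".yaml"), "w") as fh:
        fh.write(_header_lines(meta))
        yaml.safe_dump(doc, fh, sort_keys=False)
    _write_csv(report.roc_points, prefix.with_name(prefix.name + "_roc.csv"), meta)
    _write_csv(report.predictions, prefix.with_name(prefix.name + "_predictions.csv"), meta)
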