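"""Canonical table/config formats: CSV with header for subject tables, JSON
for structured reports, YAML for configuration, NIfTI-1 for volumes.

Every file the pipeline writes carries the resolved configuration's hash as a
leading ``# config_hash=...`` comment (CSV) or a ``config_hash`` field (JSON)
so mixed-provenance inputs can be refused.  No timestamps go into output
files: reruns with identical config and seed reproduce outputs byte for byte.
"""
from __future__ import annotations

import hashlib
import json
import warnings

import numpy as np
import pandas as pd
import yaml

from .region_select import ID_COLUMNS

REQUIRED_COLUMNS = ("subject_id", "group")


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode("utf8")).hexdigest()[:16]


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


# --------------------------------------------------------------------------
# Regional CSV
# --------------------------------------------------------------------------
def read_regional_csv(path) -> pd.DataFrame:
    """Read a subjects×regions table.

    Requires ``subject_id`` and ``group`` columns; refuses duplicated subject
    ids; unparseable or blank numeric cells become missing values, each with
    a warning.  CRLF and LF files parse identically.
    """
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicated subject_id value(s) {sorted(set(dup))}")
    for col in df.columns:
        if col in ID_COLUMNS:
            continue
        if col == "low_uptake_outlier":
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
            continue
        raw = df[col]
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna() & (raw.str.strip() != "")
        blank = raw.isna() | (raw.astype(str).str.strip() == "")
        n_bad = int(bad.sum() + blank.sum())
        if n_bad:
            warnings.warn(f"{path}: column {col!r} has {n_bad} unparseable/blank "
                          "cell(s), treated as missing", stacklevel=2)
        df[col] = converted
    return df


def write_table_csv(df: pd.DataFrame, path, cfg_hash: str | None = None) -> None:
    with open(path, "w", newline="\n") as fh:
        if cfg_hash:
            fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")


def read_file_hash(path) -> str | None:
    """Provenance hash of a pipeline-written file, if present."""
    p = str(path)
    if p.endswith(".json"):
        with open(p) as fh:
            return json.load(fh).get("config_hash")
    with open(p) as fh:
        first = fh.readline().strip()
    if first.startswith("# config_hash="):
        return first.split("=", 1)[1]
    return None


def check_provenance(*paths) -> None:
    """Refuse inputs written under different configurations."""
    hashes = {h for h in (read_file_hash(p) for p in paths) if h}
    if len(hashes) > 1:
        raise ValueError(f"mixed-provenance inputs: config hashes {sorted(hashes)}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict("records"))
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_report_json(report: dict, path, cfg_hash: str | None = None) -> None:
    payload = _jsonable(report)
    if cfg_hash:
        payload["config_hash"] = cfg_hash
    with open(path, "w", newline="\n") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, allow_nan=False)
        fh.write("\n")
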