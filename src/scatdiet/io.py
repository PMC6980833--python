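"""CSV schemas, config loading and run manifests.

All pipeline artifacts are plain CSV with a header row.  Dates are
accepted either as ISO-8601 or as DD.MM.YYYY (auto-detected per file and
logged) and always written back as ISO-8601.  Unknown columns are
preserved as passthrough metadata.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import ConfigurationError, InputError

__all__ = [
    "read_feeding_schedule",
    "read_read_table",
    "read_detection_matrix",
    "write_table",
    "read_config",
    "write_manifest",
]

logger = logging.getLogger(__name__)


def _parse_dates(series: pd.Series, path, column: str) -> pd.Series:
    """ISO-8601 first, then DD.MM.YYYY; report per-row failures."""
    for fmt, label in (("ISO8601", "ISO-8601"), ("%d.%m.%Y", "DD.MM.YYYY")):
        try:
            parsed = pd.to_datetime(series, format=fmt)
            logger.info("%s: column %s parsed as %s dates", path, column, label)
            return parsed
        except (ValueError, TypeError):
            continue
    bad = []
    for idx, value in series.items():
        try:
            pd.to_datetime(value, format="ISO8601")
        except (ValueError, TypeError):
            try:
                pd.to_datetime(value, format="%d.%m.%Y")
            except (ValueError, TypeError):
                bad.append(f"row {idx}: unparseable date {value!r}")
    raise InputError(f"{path}, column {column!r}: " + "; ".join(bad[:20]))


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")


def read_feeding_schedule(path) -> pd.DataFrame:
    """Read a feeding schedule CSV (date, individual_id, species, proportion)."""
    df = pd.read_csv(path)
    _require(df, ["date", "individual_id", "species", "proportion"], path)
    df["date"] = _parse_dates(df["date"], path, "date")
    bad = df[(df["proportion"] < 0) | (df["proportion"] > 1) | df["proportion"].isna()]
    if len(bad):
        msgs = [f"row {i}: proportion {v!r} outside [0,1]"
                for i, v in bad["proportion"].items()]
        raise InputError(f"{path}: " + "; ".join(msgs[:20]))
    return df


def read_read_table(path, controls: bool = False) -> pd.DataFrame:
    """Read a taxon-assigned read-count CSV.

    Sample tables need subsample_id, control_id, taxon, read_count,
    sequence_length; control tables need control_id, taxon, read_count.
    """
    df = pd.read_csv(path)
    if controls:
        _require(df, ["control_id", "taxon", "read_count"], path)
    else:
        _require(df, ["subsample_id", "control_id", "taxon", "read_count",
                      "sequence_length"], path)
    if (df["read_count"] < 0).any():
        rows = df.index[df["read_count"] < 0].tolist()
        raise InputError(f"{path}: negative read_count at rows {rows[:20]}")
    return df


def read_detection_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["scat_id", "subsample_id", "individual_id", "defecation_date",
                  "degradation_day", "species", "detected"], path)
    df["defecation_date"] = _parse_dates(df["defecation_date"], path, "defecation_date")
    if not df["detected"].isin((0, 1)).all():
        raise InputError(f"{path}: detected must be 0/1")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a CSV with ISO-8601 dates and no index column."""
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[c]):
            df[c] = df[c].dt.strftime("%Y-%m-%d")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_config(path) -> dict:
    """Load a YAML or JSON pipeline config."""
    p = Path(path)
    text = p.read_text()
    if p.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    elif p.suffix == ".json":
        cfg = json.loads(text)
    else:
        raise ConfigurationError(f"config must be .yaml/.yml/.json, got {p.suffix}")
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config root must be a mapping")
    return cfg


def write_manifest(path, stage: str, seed: int | None, inputs: dict, outputs: dict,
                   extra: dict | None = None) -> None:
    """Machine-readable record of one pipeline stage run."""
    manifest = {
        "stage": stage,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    if extra:
        manifest.update(extra)
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(manifest, indent=1, default=str))
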