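"""Long-format series I/O and run configuration.

The on-disk exchange format is a UTF-8 comma-delimited table with header
``replicate,patch,species,treatment,week,count`` — one row per weekly
observation, (replicate, patch, species, week) unique, weeks numeric (halves
allowed for interpolated outputs), counts non-negative. Row order on write is
deterministic (sorted by replicate, patch, species, week), so identical data
always produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .nbmodel import NBParams
from .series import LONG_COLUMNS, PatchTimeSeries, frame_to_series, series_to_frame

__all__ = ["read_series", "write_series", "RunConfig", "load_config"]

logger = logging.getLogger(__name__)


def read_series(path) -> list[PatchTimeSeries]:
    """Read and validate a long-format series file.

    Schema violations (missing columns, duplicate (replicate, patch, species,
    week) keys, negative counts, non-numeric weeks) raise a ValueError naming
    the offending rows (1-based data row numbers).
    """
    df = pd.read_csv(path, dtype={"replicate": str, "patch": str,
                                  "species": str, "treatment": str})
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: no observations", RuntimeWarning, stacklevel=2)
        return []
    for col in ("week", "count"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            raise ValueError(f"{path}: non-numeric {col} in rows {list(df.index[bad] + 1)}")
        df[col] = pd.to_numeric(df[col])
    neg = df["count"] < 0
    if neg.any():
        raise ValueError(f"{path}: negative counts in rows {list(df.index[neg] + 1)}")
    dup = df.duplicated(subset=["replicate", "patch", "species", "week"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (replicate, patch, species, week) keys in rows "
            f"{list(df.index[dup] + 1)}"
        )
    return frame_to_series(df)


def write_series(series_set: list[PatchTimeSeries], path) -> Path:
    """Write a series set as a long-format file with deterministic row order."""
    path = Path(path)
    df = series_to_frame(series_set)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return path


_DEFAULTS = dict(
    R=2.718, a=0.1, S=0.7, c=1.0, sigma=0.1, dH=0.0, dP=0.0,
    n_patches=2, topology="pair", n_steps=1000, burn_in=500,
    n_reps=100, seed=0, threshold=None,
)


@dataclass
class RunConfig:
    """Flat simulation/pipeline configuration (YAML on disk)."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        merged = dict(_DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    @property
    def nb_params(self) -> NBParams:
        v = self.values
        return NBParams(R=v["R"], a=v["a"], S=v["S"], c=v["c"],
                        sigma=v["sigma"], dH=v["dH"], dP=v["dP"])

    @property
    def threshold(self) -> float:
        """Occupancy threshold; defaults to a tenth of the host equilibrium."""
        if self.values["threshold"] is not None:
            return float(self.values["threshold"])
        from .nbmodel import nb_equilibrium

        h_star, _ = nb_equilibrium(self.nb_params)
        return h_star / 10.0

    def config_hash(self) -> str:
        text = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=True)
        return path


def load_config(path, required: tuple[str, ...] = ()) -> RunConfig:
    """Load a YAML configuration; ``required`` keys must be present."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    for key in required:
        if key not in raw:
            raise ValueError(f"{path}: missing required configuration key {key!r}")
    return RunConfig(values=raw)
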