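"""Weekly patch-level abundance time series.

The experimental unit is one weekly adult count series for a single species
in a single habitat patch, nested within a replicate metapopulation and an
environmental (resource renewal) treatment. A full dataset is a flat list of
such series; helpers convert to and from a tidy long-format table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PatchTimeSeries", "series_to_frame", "frame_to_series"]

LONG_COLUMNS = ["replicate", "patch", "species", "treatment", "week", "count"]


@dataclass
class PatchTimeSeries:
    """One weekly count series for (replicate, patch, species, treatment)."""

    replicate: str
    patch: str
    species: str
    treatment: str
    weeks: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.weeks.shape != self.counts.shape or self.weeks.ndim != 1:
            raise ValueError("weeks and counts must be 1-d arrays of equal length")
        if self.weeks.size and not np.all(np.diff(self.weeks) > 0):
            raise ValueError("weeks must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.replicate, self.patch, self.species, self.treatment)

    def __len__(self) -> int:
        return self.weeks.size


def series_to_frame(series_set: list[PatchTimeSeries]) -> pd.DataFrame:
    """Stack series into a long-format table with deterministic row order."""
    frames = []
    for s in series_set:
        frames.append(
            pd.DataFrame(
                {
                    "replicate": s.replicate,
                    "patch": s.patch,
                    "species": s.species,
                    "treatment": s.treatment,
                    "week": s.weeks,
                    "count": s.counts,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=LONG_COLUMNS)
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(
        ["replicate", "patch", "species", "week"], kind="mergesort"
    ).reset_index(drop=True)


def frame_to_series(df: pd.DataFrame) -> list[PatchTimeSeries]:
    """Split a long-format table into per-(replicate, patch, species) series."""
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long-format table missing columns: {missing}")
    out = []
    for (rep, patch, species, treatment), grp in df.groupby(
        ["replicate", "patch", "species", "treatment"], sort=True
    ):
        grp = grp.sort_values("week")
        out.append(
            PatchTimeSeries(
                replicate=str(rep),
                patch=str(patch),
                species=str(species),
                treatment=str(treatment),
                weeks=grp["week"].to_numpy(dtype=float),
                counts=grp["count"].to_numpy(dtype=float),
            )
        )
    return out
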