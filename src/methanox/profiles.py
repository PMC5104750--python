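"""Water-column profile container and delimited-text IO.

A :class:`Profile` is a thin wrapper around a depth-indexed pandas DataFrame:
one row per sampling depth (metres, positive downward, strictly increasing)
and one column per analyte.  Column names follow a ``<analyte>_<unit>``
convention, e.g. ``o2_uM``, ``ch4_uM``, ``d13c_ch4_permil``.  Missing values
are NaN; per-analyte accessors drop them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["Profile", "MissingAnalyteError", "read_profile", "write_profile"]

DEPTH_COLUMN = "depth_m"


class MissingAnalyteError(KeyError):
    """Requested analyte column is absent or entirely NaN."""


@dataclass
class Profile:
    """Depth-ordered water-column measurements."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if DEPTH_COLUMN not in self.data.columns:
            raise ValueError(f"profile table needs a {DEPTH_COLUMN!r} column")
        if len(self.data) == 0:
            raise ValueError("profile table is empty")
        self.data = self.data.sort_values(DEPTH_COLUMN).reset_index(drop=True)
        depths = self.data[DEPTH_COLUMN].to_numpy(float)
        if not np.all(np.isfinite(depths)):
            raise ValueError("depths must be finite")
        if np.any(np.diff(depths) <= 0):
            raise ValueError("depths must be strictly increasing")

    @property
    def depths(self) -> np.ndarray:
        return self.data[DEPTH_COLUMN].to_numpy(float)

    @property
    def analytes(self) -> list[str]:
        return [c for c in self.data.columns if c != DEPTH_COLUMN]

    def has(self, analyte: str) -> bool:
        return analyte in self.data.columns and self.data[analyte].notna().any()

    def analyte(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (depths, values) for one analyte with NaNs dropped."""
        if name not in self.data.columns:
            raise MissingAnalyteError(name)
        sub = self.data[[DEPTH_COLUMN, name]].dropna()
        if len(sub) == 0:
            raise MissingAnalyteError(f"{name} has no finite values")
        return sub[DEPTH_COLUMN].to_numpy(float), sub[name].to_numpy(float)

    def __len__(self) -> int:
        return len(self.data)


def read_profile(path: str | Path) -> Profile:
    """Read a comma-separated profile table (UTF-8, '.' decimal, header row)."""
    frame = pd.read_csv(path)
    return Profile(frame)


def write_profile(profile: Profile, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    profile.data.to_csv(path, index=False)
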