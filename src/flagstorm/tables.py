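"""Localization tables: the common currency between pipeline stages.

A :class:`LocalizationTable` is a thin wrapper around a pandas DataFrame with
a fixed column schema (all coordinates in nanometres) plus provenance
metadata.  Every stage of the pipeline consumes and/or produces one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

#: Required columns, in canonical order.
REQUIRED_COLUMNS = ("frame", "x_nm", "y_nm", "z_nm", "photons")
#: Optional fitted-width columns produced by the localization stage.
OPTIONAL_COLUMNS = ("sigma_x_nm", "sigma_y_nm")

UNIT = "nm"


@dataclass
class LocalizationTable:
    """Per-molecule 3D localizations with provenance metadata.

    Parameters
    ----------
    df
        DataFrame with columns ``frame, x_nm, y_nm, z_nm, photons`` and
        optionally ``sigma_x_nm, sigma_y_nm``.
    source
        One of ``"synthetic"``, ``"fitted"`` or ``"file"``.
    seed
        Seed used when ``source == "synthetic"``, else ``None``.
    """

    df: pd.DataFrame
    source: str = "synthetic"
    unit: str = UNIT
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ParameterError(f"localization table missing columns: {missing}")
        if self.unit != UNIT:
            raise ParameterError(f"localization coordinates must be in {UNIT!r}, got {self.unit!r}")
        coords = self.df[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
        if coords.size and not np.all(np.isfinite(coords)):
            raise ParameterError("localization coordinates must be finite")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) coordinate array in nm."""
        return self.df[["x_nm", "y_nm", "z_nm"]].to_numpy(float)

    @classmethod
    def from_arrays(
        cls,
        *,
        frame: np.ndarray,
        xyz: np.ndarray,
        photons: np.ndarray,
        sigma_x_nm: np.ndarray | None = None,
        sigma_y_nm: np.ndarray | None = None,
        source: str = "synthetic",
        seed: int | None = None,
    ) -> "LocalizationTable":
        xyz = np.asarray(xyz, float).reshape(-1, 3)
        data = {
            "frame": np.asarray(frame, int),
            "x_nm": xyz[:, 0],
            "y_nm": xyz[:, 1],
            "z_nm": xyz[:, 2],
            "photons": np.asarray(photons, float),
        }
        if sigma_x_nm is not None:
            data["sigma_x_nm"] = np.asarray(sigma_x_nm, float)
            data["sigma_y_nm"] = np.asarray(sigma_y_nm, float)
        return cls(pd.DataFrame(data), source=source, seed=seed)

    def empty_like(self) -> "LocalizationTable":
        return LocalizationTable(self.df.iloc[0:0].copy(), source=self.source, seed=self.seed)
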