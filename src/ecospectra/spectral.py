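"""Container and plain-text round-tripping for power spectral densities.

Convention (locked package-wide): two-sided spectra on an angular-frequency
axis, normalised so that the stationary variance of a component equals
(1/2pi) * integral of its spectrum over the whole real line. Only the
nonnegative half-axis is stored; spectra of real processes are even in omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONVENTION = "two-sided, angular-frequency, variance = (1/2pi) * integral"

__all__ = ["SpectralDensity", "CONVENTION"]


@dataclass
class SpectralDensity:
    """A (mean or per-species) power spectral density on an omega >= 0 grid.

    ``values`` is either a vector (mean spectrum) or a matrix with one column
    per species, rows aligned with ``omegas``.
    """

    omegas: np.ndarray
    values: np.ndarray
    convention: str = CONVENTION
    columns: list[str] | None = None

    def __post_init__(self) -> None:
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.omegas.ndim != 1:
            raise ValueError("omegas must be one-dimensional")
        if np.any(np.diff(self.omegas) <= 0):
            raise ValueError("omegas must be strictly increasing")
        if self.values.shape[0] != self.omegas.size:
            raise ValueError("values rows must align with omegas")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < -1e-12):
            raise ValueError("power spectral density must be nonnegative")

    @property
    def mean(self) -> np.ndarray:
        """Mean spectrum across columns (identity for a vector-valued PSD)."""
        if self.values.ndim == 1:
            return self.values
        return self.values.mean(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        vals = self.values if self.values.ndim == 2 else self.values[:, None]
        if self.columns is not None:
            names = list(self.columns)
        elif vals.shape[1] == 1:
            names = ["phi_mean"]
        else:
            names = [f"phi_{k}" for k in range(vals.shape[1])]
        df = pd.DataFrame(vals, columns=names)
        df.insert(0, "omega", self.omegas)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpectralDensity":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        if "omega" not in df.columns:
            raise ValueError("spectral TSV must have an 'omega' header column")
        omegas = df.pop("omega").to_numpy()
        values = df.to_numpy()
        if values.shape[1] == 1:
            return cls(omegas=omegas, values=values[:, 0], columns=list(df.columns))
        return cls(omegas=omegas, values=values, columns=list(df.columns))
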