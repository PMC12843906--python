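"""Fixed-width sub-interval partitioning of the spectral axis.

The full grid is split into contiguous bands of ``width_points`` columns
(default 50, giving 31 bands on the canonical 1550-point grid).  Bands are
numbered from 1 starting at the high-wavenumber end.  Band subsets selected
downstream (interval PLS, ant-colony search) are materialised by
concatenating the bands' columns in ascending band order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral_io import WavenumberGrid

__all__ = ["IntervalScheme", "partition", "band_wavenumber_table", "extract_bands"]


@dataclass(frozen=True)
class IntervalScheme:
    """Partition of ``n_points`` columns into equal bands of ``width_points``."""

    n_points: int
    width_points: int

    def __post_init__(self) -> None:
        if self.width_points < 1:
            raise ValueError("width_points must be >= 1")
        if self.n_points % self.width_points != 0:
            raise ValueError(
                f"{self.n_points} points not divisible by width {self.width_points}"
                " (ragged final band not supported)"
            )

    @property
    def n_intervals(self) -> int:
        return self.n_points // self.width_points

    def band_slice(self, band: int) -> slice:
        """Half-open column range of 1-indexed ``band``."""
        if not 1 <= band <= self.n_intervals:
            raise ValueError(f"band {band} outside 1..{self.n_intervals}")
        start = (band - 1) * self.width_points
        return slice(start, start + self.width_points)


def partition(grid: WavenumberGrid, width_points: int = 50) -> IntervalScheme:
    """Partition a grid into equal-width sub-intervals."""
    return IntervalScheme(grid.n_points, width_points)


def band_wavenumber_table(scheme: IntervalScheme, grid: WavenumberGrid) -> pd.DataFrame:
    """Per-band (first, last) wavenumbers, rounded to integer cm^-1."""
    if grid.n_points != scheme.n_points:
        raise ValueError("grid length does not match scheme")
    rows = []
    for band in range(1, scheme.n_intervals + 1):
        sl = scheme.band_slice(band)
        rows.append(
            {
                "band": band,
                "first_cm": int(round(grid.values[sl.start])),
                "last_cm": int(round(grid.values[sl.stop - 1])),
            }
        )
    return pd.DataFrame(rows)


def extract_bands(X: np.ndarray, scheme: IntervalScheme, bands) -> np.ndarray:
    """Concatenate the columns of the named bands, ascending band order.

    Duplicate or out-of-range band indices are refused.
    """
    X = np.atleast_2d(np.asarray(X))
    if X.shape[1] != scheme.n_points:
        raise ValueError(
            f"matrix has {X.shape[1]} columns, scheme expects {scheme.n_points}"
        )
    bands = list(bands)
    if len(bands) != len(set(bands)):
        raise ValueError("duplicate band indices")
    cols = [X[:, scheme.band_slice(int(b))] for b in sorted(bands)]
    return np.hstack(cols)
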