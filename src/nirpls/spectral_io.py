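"""Spectra and concentration-table I/O.

Absorbance spectra live in a :class:`SpectraSet`: an ``n_rows x P`` matrix of
absorbance values bound to a strictly descending, uniform wavenumber grid
(cm^-1), with one row per (sample, replicate) scan.  Reference compositions
live in a :class:`ConcentrationTable`, a thin wrapper over a pandas DataFrame
holding the mass fractions (w/w%) of the two polymorphic impurities
(anhydrate ``an_cfz`` and monohydrate ``mono_cfz``), the hemihydrate API
``hemi_cfz``, and the excipients, plus a calibration/validation role flag.

Both objects read and write plain CSV.  The spectra CSV layout is: columns
``sample_id, replicate_id`` followed by one column per wavenumber (header is
the wavenumber printed to two decimals, descending).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WavenumberGrid",
    "SpectraSet",
    "ConcentrationTable",
    "canonical_grid",
    "read_spectra",
    "write_spectra",
    "read_concentrations",
    "write_concentrations",
    "average_replicates",
]

#: Tolerance (relative to spacing) for declaring a grid non-uniform.
_GRID_RTOL = 1e-6

# Canonical instrument grid: 1550 points descending from 9974.2 cm^-1 in
# steps of 3.8571 cm^-1, spanning ~9974-4000 cm^-1.
CANONICAL_N_POINTS = 1550
CANONICAL_START = 9974.2
CANONICAL_SPACING = 3.8571


class GridError(ValueError):
    """Raised when a wavenumber header violates the grid invariants."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform, strictly descending wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise GridError("grid needs at least two wavenumber values")
        diffs = np.diff(values)
        if np.any(diffs >= 0):
            raise GridError("wavenumber grid must be strictly decreasing")
        step = -diffs
        nominal = step.mean()
        # headers are stored to 2 decimals, so each step may deviate from
        # the nominal spacing by up to 0.01 cm^-1 from rounding alone
        tol = max(_GRID_RTOL * nominal, 0.0105)
        if np.any(np.abs(step - nominal) > tol):
            raise GridError(
                f"wavenumber grid is not uniform (steps range "
                f"{step.min():.6g}..{step.max():.6g} cm^-1)"
            )

    @property
    def spacing(self) -> float:
        """Nominal step between consecutive points, in cm^-1 (positive)."""
        return float(self.values[0] - self.values[1])

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_points

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values, atol=0.01)
        )


def canonical_grid(
    n_points: int = CANONICAL_N_POINTS,
    start: float = CANONICAL_START,
    spacing: float = CANONICAL_SPACING,
) -> WavenumberGrid:
    """The default 1550-point grid descending from ~9974 to ~4000 cm^-1."""
    return WavenumberGrid(start - spacing * np.arange(n_points))


@dataclass
class SpectraSet:
    """Absorbance matrix bound to a grid and per-row sample/replicate ids."""

    sample_ids: np.ndarray
    replicate_ids: np.ndarray
    absorbance: np.ndarray
    grid: WavenumberGrid
    roles: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.replicate_ids = np.asarray(self.replicate_ids, dtype=int)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, p = self.absorbance.shape
        if p != self.grid.n_points:
            raise ValueError(
                f"absorbance has {p} columns but grid has {self.grid.n_points} points"
            )
        if self.sample_ids.size != n or self.replicate_ids.size != n:
            raise ValueError("sample_ids/replicate_ids length must match row count")
        if n and not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if self.roles is not None:
            self.roles = np.asarray(self.roles, dtype=object)
            if self.roles.size != n:
                raise ValueError("roles length must match row count")

    @property
    def n_rows(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    def unique_samples(self) -> list:
        """Sample ids in first-appearance order."""
        seen: dict = {}
        for sid in self.sample_ids:
            seen.setdefault(sid, None)
        return list(seen)

    def subset_samples(self, sample_ids) -> "SpectraSet":
        wanted = set(sample_ids)
        mask = np.array([sid in wanted for sid in self.sample_ids])
        return SpectraSet(
            self.sample_ids[mask],
            self.replicate_ids[mask],
            self.absorbance[mask],
            self.grid,
            None if self.roles is None else self.roles[mask],
        )

    def with_absorbance(self, matrix: np.ndarray) -> "SpectraSet":
        """Same metadata, new absorbance matrix (shape must be preserved)."""
        return SpectraSet(
            self.sample_ids, self.replicate_ids, np.asarray(matrix, float),
            self.grid, self.roles,
        )


def read_spectra(path) -> SpectraSet:
    """Read a spectra CSV into a :class:`SpectraSet`.

    The header row is ``sample_id, replicate_id, <wavenumbers...>``.  An
    ascending wavenumber header is accepted and silently reversed to the
    internal descending convention (a notice is logged).
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected sample_id, replicate_id and >=2 wavenumber columns")
    try:
        wavenumbers = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavenumber header: {exc}") from exc
    body = df.iloc[:, 2:]
    bad = body.map(lambda v: not np.isfinite(pd.to_numeric(v, errors="coerce")))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric absorbance at row {r + 1}, column {body.columns[c]!r}"
        )
    matrix = body.to_numpy(dtype=float)
    if wavenumbers.size >= 2 and wavenumbers[0] < wavenumbers[-1]:
        logger.info("ascending wavenumber header in %s reversed to descending", path)
        wavenumbers = wavenumbers[::-1]
        matrix = matrix[:, ::-1]
    grid = WavenumberGrid(wavenumbers)
    return SpectraSet(
        df.iloc[:, 0].to_numpy(dtype=object),
        df.iloc[:, 1].to_numpy(dtype=int),
        matrix,
        grid,
    )


def write_spectra(spectra: SpectraSet, path) -> None:
    """Write a :class:`SpectraSet` as CSV (descending wavenumber header)."""
    header = [f"{w:.2f}" for w in spectra.grid.values]
    df = pd.DataFrame(spectra.absorbance, columns=header)
    df.insert(0, "replicate_id", spectra.replicate_ids)
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")


_CONC_COLUMNS = ["sample_id", "an_cfz", "mono_cfz", "hemi_cfz", "excipients", "role"]


class ConcentrationTable:
    """Per-sample composition in w/w% with a calibration/validation role.

    Invariants: every fraction lies in [0, 100]; the four component columns
    sum to 100 per sample; ``total_impurity`` is the anhydrate + monohydrate
    sum and is always derived, never stored.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _CONC_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"concentration table missing columns {missing}")
        frame = frame.loc[:, _CONC_COLUMNS].reset_index(drop=True).copy()
        frame["sample_id"] = frame["sample_id"].astype(str)
        comps = frame[["an_cfz", "mono_cfz", "hemi_cfz", "excipients"]].to_numpy(float)
        if np.any(comps < -1e-12) or np.any(comps > 100 + 1e-12):
            raise ValueError("component fractions must lie in [0, 100] w/w%")
        total = comps.sum(axis=1)
        if np.any(np.abs(total - 100.0) > 1e-9):
            bad = frame.loc[np.abs(total - 100.0) > 1e-9, "sample_id"].iloc[0]
            raise ValueError(f"sample {bad!r}: component fractions do not sum to 100")
        self.frame = frame

    @property
    def sample_ids(self) -> np.ndarray:
        return self.frame["sample_id"].to_numpy(dtype=object)

    def responses(self, sample_ids=None) -> np.ndarray:
        """Response matrix with columns (an_cfz, mono_cfz, total_impurity)."""
        df = self.frame.set_index("sample_id")
        if sample_ids is not None:
            df = df.loc[[str(s) for s in sample_ids]]
        an = df["an_cfz"].to_numpy(float)
        mono = df["mono_cfz"].to_numpy(float)
        return np.column_stack([an, mono, an + mono])

    def role_ids(self, role: str) -> list:
        return list(self.frame.loc[self.frame["role"] == role, "sample_id"])

    def __len__(self) -> int:
        return len(self.frame)


def read_concentrations(path) -> ConcentrationTable:
    return ConcentrationTable(pd.read_csv(path, dtype={"sample_id": str}))


def write_concentrations(table: ConcentrationTable, path) -> None:
    table.frame.to_csv(path, index=False, float_format="%.17g")


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """Collapse replicate scans into one mean spectrum per sample.

    Replicate counts must be equal across samples (the standard balanced
    triplicate protocol); an unbalanced set raises with the offending sample
    named.
    """
    order = spectra.unique_samples()
    counts = {sid: int(np.sum(spectra.sample_ids == sid)) for sid in order}
    n_rep = counts[order[0]]
    for sid, cnt in counts.items():
        if cnt != n_rep:
            raise ValueError(
                f"sample {sid!r} has {cnt} replicates; expected {n_rep}"
            )
    rows = []
    roles = [] if spectra.roles is not None else None
    for sid in order:
        mask = spectra.sample_ids == sid
        rows.append(spectra.absorbance[mask].mean(axis=0))
        if roles is not None:
            roles.append(spectra.roles[mask][0])
    return SpectraSet(
        np.array(order, dtype=object),
        np.zeros(len(order), dtype=int),
        np.vstack(rows),
        spectra.grid,
        None if roles is None else np.array(roles, dtype=object),
    )
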