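"""Seeded synthetic tablet NIR datasets.

Real tablet spectra for this problem are not publicly deposited, so the
package ships a generator that emulates their statistical structure: a
Beer-Lambert additive mixture of four component spectra (anhydrate and
monohydrate impurities, the hemihydrate API host, and a pooled excipient),
degraded by the artifacts scatter-correction and derivative preprocessing
are designed to remove — multiplicative gain, additive offset, smooth
polynomial baseline drift, and white measurement noise.

The default mixture design mirrors the study layout this package targets:
41 calibration tablets whose impurity pairs cover the 0-10 w/w% square,
plus 6 validation tablets at matched anhydrate/monohydrate levels of
0.5, 1.5, 2.5, 3.5, 4.5 and 5.0 w/w%, each measured in triplicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectral_io import (
    ConcentrationTable,
    SpectraSet,
    WavenumberGrid,
    canonical_grid,
)

__all__ = [
    "ComponentSpectrumModel",
    "MixtureDesign",
    "NoiseModel",
    "default_component_library",
    "build_design",
    "synthesize",
    "simulate_dataset",
    "emulate_validation_protocol",
    "VALIDATION_LEVELS",
    "ANCHOR_CAL_PAIRS",
]

#: Matched impurity levels (w/w%) of the six validation tablets.
VALIDATION_LEVELS = (0.5, 1.5, 2.5, 3.5, 4.5, 5.0)

#: (anhydrate, monohydrate) pairs always present in the calibration design.
ANCHOR_CAL_PAIRS = ((10.0, 0.0), (5.0, 2.5), (1.5, 3.5), (2.5, 5.0), (0.0, 10.0))

#: Tablet mass fraction of excipients; API (hemihydrate + impurities) is the
#: rest, i.e. a 1:2 API:excipient mass ratio.
EXCIPIENT_FRACTION = 200.0 / 3.0
API_FRACTION = 100.0 - EXCIPIENT_FRACTION


@dataclass(frozen=True)
class ComponentSpectrumModel:
    """Pure-component NIR signature as a sum of Gaussian bands.

    Each peak is (center cm^-1, sigma cm^-1, amplitude in AU per w/w%).
    """

    name: str
    peaks: tuple

    def spectrum(self, grid: WavenumberGrid) -> np.ndarray:
        """Absorbance per w/w% of this component on ``grid``."""
        out = np.zeros(grid.n_points)
        for center, sigma, amplitude in self.peaks:
            if sigma <= 0:
                raise ValueError(f"{self.name}: peak sigma must be positive")
            if amplitude < 0:
                raise ValueError(f"{self.name}: peak amplitude must be >= 0")
            out += amplitude * np.exp(-0.5 * ((grid.values - center) / sigma) ** 2)
        return out


def default_component_library() -> list[ComponentSpectrumModel]:
    """Four-component library anchored at the diagnostic wavenumbers.

    The hydrates carry the crystal-water combination band near 5099 cm^-1
    (strong in the monohydrate, weaker in the hemihydrate) and the
    hydroxyl/hydrogen-bond overtones near 6913 and 6811 cm^-1; the anhydrate
    has no water band near 5099 cm^-1; the excipient dominates the
    9010-7471 cm^-1 overtone region, including the carbonyl overtone near
    8621 cm^-1.
    """
    return [
        ComponentSpectrumModel(
            "An",
            (
                (8553.0, 45.0, 0.0042),
                (6652.0, 42.0, 0.0058),
                (5897.0, 38.0, 0.0051),
                (4451.0, 40.0, 0.0037),
            ),
        ),
        ComponentSpectrumModel(
            "Hemi",
            (
                (6913.0, 40.0, 0.0046),
                (6811.0, 38.0, 0.0041),
                (5099.0, 35.0, 0.0027),
                (8404.0, 48.0, 0.0033),
                (4603.0, 42.0, 0.0039),
            ),
        ),
        ComponentSpectrumModel(
            "Mono",
            (
                (5099.0, 36.0, 0.0062),
                (6913.0, 41.0, 0.0024),
                (6811.0, 39.0, 0.0021),
                (6052.0, 40.0, 0.0035),
                (5247.0, 34.0, 0.0029),
            ),
        ),
        ComponentSpectrumModel(
            "Excipient",
            (
                (8621.0, 55.0, 0.0110),
                (8902.0, 60.0, 0.0074),
                (7804.0, 52.0, 0.0088),
                (7553.0, 48.0, 0.0061),
                (5804.0, 58.0, 0.0034),
                (4398.0, 55.0, 0.0046),
            ),
        ),
    ]


@dataclass(frozen=True)
class MixtureDesign:
    """A concentration table plus the replicate count per tablet."""

    table: ConcentrationTable
    replicates: int = 3


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-artifact model; all levels in absorbance units (AU).

    ``gain_sd`` is the relative sd of a per-replicate multiplicative gain
    (particle-size / path-length scatter); ``baseline_scale`` scales the
    random degree-``baseline_degree`` polynomial drift added per replicate.
    """

    additive_sd: float = 5e-4
    gain_sd: float = 0.01
    offset_sd: float = 2e-3
    baseline_degree: int = 2
    baseline_scale: float = 5e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "gain_sd", "offset_sd", "baseline_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0, 0.0, seed)


def _composition_row(sample_id: str, an: float, mono: float, role: str) -> dict:
    hemi = API_FRACTION - an - mono
    if hemi < -1e-9:
        raise ValueError(
            f"sample {sample_id}: impurity total {an + mono:.4f} exceeds "
            f"API fraction {API_FRACTION:.4f}"
        )
    return {
        "sample_id": sample_id,
        "an_cfz": an,
        "mono_cfz": mono,
        "hemi_cfz": max(hemi, 0.0),
        "excipients": EXCIPIENT_FRACTION,
        "role": role,
    }


def build_design(
    n_cal: int = 41,
    impurity_max: float = 10.0,
    seed: int = 0,
    replicates: int = 3,
) -> MixtureDesign:
    """Calibration/validation mixture design over the impurity square.

    The calibration set always contains the anchor pairs of
    :data:`ANCHOR_CAL_PAIRS`, the blank tablet, and the six matched
    validation levels (validation tablets are re-prepared at concentration
    levels the calibration set also covers); the remaining points are a
    seeded space-filling sample of the triangle an + mono <= impurity_max.
    """
    if n_cal < 5:
        raise ValueError("n_cal must be >= 5")
    if impurity_max > API_FRACTION:
        raise ValueError(
            f"impurity_max {impurity_max} exceeds API fraction {API_FRACTION:.4f}: "
            "infeasible design"
        )
    scale = impurity_max / 10.0
    fixed = [(a * scale, m * scale) for a, m in ANCHOR_CAL_PAIRS]
    fixed.append((0.0, 0.0))
    fixed.extend((lvl * scale, lvl * scale) for lvl in VALIDATION_LEVELS)
    fixed = fixed[:n_cal]
    rng = np.random.default_rng(seed)
    pairs = list(fixed)
    while len(pairs) < n_cal:
        an, mono = rng.uniform(0.0, impurity_max, size=2)
        if an + mono <= impurity_max:
            pairs.append((float(an), float(mono)))
    rows = [
        _composition_row(f"C{i + 1:02d}", an, mono, "calibration")
        for i, (an, mono) in enumerate(pairs)
    ]
    rows += [
        _composition_row(f"V{i + 1}", lvl * scale, lvl * scale, "validation")
        for i, lvl in enumerate(VALIDATION_LEVELS)
    ]
    return MixtureDesign(ConcentrationTable(pd.DataFrame(rows)), replicates)


def _mix(concs: dict, signatures: dict, n_points: int) -> np.ndarray:
    out = np.zeros(n_points)
    for name, c in concs.items():
        out += c * signatures[name]
    return out


def synthesize(
    design: MixtureDesign,
    library: list[ComponentSpectrumModel] | None = None,
    noise: NoiseModel | None = None,
    grid: WavenumberGrid | None = None,
) -> tuple[SpectraSet, ConcentrationTable]:
    """Render a mixture design into replicate spectra.

    Each replicate row is ``gain * sum_k c_k s_k + baseline + offset + eps``
    with ``gain ~ N(1, gain_sd)``; at zero noise the spectra are an exact
    linear map of the concentrations.  Fully determined by ``noise.seed``.
    """
    library = default_component_library() if library is None else library
    noise = NoiseModel() if noise is None else noise
    grid = canonical_grid() if grid is None else grid
    signatures = {c.name: c.spectrum(grid) for c in library}
    name_map = {"an_cfz": "An", "mono_cfz": "Mono", "hemi_cfz": "Hemi", "excipients": "Excipient"}
    rng = np.random.default_rng(noise.seed)
    # domain [-1, 1] for the baseline polynomial, independent of grid units
    x01 = np.linspace(-1.0, 1.0, grid.n_points)
    rows, sids, rids, roles = [], [], [], []
    for _, rec in design.table.frame.iterrows():
        concs = {name_map[k]: float(rec[k]) for k in name_map}
        clean = _mix(concs, signatures, grid.n_points)
        for rep in range(1, design.replicates + 1):
            gain = 1.0 + noise.gain_sd * rng.standard_normal()
            offset = noise.offset_sd * rng.standard_normal()
            if noise.baseline_scale > 0 and noise.baseline_degree >= 0:
                coef = noise.baseline_scale * rng.standard_normal(noise.baseline_degree + 1)
                baseline = np.polynomial.polynomial.polyval(x01, coef)
            else:
                baseline = 0.0
            eps = noise.additive_sd * rng.standard_normal(grid.n_points)
            rows.append(gain * clean + baseline + offset + eps)
            sids.append(rec["sample_id"])
            rids.append(rep)
            roles.append(rec["role"])
    spectra = SpectraSet(
        np.array(sids, dtype=object),
        np.array(rids, dtype=int),
        np.vstack(rows),
        grid,
        np.array(roles, dtype=object),
    )
    return spectra, design.table


def simulate_dataset(
    seed: int = 0,
    n_cal: int = 41,
    impurity_max: float = 10.0,
    noise: NoiseModel | None = None,
    grid: WavenumberGrid | None = None,
) -> tuple[SpectraSet, ConcentrationTable]:
    """One-call default dataset: design, library and noise at their defaults."""
    noise = NoiseModel(seed=seed) if noise is None else replace(noise, seed=seed)
    design = build_design(n_cal=n_cal, impurity_max=impurity_max, seed=seed)
    return synthesize(design, noise=noise, grid=grid)


def emulate_validation_protocol(
    level: float = 4.5,
    n_repeats: int = 6,
    seed: int = 0,
    library: list[ComponentSpectrumModel] | None = None,
    noise: NoiseModel | None = None,
    grid: WavenumberGrid | None = None,
) -> dict[str, SpectraSet]:
    """Repeat-measurement sets for precision / repeatability / stability.

    The physical protocol re-measures one tablet at matched impurity levels
    (default 4.5 w/w% each).  Synthetically the three figures of merit are
    emulated as independent noise redraws: *precision* draws measurement
    noise only, *repeatability* adds the repack gain/offset scatter, and
    *stability* adds slow baseline drift on top of measurement noise.
    """
    noise = NoiseModel() if noise is None else noise
    base = NoiseModel(
        additive_sd=noise.additive_sd, gain_sd=0.0, offset_sd=0.0,
        baseline_degree=noise.baseline_degree, baseline_scale=0.0, seed=seed,
    )
    modes = {
        "precision": base,
        "repeatability": replace(
            base, gain_sd=noise.gain_sd, offset_sd=noise.offset_sd, seed=seed + 1
        ),
        "stability": replace(base, baseline_scale=noise.baseline_scale, seed=seed + 2),
    }
    row = _composition_row("R1", level, level, "validation")
    table = ConcentrationTable(pd.DataFrame([row]))
    out = {}
    for mode, nm in modes.items():
        design = MixtureDesign(table, replicates=n_repeats)
        spectra, _ = synthesize(design, library=library, noise=nm, grid=grid)
        out[mode] = spectra
    return out
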