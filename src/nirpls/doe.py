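"""L9(3^4) orthogonal screening of the band-selection pipeline.

Four factors at three levels each — A: number of ants {100, 200, 300},
B: pheromone evaporation rate {0.3, 0.5, 0.7}, C: number of selected bands
{5, 10, 15}, D: pretreatment {SG1st, SG2nd, SG2nd+WT} — are screened in the
standard nine-run orthogonal array: every level appears three times per
factor, and every ordered pair of levels appears exactly once across any
two factors.  Per-run response is the averaged held-out RMSEP of the
pipeline executed at that run's settings.

Range analysis summarises the nine responses per factor: k1, k2, k3 are the
mean responses at each level, R = max(k) - min(k) ranks factor influence,
and the per-factor argmin levels form the recommended combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aco_select import ACOConfig, run_aco
from .intervals import extract_bands, partition
from .pls_core import fit_plsr, predict
from .preprocess import PreprocessSpec, apply as apply_preprocess
from .spectral_io import ConcentrationTable, SpectraSet, average_replicates

__all__ = ["OrthogonalDesign", "RangeAnalysis", "build_l9", "execute_design",
           "range_analysis", "FACTOR_LEVELS"]

FACTOR_LEVELS: dict[str, tuple] = {
    "A": (100, 200, 300),
    "B": (0.3, 0.5, 0.7),
    "C": (5, 10, 15),
    "D": ("SG1st", "SG2nd", "SG2nd+WT"),
}

# L9(3^4) level indices (1-based), one row per run.
_L9 = (
    (1, 1, 1, 1),
    (1, 2, 2, 2),
    (1, 3, 3, 3),
    (2, 1, 2, 3),
    (2, 2, 3, 1),
    (2, 3, 1, 2),
    (3, 1, 3, 2),
    (3, 2, 1, 3),
    (3, 3, 2, 1),
)


@dataclass(frozen=True)
class OrthogonalDesign:
    """Nine-run assignment of factor levels."""

    runs: tuple  # tuple of dicts factor -> level value
    level_index: tuple  # tuple of dicts factor -> 1-based level index

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(list(self.runs))
        df.insert(0, "run", range(1, len(self.runs) + 1))
        return df


@dataclass(frozen=True)
class RangeAnalysis:
    """k-level means, ranges, factor ranking and recommended levels."""

    k: dict          # factor -> np.ndarray of 3 level means (k1, k2, k3)
    range_r: dict    # factor -> max(k) - min(k)
    ranking: tuple   # factors, descending R
    best_combo: dict  # factor -> level value minimising k

    def adjusted_combo(self, factor: str = "C", preferred_level=10,
                       tolerance: float = 0.05) -> dict:
        """Best combo with an efficiency preference on one factor.

        If the preferred level's mean response is within ``tolerance``
        (w/w%) of that factor's minimum, it replaces the strict argmin —
        e.g. preferring 10 selected bands over 5 when their mean RMSEPs are
        practically tied, since more bands separate co-varying components
        better at negligible cost.
        """
        combo = dict(self.best_combo)
        levels = FACTOR_LEVELS[factor]
        if preferred_level not in levels:
            raise ValueError(f"{preferred_level!r} is not a level of factor {factor}")
        k = self.k[factor]
        if k[levels.index(preferred_level)] - k.min() <= tolerance:
            combo[factor] = preferred_level
        return combo


def build_l9() -> OrthogonalDesign:
    """The standard L9(3^4) array over (A, B, C, D)."""
    runs = []
    index = []
    for row in _L9:
        index.append(dict(zip("ABCD", row)))
        runs.append({f: FACTOR_LEVELS[f][lvl - 1] for f, lvl in zip("ABCD", row)})
    return OrthogonalDesign(tuple(runs), tuple(index))


def execute_design(
    design: OrthogonalDesign,
    spectra: SpectraSet,
    concentrations: ConcentrationTable,
    n_lvs: int = 5,
    seed: int = 0,
    width_points: int = 50,
    n_iterations: int = 30,
    stagnation_limit: int = 10,
    ants_scale: float = 1.0,
) -> np.ndarray:
    """Run the pipeline once per design row; returns 9 averaged RMSEPs.

    Per run: average replicates, preprocess per factor D, partition, run the
    colony at (A, B, C) with held-out RMSEP fitness on the validation
    samples, fit the final PLS model on the selected bands and score it on
    the validation set.  One child seed per run is derived from ``seed``;
    ``ants_scale`` < 1 shrinks colonies proportionally for reduced-size
    screening runs.
    """
    averaged = average_replicates(spectra)
    cal_ids = concentrations.role_ids("calibration")
    val_ids = concentrations.role_ids("validation")
    if not cal_ids or not val_ids:
        raise ValueError("dataset must contain calibration and validation samples")
    cal = averaged.subset_samples(cal_ids)
    val = averaged.subset_samples(val_ids)
    Y_cal = concentrations.responses(cal.sample_ids)
    Y_val = concentrations.responses(val.sample_ids)
    scheme = partition(spectra.grid, width_points)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(design.runs)) % (2**31)
    responses = np.empty(len(design.runs))
    for i, run in enumerate(design.runs):
        spec = PreprocessSpec(method=run["D"])
        X_cal = apply_preprocess(cal.absorbance, spec)
        X_val = apply_preprocess(val.absorbance, spec)
        config = ACOConfig(
            n_ants=max(1, int(round(run["A"] * ants_scale))),
            evaporation_rate=run["B"],
            n_bands=run["C"],
            n_iterations=n_iterations,
            stagnation_limit=stagnation_limit,
            seed=int(child_seeds[i]),
        )
        result = run_aco(
            X_cal, Y_cal, scheme, config, n_lvs=n_lvs,
            metric="rmsep", X_val=X_val, Y_val=Y_val,
        )
        model = fit_plsr(extract_bands(X_cal, scheme, result.best_bands), Y_cal, n_lvs)
        resid = Y_val - predict(model, extract_bands(X_val, scheme, result.best_bands))
        responses[i] = float(np.sqrt(np.mean(resid**2, axis=0)).mean())
    return responses


def range_analysis(design: OrthogonalDesign, responses) -> RangeAnalysis:
    """k1/k2/k3 level means, per-factor range R, ranking and best levels."""
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (len(design.runs),):
        raise ValueError(f"expected {len(design.runs)} responses, got {responses.shape}")
    k: dict[str, np.ndarray] = {}
    range_r: dict[str, float] = {}
    best: dict[str, object] = {}
    for factor in "ABCD":
        means = np.array([
            responses[[idx[factor] == lvl for idx in design.level_index]].mean()
            for lvl in (1, 2, 3)
        ])
        k[factor] = means
        range_r[factor] = float(means.max() - means.min())
        best[factor] = FACTOR_LEVELS[factor][int(np.argmin(means))]
    ranking = tuple(sorted("ABCD", key=lambda f: -range_r[f]))
    return RangeAnalysis(k=k, range_r=range_r, ranking=ranking, best_combo=best)
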