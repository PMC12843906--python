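"""End-to-end calibration and validation orchestration.

``calibrate_pipeline`` runs the full chain on a dataset with calibration
roles: replicate averaging, pretreatment (second-derivative by default),
sub-interval partitioning, ant-colony band selection, latent-variable count
selection by the RMSEC < 0.3 w/w% rule, and the final multi-response PLS
fit with its calibration metrics.  ``validate_pipeline`` scores a fitted
calibration on held-out samples and produces the figure-of-merit report
(per-sample predictions, mean absolute errors, precision/repeatability/
stability RSDs, LOD/LOQ).  Models round-trip through a checksummed JSON
text bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .aco_select import ACOConfig, ACOResult, run_aco
from .intervals import IntervalScheme, extract_bands, partition
from .pls_core import (
    PLSModel,
    calibration_line,
    cross_validate_rmsecv,
    fit_plsr,
    lod,
    loq,
    predict,
    r_squared,
    rmse,
    rsd,
    select_n_lvs,
)
from .preprocess import PreprocessSpec, apply as apply_preprocess
from .spectral_io import ConcentrationTable, SpectraSet, average_replicates

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "CalibrationResult",
    "ValidationReport",
    "calibrate_pipeline",
    "validate_pipeline",
    "interval_pls_scan",
    "save_model",
    "load_model",
]

RESPONSE_NAMES = ("an_cfz", "mono_cfz", "total_impurity")

_BUNDLE_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the calibration chain, with study defaults."""

    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    width_points: int = 50
    aco: ACOConfig = field(default_factory=ACOConfig)
    aco_n_lvs: int = 5          # LV count used while scoring candidate subsets
    lv_threshold: float = 0.3   # RMSEC rule for the final LV count (w/w%)
    max_lvs: int = 15

    def to_dict(self) -> dict:
        return {
            "preprocess": asdict(self.preprocess),
            "width_points": self.width_points,
            "aco": asdict(self.aco),
            "aco_n_lvs": self.aco_n_lvs,
            "lv_threshold": self.lv_threshold,
            "max_lvs": self.max_lvs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            preprocess=PreprocessSpec(**d.get("preprocess", {})),
            width_points=d.get("width_points", 50),
            aco=ACOConfig(**d.get("aco", {})),
            aco_n_lvs=d.get("aco_n_lvs", 5),
            lv_threshold=d.get("lv_threshold", 0.3),
            max_lvs=d.get("max_lvs", 15),
        )


@dataclass
class CalibrationResult:
    """Fitted model plus everything needed to reproduce and apply it."""

    model: PLSModel
    aco: ACOResult
    bands: tuple
    n_lvs: int
    scheme: IntervalScheme
    config: PipelineConfig
    msc_reference: np.ndarray | None
    rmsec: dict            # response name -> RMSEC (w/w%)
    rmsecv: dict           # response name -> LOO RMSECV (w/w%)
    r2: dict               # response name -> training R^2
    lines: dict            # response name -> (intercept, slope, R^2)
    rmsec_by_n: dict       # N -> (an, mono, total) RMSEC table

    def preprocess_matrix(self, X: np.ndarray) -> np.ndarray:
        full = apply_preprocess(X, self.config.preprocess,
                                msc_reference=self.msc_reference)
        return extract_bands(full, self.scheme, self.bands)


@dataclass
class ValidationReport:
    """Held-out predictions and the validation figure-of-merit battery."""

    predictions: pd.DataFrame       # sample_id, per-response reference/predicted
    mean_abs_error: dict            # response name -> mean |pred - ref| (w/w%)
    rsd_pct: dict                   # mode -> {response: RSD %} (may be empty)
    lod: dict                       # response name -> LOD (w/w%), may be empty
    loq: dict                       # response name -> LOQ (w/w%)
    config_echo: dict

    def to_text(self) -> str:
        lines = ["Validation report", "=" * 17, "", self.predictions.to_string(index=False), ""]
        lines.append("Mean absolute prediction error (w/w%):")
        for name, v in self.mean_abs_error.items():
            lines.append(f"  {name}: {v:.4f}")
        for mode, block in self.rsd_pct.items():
            lines.append(f"{mode.capitalize()} RSD (%):")
            for name, v in block.items():
                lines.append(f"  {name}: {v:.4f}")
        if self.lod:
            lines.append("LOD / LOQ (w/w%):")
            for name in self.lod:
                lines.append(f"  {name}: {self.lod[name]:.4f} / {self.loq[name]:.4f}")
        return "\n".join(lines)


def _split_roles(
    spectra: SpectraSet, concentrations: ConcentrationTable
) -> tuple[SpectraSet, SpectraSet | None]:
    averaged = average_replicates(spectra)
    cal_ids = [s for s in averaged.unique_samples()
               if s in set(concentrations.role_ids("calibration"))]
    val_ids = [s for s in averaged.unique_samples()
               if s in set(concentrations.role_ids("validation"))]
    if not cal_ids:
        raise ValueError("no calibration samples in dataset")
    cal = averaged.subset_samples(cal_ids)
    val = averaged.subset_samples(val_ids) if val_ids else None
    return cal, val


def calibrate_pipeline(
    spectra: SpectraSet,
    concentrations: ConcentrationTable,
    config: PipelineConfig | None = None,
) -> CalibrationResult:
    """Full calibration chain on the samples flagged ``calibration``."""
    config = PipelineConfig() if config is None else config
    cal, _ = _split_roles(spectra, concentrations)
    Y = concentrations.responses(cal.sample_ids)
    msc_reference = (cal.absorbance.mean(axis=0)
                     if config.preprocess.method == "MSC" else None)
    X = apply_preprocess(cal.absorbance, config.preprocess,
                         msc_reference=msc_reference)
    scheme = partition(spectra.grid, config.width_points)
    logger.info("running band selection: %d ants, %d bands",
                config.aco.n_ants, config.aco.n_bands)
    aco = run_aco(X, Y, scheme, config.aco, n_lvs=config.aco_n_lvs)
    Xb = extract_bands(X, scheme, aco.best_bands)
    max_lvs = min(config.max_lvs, Xb.shape[0] - 1, Xb.shape[1])
    rmsec_by_n: dict[int, tuple] = {}
    models: dict[int, PLSModel] = {}
    for n in range(1, max_lvs + 1):
        m = fit_plsr(Xb, Y, n)
        resid = Y - predict(m, Xb)
        rmsec_by_n[n] = tuple(np.sqrt(np.mean(resid**2, axis=0)))
        models[n] = m
    n_lvs = select_n_lvs(rmsec_by_n, config.lv_threshold)
    model = models[n_lvs]
    fitted = predict(model, Xb)
    cv_per, _ = cross_validate_rmsecv(Xb, Y, min(n_lvs, Xb.shape[0] - 2))
    rmsec = {}
    r2 = {}
    lines = {}
    rmsecv = {}
    for j, name in enumerate(RESPONSE_NAMES):
        rmsec[name] = rmse(Y[:, j], fitted[:, j])
        r2[name] = r_squared(Y[:, j], fitted[:, j])
        lines[name] = calibration_line(Y[:, j], fitted[:, j])
        rmsecv[name] = float(cv_per[j])
    return CalibrationResult(
        model=model, aco=aco, bands=tuple(sorted(aco.best_bands)), n_lvs=n_lvs,
        scheme=scheme, config=config, msc_reference=msc_reference,
        rmsec=rmsec, rmsecv=rmsecv, r2=r2, lines=lines, rmsec_by_n=rmsec_by_n,
    )


def validate_pipeline(
    calibration: CalibrationResult,
    spectra: SpectraSet,
    concentrations: ConcentrationTable,
    rsd_sets: dict[str, SpectraSet] | None = None,
) -> ValidationReport:
    """Score a calibration on the samples flagged ``validation``.

    ``rsd_sets`` maps protocol mode (precision / repeatability / stability)
    to a set of repeat spectra of one tablet; per-mode RSDs of the predicted
    contents are reported, and the precision repeats supply sigma for the
    LOD/LOQ formulas (s is the calibration-line slope).
    """
    _, val = _split_roles(spectra, concentrations)
    if val is None:
        raise ValueError("no validation samples in dataset")
    Y = concentrations.responses(val.sample_ids)
    pred = predict(calibration.model, calibration.preprocess_matrix(val.absorbance))
    rows = {"sample_id": list(val.sample_ids)}
    mae = {}
    for j, name in enumerate(RESPONSE_NAMES):
        rows[f"{name}_reference"] = Y[:, j]
        rows[f"{name}_predicted"] = pred[:, j]
        mae[name] = float(np.mean(np.abs(pred[:, j] - Y[:, j])))
    rsd_pct: dict[str, dict] = {}
    lod_out: dict[str, float] = {}
    loq_out: dict[str, float] = {}
    if rsd_sets:
        for mode, repeats in rsd_sets.items():
            p = predict(calibration.model,
                        calibration.preprocess_matrix(repeats.absorbance))
            block = {}
            for j, name in enumerate(RESPONSE_NAMES):
                try:
                    block[name] = rsd(p[:, j])
                except ValueError:
                    block[name] = 0.0  # exact repeats at zero noise
            rsd_pct[mode] = block
        if "precision" in rsd_sets:
            p = predict(calibration.model,
                        calibration.preprocess_matrix(rsd_sets["precision"].absorbance))
            for j, name in enumerate(RESPONSE_NAMES):
                sigma = float(np.std(p[:, j], ddof=1))
                slope = calibration.lines[name][1]
                lod_out[name] = lod(sigma, slope)
                loq_out[name] = loq(sigma, slope)
    else:
        logger.warning("no repeat-measurement sets supplied; RSD/LOD/LOQ skipped")
    return ValidationReport(
        predictions=pd.DataFrame(rows),
        mean_abs_error=mae,
        rsd_pct=rsd_pct,
        lod=lod_out,
        loq=loq_out,
        config_echo=calibration.config.to_dict(),
    )


def interval_pls_scan(
    spectra: SpectraSet,
    concentrations: ConcentrationTable,
    config: PipelineConfig | None = None,
    n_lvs: int = 5,
) -> pd.DataFrame:
    """Per-band PLS scan: averaged LOO RMSECV of each sub-interval model
    next to the global-spectrum model (band 0 row)."""
    config = PipelineConfig() if config is None else config
    cal, _ = _split_roles(spectra, concentrations)
    Y = concentrations.responses(cal.sample_ids)
    X = apply_preprocess(cal.absorbance, config.preprocess)
    scheme = partition(spectra.grid, config.width_points)
    rows = []
    _, global_avg = cross_validate_rmsecv(X, Y, n_lvs)
    rows.append({"band": 0, "rmsecv_avg": global_avg})
    for band in range(1, scheme.n_intervals + 1):
        Xb = extract_bands(X, scheme, (band,))
        try:
            _, avg = cross_validate_rmsecv(Xb, Y, min(n_lvs, Xb.shape[1]))
        except ValueError as exc:
            if "latent variable" not in str(exc):
                raise
            avg = float("inf")  # band carries no signal at all
        rows.append({"band": band, "rmsecv_avg": avg})
    return pd.DataFrame(rows)


def _bundle_payload(calibration: CalibrationResult) -> dict:
    m = calibration.model
    return {
        "version": _BUNDLE_VERSION,
        "config": calibration.config.to_dict(),
        "bands": list(calibration.bands),
        "n_lvs": calibration.n_lvs,
        "scheme": {"n_points": calibration.scheme.n_points,
                   "width_points": calibration.scheme.width_points},
        "msc_reference": (None if calibration.msc_reference is None
                          else calibration.msc_reference.tolist()),
        "model": {
            "n_lvs": m.n_lvs,
            "x_mean": m.x_mean.tolist(),
            "y_mean": m.y_mean.tolist(),
            "weights": m.weights.tolist(),
            "x_loadings": m.x_loadings.tolist(),
            "y_loadings": m.y_loadings.tolist(),
            "scores": m.scores.tolist(),
            "coefficients": m.coefficients.tolist(),
            "x_var_pct": m.x_var_pct.tolist(),
            "y_var_pct": m.y_var_pct.tolist(),
        },
        "metrics": {
            "rmsec": calibration.rmsec,
            "rmsecv": calibration.rmsecv,
            "r2": calibration.r2,
            "lines": {k: list(v) for k, v in calibration.lines.items()},
        },
    }


def save_model(calibration: CalibrationResult, path) -> None:
    """Serialise a calibration to a checksummed JSON text bundle."""
    payload = _bundle_payload(calibration)
    body = json.dumps(payload, sort_keys=True)
    digest = hashlib.sha256(body.encode()).hexdigest()
    with open(path, "w") as fh:
        json.dump({"payload": payload, "sha256": digest}, fh, sort_keys=True, indent=1)


def load_model(path) -> CalibrationResult:
    """Restore a calibration bundle; predictions are bit-identical."""
    with open(path) as fh:
        doc = json.load(fh)
    payload = doc.get("payload", {})
    body = json.dumps(payload, sort_keys=True)
    if hashlib.sha256(body.encode()).hexdigest() != doc.get("sha256"):
        raise ValueError(f"{path}: checksum mismatch, bundle corrupted")
    if payload.get("version") != _BUNDLE_VERSION:
        raise ValueError(
            f"{path}: bundle version {payload.get('version')} unsupported "
            f"(expected {_BUNDLE_VERSION})"
        )
    md = payload["model"]
    model = PLSModel(
        n_lvs=md["n_lvs"],
        x_mean=np.array(md["x_mean"]),
        y_mean=np.array(md["y_mean"]),
        weights=np.array(md["weights"]),
        x_loadings=np.array(md["x_loadings"]),
        y_loadings=np.array(md["y_loadings"]),
        scores=np.array(md["scores"]),
        coefficients=np.array(md["coefficients"]),
        x_var_pct=np.array(md["x_var_pct"]),
        y_var_pct=np.array(md["y_var_pct"]),
    )
    config = PipelineConfig.from_dict(payload["config"])
    metrics = payload["metrics"]
    scheme = IntervalScheme(**payload["scheme"])
    aco = ACOResult(
        best_bands=tuple(payload["bands"]),
        discovery_order=tuple(payload["bands"]),
        best_fitness=float("nan"),
        fitness_history=[],
        pheromone=np.array([]),
    )
    return CalibrationResult(
        model=model, aco=aco, bands=tuple(payload["bands"]),
        n_lvs=payload["n_lvs"], scheme=scheme, config=config,
        msc_reference=(None if payload["msc_reference"] is None
                       else np.array(payload["msc_reference"])),
        rmsec=metrics["rmsec"], rmsecv=metrics["rmsecv"], r2=metrics["r2"],
        lines={k: tuple(v) for k, v in metrics["lines"].items()},
        rmsec_by_n={},
    )
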