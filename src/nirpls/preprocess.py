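"""Spectral pretreatment menu.

Implements the standard NIR pretreatments — standard normal variate (SNV),
multiplicative scatter correction (MSC), Savitzky-Golay first and second
derivatives, and wavelet soft-threshold denoising (WT) — plus chained
application ("SG2nd+WT" applies the derivative and then denoises).

Derivatives are taken with respect to the point index by default; scaling by
the grid spacing is exposed as an option and is irrelevant to band selection
(a global rescale of every column).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import savgol_filter

__all__ = ["PreprocessSpec", "snv", "msc", "savitzky_golay", "wavelet_denoise", "apply"]

METHODS = ("none", "SNV", "MSC", "SG1st", "SG2nd", "WT", "SG2nd+WT")


@dataclass(frozen=True)
class PreprocessSpec:
    """Pretreatment method and its parameters.

    Defaults: Savitzky-Golay window of 11 points with a quadratic fit
    (supports up to the second derivative), 'db4' wavelet at level 4 with
    the universal soft threshold.
    """

    method: str = "SG2nd"
    sg_window: int = 11
    sg_polyorder: int = 2
    wavelet_name: str = "db4"
    wavelet_level: int = 4
    threshold_rule: str = "universal"
    scale_by_spacing: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")
        deriv = {"SG1st": 1, "SG2nd": 2, "SG2nd+WT": 2}.get(self.method, 0)
        if self.sg_polyorder < deriv:
            raise ValueError("sg_polyorder must be >= derivative order")
        if self.threshold_rule not in ("universal", "none"):
            raise ValueError("threshold_rule must be 'universal' or 'none'")


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and scale one spectrum to unit sd.

    Uses the sample (n-1) standard deviation.  Affine-invariant:
    ``snv(a*x + b) == snv(x)`` for a > 0.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("SNV undefined for a constant spectrum")
    return (x - x.mean()) / sd


def msc(X: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed as ``x ~ a + b*reference`` and replaced by
    ``(x - a) / b``.  The reference defaults to the column mean of ``X``
    (at prediction time pass the calibration-set mean explicitly).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.std() == 0:
        raise ValueError("MSC reference has zero variance")
    out = np.empty_like(X)
    for i, row in enumerate(X):
        b, a = np.polyfit(ref, row, 1)
        out[i] = (row - a) / b
    return out


def savitzky_golay(
    x: np.ndarray,
    window: int = 11,
    polyorder: int = 2,
    deriv: int = 1,
    spacing: float | None = None,
) -> np.ndarray:
    """Savitzky-Golay derivative of a spectrum row.

    Differentiates with respect to the point index; pass ``spacing`` to
    rescale to per-cm^-1 units.  Boundary points come from the polynomial
    fit on the edge windows, so the derivative is exact everywhere for
    inputs that are polynomials of degree <= polyorder.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    if x.shape[-1] < window:
        raise ValueError(f"spectrum length {x.shape[-1]} shorter than window {window}")
    out = savgol_filter(x, window, polyorder, deriv=deriv, mode="interp")
    if spacing is not None:
        out = out / (-spacing) ** deriv  # descending grid: d(index) = -d(nu)/spacing
    return out


def wavelet_denoise(x: np.ndarray, spec: PreprocessSpec | None = None) -> np.ndarray:
    """Wavelet soft-threshold denoising of one spectrum.

    Multilevel DWT, soft thresholding of all detail coefficients at the
    universal threshold sigma*sqrt(2 ln P), with sigma estimated from the
    median absolute deviation of the finest-level details.  With
    ``threshold_rule='none'`` the transform is inverted untouched (identity
    up to reconstruction round-off).
    """
    spec = PreprocessSpec(method="WT") if spec is None else spec
    x = np.asarray(x, dtype=float)
    max_level = pywt.dwt_max_level(x.size, spec.wavelet_name)
    if spec.wavelet_level > max_level:
        raise ValueError(
            f"wavelet level {spec.wavelet_level} exceeds maximum {max_level} "
            f"for length {x.size}"
        )
    coeffs = pywt.wavedec(x, spec.wavelet_name, level=spec.wavelet_level)
    if spec.threshold_rule == "universal":
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(x.size))
        coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    return pywt.waverec(coeffs, spec.wavelet_name)[: x.size]


def apply(
    X: np.ndarray,
    spec: PreprocessSpec,
    msc_reference: np.ndarray | None = None,
    spacing: float | None = None,
) -> np.ndarray:
    """Apply a pretreatment row-wise to a spectra matrix; shape preserved."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    scale = spacing if (spec.scale_by_spacing and spacing is not None) else None
    if spec.method == "none":
        return X.copy()
    if spec.method == "SNV":
        return np.vstack([snv(row) for row in X])
    if spec.method == "MSC":
        return msc(X, reference=msc_reference)
    if spec.method == "SG1st":
        return savitzky_golay(X, spec.sg_window, spec.sg_polyorder, 1, scale)
    if spec.method == "SG2nd":
        return savitzky_golay(X, spec.sg_window, spec.sg_polyorder, 2, scale)
    if spec.method == "WT":
        return np.vstack([wavelet_denoise(row, spec) for row in X])
    if spec.method == "SG2nd+WT":
        d2 = savitzky_golay(X, spec.sg_window, spec.sg_polyorder, 2, scale)
        return np.vstack([wavelet_denoise(row, spec) for row in d2])
    raise ValueError(f"unknown method {spec.method!r}")  # pragma: no cover
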