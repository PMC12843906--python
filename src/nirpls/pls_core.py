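"""Multi-response partial least squares regression by NIPALS.

A single PLS2 model relates the preprocessed absorbance matrix X to the
three response columns (anhydrate, monohydrate, total impurity, all w/w%).
Components are extracted one at a time on mean-centered data with deflation;
no autoscaling is applied (absorbance columns share units, and scaling
would inflate noise-only channels).

Each latent variable (LV) carries a per-LV variance contribution: the share
of the centered ||X||_F^2 (molecular-structure information) and ||Y||_F^2
(content information) explained by its rank-one term.

The module also provides the figure-of-merit battery used to validate such
calibrations:

    R^2   = 1 - sum(y - yhat)^2 / sum(y - ybar)^2
    RMSE  = sqrt(mean((y - yhat)^2))            (RMSEC / RMSECV / RMSEP)
    RSD%  = sd(yhat, ddof=1) / mean(yhat) * 100
    LOD   = 3.3 sigma / s,   LOQ = 10 sigma / s

with sigma the standard deviation of repeated predicted contents and s the
slope of the predicted-vs-reference calibration line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PLSModel",
    "FitMetrics",
    "fit_plsr",
    "predict",
    "r_squared",
    "rmse",
    "rsd",
    "lod",
    "loq",
    "cross_validate_rmsecv",
    "variance_contributions",
    "select_n_lvs",
    "calibration_line",
]

_RANK_TOL = 1e-12


@dataclass
class PLSModel:
    """Fitted NIPALS decomposition.

    ``coefficients`` maps centered predictors to centered responses:
    ``Y_hat = (X - x_mean) @ coefficients + y_mean``.  ``n_lvs`` is the
    number of components actually extracted (less than requested if the
    residual rank was exhausted first).
    """

    n_lvs: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray        # p x A
    x_loadings: np.ndarray     # p x A
    y_loadings: np.ndarray     # m x A
    scores: np.ndarray         # n x A (training scores)
    coefficients: np.ndarray   # p x m
    x_var_pct: np.ndarray      # A
    y_var_pct: np.ndarray      # A

    @property
    def n_features(self) -> int:
        return self.x_mean.size

    @property
    def n_responses(self) -> int:
        return self.y_mean.size


@dataclass(frozen=True)
class FitMetrics:
    """R^2 and RMSE for one response under one context (RMSEC/RMSECV/RMSEP)."""

    context: str
    r2: float
    rmse: float
    n: int


def fit_plsr(X: np.ndarray, Y: np.ndarray, n_lvs: int) -> PLSModel:
    """Fit a mean-centered NIPALS PLS model with ``n_lvs`` components.

    Sign convention: each weight vector is unit length with its first
    element of magnitude > 1e-8 made positive, so scores and loadings are
    reproducible across runs and platforms.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if n_lvs < 1:
        raise ValueError("n_lvs must be >= 1")
    if n_lvs > min(n - 1, p):
        raise ValueError(f"n_lvs={n_lvs} exceeds min(n-1, p)={min(n - 1, p)}")
    if np.any(Y.std(axis=0) <= 0):
        raise ValueError("Y has a zero-variance column")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    ssx = float(np.sum(Xc**2))
    ssy = float(np.sum(Yc**2))
    W, P_load, Q, T = [], [], [], []
    x_var, y_var = [], []
    for _ in range(n_lvs):
        # start from the Y-residual column with most variance
        u = Yc[:, int(np.argmax(np.sum(Yc**2, axis=0)))].copy()
        if np.sum(u**2) <= _RANK_TOL * max(ssy, 1.0):
            break  # Y residual exhausted
        t_old = None
        for _ in range(500):
            w = Xc.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w <= _RANK_TOL * max(np.sqrt(ssx), 1.0):
                w = None
                break
            w /= norm_w
            t = Xc @ w
            tt = float(t @ t)
            if tt <= _RANK_TOL * max(ssx, 1.0):
                w = None
                break
            q = Yc.T @ t / tt
            if t_old is not None and np.linalg.norm(t - t_old) <= 1e-10 * np.linalg.norm(t):
                break
            t_old = t
            u = Yc @ q / float(q @ q)
        if w is None:
            break  # X residual exhausted
        # sign convention on the weight vector
        nz = np.flatnonzero(np.abs(w) > 1e-8)
        if nz.size and w[nz[0]] < 0:
            w = -w
            t = -t
        tt = float(t @ t)
        p_vec = Xc.T @ t / tt
        q_vec = Yc.T @ t / tt
        Xc = Xc - np.outer(t, p_vec)
        Yc = Yc - np.outer(t, q_vec)
        W.append(w)
        P_load.append(p_vec)
        Q.append(q_vec)
        T.append(t)
        x_var.append(100.0 * tt * float(p_vec @ p_vec) / ssx)
        y_var.append(100.0 * tt * float(q_vec @ q_vec) / ssy)
    if not W:
        raise ValueError("could not extract any latent variable (degenerate data)")
    Wm = np.column_stack(W)
    Pm = np.column_stack(P_load)
    Qm = np.column_stack(Q)
    Tm = np.column_stack(T)
    B = Wm @ np.linalg.solve(Pm.T @ Wm, Qm.T)
    return PLSModel(
        n_lvs=Wm.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        weights=Wm,
        x_loadings=Pm,
        y_loadings=Qm,
        scores=Tm,
        coefficients=B,
        x_var_pct=np.array(x_var),
        y_var_pct=np.array(y_var),
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses: ``(X_new - x_mean) @ B + y_mean``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.n_features}"
        )
    return (X_new - model.x_mean) @ model.coefficients + model.y_mean


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination; may be negative for poor fits."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least two observations")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined for constant reference values")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / sst


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root-mean-square error with divisor n."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ValueError("length mismatch")
    if y.size < 1:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def rsd(y_hat_repeats: np.ndarray) -> float:
    """Relative standard deviation (%) of repeated predicted contents."""
    y = np.asarray(y_hat_repeats, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("RSD needs at least two repeats")
    mean = y.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(y.std(ddof=1) / mean * 100.0)


def lod(sigma: float, slope: float) -> float:
    """Limit of detection, 3.3 sigma / s (w/w%)."""
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return 3.3 * sigma / slope


def loq(sigma: float, slope: float) -> float:
    """Limit of quantification, 10 sigma / s (w/w%)."""
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return 10.0 * sigma / slope


def cross_validate_rmsecv(
    X: np.ndarray, Y: np.ndarray, n_lvs: int
) -> tuple[np.ndarray, float]:
    """Leave-one-out RMSECV per response column, plus their unweighted mean.

    Each sample is predicted by a model fitted on all others; errors are
    pooled per Eq-style RMSE with divisor n.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOO cross-validation needs at least 3 samples")
    if n_lvs >= n - 1:
        raise ValueError("n_lvs must be < n-1 for leave-one-out")
    pred = np.empty_like(Y)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_plsr(X[mask], Y[mask], n_lvs)
        pred[i] = predict(model, X[i : i + 1])[0]
    per_response = np.sqrt(np.mean((Y - pred) ** 2, axis=0))
    return per_response, float(per_response.mean())


def variance_contributions(model: PLSModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-LV (%) shares of centered X and Y variance captured at fit time."""
    return model.x_var_pct.copy(), model.y_var_pct.copy()


def select_n_lvs(rmsec_by_n: dict[int, tuple[float, float, float]], threshold: float = 0.3) -> int:
    """Smallest component count whose three RMSEC values all beat ``threshold``.

    ``rmsec_by_n`` maps N to the (anhydrate, monohydrate, total) RMSEC in
    w/w%.  The table must start at N = 1; gaps are allowed above the answer
    (printed tables often thin out at large N).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not rmsec_by_n:
        raise ValueError("empty RMSEC table")
    if 1 not in rmsec_by_n:
        raise ValueError("RMSEC table must start at N = 1")
    for n in sorted(rmsec_by_n):
        if all(v < threshold for v in rmsec_by_n[n]):
            return n
    raise ValueError(
        f"no tabulated N drives all RMSEC below {threshold}; extend the table"
    )


def calibration_line(reference: np.ndarray, predicted: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line predicted = intercept + slope * reference.

    Returns (intercept, slope, R^2 of predicted vs reference).
    """
    reference = np.asarray(reference, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    slope, intercept = np.polyfit(reference, predicted, 1)
    return float(intercept), float(slope), r_squared(reference, predicted)
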