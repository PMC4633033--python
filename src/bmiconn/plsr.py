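"""Partial least-squares regression (PLS1) for BMI prediction.

PLSR projects the feature matrix onto latent variables (LVs) that maximise
covariance with the response, which sidesteps the multi-collinearity of a
design mixing structural densities and functional z values.  Features are
standardised to unit variance and the response is centred before extraction.

The LV count is chosen from PRESS, the leave-one-out predicted residual sum
of squares: components are added until PRESS no longer improves.  Model
assessment uses leave-one-subject-out cross-validation with the LV selection
nested inside each training fold, so the held-out subject never influences
its own fold's model.

NIPALS components are nested: one fit at ``max_lv`` yields the coefficient
vector of every smaller model, which keeps the inner PRESS loop at one fit
per held-out subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidArgumentError


@dataclass
class PLSRModel:
    """Fitted PLS1 model; ``coef[:, k-1]`` predicts with the first k LVs."""

    n_lv: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, n_lv) X-weights
    loadings: np.ndarray  # (p, n_lv) X-loadings
    y_loadings: np.ndarray  # (n_lv,)
    coef: np.ndarray  # (p, n_lv) coefficients on standardized X, nested in k
    explained_variance_y: float

    def predict(self, x_new: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        return predict(self, x_new, n_lv)


@dataclass
class PredictionReport:
    """Leave-one-subject-out prediction summary."""

    actual: np.ndarray
    predicted: np.ndarray
    per_fold_n_lv: list[int]
    rms_error: float = field(init=False)
    percent_error: float = field(init=False)
    pearson_r: float = field(init=False)

    def __post_init__(self) -> None:
        self.actual = np.asarray(self.actual, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.rms_error, self.percent_error = error_metrics(self.actual, self.predicted)
        sa, sp = self.actual.std(), self.predicted.std()
        self.pearson_r = (
            float(np.corrcoef(self.actual, self.predicted)[0, 1]) if sa > 0 and sp > 0 else 0.0
        )


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    dead = np.nonzero(scale == 0)[0]
    if dead.size:
        raise DegenerateInputError(f"feature column {int(dead[0])} is constant")
    return (X - mean) / scale, mean, scale


def fit_plsr(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSRModel:
    """NIPALS PLS1 on standardized X and centred y with X-deflation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise InvalidArgumentError("need at least 3 subjects")
    if not (1 <= n_lv <= min(n - 1, p)):
        raise InvalidArgumentError(
            f"n_lv={n_lv} outside [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise InvalidArgumentError("X and y must be finite with no missing entries")

    X0, x_mean, x_scale = _standardize(X)
    y_mean = float(y.mean())
    Xd = X0.copy()
    yd = y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    k_eff = 0
    for k in range(n_lv):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn < 1e-12:  # response fully explained; further LVs are noise
            break
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        P[:, k] = Xd.T @ t / tt
        q[k] = float(t @ yd) / tt
        W[:, k] = w
        Xd -= np.outer(t, P[:, k])
        yd = yd - q[k] * t
        k_eff = k + 1

    coef = np.zeros((p, n_lv))
    for k in range(1, k_eff + 1):
        Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
        coef[:, k - 1] = Wk @ np.linalg.solve(Pk.T @ Wk, qk)
    for k in range(k_eff, n_lv):  # early stop: later models equal the last real one
        coef[:, k] = coef[:, k_eff - 1] if k_eff else 0.0

    fitted = X0 @ coef[:, n_lv - 1] + y_mean
    tss = float(np.sum((y - y_mean) ** 2))
    rss = float(np.sum((y - fitted) ** 2))
    ev = 1.0 - rss / tss if tss > 0 else 0.0
    return PLSRModel(n_lv, x_mean, x_scale, y_mean, W, P, q[:n_lv], coef, ev)


def predict(model: PLSRModel, x_new: np.ndarray, n_lv: int | None = None) -> np.ndarray:
    """Apply stored centering/scaling and linear coefficients; no refitting."""
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    if x_new.shape[1] != model.x_mean.shape[0]:
        raise InvalidArgumentError(
            f"feature count {x_new.shape[1]} does not match model ({model.x_mean.shape[0]})"
        )
    k = model.n_lv if n_lv is None else n_lv
    if not (1 <= k <= model.n_lv):
        raise InvalidArgumentError(f"n_lv={k} outside fitted range [1, {model.n_lv}]")
    x0 = (x_new - model.x_mean) / model.x_scale
    return x0 @ model.coef[:, k - 1] + model.y_mean


def press_curve(X: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    """PRESS(k) for k = 1..max_lv from one leave-one-out pass.

    All n leave-one-out NIPALS fits run batched: fold f's design is the full
    standardized matrix with row f zeroed (a zero row contributes nothing to
    any inner product, so the algebra equals a genuine row deletion).  One
    batched ``max_lv``-component extraction supplies the nested coefficient
    vectors of every smaller model for every fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 4:
        raise InvalidArgumentError("need at least 4 subjects for PRESS")
    max_lv = int(max_lv)
    if max_lv < 1:
        raise InvalidArgumentError("max_lv must be >= 1")
    K = min(max_lv, n - 2, p)

    # per-fold mean and sd (ddof=1) of the n-1 training rows
    s_all = X.sum(axis=0)
    s2_all = (X * X).sum(axis=0)
    mean_f = (s_all[None, :] - X) / (n - 1)  # (n, p)
    var_f = (s2_all[None, :] - X * X - (n - 1) * mean_f**2) / (n - 2)
    if np.any(var_f <= 0):
        raise DegenerateInputError("a feature column is constant within a LOO fold")
    sd_f = np.sqrt(var_f)
    y_mean_f = (y.sum() - y) / (n - 1)

    mask = 1.0 - np.eye(n)  # (fold, row): row f zeroed in fold f
    Xd = (X[None, :, :] - mean_f[:, None, :]) / sd_f[:, None, :] * mask[:, :, None]
    yd = (y[None, :] - y_mean_f[:, None]) * mask

    W = np.zeros((n, p, K))
    P = np.zeros((n, p, K))
    q = np.zeros((n, K))
    for k in range(K):
        w = np.einsum("fnp,fn->fp", Xd, yd)
        wn = np.linalg.norm(w, axis=1, keepdims=True)
        w = np.where(wn > 1e-12, w / np.where(wn == 0, 1.0, wn), 0.0)
        t = np.einsum("fnp,fp->fn", Xd, w)
        tt = np.einsum("fn,fn->f", t, t)
        inv = np.where(tt > 1e-12, 1.0 / np.where(tt == 0, 1.0, tt), 0.0)
        P[:, :, k] = np.einsum("fnp,fn->fp", Xd, t) * inv[:, None]
        q[:, k] = np.einsum("fn,fn->f", t, yd) * inv
        W[:, :, k] = w
        Xd -= t[:, :, None] * P[:, None, :, k]
        yd -= q[:, k, None] * t

    x0_held = (X - mean_f) / sd_f  # fold f's standardized held-out row
    out = np.zeros(K)
    coef_prev = np.zeros((n, p))
    for k in range(1, K + 1):
        PtW = np.einsum("fpi,fpj->fij", P[:, :, :k], W[:, :, :k])
        ok = np.abs(np.linalg.det(PtW)) > 1e-300
        coef = coef_prev.copy()
        if ok.any():
            sol = np.linalg.solve(PtW[ok], q[ok, :k, None])[..., 0]
            coef[ok] = np.einsum("fpk,fk->fp", W[ok][:, :, :k], sol)
        pred = np.einsum("fp,fp->f", x0_held, coef) + y_mean_f
        out[k - 1] = float(np.sum((y - pred) ** 2))
        coef_prev = coef
    if K < max_lv:  # further LVs cannot be extracted; PRESS is flat beyond K
        out = np.concatenate([out, np.full(max_lv - K, out[-1])])
    return out[:max_lv] if max_lv <= len(out) else out


def press(X: np.ndarray, y: np.ndarray, n_lv: int) -> float:
    """Leave-one-out predicted residual sum of squares of a ``n_lv``-LV model."""
    return float(press_curve(X, y, n_lv)[-1])


def select_n_lv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    criterion: str = "first",
    curve: np.ndarray | None = None,
) -> int:
    """Pick the LV count from the PRESS curve.

    ``first`` (default): smallest k with PRESS(k+1) >= PRESS(k), i.e. stop as
    soon as adding an LV stops improving; ``min``: global PRESS minimum.
    """
    if criterion not in ("first", "min"):
        raise InvalidArgumentError(f"unknown criterion {criterion!r}")
    if curve is None:
        curve = press_curve(X, y, max_lv)
    if criterion == "min":
        return int(np.argmin(curve)) + 1
    for k in range(len(curve) - 1):
        if curve[k + 1] >= curve[k]:
            return k + 1
    return len(curve)


def simple_feature_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-predictor OLS: R^2 (= squared Pearson r) and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise InvalidArgumentError("need at least 4 subjects")
    if np.std(x) == 0:
        raise DegenerateInputError("feature is constant")
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue)


def fit_fold(
    X: np.ndarray,
    y: np.ndarray,
    holdout: int,
    max_lv: int,
    criterion: str = "first",
) -> tuple[PLSRModel, int]:
    """Fit one LOOCV fold: nested PRESS selection and final fit on the n-1
    training subjects; the held-out row is never touched."""
    n = X.shape[0]
    mask = np.ones(n, dtype=bool)
    mask[holdout] = False
    Xt, yt = X[mask], y[mask]
    cap = min(max_lv, Xt.shape[0] - 2, Xt.shape[1])
    k = select_n_lv(Xt, yt, cap, criterion=criterion)
    return fit_plsr(Xt, yt, k), k


def loocv_predict(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    criterion: str = "first",
) -> PredictionReport:
    """Leave-one-subject-out CV with nested PRESS-based LV selection."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise InvalidArgumentError("need at least 5 subjects for LOOCV")
    preds = np.zeros(n)
    ks: list[int] = []
    for i in range(n):
        model, k = fit_fold(X, y, i, max_lv, criterion)
        preds[i] = predict(model, X[i : i + 1])[0]
        ks.append(k)
    return PredictionReport(y, preds, ks)


def error_metrics(actual: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """RMS error and mean percent error |a-p|/a * 100."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise InvalidArgumentError("actual/predicted length mismatch")
    if np.any(actual <= 0):
        raise InvalidArgumentError("actual BMI values must be positive")
    rms = float(np.sqrt(np.mean((actual - predicted) ** 2)))
    percent = float(np.mean(np.abs(actual - predicted) / actual) * 100.0)
    return rms, percent
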