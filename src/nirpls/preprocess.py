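"""Spectral preprocessing transforms.

Each transform is a scikit-learn style transformer (``fit`` learns any
calibration-set state, ``transform`` is a pure matrix -> matrix map) so
pipelines compose with :class:`sklearn.pipeline.Pipeline`.  Row-wise
transforms (SNV, Savitzky-Golay, baseline, moving average, mean
reduction) are stateless; MSC and mean centering capture calibration
state (reference spectrum, column means) and apply it frozen to new
samples, preventing train/test leakage.

Functional wrappers (``snv``, ``msc``, ...) are provided for one-shot
use; the stateful ones return ``(output, fitted_transformer)``.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline

__all__ = [
    "SNVScaler",
    "MSCCorrector",
    "SavitzkyGolayFilter",
    "BaselineCorrector",
    "MeanCenterer",
    "MovingAverageSmoother",
    "MeanReducer",
    "snv",
    "msc",
    "savitzky_golay",
    "baseline",
    "mean_center",
    "apply_center",
    "moving_average",
    "mean_reduction",
    "make_pipeline_from_config",
]


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError(f"expected a 2-d spectra matrix, got ndim={X.ndim}")
    if not np.all(np.isfinite(X)):
        raise ValueError("spectra matrix contains non-finite values")
    return X


class SNVScaler(TransformerMixin, BaseEstimator):
    """Standard normal variate: standardize each spectrum to mean 0, SD 1.

    Uses the sample (n-1) standard deviation.  A constant row has no
    scale and raises.
    """

    def fit(self, X, y=None):
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        bad = np.flatnonzero(sd.ravel() <= 0)
        if bad.size:
            raise ValueError(f"constant spectrum at row {bad[0]}: SNV undefined")
        return (X - mu) / sd


class MSCCorrector(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference r by ordinary least
    squares, x ~= a + b r, and corrected to (x - a)/b.  The reference
    defaults to the column-wise mean of the calibration matrix and is
    stored so new samples are corrected against the same spectrum.
    """

    def __init__(self, reference=None):
        self.reference = reference

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if self.reference is None:
            ref = X.mean(axis=0)
        else:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != (X.shape[1],):
                raise ValueError("reference length does not match spectra columns")
        if np.std(ref) <= 0:
            raise ValueError("MSC reference spectrum is constant")
        self.reference_ = ref
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        r = self.reference_
        rc = r - r.mean()
        denom = rc @ rc
        b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
        a = X.mean(axis=1) - b * r.mean()
        bad = np.flatnonzero(np.abs(b) < 1e-12)
        if bad.size:
            raise ValueError(f"MSC slope ~0 at row {bad[0]}: correction undefined")
        return (X - a[:, None]) / b[:, None]


class SavitzkyGolayFilter(TransformerMixin, BaseEstimator):
    """Savitzky-Golay smoothing / derivative per spectrum.

    Defaults follow the common NIR setting: 17-point window, 2nd-degree
    polynomial, 1st derivative.  ``delta`` is the wavelength step in nm
    so derivative output is per-nm.  Edges use a polynomial fit to the
    terminal window, which keeps the filter exact on polynomials of the
    fitted degree everywhere.
    """

    def __init__(self, window: int = 17, polyorder: int = 2, deriv: int = 1,
                 delta: float = 1.0):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv
        self.delta = delta

    def fit(self, X, y=None):
        self._validate()
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def _validate(self):
        if self.window % 2 == 0:
            raise ValueError(f"window must be odd, got {self.window}")
        if self.window <= self.polyorder:
            raise ValueError(
                f"window ({self.window}) must exceed polyorder ({self.polyorder})"
            )
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    def transform(self, X):
        self._validate()
        X = _as_matrix(X)
        if self.window > X.shape[1]:
            raise ValueError(
                f"window ({self.window}) exceeds number of wavelengths ({X.shape[1]})"
            )
        return savgol_filter(
            X, window_length=self.window, polyorder=self.polyorder,
            deriv=self.deriv, delta=self.delta, axis=1, mode="interp",
        )


class BaselineCorrector(TransformerMixin, BaseEstimator):
    """Baseline removal per spectrum.

    mode="offset": subtract the row minimum.
    mode="linear": subtract the no-intercept least-squares line b*lambda.
    mode="offset_linear": subtract the full least-squares line a + b*lambda;
    the residual is orthogonal to [1, lambda].

    ``axis`` is the wavelength axis; defaults to 0..n-1.
    """

    MODES = ("offset", "linear", "offset_linear")

    def __init__(self, mode: str = "offset_linear", axis=None):
        self.mode = mode
        self.axis = axis

    def fit(self, X, y=None):
        if self.mode not in self.MODES:
            raise ValueError(f"mode must be one of {self.MODES}, got {self.mode!r}")
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        n = X.shape[1]
        lam = np.arange(n, dtype=float) if self.axis is None else np.asarray(self.axis, dtype=float)
        if lam.shape != (n,):
            raise ValueError("axis length does not match spectra columns")
        if self.mode == "offset":
            return X - X.min(axis=1, keepdims=True)
        if self.mode == "linear":
            b = (X @ lam) / (lam @ lam)
            return X - b[:, None] * lam[None, :]
        # offset_linear: two-parameter OLS detrend
        A = np.column_stack([np.ones(n), lam])
        coef, *_ = np.linalg.lstsq(A, X.T, rcond=None)
        return X - (A @ coef).T


class MeanCenterer(TransformerMixin, BaseEstimator):
    """Column mean centering with calibration means applied to new data."""

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if X.shape[0] < 2:
            raise ValueError("mean centering needs at least 2 calibration rows")
        self.mean_ = X.mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        if X.shape[1] != self.mean_.size:
            raise ValueError(
                f"matrix has {X.shape[1]} columns, centering state expects {self.mean_.size}"
            )
        return X - self.mean_


class MovingAverageSmoother(TransformerMixin, BaseEstimator):
    """Boxcar smoothing per spectrum with symmetrically shrinking edges.

    At column i the half-width is min(w//2, i, n-1-i), so edge points
    average over a shorter, still symmetric, window.
    """

    def __init__(self, window: int = 5):
        self.window = window

    def fit(self, X, y=None):
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError(f"window must be odd and positive, got {self.window}")
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def transform(self, X):
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError(f"window must be odd and positive, got {self.window}")
        X = _as_matrix(X)
        n = X.shape[1]
        if self.window > n:
            raise ValueError(f"window ({self.window}) exceeds columns ({n})")
        half = self.window // 2
        out = np.empty_like(X)
        for i in range(n):
            h = min(half, i, n - 1 - i)
            out[:, i] = X[:, i - h:i + h + 1].mean(axis=1)
        return out


class MeanReducer(TransformerMixin, BaseEstimator):
    """Row-mean normalization: divide each spectrum by its mean.

    A scatter-normalization reading of "mean reduction"; the definition
    is not standardized, so this transformer is isolated and swappable.
    Scale-invariant: c*x maps to the same output as x for c > 0.
    """

    def fit(self, X, y=None):
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        mu = X.mean(axis=1)
        bad = np.flatnonzero(np.abs(mu) < 1e-12)
        if bad.size:
            raise ValueError(f"row {bad[0]} has mean ~0: mean reduction undefined")
        return X / mu[:, None]


# ---------------------------------------------------------------------------
# functional wrappers

def snv(X) -> np.ndarray:
    return SNVScaler().fit(X).transform(X)


def msc(X, reference=None):
    """MSC-correct X; returns (corrected matrix, fitted corrector)."""
    t = MSCCorrector(reference=reference).fit(X)
    return t.transform(X), t


def savitzky_golay(X, window: int = 17, polyorder: int = 2, deriv: int = 1,
                   delta: float = 1.0) -> np.ndarray:
    return SavitzkyGolayFilter(window, polyorder, deriv, delta).fit(X).transform(X)


def baseline(X, axis=None, mode: str = "offset_linear") -> np.ndarray:
    return BaselineCorrector(mode=mode, axis=axis).fit(X).transform(X)


def mean_center(Xcal):
    """Center columns on calibration means; returns (centered, fitted centerer)."""
    t = MeanCenterer().fit(Xcal)
    return t.transform(Xcal), t


def apply_center(state: MeanCenterer, Xnew) -> np.ndarray:
    return state.transform(Xnew)


def moving_average(X, window: int = 5) -> np.ndarray:
    return MovingAverageSmoother(window=window).fit(X).transform(X)


def mean_reduction(X) -> np.ndarray:
    return MeanReducer().fit(X).transform(X)


_METHODS = {
    "snv": SNVScaler,
    "msc": MSCCorrector,
    "savitzky_golay": SavitzkyGolayFilter,
    "baseline": BaselineCorrector,
    "mean_center": MeanCenterer,
    "moving_average": MovingAverageSmoother,
    "mean_reduction": MeanReducer,
}


def make_pipeline_from_config(entries, wavelengths=None) -> Pipeline:
    """Build an sklearn Pipeline from a list of config entries.

    Each entry is ``{"method": <name>, ...params}``; e.g.
    ``[{"method": "snv"}, {"method": "savitzky_golay", "window": 17}]``.
    If ``wavelengths`` is given, baseline correction receives it as the
    axis and Savitzky-Golay derivatives are scaled by its step.
    An empty list yields an identity ("raw") pipeline.
    """
    steps = []
    for k, entry in enumerate(entries):
        entry = dict(entry)
        name = entry.pop("method")
        if name not in _METHODS:
            raise ValueError(f"unknown preprocessing method {name!r}")
        if wavelengths is not None:
            wavelengths = np.asarray(wavelengths, dtype=float)
            if name == "baseline" and "axis" not in entry:
                entry["axis"] = wavelengths
            if name == "savitzky_golay" and "delta" not in entry:
                entry["delta"] = float(wavelengths[1] - wavelengths[0])
        steps.append((f"{k}_{name}", _METHODS[name](**entry)))
    if not steps:
        steps = [("raw", FunctionIdentity())]
    return Pipeline(steps)


class FunctionIdentity(TransformerMixin, BaseEstimator):
    """Identity transform (the raw-data pipeline)."""

    def fit(self, X, y=None):
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def transform(self, X):
        return _as_matrix(X)
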