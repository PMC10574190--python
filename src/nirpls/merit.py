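"""Figures of merit for multivariate calibration models.

Covers the standard validation column of a calibration study: RMSEC /
RMSECV / RMSEP, R^2 (squared Pearson correlation of predicted vs
reference), prediction bias, SEP-style standard deviation of validation
(SDV), ratio of performance to deviation (RPD), relative error of
prediction (REP), plus the elliptical joint confidence region (EJCR)
accuracy test on the predicted-vs-reference line and a two-sided F-test
comparing the RMSEP of two models.

Conventions (configurable where noted):

* ``SDV = sqrt(n * (RMSEP^2 - bias^2) / (n - 1))`` — the bias-corrected
  SEP, so ``SDV^2 (n-1)/n + bias^2 = RMSEP^2`` holds as an identity.
* ``RPD = SD(reference values of the prediction set) / SDV`` by default;
  ``rpd_denominator="rmsep"`` switches to SD/RMSEP.
* ``REP = 100 * RMSEP / mean(reference values of the prediction set)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MeritReport",
    "EJCRResult",
    "FTestResult",
    "rmse",
    "figures_of_merit",
    "rsd",
    "ejcr",
    "ftest_rmsep",
    "merit_table",
]

# row order of the serialized merit column block
MERIT_ROWS = ["lv", "nv", "rmsec", "r2_cal", "rmsep", "r2_pred", "bias_pred",
              "rep", "rpd", "sdv"]


@dataclass
class MeritReport:
    """One model's column of figures of merit (concentrations in mg kg^-1)."""

    rmsec: float
    rmsecv: float
    rmsep: float
    r2_cal: float
    r2_pred: float
    bias_pred: float
    sdv: float
    rpd: float
    rep: float
    lv: int
    nv: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class EJCRResult:
    """Joint confidence region for the predicted-vs-reference line."""

    intercept: float
    slope: float
    shape: np.ndarray  # 2x2 matrix M with region {d: d' M d <= threshold}
    threshold: float   # 2 * s^2 * F(alpha; 2, n-2)
    f_critical: float
    contains_ideal: bool
    alpha: float
    n: int

    def quadratic_form(self, a0: float, b0: float) -> float:
        d = np.array([self.intercept - a0, self.slope - b0])
        return float(d @ self.shape @ d)


@dataclass
class FTestResult:
    """Two-sided F comparison of two models' RMSEP."""

    f: float
    f_critical: float
    p_value: float
    significant: bool
    alpha: float


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def _r2_corr(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if np.std(y_true) <= 0 or np.std(y_pred) <= 0:
        raise ValueError("zero variance: R^2 undefined")
    return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)


def sdv_from_rmsep(rmsep: float, bias: float, n: int) -> float:
    """Bias-corrected SEP: sqrt(n (RMSEP^2 - bias^2) / (n-1))."""
    if n < 2:
        raise ValueError("SDV needs n >= 2")
    return float(np.sqrt(n * (rmsep ** 2 - bias ** 2) / (n - 1)))


def figures_of_merit(y_cal, yhat_cal, y_pred, yhat_pred, rmsecv: float,
                     lv: int, nv: int,
                     rpd_denominator: str = "sdv") -> MeritReport:
    """Assemble the full merit column for one fitted model.

    ``y_cal``/``yhat_cal`` are reference and fitted values on the
    calibration set; ``y_pred``/``yhat_pred`` on the prediction set;
    ``rmsecv`` comes from the model's cross-validation; ``lv``/``nv``
    are the latent-variable and selected-variable counts.
    """
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    yhat_cal = np.asarray(yhat_cal, dtype=float).ravel()
    y_p = np.asarray(y_pred, dtype=float).ravel()
    yhat_p = np.asarray(yhat_pred, dtype=float).ravel()
    if y_cal.size != yhat_cal.size or y_p.size != yhat_p.size:
        raise ValueError("paired vectors must have equal length")
    for v in (y_cal, yhat_cal, y_p, yhat_p):
        if not np.all(np.isfinite(v)):
            raise ValueError("inputs must be finite")
    n = y_p.size
    rmsep = rmse(y_p, yhat_p)
    bias = float(np.mean(yhat_p - y_p))
    sdv = sdv_from_rmsep(rmsep, bias, n)
    mean_ref = float(np.mean(y_p))
    if mean_ref <= 0:
        raise ValueError("prediction-set reference mean must be positive for REP")
    sd_ref = float(np.std(y_p, ddof=1))
    if sd_ref <= 0:
        raise ValueError("prediction-set reference values are constant: RPD undefined")
    if rpd_denominator == "sdv":
        rpd = sd_ref / sdv if sdv > 0 else np.inf
    elif rpd_denominator == "rmsep":
        rpd = sd_ref / rmsep if rmsep > 0 else np.inf
    else:
        raise ValueError("rpd_denominator must be 'sdv' or 'rmsep'")
    exact_cal = np.allclose(yhat_cal, y_cal, rtol=0, atol=1e-12 * max(1.0, np.abs(y_cal).max()))
    exact_pred = np.allclose(yhat_p, y_p, rtol=0, atol=1e-12 * max(1.0, np.abs(y_p).max()))
    return MeritReport(
        rmsec=rmse(y_cal, yhat_cal),
        rmsecv=float(rmsecv),
        rmsep=rmsep,
        r2_cal=1.0 if exact_cal else _r2_corr(y_cal, yhat_cal),
        r2_pred=1.0 if exact_pred else _r2_corr(y_p, yhat_p),
        bias_pred=bias,
        sdv=sdv,
        rpd=float(rpd),
        rep=100.0 * rmsep / mean_ref,
        lv=int(lv),
        nv=int(nv),
    )


def rsd(values) -> float:
    """Relative standard deviation, percent: 100 * sample SD / mean."""
    v = np.asarray(values, dtype=float).ravel()
    m = v.mean()
    if m <= 0:
        raise ValueError("RSD requires a positive mean")
    return float(100.0 * v.std(ddof=1) / m)


def ejcr(y_ref, y_pred, alpha: float = 0.05) -> EJCRResult:
    """Elliptical joint confidence region for (intercept, slope).

    Fits yhat = a + b*y by OLS and builds the exact joint region

        n (a - a0)^2 + 2 Sum(y_i) (a - a0)(b - b0) + Sum(y_i^2) (b - b0)^2
            <= 2 s^2 F(alpha; 2, n-2)

    with s^2 the residual mean square.  The model is accurate (no joint
    bias) when the ideal point (0, 1) lies inside.
    """
    y = np.asarray(y_ref, dtype=float).ravel()
    yh = np.asarray(y_pred, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("EJCR needs at least 3 samples")
    if np.std(y) <= 0:
        raise ValueError("reference values are constant: EJCR undefined")
    A = np.column_stack([np.ones(n), y])
    coef, *_ = np.linalg.lstsq(A, yh, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    resid = yh - A @ coef
    s2 = float(resid @ resid) / (n - 2)
    shape = np.array([[n, y.sum()], [y.sum(), (y ** 2).sum()]], dtype=float)
    f_crit = float(stats.f.ppf(1 - alpha, 2, n - 2))
    threshold = 2.0 * s2 * f_crit
    d = np.array([a - 0.0, b - 1.0])
    q = float(d @ shape @ d)
    # rounding floor: exact fits have q and threshold both ~eps^2-scale
    tol = np.finfo(float).eps ** 2 * 100 * np.trace(shape) * max(
        1.0, float(np.abs(yh).max()) ** 2)
    return EJCRResult(
        intercept=a, slope=b, shape=shape, threshold=threshold,
        f_critical=f_crit, contains_ideal=bool(q <= threshold + tol),
        alpha=alpha, n=n,
    )


def ftest_rmsep(rmsep_a: float, n_a: int, rmsep_b: float, n_b: int,
                alpha: float = 0.05) -> FTestResult:
    """Two-sided F-test on the RMSEP of two models.

    F is the larger squared RMSEP over the smaller; degrees of freedom
    are the respective prediction-set sizes, larger-RMSEP model in the
    numerator.  Significance at level alpha uses F(alpha/2; df1, df2).
    """
    if rmsep_a <= 0 or rmsep_b <= 0:
        raise ValueError("RMSEP values must be positive")
    if n_a <= 1 or n_b <= 1:
        raise ValueError("n must exceed 1")
    if rmsep_a >= rmsep_b:
        f = (rmsep_a / rmsep_b) ** 2
        df1, df2 = n_a, n_b
    else:
        f = (rmsep_b / rmsep_a) ** 2
        df1, df2 = n_b, n_a
    f_crit = float(stats.f.ppf(1 - alpha / 2, df1, df2))
    p = float(2 * stats.f.sf(f, df1, df2))
    p = min(p, 1.0)
    return FTestResult(f=float(f), f_critical=f_crit, p_value=p,
                       significant=bool(f > f_crit), alpha=alpha)


def merit_table(reports: dict[str, MeritReport]) -> pd.DataFrame:
    """Column block of merit reports in the conventional table row order."""
    data = {}
    for name, rep in reports.items():
        d = rep.as_dict()
        data[name] = [d[k] for k in MERIT_ROWS]
    return pd.DataFrame(data, index=[k.upper() for k in MERIT_ROWS])
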