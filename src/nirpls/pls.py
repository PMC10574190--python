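"""PLS1 regression via NIPALS with cross-validated latent-variable choice.

The model is fit on column-centered X and centered y.  Each latent
variable (LV) extracts a weight vector proportional to X'y on the
deflated X, normalized to unit length; scores t = Xw, X-loadings
p = X't/t't, y-loading q = y't/t't, then X is deflated by t p'.  The
regression vector for any truncation 1..n_components follows from the
standard rotation recurrence, so one fit yields the whole coefficient
path — which makes RMSECV over all candidate LV counts a single fit per
fold.

The number of LVs is chosen as the global minimizer of RMSECV
(smallest LV on ties); venetian-blinds CV with 10 splits is the
default, leave-one-out is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["PLS1Regression", "CVResult", "fit_pls1", "cross_validate", "cv_folds"]


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS on centered data; returns (W, P, q, T, coef_path, n_eff).

    coef_path[:, k-1] is the regression vector using the first k LVs.
    Stops early (with a warning) when the X residual is numerically
    exhausted.
    """
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    x_scale = np.linalg.norm(Xc)
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    n_eff = 0
    for k in range(n_lv):
        if np.linalg.norm(X) <= 1e-12 * max(x_scale, 1.0):
            warnings.warn(
                f"X residual exhausted after {n_eff} latent variables "
                f"(requested {n_lv})", stacklevel=3,
            )
            break
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-14 * max(x_scale, 1.0):
            warnings.warn(
                f"no covariance left after {n_eff} latent variables", stacklevel=3,
            )
            break
        w /= nw
        t = X @ w
        tt = t @ t
        p_vec = X.T @ t / tt
        q_k = (y @ t) / tt
        X -= np.outer(t, p_vec)
        y = y - q_k * t
        W[:, k], P[:, k], q[k], T[:, k] = w, p_vec, q_k, t
        n_eff += 1
    W, P, q, T = W[:, :n_eff], P[:, :n_eff], q[:n_eff], T[:, :n_eff]
    # rotation recurrence: r_k = w_k - sum_{j<k} (p_j' w_k) r_j ; B_k = B_{k-1} + q_k r_k
    R = np.zeros((p, n_eff))
    coef_path = np.zeros((p, n_eff))
    b = np.zeros(p)
    for k in range(n_eff):
        r = W[:, k] - R[:, :k] @ (P[:, :k].T @ W[:, k])
        R[:, k] = r
        b = b + q[k] * r
        coef_path[:, k] = b
    return W, P, q, T, coef_path, n_eff


class PLS1Regression(RegressorMixin, BaseEstimator):
    """Univariate-response partial least squares (PLS1, NIPALS).

    Parameters
    ----------
    n_components : int
        Number of latent variables to extract; capped at
        min(n_samples - 1, n_features) and at the numerical rank of the
        centered X (with a warning when fewer LVs than requested are
        available).

    Attributes
    ----------
    x_weights_ : (n_features, n_components_) deflation-step weights, unit norm.
    x_loadings_ : (n_features, n_components_) X loadings.
    y_loadings_ : (n_components_,) y loadings.
    x_scores_ : (n_samples, n_components_) mutually orthogonal scores.
    coef_ : (n_features,) regression vector on centered data.
    coef_path_ : (n_features, n_components_) coefficients for 1..k LVs.
    x_mean_, y_mean_ : centering state from the calibration set.
    n_components_ : effective number of latent variables.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-d")
        n, p = X.shape
        if y.size != n:
            raise ValueError(f"y has {y.size} entries for {n} samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        cap = min(n - 1, p)
        if self.n_components > cap:
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n_samples-1, "
                f"n_features)={cap}"
            )
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = y.mean()
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        (self.x_weights_, self.x_loadings_, self.y_loadings_, self.x_scores_,
         self.coef_path_, self.n_components_) = _nipals_path(Xc, yc, self.n_components)
        self.coef_ = self.coef_path_[:, -1] if self.n_components_ else np.zeros(p)
        self.n_features_in_ = p
        return self

    def predict(self, X, n_components: int | None = None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean_.size:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.x_mean_.size}"
            )
        if n_components is None:
            b = self.coef_
        else:
            if not 1 <= n_components <= self.n_components_:
                raise ValueError(
                    f"n_components must be in [1, {self.n_components_}]"
                )
            b = self.coef_path_[:, n_components - 1]
        return self.y_mean_ + (X - self.x_mean_) @ b

    def save(self, path) -> None:
        """Serialize to a plain-text key/value + matrix-block format."""
        with open(path, "w") as fh:
            fh.write("format: nirpls-pls1 v1\n")
            fh.write(f"n_components: {self.n_components_}\n")
            fh.write(f"n_features: {self.n_features_in_}\n")
            fh.write(f"y_mean: {float(self.y_mean_)!r}\n")
            for name in ("x_mean_", "coef_", "y_loadings_"):
                arr = np.atleast_1d(getattr(self, name)).ravel()
                fh.write(f"[{name}]\n")
                fh.write(" ".join(repr(float(v)) for v in arr) + "\n")
            for name in ("x_weights_", "x_loadings_", "coef_path_"):
                arr = getattr(self, name)
                fh.write(f"[{name}] rows={arr.shape[0]} cols={arr.shape[1]}\n")
                for row in arr:
                    fh.write(" ".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def load(cls, path) -> "PLS1Regression":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        if not lines or lines[0] != "format: nirpls-pls1 v1":
            raise ValueError("not a nirpls PLS1 model file")
        model = cls.__new__(cls)
        i = 1
        header = {}
        while i < len(lines) and not lines[i].startswith("["):
            key, val = lines[i].split(":", 1)
            header[key.strip()] = val.strip()
            i += 1
        model.n_components = model.n_components_ = int(header["n_components"])
        model.n_features_in_ = int(header["n_features"])
        model.y_mean_ = float(header["y_mean"])
        while i < len(lines):
            tag = lines[i]
            name = tag[1:tag.index("]")]
            if "rows=" in tag:
                rows = int(tag.split("rows=")[1].split()[0])
                block = [
                    [float(t) for t in lines[i + 1 + r].split()] for r in range(rows)
                ]
                setattr(model, name, np.array(block))
                i += 1 + rows
            else:
                setattr(model, name, np.array([float(t) for t in lines[i + 1].split()]))
                i += 2
        model.y_loadings_ = np.atleast_1d(model.y_loadings_)
        return model


def fit_pls1(X, y, n_lv: int) -> PLS1Regression:
    """Fit a PLS1 model with ``n_lv`` latent variables."""
    return PLS1Regression(n_components=n_lv).fit(X, y)


@dataclass
class CVResult:
    """Cross-validation curve over candidate LV counts."""

    rmsecv: np.ndarray  # rmsecv[k-1] for k latent variables
    chosen_lv: int

    @property
    def min_rmsecv(self) -> float:
        return float(self.rmsecv[self.chosen_lv - 1])


def cv_folds(n: int, scheme: str) -> list[np.ndarray]:
    """Validation-fold index lists for 'loo' or 'venetian:k' schemes.

    Venetian blinds assigns sample i to fold i mod k, interleaving the
    folds across the (SPXy-ordered) calibration set.
    """
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    if scheme.startswith("venetian"):
        k = int(scheme.split(":")[1]) if ":" in scheme else 10
        if k < 2:
            raise ValueError("venetian blinds needs k >= 2")
        k = min(k, n)
        return [np.arange(i, n, k) for i in range(k)]
    raise ValueError(f"unknown CV scheme {scheme!r}")


def _rmsecv_curve(X, y, max_lv: int, folds, pipeline=None) -> np.ndarray:
    """RMSECV(h) for h = 1..max_lv_eff over the given validation folds.

    max_lv is reduced (with a warning) if some training fold cannot
    support it.  ``pipeline`` (an unfitted transformer) is cloned and
    refit inside each training fold to avoid leakage.
    """
    from sklearn.base import clone

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    min_train = min(n - len(f) for f in folds)
    cap = min(max_lv, min_train - 1, p)
    if cap < max_lv:
        warnings.warn(
            f"max_lv reduced from {max_lv} to {cap} to fit the smallest "
            f"training fold", stacklevel=3,
        )
    if cap < 1:
        raise ValueError("folds too small for even one latent variable")
    press = np.zeros(cap)
    counted = 0
    for val in folds:
        train = np.setdiff1d(np.arange(n), val)
        Xtr, ytr = X[train], y[train]
        Xva = X[val]
        if pipeline is not None:
            pipe = clone(pipeline).fit(Xtr)
            Xtr = pipe.transform(Xtr)
            Xva = pipe.transform(Xva)
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            *_, coef_path, n_eff = _nipals_path(Xtr - x_mean, ytr - y_mean, cap)
        if n_eff < cap:  # rank-deficient fold: pad with the last usable coefs
            coef_path = np.column_stack(
                [coef_path] + [coef_path[:, -1:]] * (cap - n_eff)
            ) if n_eff else np.zeros((Xtr.shape[1], cap))
        pred = y_mean + (Xva - x_mean) @ coef_path  # (n_val, cap)
        press += ((pred - y[val, None]) ** 2).sum(axis=0)
        counted += len(val)
    return np.sqrt(press / counted)


def cross_validate(X, y, max_lv: int, scheme: str = "venetian:10",
                   pipeline=None) -> CVResult:
    """Cross-validated RMSECV curve and LV choice (min RMSECV, smallest on ties)."""
    folds = cv_folds(np.asarray(X).shape[0], scheme)
    curve = _rmsecv_curve(X, y, max_lv, folds, pipeline=pipeline)
    chosen = int(np.argmin(curve)) + 1  # argmin returns the first = smallest LV
    return CVResult(rmsecv=curve, chosen_lv=chosen)
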