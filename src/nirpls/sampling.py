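"""SPXy calibration/prediction splitting.

SPXy generalizes Kennard-Stone sample selection to joint X-y space:
pairwise distances are Euclidean on spectra and absolute on the
response, each normalized by its maximum, and summed.  The two most
distant samples seed the calibration set; samples are then added
greedily by maximal minimum distance to the already-selected set.  The
leftover samples form the prediction set, so both sets span the
response range and the calibration set covers the spectral space.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .dataset import SplitIndices

__all__ = ["spxy_split", "kennard_stone_distances"]


def kennard_stone_distances(X, y=None) -> np.ndarray:
    """Joint normalized distance matrix d_x/max(d_x) + d_y/max(d_y).

    With ``y=None`` this is plain Kennard-Stone (X-only) normalized
    distance.  Raises if all rows of X are identical (max distance 0).
    """
    X = np.asarray(X, dtype=float)
    dx = squareform(pdist(X, metric="euclidean"))
    dx_max = dx.max()
    if dx_max <= 0:
        raise ValueError("all spectra identical: SPXy distances degenerate")
    d = dx / dx_max
    if y is not None:
        y = np.asarray(y, dtype=float).ravel()
        if y.size != X.shape[0]:
            raise ValueError("y length does not match number of spectra")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        dy = np.abs(y[:, None] - y[None, :])
        dy_max = dy.max()
        if dy_max <= 0:
            raise ValueError("y has zero range: SPXy distances degenerate")
        d = d + dy / dy_max
    return d


def spxy_split(X, y, n_cal: int) -> SplitIndices:
    """Split samples into calibration/prediction sets by the SPXy rule.

    Parameters
    ----------
    X : array (n_samples, n_wavelengths)
        Spectra (raw or preprocessed; distances are computed on what is
        passed in).
    y : array (n_samples,)
        Reference concentrations.
    n_cal : int
        Calibration-set size, 2 <= n_cal <= n_samples.  With
        n_cal == n_samples every sample lands in calibration and the
        prediction set is empty.

    Ties in the greedy max-min step break toward the lowest index, so
    the selection is deterministic for a given row order.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= n_cal <= n:
        raise ValueError(f"n_cal must be in [2, {n}], got {n_cal}")
    d = kennard_stone_distances(X, y)

    # seed pair: argmax joint distance, lowest (i, j) on ties
    flat = np.round(d, 12)
    i, j = np.unravel_index(np.argmax(flat), flat.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]

    while len(selected) < n_cal:
        sub = d[np.ix_(remaining, selected)]
        min_d = sub.min(axis=1)
        best = int(np.argmax(np.round(min_d, 12)))
        selected.append(remaining.pop(best))

    return SplitIndices(calibration=np.array(selected), prediction=np.array(remaining))


def default_n_cal(n_samples: int, fraction: float = 0.75) -> int:
    """Calibration size round(fraction * n); 0.75 gives 76 of 101."""
    return int(round(fraction * n_samples))
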