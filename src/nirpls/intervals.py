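"""Interval partitioning and interval-based wavelength selection.

The wavelength axis is cut into contiguous intervals (20 by default on
a full NIR axis) and three selectors pick the informative ones:

* :class:`IntervalPLS` (iPLS) — one PLS model per interval, keep the
  interval with the lowest RMSECV.
* :class:`IntervalSPAPLS` (iSPA-PLS) — successive-projections chains of
  intervals grown by maximal orthogonal projection norm (suppressing
  collinear intervals), every chain prefix scored by RMSECV.
* :class:`FireflyIntervalPLS` (FFiPLS) — a firefly swarm over continuous
  interval-activation vectors; brightness is negative RMSECV of the PLS
  model on the active intervals, fireflies drift toward brighter ones
  with exponentially decaying attraction, decaying inertia and uniform
  noise.

All selectors expose the fitted subset as a boolean ``support_`` over
variables plus ``selected_intervals_``, and ``transform`` restricts a
matrix to the selected columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .pls import _rmsecv_curve, cv_folds

__all__ = [
    "IntervalPartition",
    "make_intervals",
    "FireflyConfig",
    "SelectionResult",
    "IntervalPLS",
    "IntervalSPAPLS",
    "FireflyIntervalPLS",
    "ipls",
    "ispa_pls",
    "ffipls",
]


@dataclass(frozen=True)
class IntervalPartition:
    """Contiguous disjoint half-open index ranges covering 0..n_variables."""

    n_variables: int
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self):
        stop = 0
        for lo, hi in self.ranges:
            if lo != stop or hi <= lo:
                raise ValueError("ranges must be contiguous, non-empty, ordered")
            stop = hi
        if stop != self.n_variables:
            raise ValueError("ranges must cover exactly 0..n_variables")

    @property
    def n_intervals(self) -> int:
        return len(self.ranges)

    def sizes(self) -> list[int]:
        return [hi - lo for lo, hi in self.ranges]

    def columns(self, interval_indices) -> np.ndarray:
        """Sorted variable indices of the union of the given intervals."""
        idx = sorted(set(int(i) for i in interval_indices))
        cols = []
        for i in idx:
            lo, hi = self.ranges[i]
            cols.extend(range(lo, hi))
        return np.array(cols, dtype=int)

    def mask(self, interval_indices) -> np.ndarray:
        m = np.zeros(self.n_variables, dtype=bool)
        m[self.columns(interval_indices)] = True
        return m


def make_intervals(n_variables: int, n_intervals: int) -> IntervalPartition:
    """Equal-width partition: n_intervals-1 intervals of floor(n/k), the
    last takes the remainder (3001 variables, 20 intervals -> 19x150 + 151)."""
    if n_intervals <= 0:
        raise ValueError("n_intervals must be positive")
    if n_intervals > n_variables:
        raise ValueError(
            f"n_intervals ({n_intervals}) exceeds n_variables ({n_variables})"
        )
    size = n_variables // n_intervals
    bounds = [i * size for i in range(n_intervals)] + [n_variables]
    return IntervalPartition(
        n_variables=n_variables,
        ranges=tuple((bounds[i], bounds[i + 1]) for i in range(n_intervals)),
    )


@dataclass
class FireflyConfig:
    """Hyperparameters of the firefly interval search.

    ffpop fireflies move for the given number of generations; the
    attraction of a brighter firefly decays as beta0*exp(-gamma r^2)
    with Euclidean distance r, positions carry an inertia weight w0^t at
    generation t, and alpha scales uniform per-coordinate noise.
    """

    ffpop: int = 50
    generations: int = 50
    w0: float = 0.97
    gamma: float = 1.0
    alpha: float = 0.2
    beta0: float = 1.0
    seed: int | None = None
    max_lv: int = 10

    def __post_init__(self):
        if self.ffpop < 1:
            raise ValueError("ffpop must be >= 1")
        if not 0 < self.w0 <= 1:
            raise ValueError("w0 must be in (0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass
class SelectionResult:
    """Outcome of an interval-selection run."""

    algorithm: str
    selected_intervals: list[int]
    n_variables_selected: int
    fitness: float  # RMSECV of the final model
    chosen_lv: int
    trace: list[float] = field(default_factory=list)  # best fitness per generation
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.trace and np.any(np.diff(self.trace) > 1e-12):
            raise ValueError("best-fitness trace must be non-increasing")


class _IntervalFitness:
    """RMSECV fitness of interval subsets, cached by bitmask."""

    def __init__(self, X, y, partition: IntervalPartition, max_lv: int,
                 cv_scheme: str):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        self.partition = partition
        self.max_lv = max_lv
        self.folds = cv_folds(self.X.shape[0], cv_scheme)
        self.cache: dict[int, tuple[float, int]] = {}
        self.n_evaluations = 0

    def _bitmask(self, intervals) -> int:
        m = 0
        for i in intervals:
            m |= 1 << int(i)
        return m

    def __call__(self, intervals) -> tuple[float, int]:
        """(RMSECV, chosen LV) of the PLS model on the interval union."""
        key = self._bitmask(intervals)
        if key == 0:
            return (np.inf, 0)
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        cols = self.partition.columns(intervals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                curve = _rmsecv_curve(
                    self.X[:, cols], self.y, self.max_lv, self.folds
                )
                lv = int(np.argmin(curve)) + 1
                out = (float(curve[lv - 1]), lv)
            except Exception:
                out = (np.inf, 0)
        self.cache[key] = out
        self.n_evaluations += 1
        return out


class _BaseIntervalSelector(TransformerMixin, BaseEstimator):
    """Shared fitted surface: support_, selected_intervals_, transform."""

    def _finalize(self, partition, intervals, fitness, lv, trace=None, extras=None):
        intervals = sorted(int(i) for i in intervals)
        self.partition_ = partition
        self.selected_intervals_ = intervals
        self.support_ = partition.mask(intervals)
        self.n_variables_selected_ = int(self.support_.sum())
        self.fitness_ = float(fitness)
        self.n_lv_ = int(lv)
        self.trace_ = list(trace) if trace is not None else []
        self.extras_ = extras or {}
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.support_.size:
            raise ValueError(
                f"X has {X.shape[1]} columns, selector expects {self.support_.size}"
            )
        return X[:, self.support_]

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)

    def result(self) -> SelectionResult:
        return SelectionResult(
            algorithm=type(self).__name__,
            selected_intervals=self.selected_intervals_,
            n_variables_selected=self.n_variables_selected_,
            fitness=self.fitness_,
            chosen_lv=self.n_lv_,
            trace=self.trace_,
            extras=self.extras_,
        )

    def _partition_for(self, X):
        if isinstance(self.n_intervals, IntervalPartition):
            return self.n_intervals
        return make_intervals(np.asarray(X).shape[1], int(self.n_intervals))


class IntervalPLS(_BaseIntervalSelector):
    """iPLS: per-interval PLS models, keep the lowest-RMSECV interval.

    mode="single" (classic) returns one interval; mode="forward" keeps
    greedily adding intervals while RMSECV improves.
    """

    def __init__(self, n_intervals=20, max_lv: int = 10,
                 cv: str = "venetian:10", mode: str = "single"):
        self.n_intervals = n_intervals
        self.max_lv = max_lv
        self.cv = cv
        self.mode = mode

    def fit(self, X, y):
        if self.mode not in ("single", "forward"):
            raise ValueError("mode must be 'single' or 'forward'")
        partition = self._partition_for(X)
        fitness = _IntervalFitness(X, y, partition, self.max_lv, self.cv)
        per_interval = [fitness([i]) for i in range(partition.n_intervals)]
        self.rmsecv_per_interval_ = np.array([r for r, _ in per_interval])
        best = int(np.argmin(self.rmsecv_per_interval_))
        selected = [best]
        fit_val, lv = per_interval[best]
        if self.mode == "forward":
            improved = True
            while improved and len(selected) < partition.n_intervals:
                improved = False
                candidates = [
                    (fitness(selected + [j]), j)
                    for j in range(partition.n_intervals) if j not in selected
                ]
                (cand_val, cand_lv), j = min(candidates)
                if cand_val < fit_val - 1e-15:
                    selected.append(j)
                    fit_val, lv = cand_val, cand_lv
                    improved = True
        return self._finalize(partition, selected, fit_val, lv)


class IntervalSPAPLS(_BaseIntervalSelector):
    """iSPA-PLS: successive-projection chains of intervals scored by RMSECV.

    Each interval is represented by its mean spectrum over samples (a
    column vector in sample space).  From every possible starting
    interval a chain is grown; at each step the unused interval whose
    representative has the largest norm orthogonal to the span of the
    chain's representatives is appended — exact duplicates project to
    zero and are never chosen next, which suppresses collinearity.
    Every chain prefix (lengths 1..max_intervals) is a candidate subset;
    the one with minimum RMSECV wins (ties: fewer intervals, then
    lexicographic order).
    """

    def __init__(self, n_intervals=20, max_intervals: int = 5,
                 max_lv: int = 10, cv: str = "venetian:10"):
        self.n_intervals = n_intervals
        self.max_intervals = max_intervals
        self.max_lv = max_lv
        self.cv = cv

    def fit(self, X, y):
        partition = self._partition_for(X)
        if self.max_intervals > partition.n_intervals:
            raise ValueError("max_intervals exceeds the number of intervals")
        X = np.asarray(X, dtype=float)
        k = partition.n_intervals
        reps = np.column_stack([
            X[:, lo:hi].mean(axis=1) for lo, hi in partition.ranges
        ])  # (n_samples, k)
        norms = np.linalg.norm(reps, axis=0)
        usable = norms > 1e-12 * max(norms.max(), 1.0)
        if not np.all(usable):
            warnings.warn(
                f"{int((~usable).sum())} interval representative(s) have zero "
                "norm and are excluded from SPA chains"
            )
        fitness = _IntervalFitness(X, y, partition, self.max_lv, self.cv)
        candidates: set[tuple[int, ...]] = set()
        for start in range(k):
            if not usable[start]:
                continue
            chain = [start]
            Q = reps[:, [start]] / norms[start]
            candidates.add(tuple(sorted(chain)))
            while len(chain) < self.max_intervals:
                resid_norm = np.full(k, -1.0)
                for j in range(k):
                    if j in chain or not usable[j]:
                        continue
                    r = reps[:, j] - Q @ (Q.T @ reps[:, j])
                    resid_norm[j] = np.linalg.norm(r)
                nxt = int(np.argmax(np.round(resid_norm, 12)))
                if resid_norm[nxt] <= 1e-12 * max(norms.max(), 1.0):
                    break
                chain.append(nxt)
                r = reps[:, nxt] - Q @ (Q.T @ reps[:, nxt])
                Q = np.column_stack([Q, r / np.linalg.norm(r)])
                candidates.add(tuple(sorted(chain)))
        scored = sorted(
            (fitness(c), len(c), c) for c in candidates
        )
        (fit_val, lv), _, best = scored[0]
        self.n_candidates_ = len(candidates)
        return self._finalize(partition, list(best), fit_val, lv)


class FireflyIntervalPLS(_BaseIntervalSelector):
    """FFiPLS: firefly-swarm search over interval subsets.

    Each firefly is a continuous position in [0,1]^n_intervals; interval
    k is active when position_k > 0.5.  Brightness is negative RMSECV of
    the PLS model (CV-chosen LV) on the active intervals.  At generation
    t every firefly i moves once toward each brighter j:

        pos_i <- w0^t * pos_i + beta0 * exp(-gamma * r_ij^2) * (pos_j - pos_i)
                 + alpha * (u - 0.5)

    with r_ij the Euclidean position distance and u uniform per
    coordinate; positions are clipped to [0,1].  All-inactive vectors
    are repaired by activating the single interval with the best
    univariate fitness.  The brightest firefly has no brighter neighbor
    and therefore never moves (elitism), so the best-ever fitness trace
    is non-increasing.  Runs are bit-reproducible given (data, config,
    seed).
    """

    def __init__(self, n_intervals=20, config: FireflyConfig | None = None,
                 cv: str = "venetian:10", random_state: int | None = None):
        self.n_intervals = n_intervals
        self.config = config
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        cfg = self.config if self.config is not None else FireflyConfig()
        seed = cfg.seed if cfg.seed is not None else self.random_state
        rng = np.random.default_rng(seed)
        partition = self._partition_for(X)
        k = partition.n_intervals
        fitness = _IntervalFitness(X, y, partition, cfg.max_lv, self.cv)

        # repair target: best single interval
        uni = np.array([fitness([i])[0] for i in range(k)])
        repair_interval = int(np.argmin(uni))

        pos = rng.uniform(size=(cfg.ffpop, k))

        def evaluate(positions):
            masks = positions > 0.5
            vals = np.empty(len(positions))
            lvs = np.empty(len(positions), dtype=int)
            for i, m in enumerate(masks):
                if not m.any():
                    m[repair_interval] = True
                    positions[i, repair_interval] = 0.75
                vals[i], lvs[i] = fitness(np.flatnonzero(m))
            return masks, vals, lvs

        masks, vals, lvs = evaluate(pos)
        best_i = int(np.argmin(vals))
        best = {
            "intervals": list(np.flatnonzero(masks[best_i])),
            "fitness": vals[best_i],
            "lv": lvs[best_i],
        }
        trace = [best["fitness"]]

        for t in range(1, cfg.generations + 1):
            w = cfg.w0 ** t
            for i in range(cfg.ffpop):
                for j in range(cfg.ffpop):
                    if vals[j] < vals[i]:  # j is brighter (lower RMSECV)
                        diff = pos[j] - pos[i]
                        r2 = float(diff @ diff)
                        beta = cfg.beta0 * np.exp(-cfg.gamma * r2)
                        noise = cfg.alpha * (rng.uniform(size=k) - 0.5)
                        pos[i] = w * pos[i] + beta * diff + noise
            np.clip(pos, 0.0, 1.0, out=pos)
            masks, vals, lvs = evaluate(pos)
            gen_best = int(np.argmin(vals))
            if vals[gen_best] < best["fitness"]:
                best = {
                    "intervals": list(np.flatnonzero(masks[gen_best])),
                    "fitness": vals[gen_best],
                    "lv": lvs[gen_best],
                }
            trace.append(best["fitness"])

        self.n_evaluations_ = fitness.n_evaluations
        return self._finalize(
            partition, best["intervals"], best["fitness"], best["lv"],
            trace=trace, extras={"n_evaluations": fitness.n_evaluations},
        )


# ---------------------------------------------------------------------------
# functional wrappers

def ipls(X, y, partition: IntervalPartition, max_lv: int = 10,
         cv_scheme: str = "venetian:10", mode: str = "single") -> SelectionResult:
    sel = IntervalPLS(n_intervals=partition, max_lv=max_lv, cv=cv_scheme,
                      mode=mode).fit(X, y)
    return sel.result()


def ispa_pls(X, y, partition: IntervalPartition, max_intervals: int = 5,
             max_lv: int = 10, cv_scheme: str = "venetian:10") -> SelectionResult:
    sel = IntervalSPAPLS(n_intervals=partition, max_intervals=max_intervals,
                         max_lv=max_lv, cv=cv_scheme).fit(X, y)
    return sel.result()


def ffipls(X, y, partition: IntervalPartition, config: FireflyConfig,
           cv_scheme: str = "venetian:10") -> SelectionResult:
    sel = FireflyIntervalPLS(n_intervals=partition, config=config,
                             cv=cv_scheme).fit(X, y)
    return sel.result()
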