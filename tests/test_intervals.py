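"""Interval partitioning and the three selectors, checked against
planted-truth benchmarks and exhaustive oracles."""

import itertools

import numpy as np
import pytest

from nirpls import (FireflyConfig, FireflyIntervalPLS, IntervalPLS,
                    IntervalPartition, IntervalSPAPLS, SelectionResult,
                    cross_validate, ffipls, ipls, ispa_pls, make_intervals,
                    planted_benchmark)
from nirpls.intervals import _IntervalFitness


class TestPartition:
    @pytest.mark.parametrize("n,k,sizes", [
        (3001, 20, [150] * 19 + [151]),
        (10, 10, [1] * 10),
        (7, 3, [2, 2, 3]),
    ])
    def test_sizes(self, n, k, sizes):
        assert make_intervals(n, k).sizes() == sizes

    def test_covers_and_contiguous(self):
        p = make_intervals(103, 7)
        assert sum(p.sizes()) == 103
        assert p.ranges[0][0] == 0 and p.ranges[-1][1] == 103

    def test_columns_and_mask(self):
        p = make_intervals(10, 5)
        np.testing.assert_array_equal(p.columns([1, 3]), [2, 3, 6, 7])
        assert p.mask([1, 3]).sum() == 4

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_intervals(5, 0)
        with pytest.raises(ValueError):
            make_intervals(5, 6)
        with pytest.raises(ValueError, match="contiguous"):
            IntervalPartition(n_variables=4, ranges=((0, 2), (3, 4)))


@pytest.fixture(scope="module")
def planted_single():
    return planted_benchmark(10, [7], snr=10, seed=3)


@pytest.fixture(scope="module")
def planted_double():
    return planted_benchmark(10, [2, 7], snr=10, seed=42)


class TestIPLS:
    def test_recovers_planted_interval(self, planted_single):
        ds, part, truth = planted_single
        res = ipls(ds.intensities, ds.reference["analyte"], part,
                   max_lv=5, cv_scheme="venetian:5")
        assert res.selected_intervals == [7]

    def test_one_interval_equals_full_spectrum(self, planted_single):
        ds, part, _ = planted_single
        X, y = ds.intensities, ds.reference["analyte"]
        one = make_intervals(X.shape[1], 1)
        res = ipls(X, y, one, max_lv=5, cv_scheme="venetian:5")
        cv = cross_validate(X, y, 5, "venetian:5")
        assert res.selected_intervals == [0]
        assert res.fitness == pytest.approx(cv.min_rmsecv, abs=1e-12)

    def test_matches_per_interval_refit_oracle(self, rng):
        X = rng.normal(size=(25, 20))
        y = 2 * X[:, 13] + rng.normal(0, 0.1, 25)
        part = make_intervals(20, 5)
        res = ipls(X, y, part, max_lv=3, cv_scheme="venetian:5")
        oracle = []
        for lo, hi in part.ranges:
            cv = cross_validate(X[:, lo:hi], y, 3, "venetian:5")
            oracle.append(cv.min_rmsecv)
        assert res.selected_intervals == [int(np.argmin(oracle))]
        assert res.fitness == pytest.approx(min(oracle), abs=1e-12)

    def test_forward_mode_never_worse(self, planted_double):
        ds, part, _ = planted_double
        X, y = ds.intensities, ds.reference["analyte"]
        single = ipls(X, y, part, max_lv=5, cv_scheme="venetian:5")
        fwd = ipls(X, y, part, max_lv=5, cv_scheme="venetian:5", mode="forward")
        assert fwd.fitness <= single.fitness + 1e-12


class TestISPAPLS:
    def test_duplicate_interval_not_selected_twice(self, rng):
        # interval 1 duplicates interval 0 exactly; chains never take both
        n = 40
        info = rng.normal(size=(n, 8))
        y = info @ rng.normal(size=8) + rng.normal(0, 0.05, n)
        noise = rng.normal(size=(n, 16))
        X = np.hstack([info, info, noise])
        part = make_intervals(32, 4)
        sel = IntervalSPAPLS(n_intervals=part, max_intervals=3, max_lv=4,
                             cv="venetian:5").fit(X, y)
        assert not ({0, 1} <= set(sel.selected_intervals_))

    def test_max_intervals_one_reduces_to_ipls(self, planted_single):
        ds, part, _ = planted_single
        X, y = ds.intensities, ds.reference["analyte"]
        spa = ispa_pls(X, y, part, max_intervals=1, max_lv=5,
                       cv_scheme="venetian:5")
        best = ipls(X, y, part, max_lv=5, cv_scheme="venetian:5")
        assert spa.selected_intervals == best.selected_intervals
        assert spa.fitness == pytest.approx(best.fitness, abs=1e-12)

    def test_matches_exhaustive_chain_oracle(self, rng):
        X = rng.normal(size=(30, 18))
        y = X[:, 2] - X[:, 10] + rng.normal(0, 0.05, 30)
        part = make_intervals(18, 6)
        k, max_int = 6, 3
        reps = np.column_stack([X[:, lo:hi].mean(axis=1)
                                for lo, hi in part.ranges])
        # independent chain construction by explicit Gram-Schmidt
        chains = set()
        for start in range(k):
            chain = [start]
            chains.add(tuple(sorted(chain)))
            while len(chain) < max_int:
                V = reps[:, chain]
                P = V @ np.linalg.pinv(V)
                norms = [(-1.0 if j in chain else
                          np.linalg.norm(reps[:, j] - P @ reps[:, j]), j)
                         for j in range(k)]
                best_norm, j = max(norms, key=lambda t: (round(t[0], 12), -t[1]))
                if best_norm <= 1e-12:
                    break
                chain.append(j)
                chains.add(tuple(sorted(chain)))
        fitness = _IntervalFitness(X, y, part, 4, "venetian:5")
        oracle = min((fitness(c), len(c), c) for c in chains)
        res = ispa_pls(X, y, part, max_intervals=max_int, max_lv=4,
                       cv_scheme="venetian:5")
        assert res.fitness == pytest.approx(oracle[0][0], abs=1e-12)
        assert tuple(res.selected_intervals) == oracle[2]


class TestFFiPLS:
    def test_frozen_single_firefly_keeps_initial_selection(self, planted_single):
        ds, part, _ = planted_single
        cfg = FireflyConfig(ffpop=1, generations=5, alpha=0.0, seed=11,
                            max_lv=5)
        res = ffipls(ds.intensities, ds.reference["analyte"], part, cfg,
                     cv_scheme="venetian:5")
        rng = np.random.default_rng(11)
        initial = np.flatnonzero(rng.uniform(size=(1, 10))[0] > 0.5)
        assert res.selected_intervals == sorted(initial)

    def test_trace_monotone_nonincreasing(self, planted_double):
        ds, part, _ = planted_double
        cfg = FireflyConfig(ffpop=10, generations=10, seed=0, max_lv=5)
        res = ffipls(ds.intensities, ds.reference["analyte"], part, cfg,
                     cv_scheme="venetian:5")
        assert all(b <= a + 1e-15 for a, b in zip(res.trace, res.trace[1:]))
        assert len(res.trace) == 11  # initial + one per generation

    def test_finds_exhaustive_optimum(self, planted_double):
        ds, part, _ = planted_double
        X, y = ds.intensities, ds.reference["analyte"]
        fitness = _IntervalFitness(X, y, part, 6, "venetian:5")
        best = min(fitness(list(c))[0]
                   for r in range(1, 11)
                   for c in itertools.combinations(range(10), r))
        hits = 0
        for seed in range(10):
            res = ffipls(X, y, part, FireflyConfig(seed=seed, max_lv=6),
                         cv_scheme="venetian:5")
            hits += abs(res.fitness - best) < 1e-9
        assert hits >= 8

    def test_reproducible_given_seed(self, planted_double):
        ds, part, _ = planted_double
        cfg = FireflyConfig(ffpop=8, generations=5, seed=99, max_lv=5)
        a = ffipls(ds.intensities, ds.reference["analyte"], part, cfg,
                   cv_scheme="venetian:5")
        b = ffipls(ds.intensities, ds.reference["analyte"], part, cfg,
                   cv_scheme="venetian:5")
        assert a.selected_intervals == b.selected_intervals
        assert a.trace == b.trace

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FireflyConfig(ffpop=0)
        with pytest.raises(ValueError):
            FireflyConfig(w0=0.0)
        with pytest.raises(ValueError):
            FireflyConfig(alpha=-1.0)


class TestSelectionInvariants:
    def test_nv_matches_selected_ranges(self, planted_double):
        ds, part, _ = planted_double
        X, y = ds.intensities, ds.reference["analyte"]
        for sel in (IntervalPLS(n_intervals=part, max_lv=5, cv="venetian:5"),
                    IntervalSPAPLS(n_intervals=part, max_intervals=3,
                                   max_lv=5, cv="venetian:5"),
                    FireflyIntervalPLS(n_intervals=part,
                                       config=FireflyConfig(
                                           ffpop=8, generations=5, seed=1,
                                           max_lv=5),
                                       cv="venetian:5")):
            sel.fit(X, y)
            expected = sum(part.sizes()[i] for i in sel.selected_intervals_)
            assert sel.n_variables_selected_ == expected
            assert sel.transform(X).shape == (X.shape[0], expected)

    def test_trace_must_be_monotone(self):
        with pytest.raises(ValueError, match="non-increasing"):
            SelectionResult("x", [0], 1, 1.0, 1, trace=[1.0, 2.0])

    def test_no_free_lunch_on_pure_noise(self):
        # with every interval pure noise, no selected model shows skill
        # on held-out samples: RMSEP stays near the response SD.  (The
        # in-search RMSECV fitness is selection-biased downward by
        # construction and is not a fair baseline comparison.)
        from nirpls import fit_pls1
        for seed in range(6):
            r = np.random.default_rng(seed)
            X = r.normal(size=(40, 40))
            y = r.uniform(1, 2, 40)
            part = make_intervals(40, 8)
            cal, pred = np.arange(30), np.arange(30, 40)
            results = (
                ipls(X[cal], y[cal], part, 4, "venetian:5"),
                ispa_pls(X[cal], y[cal], part, 3, 4, "venetian:5"),
                ffipls(X[cal], y[cal], part,
                       FireflyConfig(ffpop=10, generations=10, seed=5,
                                     max_lv=4), "venetian:5"),
            )
            for res in results:
                cols = part.columns(res.selected_intervals)
                m = fit_pls1(X[cal][:, cols], y[cal], res.chosen_lv)
                rmsep = np.sqrt(np.mean((m.predict(X[pred][:, cols])
                                         - y[pred]) ** 2))
                assert rmsep > 0.8 * np.std(y[pred])
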