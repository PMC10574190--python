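"""End-to-end model comparison protocol.

For every (analyte x preprocessing pipeline x algorithm) cell:
SPXy split -> preprocess (fitted on the calibration rows only) ->
interval selection -> final PLS1 fit at the CV-chosen number of latent
variables -> figures of merit + EJCR, then pairwise F-tests on RMSEP
between algorithms within each (analyte, pipeline).  The output grid is
a merit table with one column per cell, shaped like the conventional
calibration-study comparison tables.

Cells are seeded independently from the run seed and a stable hash of
the cell key, so results do not depend on execution order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import clone

from .dataset import SpectralDataset, read_spectra_csv
from .intervals import (FireflyConfig, FireflyIntervalPLS, IntervalPLS,
                        IntervalSPAPLS, make_intervals)
from .merit import MERIT_ROWS, ejcr, figures_of_merit, ftest_rmsep
from .pls import PLS1Regression, cross_validate
from .preprocess import make_pipeline_from_config
from .sampling import default_n_cal, spxy_split
from .synthetic import generate, soil_preset

__all__ = ["run_comparison", "ComparisonResult", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "dataset": {"synthetic": {"preset": "soil", "n_samples": 101, "seed": 0}},
    "analytes": None,           # default: every analyte in the dataset
    "pipelines": {"raw": [], "snv": [{"method": "snv"}]},
    "algorithms": [{"name": "pls"}, {"name": "ffipls"}],
    "n_intervals": 20,
    "cal_fraction": 0.75,
    "cv": "venetian:10",
    "max_lv": 10,
    "split_on": "preprocessed",  # or "raw"
    "seed": 0,
    "ffipls": {},                # FireflyConfig overrides
    "ispa": {"max_intervals": 5},
}


@dataclass
class CellRecord:
    """One grid cell: selection + merit + accuracy test."""

    analyte: str
    pipeline: str
    algorithm: str
    merit: dict | None = None
    selected_intervals: list[int] = field(default_factory=list)
    ejcr_contains_ideal: bool | None = None
    ejcr_intercept: float | None = None
    ejcr_slope: float | None = None
    seed: int | None = None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


@dataclass
class ComparisonResult:
    grid: pd.DataFrame
    records: list[CellRecord]
    f_tests: pd.DataFrame
    manifest: dict

    @property
    def n_failed(self) -> int:
        return sum(r.failed for r in self.records)


def _load_dataset(entry) -> SpectralDataset:
    if "path" in entry:
        return read_spectra_csv(entry["path"])
    if "synthetic" in entry:
        params = dict(entry["synthetic"])
        preset = params.pop("preset", "soil")
        if preset != "soil":
            raise ValueError(f"unknown synthetic preset {preset!r}")
        dataset, _ = generate(soil_preset(**params))
        return dataset
    raise ValueError("dataset config needs 'path' or 'synthetic'")


def _cell_seed(base: int, *key: str) -> int:
    return (int(base) * 1000003 + zlib.crc32("/".join(key).encode())) % (2 ** 31)


def _run_cell(Xcal, ycal, Xpred, ypred, algo: dict, cfg: dict, seed: int):
    """Select variables, fit the final model, and score one cell."""
    name = algo["name"]
    max_lv = int(algo.get("max_lv", cfg["max_lv"]))
    cv = cfg["cv"]
    n_intervals = int(cfg["n_intervals"])
    max_lv = max(1, min(max_lv, Xcal.shape[0] - 1, Xcal.shape[1]))

    if name == "pls":
        cvres = cross_validate(Xcal, ycal, max_lv, cv)
        lv, fitness = cvres.chosen_lv, cvres.min_rmsecv
        support = np.ones(Xcal.shape[1], dtype=bool)
        intervals = list(range(n_intervals))
    else:
        if name == "ipls":
            sel = IntervalPLS(n_intervals=n_intervals, max_lv=max_lv, cv=cv)
        elif name == "ispa":
            sel = IntervalSPAPLS(
                n_intervals=n_intervals,
                max_intervals=int(algo.get("max_intervals",
                                           cfg["ispa"]["max_intervals"])),
                max_lv=max_lv, cv=cv)
        elif name == "ffipls":
            ff_kwargs = {**cfg.get("ffipls", {}),
                         **{k: v for k, v in algo.items() if k != "name"}}
            ff_kwargs.setdefault("max_lv", max_lv)
            ff_kwargs["seed"] = seed
            sel = FireflyIntervalPLS(n_intervals=n_intervals,
                                     config=FireflyConfig(**ff_kwargs), cv=cv)
        else:
            raise ValueError(f"unknown algorithm {name!r}")
        sel.fit(Xcal, ycal)
        lv, fitness = sel.n_lv_, sel.fitness_
        support = sel.support_
        intervals = sel.selected_intervals_

    model = PLS1Regression(n_components=lv).fit(Xcal[:, support], ycal)
    yhat_cal = model.predict(Xcal[:, support])
    yhat_pred = model.predict(Xpred[:, support])
    report = figures_of_merit(ycal, yhat_cal, ypred, yhat_pred,
                              rmsecv=fitness, lv=model.n_components_,
                              nv=int(support.sum()))
    region = ejcr(ypred, yhat_pred)
    return report, intervals, region


def run_comparison(config: dict | None = None) -> ComparisonResult:
    """Run the full comparison grid; per-cell failures are recorded, not raised."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    dataset = _load_dataset(cfg["dataset"])
    analytes = cfg["analytes"] or list(dataset.reference)
    base_seed = int(cfg["seed"])
    records: list[CellRecord] = []
    columns: dict[tuple, list] = {}

    for analyte in analytes:
        y = dataset.reference[analyte]
        for pipe_name, steps in cfg["pipelines"].items():
            pipe = make_pipeline_from_config(steps, wavelengths=dataset.wavelengths)
            X = dataset.intensities
            if cfg["split_on"] == "preprocessed":
                Xsplit = clone(pipe).fit(X).transform(X)
            else:
                Xsplit = X
            split = spxy_split(Xsplit, y, default_n_cal(dataset.n_samples,
                                                        cfg["cal_fraction"]))
            cal, pred = split.calibration, split.prediction
            fitted = clone(pipe).fit(X[cal])
            Xcal, Xpred = fitted.transform(X[cal]), fitted.transform(X[pred])
            for algo in cfg["algorithms"]:
                key = (analyte, pipe_name, algo["name"])
                seed = _cell_seed(base_seed, *key)
                rec = CellRecord(analyte=analyte, pipeline=pipe_name,
                                 algorithm=algo["name"], seed=seed)
                try:
                    report, intervals, region = _run_cell(
                        Xcal, y[cal], Xpred, y[pred], algo, cfg, seed)
                    rec.merit = report.as_dict()
                    rec.selected_intervals = intervals
                    rec.ejcr_contains_ideal = region.contains_ideal
                    rec.ejcr_intercept = region.intercept
                    rec.ejcr_slope = region.slope
                    columns[key] = [rec.merit[k] for k in MERIT_ROWS]
                except Exception as exc:  # cell failure must not kill the run
                    rec.error = f"{type(exc).__name__}: {exc}"
                    columns[key] = [np.nan] * len(MERIT_ROWS)
                records.append(rec)

    grid = pd.DataFrame(columns, index=[k.upper() for k in MERIT_ROWS])
    grid.columns = pd.MultiIndex.from_tuples(grid.columns,
                                             names=["analyte", "pipeline",
                                                    "algorithm"])

    # pairwise F-tests on RMSEP between algorithms within (analyte, pipeline)
    n_pred = dataset.n_samples - default_n_cal(dataset.n_samples,
                                               cfg["cal_fraction"])
    rows = []
    ok = {(r.analyte, r.pipeline, r.algorithm): r for r in records if not r.failed}
    for analyte in analytes:
        for pipe_name in cfg["pipelines"]:
            algos = [a["name"] for a in cfg["algorithms"]]
            for i, a in enumerate(algos):
                for b in algos[i + 1:]:
                    ra, rb = ok.get((analyte, pipe_name, a)), ok.get(
                        (analyte, pipe_name, b))
                    if ra is None or rb is None:
                        continue
                    ft = ftest_rmsep(ra.merit["rmsep"], n_pred,
                                     rb.merit["rmsep"], n_pred)
                    rows.append({"analyte": analyte, "pipeline": pipe_name,
                                 "model_a": a, "model_b": b, "f": ft.f,
                                 "f_critical": ft.f_critical,
                                 "p_value": ft.p_value,
                                 "significant": ft.significant})
    f_tests = pd.DataFrame(rows)

    manifest = {
        "config": {k: v for k, v in cfg.items()},
        "seed": base_seed,
        "n_samples": dataset.n_samples,
        "n_wavelengths": dataset.n_wavelengths,
        "cell_seeds": {"/".join(k): r.seed
                       for k, r in zip([(r.analyte, r.pipeline, r.algorithm)
                                        for r in records], records)},
    }
    return ComparisonResult(grid=grid, records=records, f_tests=f_tests,
                            manifest=manifest)
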