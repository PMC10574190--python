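"""Spectral calibration data model and delimited-text I/O.

A :class:`SpectralDataset` bundles a strictly increasing wavelength axis
(nm), a samples x wavelengths intensity matrix (reflectance or
absorbance), opaque sample labels and per-analyte reference
concentrations (mg kg^-1).  The CSV layout is single-file interchange:
row 1 is ``sample_id, <analyte names...>, <wavelengths...>`` and each
following row is one sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataset",
    "SplitIndices",
    "wavelength_grid",
    "read_spectra_csv",
    "write_spectra_csv",
]


def wavelength_grid(start_nm: float, end_nm: float, step_nm: float) -> np.ndarray:
    """Inclusive, evenly spaced wavelength axis from ``start_nm`` to ``end_nm``.

    The span must be an integral number of steps (relative tolerance
    1e-9); e.g. 1000-2500 nm at 0.5 nm gives 3001 points.
    """
    if not (start_nm < end_nm):
        raise ValueError(f"start_nm ({start_nm}) must be < end_nm ({end_nm})")
    if step_nm <= 0:
        raise ValueError(f"step_nm must be positive, got {step_nm}")
    span = (end_nm - start_nm) / step_nm
    n_steps = round(span)
    residue = abs(span - n_steps)
    if residue > 1e-9 * max(1.0, abs(span)):
        raise ValueError(
            f"span {end_nm}-{start_nm} is not an integral multiple of "
            f"step {step_nm} (residue {residue:.3e} steps)"
        )
    return start_nm + step_nm * np.arange(n_steps + 1)


@dataclass
class SpectralDataset:
    """Samples x wavelengths spectra with reference concentrations.

    Parameters
    ----------
    wavelengths : array, shape (n_wavelengths,)
        Strictly increasing axis in nm.
    intensities : array, shape (n_samples, n_wavelengths)
        Reflectance or absorbance values, one row per sample.
    sample_ids : list of str
        Opaque labels, one per row.
    reference : dict, analyte name -> array of shape (n_samples,)
        Concentrations in mg kg^-1; non-negative, finite.
    mode_flag : {"reflectance", "absorbance"}
        Stored as-is; no automatic log(1/R) transform is applied.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    reference: dict[str, np.ndarray] = field(default_factory=dict)
    mode_flag: str = "reflectance"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if self.intensities.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"intensities has {self.intensities.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            bad = int(np.argmax(np.diff(self.wavelengths) <= 0))
            raise ValueError(f"wavelengths not strictly increasing at index {bad}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        if not np.all(np.isfinite(self.wavelengths)):
            raise ValueError("wavelengths contain non-finite values")
        n = self.intensities.shape[0]
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample_ids for {n} spectra rows"
            )
        ref = {}
        for name, values in self.reference.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (n,):
                raise ValueError(
                    f"reference '{name}' has length {values.size}, expected {n}"
                )
            if not np.all(np.isfinite(values)):
                raise ValueError(f"reference '{name}' contains non-finite values")
            if np.any(values < 0):
                raise ValueError(f"reference '{name}' contains negative values")
            ref[name] = values
        self.reference = ref
        if self.mode_flag not in ("reflectance", "absorbance"):
            raise ValueError(f"unknown mode_flag {self.mode_flag!r}")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def is_gridded(self, rtol: float = 1e-9) -> bool:
        """True when the axis has a constant step within relative tolerance."""
        steps = np.diff(self.wavelengths)
        return bool(np.all(np.abs(steps - steps[0]) <= rtol * abs(steps[0])))

    def subset(self, rows) -> "SpectralDataset":
        """New dataset restricted to the given row indices."""
        rows = np.asarray(rows, dtype=int)
        return SpectralDataset(
            wavelengths=self.wavelengths,
            intensities=self.intensities[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            reference={k: v[rows] for k, v in self.reference.items()},
            mode_flag=self.mode_flag,
        )


@dataclass
class SplitIndices:
    """Disjoint calibration/prediction row indices covering all samples."""

    calibration: np.ndarray
    prediction: np.ndarray

    def __post_init__(self) -> None:
        self.calibration = np.sort(np.asarray(self.calibration, dtype=int))
        self.prediction = np.sort(np.asarray(self.prediction, dtype=int))
        if self.calibration.size == 0:
            raise ValueError("calibration set must be non-empty")
        if np.intersect1d(self.calibration, self.prediction).size:
            raise ValueError("calibration and prediction sets overlap")

    @property
    def n_total(self) -> int:
        return self.calibration.size + self.prediction.size

    def validate_cover(self, n_samples: int) -> None:
        union = np.union1d(self.calibration, self.prediction)
        if union.size != n_samples or union[0] != 0 or union[-1] != n_samples - 1:
            raise ValueError(f"split does not partition range(0, {n_samples})")

    def to_csv(self, path) -> None:
        rows = [("calibration", i) for i in self.calibration]
        rows += [("prediction", i) for i in self.prediction]
        pd.DataFrame(rows, columns=["set", "row"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SplitIndices":
        df = pd.read_csv(path)
        return cls(
            calibration=df.loc[df["set"] == "calibration", "row"].to_numpy(),
            prediction=df.loc[df["set"] == "prediction", "row"].to_numpy(),
        )


def read_spectra_csv(path, n_analytes: int | None = None) -> SpectralDataset:
    """Read a SpectralDataset from the single-file CSV layout.

    Header: ``sample_id, <analyte names...>, <wavelengths...>``.  Analyte
    columns are detected as the leading non-numeric header cells after
    ``sample_id`` unless ``n_analytes`` is given explicitly.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("CSV must have a sample_id column and wavelength columns")
    cols = list(df.columns)[1:]
    if n_analytes is None:
        n_analytes = 0
        for c in cols:
            try:
                float(c)
                break
            except ValueError:
                n_analytes += 1
    analyte_names = cols[:n_analytes]
    wl_cols = cols[n_analytes:]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header: {exc}") from exc
    inten = df[wl_cols].to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(inten))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-finite intensity at row {int(r)}, wavelength {wl_cols[int(c)]}"
        )
    reference = {}
    for name in analyte_names:
        vals = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            r = int(np.argmax(~np.isfinite(vals)))
            raise ValueError(f"non-finite reference for '{name}' at row {r}")
        reference[name] = vals
    mode = "reflectance"
    return SpectralDataset(
        wavelengths=wavelengths,
        intensities=inten,
        sample_ids=[str(s) for s in df.iloc[:, 0]],
        reference=reference,
        mode_flag=mode,
    )


def write_spectra_csv(dataset: SpectralDataset, path, float_format: str = "%.12g") -> None:
    """Write the single-file CSV layout; round-trips with read_spectra_csv."""
    data = {"sample_id": dataset.sample_ids}
    for name, vals in dataset.reference.items():
        data[name] = vals
    for j, wl in enumerate(dataset.wavelengths):
        data[float_format % wl] = dataset.intensities[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format=float_format)
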