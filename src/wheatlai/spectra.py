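"""Canopy spectra container, wide-CSV I/O, resampling and Savitzky-Golay smoothing.

The analysis operates on per-growth-stage tables of canopy reflectance:
one row per plot sample, one column per wavelength (nm), plus the measured
leaf area index (LAI) of the plot.  All downstream stages assume spectra
resampled to the 350-1350 nm range at 1 nm (1001 bands).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

GROWTH_STAGES = ("jointing", "booting", "flowering", "filling")

#: Default analysis grid: 350-1350 nm at 1 nm -> 1001 bands.
DEFAULT_GRID = (350.0, 1350.0, 1.0)


class SpectraFormatError(ValueError):
    """Raised when a spectra CSV violates the wide-table format contract."""


@dataclass
class SpectraSet:
    """A per-stage set of canopy reflectance spectra with paired LAI values.

    Parameters
    ----------
    wavelengths : (n_bands,) strictly increasing grid in nm.
    reflectance : (n_samples, n_bands) reflectance matrix, values in [0, ~1].
    lai : (n_samples,) dimensionless leaf area index per plot sample.
    stage : growth-stage label (jointing / booting / flowering / filling).
    sample_ids : optional per-sample identifiers; generated if omitted.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    lai: np.ndarray
    stage: str = "jointing"
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.lai = np.asarray(self.lai, dtype=float)
        if self.wavelengths.ndim != 1 or not np.all(np.diff(self.wavelengths) > 0):
            raise SpectraFormatError("wavelength grid must be 1-D and strictly increasing")
        n_samples, n_bands = self.reflectance.shape
        if n_bands != self.wavelengths.size:
            raise SpectraFormatError(
                f"reflectance has {n_bands} bands but grid has {self.wavelengths.size}"
            )
        if self.lai.shape != (n_samples,):
            raise SpectraFormatError("lai must hold one value per sample")
        if not (np.isfinite(self.reflectance).all() and np.isfinite(self.lai).all()):
            raise SpectraFormatError("reflectance and lai must be finite (no missing values)")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i + 1:03d}" for i in range(n_samples)])
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=str)
            if self.sample_ids.shape != (n_samples,):
                raise SpectraFormatError("sample_ids must hold one id per sample")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]


_WAVELENGTH_RE = re.compile(r"^\d+(\.\d+)?$")


def read_spectra_csv(path, stage: str | None = None) -> SpectraSet:
    """Read a wide spectra CSV (`sample_id`, `lai`, then one column per nm).

    Raises :class:`SpectraFormatError` on a missing ``lai`` column, a
    non-monotone wavelength header, or missing values.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if "lai" not in cols:
        raise SpectraFormatError(f"{path}: missing required 'lai' column")
    band_cols = [c for c in cols if _WAVELENGTH_RE.match(str(c))]
    if not band_cols:
        raise SpectraFormatError(f"{path}: no wavelength columns found")
    wavelengths = np.array([float(c) for c in band_cols])
    if not np.all(np.diff(wavelengths) > 0):
        raise SpectraFormatError(f"{path}: wavelength header is not strictly increasing")
    refl = df[band_cols].to_numpy(dtype=float)
    if np.isnan(refl).any() or df["lai"].isna().any():
        raise SpectraFormatError(f"{path}: missing values in table")
    sample_ids = (
        df["sample_id"].astype(str).to_numpy() if "sample_id" in cols else None
    )
    if stage is None:
        stage = df["stage"].iloc[0] if "stage" in cols else "jointing"
    return SpectraSet(wavelengths, refl, df["lai"].to_numpy(dtype=float),
                      stage=stage, sample_ids=sample_ids)


def write_spectra_csv(s: SpectraSet, path) -> None:
    """Write a :class:`SpectraSet` as wide CSV with 6-significant-digit values."""
    cols = {"sample_id": s.sample_ids, "lai": s.lai}
    labels = [
        str(int(w)) if float(w).is_integer() else f"{w:g}" for w in s.wavelengths
    ]
    for j, lab in enumerate(labels):
        cols[lab] = s.reflectance[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")


def resample_to_grid(
    s: SpectraSet,
    start_nm: float = DEFAULT_GRID[0],
    end_nm: float = DEFAULT_GRID[1],
    step_nm: float = DEFAULT_GRID[2],
) -> SpectraSet:
    """Linearly interpolate each spectrum onto ``arange(start, end, step)``
    inclusive of the end point (350-1350 at 1 nm gives 1001 bands).

    Raises ``ValueError`` if the requested grid extends beyond the measured
    wavelength span (no extrapolation).
    """
    grid = np.arange(start_nm, end_nm + step_nm / 2, step_nm)
    if grid[0] < s.wavelengths[0] or grid[-1] > s.wavelengths[-1]:
        raise ValueError(
            f"requested grid [{grid[0]}, {grid[-1]}] nm extends beyond the "
            f"measured span [{s.wavelengths[0]}, {s.wavelengths[-1]}] nm"
        )
    out = np.empty((s.n_samples, grid.size))
    for i in range(s.n_samples):
        out[i] = np.interp(grid, s.wavelengths, s.reflectance[i])
    return replace(s, wavelengths=grid, reflectance=out)


def savitzky_golay_smooth(
    s: SpectraSet, window_len: int = 11, poly_order: int = 2
) -> SpectraSet:
    """Savitzky-Golay smoothing of each spectrum along the band axis.

    Edges are handled by fitting the boundary polynomial to the available
    window ('interp' mode), so a spectrum that is globally a polynomial of
    degree <= poly_order passes through unchanged.
    """
    if window_len % 2 == 0:
        raise ValueError("window_len must be odd")
    if window_len <= poly_order:
        raise ValueError("window_len must exceed poly_order")
    smoothed = savgol_filter(s.reflectance, window_len, poly_order, axis=1, mode="interp")
    return replace(s, reflectance=smoothed)
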