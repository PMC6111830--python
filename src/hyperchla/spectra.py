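"""Containers and preprocessing for hyperspectral water-leaving reflectance.

The central object is :class:`SpectrumSet`: a samples x wavebands matrix on a
uniform 1-nm wavelength grid, tagged with the physical quantity it holds --
water-leaving reflectance (``RL``), remote-sensing reflectance (``RRS``) or
first-derivative reflectance (``FDR``).  All preprocessing steps (trimming to
the 400-900 nm analysis window, Savitzky-Golay smoothing, derivative
computation, R_rs conversion) consume and produce a ``SpectrumSet`` so stages
compose freely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "SpectrumSet",
    "ChlTable",
    "SpectraFormatError",
    "load_spectra",
    "write_spectra_csv",
    "write_chl_csv",
    "trim_to_analysis_range",
    "savgol_smooth",
    "first_derivative",
    "to_rrs",
]

#: tags for the physical quantity a SpectrumSet holds
KINDS = ("RL", "FDR", "RRS")


class SpectraFormatError(ValueError):
    """Raised when an input file or container violates the spectral contract."""


@dataclass
class SpectrumSet:
    """Hyperspectral reflectance matrix on a uniform integer-nm grid.

    Parameters
    ----------
    wavelengths : array of int
        Strictly increasing wavelengths in nm with a constant step.
    values : array, shape (n_samples, n_bands)
        Reflectance (dimensionless) for RL/RRS, or nm^-1 for FDR.
    sample_ids : sequence of str
        Unique per-sample identifiers, alignable to a :class:`ChlTable`.
    kind : {"RL", "FDR", "RRS"}
    station_ids : sequence of str, optional
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: np.ndarray
    kind: str = "RL"
    station_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.station_ids is not None:
            self.station_ids = np.asarray(self.station_ids, dtype=object)
        if self.kind not in KINDS:
            raise SpectraFormatError(f"unknown kind {self.kind!r}; expected one of {KINDS}")
        wl = self.wavelengths
        if wl.ndim != 1 or wl.size < 1:
            raise SpectraFormatError("wavelengths must be a non-empty 1-d array")
        if wl.size > 1:
            steps = np.diff(wl)
            if np.any(steps <= 0) or not np.all(steps == steps[0]):
                raise SpectraFormatError(
                    "wavelengths must be strictly increasing with a constant step"
                )
        if self.values.shape[1] != wl.size:
            raise SpectraFormatError(
                f"values has {self.values.shape[1]} columns but {wl.size} wavelengths"
            )
        if self.values.shape[0] != self.sample_ids.size:
            raise SpectraFormatError("sample_ids length must match number of rows")
        if pd.Index(self.sample_ids).has_duplicates:
            dup = pd.Index(self.sample_ids)
            offenders = sorted(set(dup[dup.duplicated()]))
            raise SpectraFormatError(f"duplicate sample ids: {offenders}")
        if self.kind in ("RL", "RRS") and np.any(self.values < 0):
            raise SpectraFormatError(f"{self.kind} reflectance must be non-negative")

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def step(self) -> float:
        if self.wavelengths.size < 2:
            return float("nan")
        return float(self.wavelengths[1] - self.wavelengths[0])

    def band_index(self, wavelength: float) -> int:
        """Index of the grid band at ``wavelength`` (must lie on the grid)."""
        idx = np.nonzero(self.wavelengths == wavelength)[0]
        if idx.size == 0:
            raise KeyError(f"wavelength {wavelength} nm is not on the grid")
        return int(idx[0])

    def at(self, wavelength: float) -> np.ndarray:
        """Per-sample values at one grid wavelength."""
        return self.values[:, self.band_index(wavelength)]

    def with_values(self, values: np.ndarray, kind: str | None = None,
                    wavelengths: np.ndarray | None = None) -> "SpectrumSet":
        return SpectrumSet(
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
            values=values,
            sample_ids=self.sample_ids,
            kind=self.kind if kind is None else kind,
            station_ids=self.station_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.wavelengths)


@dataclass
class ChlTable:
    """Per-sample chlorophyll-a concentrations (ug/L) with station labels."""

    sample_ids: np.ndarray
    chl: np.ndarray
    station_ids: np.ndarray | None = None
    dates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.chl = np.asarray(self.chl, dtype=float)
        if self.sample_ids.size != self.chl.size:
            raise SpectraFormatError("sample_ids and chl must have equal length")
        if pd.Index(self.sample_ids).has_duplicates:
            raise SpectraFormatError("duplicate sample ids in chlorophyll table")
        if np.any(~np.isfinite(self.chl)) or np.any(self.chl <= 0):
            raise SpectraFormatError("chl values must be finite and > 0")
        if self.station_ids is not None:
            self.station_ids = np.asarray(self.station_ids, dtype=object)

    @property
    def n(self) -> int:
        return self.chl.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids, "chl_ugL": self.chl})
        if self.station_ids is not None:
            df.insert(1, "station_id", self.station_ids)
        if self.dates is not None:
            df["date"] = self.dates
        return df


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_spectra_csv(s: SpectrumSet, path) -> None:
    """Write spectra as CSV: first column sample_id, remaining integer nm."""
    df = s.to_frame().reset_index()
    df.to_csv(path, index=False, float_format="%.17g")


def write_chl_csv(chl: ChlTable, path) -> None:
    df = chl.to_frame()
    if "station_id" not in df.columns:
        df.insert(1, "station_id", "")
    if "date" not in df.columns:
        df["date"] = ""
    df.to_csv(path, index=False, float_format="%.17g")


def load_spectra(path, chl_path) -> tuple[SpectrumSet, ChlTable]:
    """Read a spectra CSV and a chlorophyll CSV and align them on sample_id.

    Samples lacking a chlorophyll value are rejected with an explicit error
    listing the offenders; a non-uniform wavelength grid or duplicate ids are
    format errors.
    """
    try:
        sdf = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SpectraFormatError(f"empty spectra file: {path}") from exc
    if sdf.shape[0] == 0 or sdf.shape[1] < 2:
        raise SpectraFormatError(f"spectra file {path} has no data")
    if sdf.columns[0] != "sample_id":
        raise SpectraFormatError("spectra CSV must start with a sample_id column")
    try:
        wavelengths = np.array([int(c) for c in sdf.columns[1:]])
    except ValueError as exc:
        raise SpectraFormatError("spectra CSV header must be integer wavelengths") from exc

    try:
        cdf = pd.read_csv(chl_path)
    except pd.errors.EmptyDataError as exc:
        raise SpectraFormatError(f"empty chlorophyll file: {chl_path}") from exc
    if "sample_id" not in cdf.columns or "chl_ugL" not in cdf.columns:
        raise SpectraFormatError("chl CSV needs sample_id and chl_ugL columns")

    sids = sdf["sample_id"].astype(str)
    cids = cdf["sample_id"].astype(str)
    missing = sorted(set(sids) - set(cids))
    if missing:
        raise SpectraFormatError(
            f"{len(missing)} spectra sample(s) lack a chlorophyll value: {missing}"
        )
    cdf = cdf.set_index(cids).loc[sids]

    stations = (cdf["station_id"].astype(str).to_numpy()
                if "station_id" in cdf.columns else None)
    dates = cdf["date"].to_numpy() if "date" in cdf.columns else None
    spectra = SpectrumSet(
        wavelengths=wavelengths,
        values=sdf.iloc[:, 1:].to_numpy(dtype=float),
        sample_ids=sids.to_numpy(dtype=object),
        kind="RL",
        station_ids=stations,
    )
    table = ChlTable(sample_ids=sids.to_numpy(dtype=object),
                     chl=cdf["chl_ugL"].to_numpy(dtype=float),
                     station_ids=stations, dates=dates)
    return spectra, table


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def trim_to_analysis_range(s: SpectrumSet, lo: float = 400, hi: float = 900) -> SpectrumSet:
    """Restrict to the analysis window [lo, hi] nm, bounds inclusive.

    The default 400-900 nm window on a 1-nm grid holds 501 bands; the ranges
    below 400 nm and above 900 nm are instrument noise and are discarded.
    """
    wl = s.wavelengths
    if lo > hi:
        raise ValueError(f"lo ({lo}) must not exceed hi ({hi})")
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(
            f"analysis range [{lo}, {hi}] is outside the grid [{wl[0]}, {wl[-1]}]"
        )
    mask = (wl >= lo) & (wl <= hi)
    return s.with_values(s.values[:, mask], wavelengths=wl[mask])


def savgol_smooth(s: SpectrumSet, window: int = 15, polyorder: int = 2) -> SpectrumSet:
    """Savitzky-Golay smoothing of every sample row; grid unchanged.

    The filter fits a local polynomial of the given order in a moving window
    (default 15 points, order 2), which preserves any spectrum that is locally
    polynomial up to that order.  Smoothing of a noisy non-negative spectrum
    can slightly undershoot zero; RL/RRS output is clipped at zero to keep the
    reflectance contract.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > s.n_bands:
        raise ValueError("window exceeds the number of bands")
    out = savgol_filter(s.values, window_length=window, polyorder=polyorder, axis=1)
    if s.kind in ("RL", "RRS"):
        out = np.clip(out, 0.0, None)
    return s.with_values(out)


def first_derivative(s: SpectrumSet) -> SpectrumSet:
    """First-derivative reflectance (FDR), in nm^-1, on the same grid.

    Uses centred differences at interior bands and one-sided differences at
    the two edges, so an N-band input yields an N-band FDR spectrum.  The
    derivative suppresses smooth baseline and suspended-matter effects while
    keeping pigment absorption features.
    """
    if s.kind != "RL":
        raise ValueError("first_derivative expects kind='RL' input")
    if s.n_bands < 2:
        raise ValueError("need at least two bands to differentiate")
    deriv = np.gradient(s.values, s.wavelengths.astype(float), axis=1)
    return s.with_values(deriv, kind="FDR")


def to_rrs(s: SpectrumSet, convention: str = "divide") -> SpectrumSet:
    """Convert water-leaving reflectance to remote-sensing reflectance.

    R_rs and R_L differ by the constant factor pi; the default convention is
    ``R_rs = R_L / pi`` (sr^-1).  Every band-ratio algorithm downstream is
    invariant to this constant, so the choice only affects absolute values.
    """
    if s.kind != "RL":
        raise ValueError("to_rrs expects kind='RL' input")
    if convention == "divide":
        vals = s.values / math.pi
    elif convention == "multiply":
        vals = s.values * math.pi
    else:
        raise ValueError("convention must be 'divide' or 'multiply'")
    return s.with_values(vals, kind="RRS")
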