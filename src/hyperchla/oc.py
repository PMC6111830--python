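"""Empirical ocean-chlorophyll (OC) band-ratio algorithms, version 6.

The OC family estimates Chl-a from the maximum blue/green remote-sensing
reflectance ratio via a fourth-order polynomial:

    log10(Chl-a) = a0 + a1*R + a2*R^2 + a3*R^3 + a4*R^4,
    R = log10( max_b Rrs(blue_b) / Rrs(green) )

OC2 uses the single 490/555 ratio, OC3 the maximum of 443/555 and 490/555,
OC4 additionally 510/555 (SeaWiFS band centres).  The standard version-6
coefficient vectors ship in a registry; `oc_recalibrate` refits the five
coefficients to a local dataset by ordinary least squares of log10(Chl-a)
on the polynomial basis — the canonical adjustment when applying the
algorithms to waters optically unlike the global calibration set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectrumSet

__all__ = ["OCVariant", "OCCoefficients", "OCRatioResult", "OC_VARIANTS",
           "STANDARD_COEFFICIENTS", "oc_ratio", "oc_predict", "oc_recalibrate"]


@dataclass(frozen=True)
class OCVariant:
    """Band definition of one OC algorithm (wavelengths in nm)."""

    name: str
    blue_bands: tuple[int, ...]
    green_band: int = 555


OC_VARIANTS: dict[str, OCVariant] = {
    "OC2": OCVariant("OC2", (490,)),
    "OC3": OCVariant("OC3", (443, 490)),
    "OC4": OCVariant("OC4", (443, 490, 510)),
}


@dataclass(frozen=True)
class OCCoefficients:
    """Polynomial coefficients (a0..a4) of Eq. log10(Chl) = sum a_k R^k."""

    a: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.a) != 5 or not np.all(np.isfinite(self.a)):
            raise ValueError("need exactly 5 finite coefficients")

    def __iter__(self):
        return iter(self.a)


#: standard version-6 coefficient vectors (a0, a1, a2, a3, a4)
STANDARD_COEFFICIENTS: dict[str, OCCoefficients] = {
    "OC2": OCCoefficients((0.2511, -2.0853, 1.5035, -3.1747, 0.3383)),
    "OC3": OCCoefficients((0.2515, -2.3798, 1.5823, -0.6372, -0.5692)),
    "OC4": OCCoefficients((0.3272, -2.9940, 2.7218, -1.2259, -0.5683)),
}


@dataclass
class OCRatioResult:
    """Per-sample log10 maximum band ratio with an explicit validity mask.

    Samples with non-positive Rrs at a required band are flagged (``valid``
    False, value NaN) rather than silently propagated, because a NaN inside
    the max-ratio selection would corrupt the result.
    """

    values: np.ndarray
    valid: np.ndarray

    @property
    def n_flagged(self) -> int:
        return int((~self.valid).sum())


def _nearest_band(s: SpectrumSet, wavelength: int, box_width: int = 1) -> np.ndarray:
    """Rrs at the grid band nearest ``wavelength``; optional boxcar average."""
    wl = np.asarray(s.wavelengths, dtype=float)
    idx = int(np.argmin(np.abs(wl - wavelength)))
    if box_width <= 1:
        return s.values[:, idx]
    half = box_width // 2
    lo, hi = max(0, idx - half), min(s.n_bands, idx + half + 1)
    return s.values[:, lo:hi].mean(axis=1)


def oc_ratio(s: SpectrumSet, variant: OCVariant | str,
             box_width: int = 1) -> OCRatioResult:
    """R = log10(max over blue bands of Rrs(blue)/Rrs(green)) per sample.

    Band extraction takes the nearest 1-nm grid band to each nominal centre
    (``box_width`` > 1 averages a boxcar of that many bands).  Invariant to
    uniform scaling of a spectrum, hence to the R_L/R_rs pi convention.
    """
    if isinstance(variant, str):
        variant = OC_VARIANTS[variant]
    if s.kind != "RRS":
        raise ValueError("oc_ratio expects kind='RRS' spectra")
    green = _nearest_band(s, variant.green_band, box_width)
    blues = np.column_stack([_nearest_band(s, b, box_width)
                             for b in variant.blue_bands])
    valid = (green > 0) & np.all(blues > 0, axis=1)
    values = np.full(s.n_samples, np.nan)
    if valid.any():
        ratios = blues[valid] / green[valid, None]
        values[valid] = np.log10(ratios.max(axis=1))
    return OCRatioResult(values=values, valid=valid)


def oc_predict(R: np.ndarray | OCRatioResult,
               coeffs: OCCoefficients | str) -> np.ndarray:
    """Chl-a (ug/L) from the log10 band ratio via the 4th-order polynomial."""
    if isinstance(coeffs, str):
        coeffs = STANDARD_COEFFICIENTS[coeffs]
    if isinstance(R, OCRatioResult):
        R = R.values
    R = np.asarray(R, dtype=float)
    log_chl = np.polynomial.polynomial.polyval(R, np.asarray(list(coeffs)))
    return 10.0 ** log_chl


def oc_recalibrate(s: SpectrumSet, chl: np.ndarray, variant: OCVariant | str,
                   box_width: int = 1) -> tuple[OCCoefficients, dict]:
    """Refit the five polynomial coefficients to a local dataset by OLS.

    Regresses log10(chl) on (1, R, R^2, R^3, R^4) over the valid samples.
    Returns the coefficients and fit diagnostics (n used, flagged count,
    RMS residual in log10 space).
    """
    if isinstance(variant, str):
        variant = OC_VARIANTS[variant]
    chl = np.asarray(chl, dtype=float).ravel()
    if chl.size != s.n_samples:
        raise ValueError("chl length does not match spectra")
    rat = oc_ratio(s, variant, box_width)
    use = rat.valid & (chl > 0)
    n_used = int(use.sum())
    if n_used < 6:
        raise ValueError(f"need >= 6 valid samples, have {n_used}")
    R = rat.values[use]
    design = np.vander(R, 5, increasing=True)
    rank = np.linalg.matrix_rank(design)
    if rank < 5:
        raise np.linalg.LinAlgError(
            f"rank-deficient polynomial design (rank {rank} < 5); "
            "band-ratio values are not distinct enough")
    target = np.log10(chl[use])
    a, res, *_ = np.linalg.lstsq(design, target, rcond=None)
    fitted = design @ a
    diagnostics = {"n_used": n_used, "n_flagged": rat.n_flagged,
                   "log10_rms_residual": float(np.sqrt(np.mean((target - fitted) ** 2)))}
    return OCCoefficients(tuple(a)), diagnostics
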