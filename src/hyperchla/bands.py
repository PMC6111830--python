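"""Semi-analytical red/NIR band indices, stepwise spectral tuning, and the
exhaustive band-ratio R^2 matrix.

Two conceptual indices are implemented:

* three-band: (1/R(l1) - 1/R(l2)) * R(l3), with l1 in the red chlorophyll
  absorption region, l2 in the NIR where Chl-a absorption is minimal, and
  l3 further into the NIR where no constituent absorbs appreciably;
* two-band: R(l_nir) / R(l_red), the classic NIR/red ratio.

Both are invariant to per-sample positive scaling of the spectrum.  The
tuning searches scan one wavelength at a time (single pass, no iteration),
keeping the candidate maximising |Pearson r| between the index and Chl-a;
ties break toward the smallest wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectrumSet

__all__ = ["BandTriplet", "BandPair", "LinearFit", "TuningResult",
           "three_band_value", "two_band_value", "tune_three_band",
           "tune_two_band", "calibrate_linear", "ratio_matrix"]


@dataclass(frozen=True)
class BandTriplet:
    """Wavelengths (nm) of the three-band index; l1 < l2 < l3."""

    l1: int
    l2: int
    l3: int


@dataclass(frozen=True)
class BandPair:
    """Red and NIR wavelengths (nm) of the two-band ratio; red < nir."""

    red: int
    nir: int


@dataclass
class LinearFit:
    """OLS calibration Chl-a = a * index + b with training-set statistics."""

    a: float
    b: float
    r2: float
    rmse: float
    bias: float

    def predict(self, index: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(index, dtype=float) + self.b


@dataclass
class TuningResult:
    """Outcome of a stepwise band search.

    ``traces`` maps stage name to a DataFrame (wavelength, r) of the
    correlation scan for that stage.
    """

    selected: BandTriplet | BandPair
    traces: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def n_stages(self) -> int:
        return len(self.traces)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        return 0.0  # constant index carries no information
    return float((x @ y) / denom)


def three_band_value(s: SpectrumSet, t: BandTriplet) -> np.ndarray:
    """(1/R(l1) - 1/R(l2)) * R(l3) per sample; zero R(l1)/R(l2) -> NaN flag."""
    r1, r2, r3 = s.at(t.l1), s.at(t.l2), s.at(t.l3)
    out = np.full(s.n_samples, np.nan)
    ok = (r1 != 0) & (r2 != 0)
    out[ok] = (1.0 / r1[ok] - 1.0 / r2[ok]) * r3[ok]
    return out


def two_band_value(s: SpectrumSet, p: BandPair) -> np.ndarray:
    """R(nir) / R(red) per sample; zero red reflectance -> NaN flag."""
    red, nir = s.at(p.red), s.at(p.nir)
    out = np.full(s.n_samples, np.nan)
    ok = red != 0
    out[ok] = nir[ok] / red[ok]
    return out


def _check_tuning_inputs(s: SpectrumSet, chl: np.ndarray) -> np.ndarray:
    chl = np.asarray(chl, dtype=float).ravel()
    if chl.size != s.n_samples:
        raise ValueError("chl length does not match spectra")
    if chl.size < 3:
        raise ValueError("need at least 3 samples to tune")
    if np.ptp(chl) == 0:
        raise ValueError("constant chl: correlation undefined")
    return chl


def _scan(candidates: np.ndarray, chl: np.ndarray, index_fn) -> tuple[int, pd.DataFrame]:
    rs = np.empty(candidates.size)
    for k, wl in enumerate(candidates):
        vals = index_fn(int(wl))
        ok = np.isfinite(vals)
        rs[k] = _pearson(vals[ok], chl[ok]) if ok.sum() >= 3 else 0.0
    best = int(candidates[np.argmax(np.abs(rs))])  # first max = smallest wl
    return best, pd.DataFrame({"wavelength": candidates, "r": rs})


def _grid_range(s: SpectrumSet, lo: float, hi: float) -> np.ndarray:
    wl = s.wavelengths
    cand = wl[(wl >= lo) & (wl <= hi)]
    if cand.size == 0:
        raise ValueError(f"no grid bands inside [{lo}, {hi}] nm")
    return cand


def tune_three_band(s: SpectrumSet, chl: np.ndarray,
                    ranges: tuple[tuple[float, float], ...] = ((600, 700), (680, 740), (700, 800)),
                    init_l2: int = 700, init_l3: int = 750,
                    iterate: bool = False, max_iter: int = 10) -> TuningResult:
    """Three-stage search for the optimal (l1, l2, l3).

    Stage 1 scans l1 with (init_l2, init_l3) fixed; stage 2 scans l2 with
    the chosen l1 and init_l3; stage 3 scans l3 with (l1, l2) fixed.  Later
    stages are restricted to wavelengths above the previously fixed band so
    the returned triplet satisfies l1 < l2 < l3.

    The default is a single pass.  With ``iterate=True`` the three stages
    are repeated, re-initialised from the previous selection, until the
    triplet stops changing (a fixed point of the search) or ``max_iter``
    passes have run; the traces of the last pass are returned.
    """
    chl = _check_tuning_inputs(s, chl)

    def one_pass(i2: int, i3: int):
        c1 = _grid_range(s, *ranges[0])
        l1, t1 = _scan(c1, chl, lambda w: three_band_value(s, BandTriplet(w, i2, i3)))
        c2 = _grid_range(s, *ranges[1])
        c2 = c2[c2 > l1]
        l2, t2 = _scan(c2, chl, lambda w: three_band_value(s, BandTriplet(l1, w, i3)))
        c3 = _grid_range(s, *ranges[2])
        c3 = c3[c3 > l2]
        l3, t3 = _scan(c3, chl, lambda w: three_band_value(s, BandTriplet(l1, l2, w)))
        return BandTriplet(l1, l2, l3), {"lambda1": t1, "lambda2": t2, "lambda3": t3}

    selected, traces = one_pass(init_l2, init_l3)
    if iterate:
        for _ in range(max_iter - 1):
            nxt, traces = one_pass(selected.l2, selected.l3)
            if nxt == selected:
                break
            selected = nxt
    return TuningResult(selected=selected, traces=traces)


def tune_two_band(s: SpectrumSet, chl: np.ndarray,
                  red_range: tuple[float, float] = (620, 680),
                  nir_range: tuple[float, float] = (680, 740),
                  init_nir: int = 705, iterate: bool = False,
                  max_iter: int = 10) -> TuningResult:
    """Two-stage search for the optimal NIR/red band pair.

    Stage 1 scans the red band with the NIR band fixed at ``init_nir``;
    stage 2 scans the NIR band (restricted above the chosen red band).
    ``iterate=True`` repeats the two stages from the previous selection
    until the pair stops changing.
    """
    chl = _check_tuning_inputs(s, chl)

    def one_pass(i_nir: int):
        c1 = _grid_range(s, *red_range)
        red, t1 = _scan(c1, chl, lambda w: two_band_value(s, BandPair(w, i_nir)))
        c2 = _grid_range(s, *nir_range)
        c2 = c2[c2 > red]
        nir, t2 = _scan(c2, chl, lambda w: two_band_value(s, BandPair(red, w)))
        return BandPair(red, nir), {"red": t1, "nir": t2}

    selected, traces = one_pass(init_nir)
    if iterate:
        for _ in range(max_iter - 1):
            nxt, traces = one_pass(selected.nir)
            if nxt == selected:
                break
            selected = nxt
    return TuningResult(selected=selected, traces=traces)


def calibrate_linear(index: np.ndarray, chl: np.ndarray) -> LinearFit:
    """OLS calibration Chl-a = a * index + b, with training R^2/RMSE/bias.

    Because the fit includes an intercept, the training-set bias is zero to
    numerical precision; it is reported for symmetry with external models.
    """
    index = np.asarray(index, dtype=float).ravel()
    chl = np.asarray(chl, dtype=float).ravel()
    ok = np.isfinite(index) & np.isfinite(chl)
    index, chl = index[ok], chl[ok]
    if index.size < 2:
        raise ValueError("need at least 2 finite samples")
    if np.ptp(index) == 0:
        raise ValueError("constant index: slope undefined")
    xm, ym = index.mean(), chl.mean()
    xc = index - xm
    a = float((xc @ (chl - ym)) / (xc @ xc))
    b = float(ym - a * xm)
    pred = a * index + b
    resid = pred - chl
    ss_tot = float(np.sum((chl - ym) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return LinearFit(a=a, b=b, r2=r2,
                     rmse=float(np.sqrt(np.mean(resid ** 2))),
                     bias=float(resid.mean()))


def ratio_matrix(s: SpectrumSet, chl: np.ndarray) -> pd.DataFrame:
    """R^2 of the simple regression of Chl-a on R(li)/R(lj), all band pairs.

    Entry (i, j) uses band i as numerator and band j as denominator; the
    diagonal is NaN (a constant ratio carries no information).  Samples with
    zero or non-finite denominator values are excluded per pair.  On the
    501-band analysis grid this is the full 501 x 501 matrix.
    """
    chl = _check_tuning_inputs(s, chl)
    R = s.values
    n_bands = s.n_bands
    out = np.full((n_bands, n_bands), np.nan)
    yc = chl - chl.mean()
    syy = yc @ yc
    for j in range(n_bands):
        denom = R[:, j]
        ok = np.isfinite(denom) & (denom != 0)
        if ok.sum() < 3:
            continue
        ratios = R[ok][:, :] / denom[ok, None]
        y = chl[ok]
        yc_j = y - y.mean()
        syy_j = yc_j @ yc_j
        if syy_j == 0:
            continue
        Xc = ratios - ratios.mean(axis=0)
        sxy = yc_j @ Xc
        sxx = np.einsum("ij,ij->j", Xc, Xc)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (sxy ** 2) / (sxx * syy_j)
        r2[~np.isfinite(r2)] = np.nan
        out[:, j] = r2
    np.fill_diagonal(out, np.nan)
    wl = s.wavelengths
    return pd.DataFrame(out, index=pd.Index(wl, name="numerator_nm"),
                        columns=pd.Index(wl, name="denominator_nm"))
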