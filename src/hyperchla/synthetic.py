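"""Forward simulation of paired (Chl-a, water-leaving reflectance) datasets.

The generator produces spectra with the qualitative optical structure of
phytoplankton-dominated coastal water over 350-1050 nm:

* a broad reflectance baseline peaking in the green (~580 nm, minimum pigment
  absorption),
* Beer-Lambert-style attenuation by chlorophyll absorption Gaussians in the
  red (~670 nm) and blue (~443 nm), an exponentially decaying CDOM term, and
  a flatter tripton (suspended-matter) absorption term,
* a chlorophyll fluorescence / scattering peak near 685 nm whose amplitude
  grows with Chl-a and whose centre red-shifts with concentration,
* strong, smooth water absorption above ~750 nm (NIR ramp),
* multiplicative and additive sensor noise, clipped at zero.

Two sources of stochasticity are distinguished.  *Sensor noise* (the
multiplicative/additive terms) perturbs each measured spectrum.  *Water
composition variability* (per-sample log-normal jitter of the CDOM and
tripton levels) makes the optically active constituents vary across samples
independently of Chl-a, as they do in coastal water.  The latter is what
makes wavelength selection a meaningful problem: without it every band is a
deterministic function of Chl-a and correlation-based band tuning becomes
degenerate.  ``noise_free`` switches off the sensor noise only;
``deterministic`` additionally freezes the composition jitter so the
spectrum is an exact function of Chl-a.

This is a phenomenological model built for testability of the retrieval
algorithms, not a radiative-transfer simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .spectra import ChlTable, SpectrumSet

__all__ = ["SyntheticParams", "SyntheticDataset", "generate_chl",
           "simulate_spectrum", "generate_dataset", "noise_free",
           "deterministic"]

#: station sample counts of the emulated 59-sample, six-station campaign
_CAMPAIGN_STATIONS = (12, 12, 12, 12, 6, 5)


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the forward model.

    Defaults emulate a 59-sample coastal campaign spanning 0.83-14.33 ug/L
    Chl-a.  ``red_shift_rate`` of 1 nm/(ug/L) moves the fluorescence peak
    from ~685 nm at the bottom of that range to ~699 nm at the top.
    """

    n_samples: int = 59
    chl_range: tuple[float, float] = (0.83, 14.33)
    chl_distribution: str = "log-uniform"          # or "uniform"
    grid: tuple[float, float, float] = (350.0, 1050.0, 1.0)
    fluor_center0: float = 685.0                   # nm, peak centre at chl -> 0
    red_shift_rate: float = 1.0                    # nm per ug/L
    abs_red_center: float = 670.0                  # nm
    abs_blue_center: float = 443.0                 # nm
    green_peak_center: float = 580.0               # nm
    noise_sd_additive: float = 1e-4                # reflectance units
    noise_sd_multiplicative: float = 0.02          # fraction
    cdom_level: float = 0.25                       # relative absorption scale
    seed: int = 0

    # per-sample water-composition variability (log-normal sigma of the
    # CDOM / tripton levels across samples; 0 freezes composition)
    cdom_sd_log: float = 0.30
    tripton_level: float = 0.10
    tripton_sd_log: float = 0.50
    tripton_decay: float = 0.004                   # nm^-1 from 400 nm

    # shape/magnitude constants of the forward model (per-ug/L absorption
    # scales, Gaussian widths in nm, baseline reflectance levels)
    abs_red_scale: float = 0.035
    abs_blue_scale: float = 0.020
    abs_red_sigma: float = 13.0
    abs_blue_sigma: float = 28.0
    cdom_decay: float = 0.011                      # nm^-1 from 400 nm
    baseline_offset: float = 0.006
    baseline_green_amp: float = 0.022
    baseline_green_sigma: float = 95.0
    fluor_amp_per_chl: float = 0.0012              # reflectance per ug/L
    fluor_sigma: float = 8.0
    nir_ramp_center: float = 770.0                 # nm
    nir_ramp_width: float = 22.0                   # nm

    def validate(self) -> None:
        lo, hi = self.chl_range
        if not (0 < lo < hi):
            raise ValueError(f"chl_range must satisfy 0 < min < max, got {self.chl_range}")
        start, stop, step = self.grid
        if step <= 0 or stop <= start:
            raise ValueError(f"invalid grid {self.grid}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.chl_distribution not in ("log-uniform", "uniform"):
            raise ValueError(f"unknown chl_distribution {self.chl_distribution!r}")
        for name in ("fluor_center0", "abs_red_center", "abs_blue_center",
                     "green_peak_center"):
            c = getattr(self, name)
            if not (start <= c <= stop):
                raise ValueError(f"{name}={c} nm lies outside the grid {self.grid}")

    def wavelengths(self) -> np.ndarray:
        start, stop, step = self.grid
        n = int(round((stop - start) / step)) + 1
        return start + step * np.arange(n)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chl_range"] = list(d["chl_range"])
        d["grid"] = list(d["grid"])
        return d


@dataclass
class SyntheticDataset:
    """Spectra + chlorophyll + per-sample generator ground truth."""

    spectra: SpectrumSet
    chl: np.ndarray
    truth: pd.DataFrame
    params: SyntheticParams

    def __post_init__(self) -> None:
        if self.spectra.n_samples != self.chl.size:
            raise ValueError("spectra rows and chl length differ")
        if np.any(self.spectra.values < 0):
            raise ValueError("reflectance must be non-negative")

    def chl_table(self) -> ChlTable:
        return ChlTable(sample_ids=self.spectra.sample_ids, chl=self.chl,
                        station_ids=self.spectra.station_ids)


def generate_chl(params: SyntheticParams) -> np.ndarray:
    """Draw ``n_samples`` Chl-a concentrations (ug/L) inside ``chl_range``.

    The default log-uniform draw reflects the right-skewed concentration
    distributions typical of bloom-prone coastal campaigns (many low values,
    a few high ones).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.chl_range
    if params.chl_distribution == "log-uniform":
        chl = np.exp(rng.uniform(np.log(lo), np.log(hi), size=params.n_samples))
    else:
        chl = rng.uniform(lo, hi, size=params.n_samples)
    return np.clip(chl, lo, hi)


def _clean_spectrum(chl: float, params: SyntheticParams, wl: np.ndarray,
                    cdom_level: float | None = None,
                    tripton_level: float | None = None) -> tuple[np.ndarray, dict]:
    """Sensor-noise-free forward model; returns (reflectance, truth record)."""
    cdom_level = params.cdom_level if cdom_level is None else cdom_level
    tripton_level = params.tripton_level if tripton_level is None else tripton_level

    baseline = params.baseline_offset + params.baseline_green_amp * np.exp(
        -0.5 * ((wl - params.green_peak_center) / params.baseline_green_sigma) ** 2)

    red_mag = chl * params.abs_red_scale
    blue_mag = chl * params.abs_blue_scale
    absorption = (red_mag * np.exp(-0.5 * ((wl - params.abs_red_center)
                                           / params.abs_red_sigma) ** 2)
                  + blue_mag * np.exp(-0.5 * ((wl - params.abs_blue_center)
                                              / params.abs_blue_sigma) ** 2))
    cdom = cdom_level * np.exp(-params.cdom_decay * (wl - 400.0))
    tripton = tripton_level * np.exp(-params.tripton_decay * (wl - 400.0))

    fluor_center = params.fluor_center0 + params.red_shift_rate * chl
    fluor_amp = params.fluor_amp_per_chl * chl
    fluor = fluor_amp * np.exp(-0.5 * ((wl - fluor_center) / params.fluor_sigma) ** 2)

    ramp = 1.0 / (1.0 + np.exp((wl - params.nir_ramp_center) / params.nir_ramp_width))
    refl = (baseline * np.exp(-(absorption + cdom + tripton)) + fluor) * ramp
    truth = {"fluor_center_nm": fluor_center, "fluor_amp": fluor_amp,
             "abs_red_mag": red_mag, "abs_blue_mag": blue_mag,
             "cdom_level": cdom_level, "tripton_level": tripton_level}
    return refl, truth


def simulate_spectrum(chl: float, params: SyntheticParams,
                      noise_seed: int | None = None) -> np.ndarray:
    """Simulate one reflectance spectrum for a Chl-a concentration (ug/L).

    Sensor noise is multiplicative Gaussian (fractional sd
    ``noise_sd_multiplicative``) plus additive Gaussian (sd
    ``noise_sd_additive``), independent across bands, clipped at zero.
    The constituent levels are taken at their nominal values; per-sample
    composition jitter is applied by :func:`generate_dataset`.
    """
    params.validate()
    if not np.isfinite(chl) or chl <= 0:
        raise ValueError(f"chl must be positive, got {chl}")
    wl = params.wavelengths()
    refl, _ = _clean_spectrum(float(chl), params, wl)
    if params.noise_sd_multiplicative > 0 or params.noise_sd_additive > 0:
        rng = np.random.default_rng(noise_seed)
        refl = refl * (1.0 + params.noise_sd_multiplicative * rng.standard_normal(wl.size))
        refl = refl + params.noise_sd_additive * rng.standard_normal(wl.size)
    return np.clip(refl, 0.0, None)


def _station_labels(n: int) -> np.ndarray:
    """Assign samples to pseudo-stations, emulating a six-station campaign."""
    labels: list[str] = []
    counts = list(_CAMPAIGN_STATIONS)
    station = 0
    for _ in range(n):
        while station < len(counts) and counts[station] == 0:
            station += 1
        if station >= len(counts):        # beyond 59 samples: cycle stations
            labels.append(f"st{(len(labels) % len(_CAMPAIGN_STATIONS)) + 1}")
            continue
        labels.append(f"st{station + 1}")
        counts[station] -= 1
    return np.asarray(labels, dtype=object)


def generate_dataset(params: SyntheticParams | None = None) -> SyntheticDataset:
    """Generate a full paired dataset: spectra, chlorophyll, and ground truth.

    Identical ``(params, seed)`` give bit-identical output.  Per-sample CDOM
    and tripton levels are drawn log-normally around their nominal levels
    (``cdom_sd_log``/``tripton_sd_log`` log-sigmas), then sensor noise is
    drawn independently per sample, all from streams derived from
    ``params.seed``.
    """
    if params is None:
        params = SyntheticParams()
    params.validate()
    chl = generate_chl(params)
    wl = params.wavelengths()
    comp_rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    cdom_levels = params.cdom_level * np.exp(
        params.cdom_sd_log * comp_rng.standard_normal(params.n_samples))
    tripton_levels = params.tripton_level * np.exp(
        params.tripton_sd_log * comp_rng.standard_normal(params.n_samples))
    noise_master = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    noise_seeds = noise_master.integers(2 ** 31, size=params.n_samples)

    noisy = params.noise_sd_multiplicative > 0 or params.noise_sd_additive > 0
    rows = np.empty((params.n_samples, wl.size))
    records = []
    for i, c in enumerate(chl):
        refl, truth = _clean_spectrum(float(c), params, wl,
                                      cdom_level=float(cdom_levels[i]),
                                      tripton_level=float(tripton_levels[i]))
        if noisy:
            rng = np.random.default_rng(int(noise_seeds[i]))
            refl = refl * (1.0 + params.noise_sd_multiplicative
                           * rng.standard_normal(wl.size))
            refl = refl + params.noise_sd_additive * rng.standard_normal(wl.size)
        rows[i] = np.clip(refl, 0.0, None)
        truth["noise_seed"] = int(noise_seeds[i])
        truth["chl_ugL"] = float(c)
        records.append(truth)

    ids = np.asarray([f"s{i + 1:03d}" for i in range(params.n_samples)], dtype=object)
    wavelengths = wl.astype(int) if float(params.grid[2]).is_integer() else wl
    spectra = SpectrumSet(wavelengths=wavelengths, values=rows, sample_ids=ids,
                          kind="RL", station_ids=_station_labels(params.n_samples))
    truth = pd.DataFrame(records, index=pd.Index(ids, name="sample_id"))
    return SyntheticDataset(spectra=spectra, chl=chl, truth=truth, params=params)


def noise_free(params: SyntheticParams | None = None) -> SyntheticParams:
    """Copy of ``params`` with the sensor-noise terms switched off.

    Water-composition variability is retained; use :func:`deterministic`
    to freeze that as well.
    """
    if params is None:
        params = SyntheticParams()
    return replace(params, noise_sd_additive=0.0, noise_sd_multiplicative=0.0)


def deterministic(params: SyntheticParams | None = None) -> SyntheticParams:
    """Copy of ``params`` in which a spectrum is an exact function of Chl-a:
    sensor noise off and composition jitter frozen at the nominal levels."""
    return replace(noise_free(params), cdom_sd_log=0.0, tripton_sd_log=0.0)
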