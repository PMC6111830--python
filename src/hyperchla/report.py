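"""Model-comparison orchestration: run every retrieval algorithm on one
dataset and emit consolidated report tables.

The comparison mirrors the standard structure of a retrieval-method
intercomparison: descriptive statistics of the campaign, one row per
empirical/semi-analytical model (OC2/3/4 standard and recalibrated,
three-band tuned, NIR/red fixed and tuned) with R^2 / RMSE / bias, and one
row per ISE-PLS dataset (R_L and FDR) with calibration and LOO-validation
statistics, RPD and the selected-band percentage.  An optional
station-exclusion rerun repeats the ISE-PLS validation without one station
to probe sensitivity to the Chl-a range.

Every report embeds the resolved configuration (including the seed), so a
rerun with the same config reproduces it bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bands as bd
from . import isepls as ip
from . import metrics as mt
from . import oc as ocmod
from .spectra import (ChlTable, SpectrumSet, first_derivative, load_spectra,
                      savgol_smooth, to_rrs, trim_to_analysis_range)
from .synthetic import SyntheticParams, generate_dataset

__all__ = ["RunConfig", "ReportBundle", "preprocess", "compare_models",
           "write_report"]


@dataclass
class RunConfig:
    """Resolved configuration of one comparison run.

    Either ``spectra_csv``/``chl_csv`` point at input files, or the
    synthetic generator is used with ``synthetic`` parameter overrides.
    """

    spectra_csv: str | None = None
    chl_csv: str | None = None
    synthetic: dict = field(default_factory=dict)
    seed: int = 0
    smooth_window: int = 15
    smooth_polyorder: int = 2
    analysis_range: tuple[float, float] = (400.0, 900.0)
    rrs_convention: str = "divide"
    max_nlv: int = 10
    sd_convention: str = "population"
    exclude_stations: tuple[str, ...] = ()
    with_ratio_matrix: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.spectra_csv is None) != (self.chl_csv is None):
            raise ValueError("spectra_csv and chl_csv must be given together")
        if self.smooth_window % 2 == 0 or self.smooth_window <= self.smooth_polyorder:
            raise ValueError("smooth_window must be odd and > polyorder")
        lo, hi = self.analysis_range
        if lo >= hi:
            raise ValueError("invalid analysis_range")
        if self.max_nlv < 1:
            raise ValueError("max_nlv must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analysis_range"] = list(d["analysis_range"])
        d["exclude_stations"] = list(d["exclude_stations"])
        return d

    def synthetic_params(self) -> SyntheticParams:
        over = dict(self.synthetic)
        over.setdefault("seed", self.seed)
        if "chl_range" in over:
            over["chl_range"] = tuple(over["chl_range"])
        if "grid" in over:
            over["grid"] = tuple(over["grid"])
        return SyntheticParams(**over)


@dataclass
class ReportBundle:
    """All tables produced by one comparison run."""

    config: dict
    descriptive: pd.DataFrame
    models: pd.DataFrame
    isepls: pd.DataFrame
    isepls_results: dict[str, ip.ISEPLSResult]
    station_rerun: pd.DataFrame | None = None
    ratio_matrix: pd.DataFrame | None = None


def _load_dataset(config: RunConfig) -> tuple[SpectrumSet, ChlTable]:
    if config.spectra_csv is not None:
        return load_spectra(config.spectra_csv, config.chl_csv)
    ds = generate_dataset(config.synthetic_params())
    return ds.spectra, ds.chl_table()


def preprocess(spectra: SpectrumSet, config: RunConfig) -> dict[str, SpectrumSet]:
    """Smoothing on the native grid, trim to the analysis window, derived sets.

    Smoothing precedes trimming so the analysis window carries no filter edge
    artefacts.  Returns the R_L, R_rs and FDR spectrum sets on the analysis
    grid.
    """
    smoothed = savgol_smooth(spectra, config.smooth_window, config.smooth_polyorder)
    rl = trim_to_analysis_range(smoothed, *config.analysis_range)
    return {"RL": rl, "RRS": to_rrs(rl, config.rrs_convention),
            "FDR": first_derivative(rl)}


def _metrics_row(name: str, equation: str, detail: str,
                 m: mt.Metrics) -> dict:
    return {"model": name, "equation": equation, "detail": detail,
            "r2": m.r2, "rmse": m.rmse, "bias": m.bias, "n": m.n}


def _fmt_coeffs(c) -> str:
    return "[" + " ".join(f"{v:.6g}" for v in c) + "]"


def compare_models(config: RunConfig) -> ReportBundle:
    """Run the full model comparison described in the module docstring."""
    config.validate()
    spectra, chl_table = _load_dataset(config)
    sets = preprocess(spectra, config)
    rl, rrs, fdr = sets["RL"], sets["RRS"], sets["FDR"]
    y = chl_table.chl

    rows: list[dict] = []
    poly_eq = "Chl_a = 10^(a0+a1*R+a2*R^2+a3*R^3+a4*R^4)"

    # OC algorithms, standard then recalibrated coefficients
    for name, variant in ocmod.OC_VARIANTS.items():
        rat = ocmod.oc_ratio(rrs, variant)
        ok = rat.valid
        pred = ocmod.oc_predict(rat.values[ok], ocmod.STANDARD_COEFFICIENTS[name])
        m = mt.compute_metrics(y[ok], pred, config.sd_convention)
        rows.append(_metrics_row(
            name, poly_eq,
            f"bands {variant.blue_bands}/{variant.green_band}, "
            f"a = {_fmt_coeffs(ocmod.STANDARD_COEFFICIENTS[name])}", m))
    for name, variant in ocmod.OC_VARIANTS.items():
        coeffs, diag = ocmod.oc_recalibrate(rrs, y, variant)
        rat = ocmod.oc_ratio(rrs, variant)
        ok = rat.valid
        pred = ocmod.oc_predict(rat.values[ok], coeffs)
        m = mt.compute_metrics(y[ok], pred, config.sd_convention)
        rows.append(_metrics_row(
            f"Recalibrated {name}", poly_eq,
            f"bands {variant.blue_bands}/{variant.green_band}, "
            f"a = {_fmt_coeffs(coeffs)}", m))

    # three-band, tuned
    tuned3 = bd.tune_three_band(rl, y)
    t = tuned3.selected
    idx3 = bd.three_band_value(rl, t)
    fit3 = bd.calibrate_linear(idx3, y)
    m3 = mt.compute_metrics(y, fit3.predict(idx3), config.sd_convention)
    rows.append(_metrics_row(
        "Three-band", "Chl_a = a*R + b",
        f"R = (R({t.l1})^-1 - R({t.l2})^-1)*R({t.l3}), "
        f"a = {fit3.a:.4g}, b = {fit3.b:.4g}", m3))

    # two-band, fixed 705/670 then tuned
    fixed_pair = bd.BandPair(red=670, nir=705)
    idx2f = bd.two_band_value(rl, fixed_pair)
    fit2f = bd.calibrate_linear(idx2f, y)
    m2f = mt.compute_metrics(y, fit2f.predict(idx2f), config.sd_convention)
    rows.append(_metrics_row(
        "NIR/red", "Chl_a = a*R + b",
        f"R = R(705)/R(670), a = {fit2f.a:.4g}, b = {fit2f.b:.4g}", m2f))

    tuned2 = bd.tune_two_band(rl, y)
    p = tuned2.selected
    idx2 = bd.two_band_value(rl, p)
    fit2 = bd.calibrate_linear(idx2, y)
    m2 = mt.compute_metrics(y, fit2.predict(idx2), config.sd_convention)
    rows.append(_metrics_row(
        "NIR/red tuning", "Chl_a = a*R + b",
        f"R = R({p.nir})/R({p.red}), a = {fit2.a:.4g}, b = {fit2.b:.4g}", m2))

    models = pd.DataFrame(rows)

    # ISE-PLS on RL and FDR
    ise_results: dict[str, ip.ISEPLSResult] = {}
    ise_rows = []
    for key, sset in (("RL", rl), ("FDR", fdr)):
        res = ip.run_ise_pls(sset, y, max_nlv=config.max_nlv,
                             sd_convention=config.sd_convention)
        ise_results[key] = res
        ise_rows.append(res.summary)
    isepls_table = pd.DataFrame(ise_rows)

    # optional station-exclusion rerun (ISE-PLS on RL without some stations)
    station_rerun = None
    if config.exclude_stations and chl_table.station_ids is not None:
        keep = ~np.isin(chl_table.station_ids, list(config.exclude_stations))
        if keep.sum() >= 10:
            sub = SpectrumSet(wavelengths=rl.wavelengths,
                              values=rl.values[keep],
                              sample_ids=rl.sample_ids[keep], kind="RL",
                              station_ids=(rl.station_ids[keep]
                                           if rl.station_ids is not None else None))
            res = ip.run_ise_pls(sub, y[keep], max_nlv=config.max_nlv,
                                 sd_convention=config.sd_convention)
            row = dict(res.summary)
            row["excluded"] = ",".join(config.exclude_stations)
            row["chl_min"] = float(y[keep].min())
            row["chl_max"] = float(y[keep].max())
            station_rerun = pd.DataFrame([row])

    rmatrix = bd.ratio_matrix(rl, y) if config.with_ratio_matrix else None

    return ReportBundle(config=config.to_dict(),
                        descriptive=mt.descriptive_table(chl_table),
                        models=models, isepls=isepls_table,
                        isepls_results=ise_results,
                        station_rerun=station_rerun, ratio_matrix=rmatrix)


def write_report(bundle: ReportBundle, outdir) -> list[Path]:
    """Serialise a report bundle to CSV/JSON files; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = outdir / name
        df.to_csv(path, index=index, float_format="%.17g")
        written.append(path)

    with open(outdir / "config.json", "w") as fh:
        json.dump(bundle.config, fh, indent=2, sort_keys=True)
    written.append(outdir / "config.json")
    _csv(bundle.descriptive, "descriptive_stats.csv", index=True)
    _csv(bundle.models, "model_comparison.csv")
    _csv(bundle.isepls, "isepls_summary.csv")
    for key, res in bundle.isepls_results.items():
        _csv(res.trace.as_frame(), f"isepls_{key.lower()}_trace.csv")
        _csv(res.nlv_selection.as_frame(), f"isepls_{key.lower()}_nlv.csv")
        model_doc = {
            "dataset": key,
            "nlv": res.model.nlv,
            "wavelengths_nm": [int(w) for w in res.wavelengths],
            "beta": [float(b) for b in res.model.beta],
            "x_mean": [float(v) for v in res.model.x_mean],
            "y_mean": res.model.y_mean,
            "intercept": res.model.intercept,
        }
        path = outdir / f"isepls_{key.lower()}_model.json"
        with open(path, "w") as fh:
            json.dump(model_doc, fh, indent=2)
        written.append(path)
    if bundle.station_rerun is not None:
        _csv(bundle.station_rerun, "station_exclusion_rerun.csv")
    if bundle.ratio_matrix is not None:
        _csv(bundle.ratio_matrix, "ratio_matrix_r2.csv", index=True)
    return written


def plot_ratio_matrix(rmatrix: pd.DataFrame, path) -> None:
    """Render the band-ratio R^2 matrix as a PNG heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    wl = rmatrix.columns.to_numpy(dtype=float)
    im = ax.imshow(rmatrix.to_numpy(), origin="lower", aspect="auto",
                   extent=(wl[0], wl[-1], wl[0], wl[-1]), vmin=0, vmax=1,
                   cmap="viridis")
    ax.set_xlabel("denominator band (nm)")
    ax.set_ylabel("numerator band (nm)")
    fig.colorbar(im, ax=ax, label="$R^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_validation(cv: ip.CVResult, path, title: str = "") -> None:
    """Scatter of observed vs LOO-predicted Chl-a with the 1:1 line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(cv.y_obs, cv.y_pred, s=18, alpha=0.8)
    lim = (0, max(cv.y_obs.max(), cv.y_pred.max()) * 1.05)
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlim(lim); ax.set_ylim(lim)
    ax.set_xlabel("observed Chl-a (ug/L)")
    ax.set_ylabel("predicted Chl-a (ug/L)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
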