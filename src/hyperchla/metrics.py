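"""Shared model-assessment metrics and descriptive statistics.

Conventions (exposed where a choice exists):

* R^2 is the squared Pearson correlation between observed and predicted
  values (a ``1 - SS_res/SS_tot`` alternative is available by flag).
* bias = mean(predicted - observed), so underestimation is negative.
* RPD = SD(observed) / RMSE, with the n-divisor (population) standard
  deviation by default; descriptive tables use the (n-1) sample SD.
* RPD classes: > 2 good, 1.4-2 moderately good, < 1.4 poor; boundary values
  are assigned to the higher class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import ChlTable

__all__ = ["Metrics", "compute_metrics", "rpd_class", "descriptive_table",
           "population_sd", "sample_sd", "sample_to_population_sd",
           "pooled_mean"]


def sample_sd(y: np.ndarray) -> float:
    """Standard deviation with the (n-1) divisor."""
    return float(np.std(np.asarray(y, dtype=float), ddof=1))


def population_sd(y: np.ndarray) -> float:
    """Standard deviation with the n divisor."""
    return float(np.std(np.asarray(y, dtype=float), ddof=0))


def sample_to_population_sd(sd: float, n: int) -> float:
    """Convert an (n-1)-divisor SD to the n-divisor form."""
    if n < 2:
        raise ValueError("need n >= 2")
    return float(sd * np.sqrt((n - 1) / n))


def pooled_mean(counts, means) -> float:
    """Pooled mean from per-group sample counts and group means."""
    counts = np.asarray(counts, dtype=float)
    means = np.asarray(means, dtype=float)
    if counts.size != means.size or counts.size == 0:
        raise ValueError("counts and means must be equal-length, non-empty")
    return float((counts * means).sum() / counts.sum())


@dataclass
class Metrics:
    """Assessment bundle for one model on one dataset."""

    r2: float
    rmse: float               # ug/L
    bias: float               # ug/L, mean(pred - obs)
    sd: float                 # ug/L, SD of observations
    rpd: float                # dimensionless, sd / rmse
    n: int

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "bias": self.bias,
                "sd": self.sd, "rpd": self.rpd, "n": self.n}


def compute_metrics(y_obs, y_pred, sd_convention: str = "population",
                    r2_convention: str = "pearson") -> Metrics:
    """R^2, RMSE, bias, SD and RPD of predictions against observations.

    ``rpd`` is infinite (flagged, not an error) for perfect predictions.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size != y_pred.size:
        raise ValueError("y_obs and y_pred must have equal length")
    if y_obs.size < 2:
        raise ValueError("need at least two samples")
    if np.ptp(y_obs) == 0:
        raise ValueError("constant y_obs: R^2 undefined")

    resid = y_pred - y_obs
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    bias = float(resid.mean())
    if r2_convention == "pearson":
        a = y_obs - y_obs.mean()
        b = y_pred - y_pred.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        r2 = float(((a @ b) / denom) ** 2) if denom > 0 else float("nan")
    elif r2_convention == "ss":
        ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    else:
        raise ValueError("r2_convention must be 'pearson' or 'ss'")
    if sd_convention == "population":
        sd = population_sd(y_obs)
    elif sd_convention == "sample":
        sd = sample_sd(y_obs)
    else:
        raise ValueError("sd_convention must be 'population' or 'sample'")
    rpd = sd / rmse if rmse > 0 else float("inf")
    return Metrics(r2=r2, rmse=rmse, bias=bias, sd=sd, rpd=rpd, n=y_obs.size)


def rpd_class(rpd: float) -> str:
    """Qualitative predictive-ability class of a residual predictive deviation."""
    if rpd < 0:
        raise ValueError("rpd must be non-negative")
    if rpd >= 2.0:
        return "good"
    if rpd >= 1.4:
        return "moderate"
    return "poor"


def descriptive_table(chl: ChlTable) -> pd.DataFrame:
    """Per-station and pooled descriptive statistics of Chl-a (ug/L).

    Columns: N, min, max, mean, sd ((n-1) divisor), cv = sd/mean.  Groups
    with a single sample report missing sd/cv.
    """
    df = chl.to_frame()
    if "station_id" not in df.columns:
        df["station_id"] = "all"

    def _stats(g: pd.Series) -> pd.Series:
        sd = g.std(ddof=1) if g.size > 1 else np.nan
        return pd.Series({"N": g.size, "min": g.min(), "max": g.max(),
                          "mean": g.mean(), "sd": sd,
                          "cv": sd / g.mean() if g.size > 1 else np.nan})

    rows = df.groupby("station_id", sort=True)["chl_ugL"].apply(_stats).unstack()
    total = _stats(df["chl_ugL"]).to_frame().T
    total.index = pd.Index(["Total"], name="station_id")
    out = pd.concat([rows, total])
    out["N"] = out["N"].astype(int)
    return out
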