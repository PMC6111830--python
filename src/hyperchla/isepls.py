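"""PLS1 regression with iterative stepwise elimination of wavebands (ISE-PLS).

The engine combines four pieces:

1. **PLS1 (NIPALS)** on mean-centred (not autoscaled) data: the response
   y (Chl-a, ug/L) is regressed on the reflectance matrix X by projecting X
   onto a small number of orthogonal latent variables; the result is a vector
   of weighted regression coefficients beta over the retained bands.
2. **Leave-one-out cross-validation (LOO)**: every sample is predicted by a
   model fitted on the remaining n-1; RMSE = sqrt(mean((y_i - y_p)^2)).
3. **Iterative stepwise elimination**: each cycle fits a PLS model (number of
   latent variables re-selected by LOO-minimum RMSE), computes the predictor
   importance z_i = |beta_i| * s_i / sum(|beta_i| * s_i) with s_i the
   per-band standard deviation, and removes the single band with the lowest
   importance; the band set with the global minimum cross-validated RMSE over
   all cycles is kept.
4. **Final latent-variable selection**: on the selected bands, for each
   candidate count j = 1..10 the LOO RMSE and the coefficient jaggedness
   J_j = sum_i (beta_ji - beta_j,i-1)^2 (successive differences in
   wavelength order) are computed, each rescaled to [0, 1], and the j
   minimising RMSE_r + J_r is chosen.  The jaggedness penalty discourages
   the rough coefficient vectors typical of over-fitted models.

Everything in this module is deterministic; ties break toward fewer latent
variables, fewer bands and smaller wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectrumSet

__all__ = ["PLSModel", "CVResult", "ImportanceVector", "EliminationTrace",
           "NLVSelection", "ISEPLSResult", "pls_fit", "pls_predict",
           "loo_rmse", "loo_predictions", "select_nlv_by_rmse", "importance",
           "ise_eliminate", "jaggedness", "select_final_nlv", "run_ise_pls"]

_TINY = 1e-14


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Centred-data PLS1 solution.

    Training predictions satisfy ``y_mean + (X - x_mean) @ beta`` exactly.
    ``band_mask`` records which bands of the originating grid are retained
    (all True for a model fitted on a full matrix).
    """

    nlv: int
    beta: np.ndarray              # per retained band, chl per reflectance unit
    x_mean: np.ndarray
    y_mean: float
    band_mask: np.ndarray
    residuals: np.ndarray

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.beta)

    @property
    def n_bands(self) -> int:
        return int(self.beta.size)


@dataclass
class CVResult:
    """Observed vs leave-one-out predicted values with summary statistics."""

    y_obs: np.ndarray
    y_pred: np.ndarray
    rmse: float
    r2: float

    @property
    def n(self) -> int:
        return int(self.y_obs.size)


@dataclass
class ImportanceVector:
    """Normalised predictor importance z_i = |beta_i| s_i / sum |beta_i| s_i."""

    z: np.ndarray
    s: np.ndarray

    @property
    def n_predictors(self) -> int:
        return int(self.z.size)


@dataclass
class EliminationTrace:
    """Per-cycle record of the elimination loop."""

    retained_counts: list[int] = field(default_factory=list)
    masks: list[np.ndarray] = field(default_factory=list)
    nlvs: list[int] = field(default_factory=list)
    rmses: list[float] = field(default_factory=list)
    best_cycle: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cycle": np.arange(len(self.rmses)),
                             "retained": self.retained_counts,
                             "nlv": self.nlvs, "loo_rmse": self.rmses})


@dataclass
class NLVSelection:
    """RMSE/jaggedness trade-off over candidate latent-variable counts."""

    candidates: np.ndarray
    rmse_cv: np.ndarray
    jaggedness: np.ndarray
    rmse_r: np.ndarray
    jaggedness_r: np.ndarray
    chosen_nlv: int
    degenerate_rmse: bool = False

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"nlv": self.candidates, "rmse_cv": self.rmse_cv,
                             "J": self.jaggedness, "rmse_r": self.rmse_r,
                             "J_r": self.jaggedness_r})


@dataclass
class ISEPLSResult:
    """Full ISE-PLS pipeline output (model + diagnostics + report row)."""

    model: PLSModel
    cv: CVResult
    trace: EliminationTrace
    nlv_selection: NLVSelection
    wavelengths: np.ndarray       # selected band centres, nm
    summary: dict


# ---------------------------------------------------------------------------
# Core PLS1
# ---------------------------------------------------------------------------

def _nipals(X0: np.ndarray, y0: np.ndarray, nlv: int):
    """NIPALS PLS1 on centred data; returns (W, P, q, n_effective).

    Extraction stops early if the residual covariance vanishes (rank
    exhausted); remaining components are zero-padded, which leaves
    predictions unchanged.
    """
    n, p = X0.shape
    W = np.zeros((p, nlv))
    P = np.zeros((p, nlv))
    q = np.zeros(nlv)
    Xr = X0.copy()
    yr = y0.copy()
    k_eff = 0
    for k in range(nlv):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw <= _TINY:
            break
        w /= nw
        t = Xr @ w
        tt = t @ t
        if tt <= _TINY:
            break
        W[:, k] = w
        P[:, k] = Xr.T @ t / tt
        q[k] = (yr @ t) / tt
        Xr -= np.outer(t, P[:, k])
        yr = yr - q[k] * t
        k_eff = k + 1
    return W, P, q, k_eff


def _beta_from_loadings(W: np.ndarray, P: np.ndarray, q: np.ndarray,
                        j: int) -> np.ndarray:
    """Regression coefficients using the first ``j`` latent variables."""
    if j == 0:
        return np.zeros(W.shape[0])
    Wj, Pj, qj = W[:, :j], P[:, :j], q[:j]
    # (P^T W) is upper triangular for NIPALS; small j so a dense solve is fine
    return Wj @ np.linalg.solve(Pj.T @ Wj, qj)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-d (samples x bands)")
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("X and y must be finite (no missing values)")
    return X, y


def pls_fit(X: np.ndarray, y: np.ndarray, nlv: int,
            band_mask: np.ndarray | None = None) -> PLSModel:
    """Fit a mean-centred PLS1 model with ``nlv`` latent variables.

    With one predictor and ``nlv=1`` this reduces to simple OLS; with
    ``nlv`` equal to the rank of the centred X it reproduces multivariate
    least squares.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if nlv < 1:
        raise ValueError("nlv must be >= 1")
    if nlv > min(n - 1, p):
        raise ValueError(f"nlv={nlv} exceeds min(n-1={n - 1}, bands={p})")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, _ = _nipals(X - x_mean, y - y_mean, nlv)
    beta = _beta_from_loadings(W, P, q, nlv)
    resid = y - (y_mean + (X - x_mean) @ beta)
    if band_mask is None:
        band_mask = np.ones(p, dtype=bool)
    return PLSModel(nlv=nlv, beta=beta, x_mean=x_mean, y_mean=y_mean,
                    band_mask=np.asarray(band_mask, dtype=bool),
                    residuals=resid)


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict Chl-a for new spectra (columns must match the fitted bands)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.beta.size:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.beta.size}")
    return model.y_mean + (X - model.x_mean) @ model.beta


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

def _rmse(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))


def _r2_pearson(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    a = y_obs - y_obs.mean()
    b = y_pred - y_pred.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return float("nan")
    return float(((a @ b) / denom) ** 2)


def loo_predictions(X: np.ndarray, y: np.ndarray, max_nlv: int) -> np.ndarray:
    """LOO predictions for every latent-variable count 1..max_nlv at once.

    Returns an (n, max_nlv) matrix; column j-1 holds the held-out
    predictions of the j-component model.  A single NIPALS pass per fold
    yields all truncations because the components are nested.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for LOO")
    if max_nlv < 1 or max_nlv > min(n - 2, p):
        raise ValueError(f"max_nlv={max_nlv} infeasible for n={n}, bands={p}")
    preds = np.empty((n, max_nlv))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xi, yi = X[keep], y[keep]
        x_mean = Xi.mean(axis=0)
        y_mean = yi.mean()
        W, P, q, _ = _nipals(Xi - x_mean, yi - y_mean, max_nlv)
        # deflate the held-out spectrum through the component sequence
        x0 = X[i] - x_mean
        contrib = np.empty(max_nlv)
        for k in range(max_nlv):
            t = x0 @ W[:, k]
            contrib[k] = t * q[k]
            x0 = x0 - t * P[:, k]
        preds[i] = y_mean + np.cumsum(contrib)
    return preds


def loo_rmse(X: np.ndarray, y: np.ndarray, nlv: int) -> CVResult:
    """Leave-one-out RMSE and R^2 for a fixed latent-variable count."""
    preds = loo_predictions(X, y, nlv)[:, nlv - 1]
    y = np.asarray(y, dtype=float).ravel()
    return CVResult(y_obs=y, y_pred=preds, rmse=_rmse(y, preds),
                    r2=_r2_pearson(y, preds))


def select_nlv_by_rmse(X: np.ndarray, y: np.ndarray, max_nlv: int = 10) -> int:
    """Latent-variable count minimising the LOO RMSE (ties: fewest)."""
    preds = loo_predictions(X, y, max_nlv)
    y = np.asarray(y, dtype=float).ravel()
    rmses = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    return int(np.argmin(rmses)) + 1


# ---------------------------------------------------------------------------
# Importance and elimination
# ---------------------------------------------------------------------------

def importance(model: PLSModel, X: np.ndarray) -> ImportanceVector:
    """Predictor importance z_i = |beta_i| s_i / sum(|beta_i| s_i).

    ``s_i`` is the standard deviation of band i over the samples; a constant
    band has zero importance regardless of its coefficient.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.beta.size:
        raise ValueError("X columns do not match the fitted bands")
    s = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    raw = np.abs(model.beta) * s
    total = raw.sum()
    if total <= 0:
        raise ValueError("all importances are zero; normalisation undefined")
    return ImportanceVector(z=raw / total, s=s)


def _feasible_max_nlv(n: int, p: int, max_nlv: int) -> int:
    # LOO folds have n-1 samples, so at most n-2 components there
    return max(1, min(max_nlv, n - 2, p))


def ise_eliminate(X: np.ndarray, y: np.ndarray, max_nlv: int = 10,
                  min_bands: int = 2) -> tuple[PLSModel, EliminationTrace]:
    """Iterative stepwise elimination of bands by minimum importance.

    Each cycle re-selects the latent-variable count by LOO-minimum RMSE
    (capped at ``max_nlv``), records the cross-validated RMSE of the current
    band set, then drops the single band with minimum importance.  After
    reaching ``min_bands`` the band set of the cycle with the globally
    minimal RMSE is refitted and returned (ties resolved toward fewer
    bands).
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if min_bands < 2:
        raise ValueError("min_bands must be >= 2")
    if p < min_bands:
        raise ValueError(f"need at least {min_bands} bands, got {p}")

    mask = np.ones(p, dtype=bool)
    trace = EliminationTrace()
    while True:
        Xc = X[:, mask]
        cap = _feasible_max_nlv(n, Xc.shape[1], max_nlv)
        preds = loo_predictions(Xc, y, cap)
        rmses = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
        nlv = int(np.argmin(rmses)) + 1
        trace.masks.append(mask.copy())
        trace.retained_counts.append(int(mask.sum()))
        trace.nlvs.append(nlv)
        trace.rmses.append(float(rmses[nlv - 1]))
        if mask.sum() == min_bands:
            break
        m = pls_fit(Xc, y, nlv)
        z = importance(m, Xc).z
        # minimum importance; ties toward the smallest wavelength (first index)
        drop_local = int(np.argmin(z))
        drop_global = np.nonzero(mask)[0][drop_local]
        mask[drop_global] = False

    rmse_arr = np.asarray(trace.rmses)
    best = int(np.flatnonzero(rmse_arr == rmse_arr.min())[-1])  # fewest bands
    trace.best_cycle = best
    best_mask = trace.masks[best]
    model = pls_fit(X[:, best_mask], y, trace.nlvs[best], band_mask=best_mask)
    return model, trace


# ---------------------------------------------------------------------------
# Jaggedness and final NLV selection
# ---------------------------------------------------------------------------

def jaggedness(beta: np.ndarray) -> float:
    """Sum of squared successive differences of beta in wavelength order."""
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.size < 2:
        raise ValueError("jaggedness needs at least two coefficients")
    return float(np.sum(np.diff(beta) ** 2))


def _rescale01(v: np.ndarray) -> tuple[np.ndarray, bool]:
    v = np.asarray(v, dtype=float)
    span = v.max() - v.min()
    if span == 0:
        return np.zeros_like(v), True
    return (v - v.min()) / span, False


def select_final_nlv(X_selected: np.ndarray, y: np.ndarray,
                     max_nlv: int = 10) -> NLVSelection:
    """Choose the final latent-variable count on the selected bands.

    For each candidate j the LOO RMSE and the jaggedness of the full-data
    coefficient vector are rescaled to [0, 1]; the j minimising
    RMSE_r + J_r wins (ties: smallest j).  If all candidate RMSEs are equal
    the rescaled RMSE is defined as zero for all (degenerate case, flagged).
    """
    X, y = _check_xy(X_selected, y)
    n, p = X.shape
    cap = _feasible_max_nlv(n, p, max_nlv)
    cands = np.arange(1, cap + 1)

    preds = loo_predictions(X, y, cap)
    rmse_cv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))

    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    W, P, q, _ = _nipals(X - x_mean, y - y_mean, cap)
    J = np.array([jaggedness(_beta_from_loadings(W, P, q, j)) for j in cands])

    rmse_r, degen = _rescale01(rmse_cv)
    j_r, _ = _rescale01(J)
    total = rmse_r + j_r
    chosen = int(cands[np.argmin(total)])
    return NLVSelection(candidates=cands, rmse_cv=rmse_cv, jaggedness=J,
                        rmse_r=rmse_r, jaggedness_r=j_r, chosen_nlv=chosen,
                        degenerate_rmse=degen)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_ise_pls(spectra: SpectrumSet, chl: np.ndarray, max_nlv: int = 10,
                min_bands: int = 2, sd_convention: str = "population",
                percentage_base: int | None = None) -> ISEPLSResult:
    """Run the complete ISE-PLS workflow on an RL or FDR spectrum set.

    Steps: eliminate bands -> choose the final latent-variable count by the
    rescaled RMSE + jaggedness criterion -> refit -> report calibration
    (training fit) and validation (LOO) statistics, the residual predictive
    deviation RPD = SD(y)/RMSE_val, and the selected-band percentage of the
    input grid.
    """
    from .metrics import population_sd, sample_sd  # local import, no cycle

    X = spectra.values
    y = np.asarray(chl, dtype=float).ravel()
    elim_model, trace = ise_eliminate(X, y, max_nlv=max_nlv, min_bands=min_bands)
    mask = elim_model.band_mask
    X_sel = X[:, mask]

    sel = select_final_nlv(X_sel, y, max_nlv=max_nlv)
    model = pls_fit(X_sel, y, sel.chosen_nlv, band_mask=mask)

    y_cal = pls_predict(model, X_sel)
    cal_r2 = _r2_pearson(y, y_cal)
    cal_rmse = _rmse(y, y_cal)

    y_val = loo_predictions(X_sel, y, sel.chosen_nlv)[:, sel.chosen_nlv - 1]
    val_rmse = _rmse(y, y_val)
    cv = CVResult(y_obs=y, y_pred=y_val, rmse=val_rmse,
                  r2=_r2_pearson(y, y_val))

    sd = population_sd(y) if sd_convention == "population" else sample_sd(y)
    rpd = sd / val_rmse if val_rmse > 0 else float("inf")
    base = spectra.n_bands if percentage_base is None else percentage_base
    n_sel = int(mask.sum())
    summary = {
        "dataset": spectra.kind,
        "n": int(y.size),
        "nlv": sel.chosen_nlv,
        "calibration_r2": cal_r2,
        "calibration_rmse": cal_rmse,
        "validation_r2": cv.r2,
        "validation_rmse": val_rmse,
        "rpd": rpd,
        "n_selected_bands": n_sel,
        "selected_band_percentage": round(100.0 * n_sel / base, 1),
    }
    return ISEPLSResult(model=model, cv=cv, trace=trace, nlv_selection=sel,
                        wavelengths=spectra.wavelengths[mask], summary=summary)
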