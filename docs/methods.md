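# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical conventions, and the design decisions taken where the
methodology left genuine latitude.

## Preprocessing chain

Input spectra are water-leaving reflectance R_L(λ) on a uniform 1-nm grid,
nominally 350–1050 nm. The chain is:

1. **Savitzky–Golay smoothing**, window 15 points, polynomial order 2,
   applied per sample on the full native grid. The polynomial order is a
   standard chemometrics default (the window width is the better-known
   tuning handle); both are configurable. Smoothing runs *before* trimming
   so that the analysis window carries no filter edge artefacts; the
   alternative order differs only within half a window of the boundary
   (tested). Smoothed R_L/R_rs is clipped at zero to preserve the
   non-negativity contract of reflectance.
2. **Trimming** to the 400–900 nm analysis window (bounds inclusive):
   501 bands on the 1-nm grid. The excluded ranges are instrument noise.
3. **Derived quantities.** Remote-sensing reflectance R_rs = R_L/π sr⁻¹.
   The π convention is exposed as a flag because conventions differ in the
   literature; every implemented model is ratio-based, so the choice
   provably cancels (tested). First-derivative reflectance (FDR, nm⁻¹)
   uses centred differences with one-sided stencils at the two edges, so
   the 501-band grid is preserved and R_L and FDR models are compared on
   identical band counts. A plain adjacent difference would lose one band
   and misalign the two reports.

## OC algorithms

OC2/OC3/OC4 are degree-4 polynomials in R = log10(max blue/green R_rs
ratio); the shipped standard coefficients are the version-6 vectors. Band
extraction takes the nearest grid band to each nominal SeaWiFS centre
(443/490/510/555 nm); an optional boxcar width emulates finite bandwidth.
Samples with non-positive R_rs at a required band are flagged and excluded
explicitly rather than left as NaN, since NaN inside the max-ratio
selection would propagate silently.

**Recalibration** refits the five coefficients by ordinary least squares of
log10(Chl-a) on (1, R, R², R³, R⁴). OLS in log space is the canonical
choice and makes recovery exactly testable: data generated from known
coefficients are recovered to numerical precision, and on the training set
the recalibrated polynomial cannot lose to the standard one in log10 RMSE
(least-squares optimality — note this guarantee does not transfer to
linear-space RMSE, and the comparison tests respect that). At least six
valid samples are required (five coefficients plus one).

## Band-tuned indices

The three-band index (R(λ1)⁻¹ − R(λ2)⁻¹)·R(λ3) and the two-band ratio
R(λ_nir)/R(λ_red) are tuned by stagewise scans: three-band — λ1 over
600–700 nm with (λ2, λ3) initialised at (700, 750) nm, then λ2 over
680–740 nm, then λ3 over 700–800 nm; two-band — red over 620–680 nm with
the NIR band initialised at 705 nm, then NIR over 680–740 nm. Each stage
keeps the candidate maximising |Pearson r| between the index and raw
Chl-a (the calibration model is linear in concentration, so correlation is
computed against concentration, not its log). Ties break to the smallest
wavelength; later stages are restricted above the previously fixed band so
the selection satisfies λ1 < λ2 < λ3. The default is a single pass per
stage sequence; an optional iterate-until-stable mode repeats the passes
from the previous selection until a fixed point (reached within a few
passes on noise-free synthetic data — the fixed-point property is tested
through this mode, as a single pass from arbitrary initial bands is not
itself idempotent). The exhaustive ratio matrix computes, for every
ordered band pair (i, j) of the 501-band grid, the R² of the simple
regression of Chl-a on R(λi)/R(λj) — the full 501² search space with the
uninformative diagonal masked.

## ISE-PLS

PLS1 by NIPALS on mean-centred data. Predictors are *not* autoscaled: the
importance weight z_i = |β_i|s_i / Σ|β_i|s_i explicitly multiplies the
coefficient by the predictor's standard deviation, which only carries
information when the predictors keep their natural scales (an autoscaling
flag exists for experimentation). Components are extracted sequentially,
so one NIPALS pass yields the nested coefficient vectors for every
truncation 1..j; the leave-one-out routine exploits this to return
held-out predictions for all candidate latent-variable counts from a
single pass per fold, which is what makes full-grid elimination (~500
cycles × 59 folds) tractable.

The elimination loop: fit PLS with the LOO-RMSE-minimising number of
latent variables (re-selected every cycle, capped at 10 — the in-loop
criterion), record the cycle's LOO RMSE, drop the single band with minimum
importance, repeat to a floor of 2 bands (the jaggedness of a final model
needs at least two coefficients). The retained band set is the cycle with
the global minimum LOO RMSE; ties resolve toward fewer bands. Ties in any
argmin resolve toward fewer latent variables / smaller wavelengths;
nothing in the module is stochastic.

Final latent-variable selection on the retained bands: for j = 1..10
compute the LOO RMSE and the jaggedness J_j = Σ_{i≥2}(β_{j,i} −
β_{j,i−1})² of the full-data coefficient vector, in wavelength order over
the retained bands with gaps ignored (zero-filling over the full grid
would inject artificial jumps at every gap edge); rescale both to [0, 1]
by (v − v_min)/(v_max − v_min); choose the j minimising the sum. If all
candidate RMSEs coincide, the rescaled RMSE is defined as zero for all
candidates and the choice degenerates to the jaggedness term (flagged on
the result).

Reported statistics: calibration R²/RMSE from the training fit; validation
R²/RMSE from the LOO predictions at the chosen NLV on the selected bands;
RPD = SD(y)/RMSE_val. R² is the squared Pearson correlation between
observed and predicted values (the convention behind most published
calibration/validation tables; 1 − SS_res/SS_tot is available by flag).
RPD uses the n-divisor SD — the convention consistent with reporting RPD
alongside an (n−1)-divisor descriptive SD on the same data — while
descriptive tables use the (n−1) sample SD. RPD class boundaries (1.4, 2)
are assigned upward, since the conventional strict inequalities leave the
boundary values unclassified.

## Synthetic campaign generator

The generator emulates the measurement regime the retrieval methods
assume: n = 59 samples across six pseudo-stations (12/12/12/12/6/5),
Chl-a log-uniform over 0.83–14.33 µg/L (right-skewed, as in bloom-prone
coastal water), spectra on 350–1050 nm at 1 nm. The forward model is

    R(λ) = [ B(λ) · exp(−(a_chl(λ;C) + a_CDOM(λ) + a_tr(λ))) + F(λ;C) ] · W(λ)

with B a broad green-peaked baseline (580 nm, amplitude ~0.028), Gaussian
Chl-a absorption at 670 nm (σ 13 nm) and 443 nm (σ 28 nm) scaling
linearly with concentration C, exponentially decaying CDOM (slope
0.011 nm⁻¹) and flatter tripton (0.004 nm⁻¹) absorption, a fluorescence
peak F centred at 685 + 1.0·C nm (σ 8 nm, amplitude 0.0012·C) so the peak
red-shifts from ~686 to ~699 nm across the campaign range, and a smooth
logistic NIR water-absorption ramp W (centre 770 nm, width 22 nm).
Sensor noise is 2% multiplicative plus 10⁻⁴ additive Gaussian per band,
clipped at zero.

Two stochastic layers are deliberately distinct. *Sensor noise* perturbs
each spectrum. *Composition variability* draws each sample's CDOM and
tripton levels log-normally (log-σ 0.30 and 0.50) around their nominal
levels, independently of Chl-a. The second layer is essential to the
band-selection problem: if every band is an exact function of Chl-a, all
red/NIR indices correlate with concentration at r ≈ 0.97+ and the argmax
of a tuning scan is governed by curvature of the response rather than by
chlorophyll signal. With realistic constituent variability the scans
recover the absorption centre robustly (λ1 within 661–666 nm across
seeds). `noise_free()` disables sensor noise only — the right regime for
selection/recovery experiments; `deterministic()` additionally freezes
composition, making the spectrum an exact, strictly monotone function of
Chl-a — the right regime for shape and monotonicity contracts. The
fluorescence width default (σ 8 nm, FWHM ≈ 19 nm) was fixed together with
the recovery requirement: a much wider peak leaks enough
concentration-correlated signal into the 670 nm region to displace the
two-band scan.

What the generator does *not* emulate: radiative transfer (no
backscattering spectrum, no bidirectional effects), sky/sun glint,
inelastic scattering other than the phenomenological fluorescence peak,
station-specific water types, or temporal autocorrelation between
samples. Passing recovery tests therefore demonstrates that the
algorithms extract the signal their design targets, not that they achieve
any particular accuracy on real coastal water — on real campaigns the
unmodelled variability lowers validation R² and RPD substantially, and
the ISE-PLS scores obtained here (R² ≈ 0.999, RPD ≫ 2) should be read as
upper bounds under idealised optics.

## Problem sizes and numerical choices

The full-resolution runs used throughout (59 samples × 501 bands,
elimination to 2 bands, LOO at up to 10 latent variables) complete in
~15 s each; fast pipeline tests use a 5-nm grid (101 bands). NIPALS stops
early when the residual covariance norm falls below 10⁻¹⁴ (rank
exhaustion); remaining components are zero, leaving predictions unchanged.
PLS at full rank is verified against direct least squares to 10⁻⁸
relative error, and against an independent reference PLS implementation.
Degenerate inputs fail loudly: constant response, constant chlorophyll in
tuning, rank-deficient recalibration designs, infeasible latent-variable
counts, misaligned sample identifiers.

## CLI

The command-line layer is intentionally thin: `simulate` (write a
synthetic campaign as CSV), `isepls` (run ISE-PLS on a spectra/chl CSV
pair), and `compare` (the full model comparison with report files, which
internally runs preprocessing, OC standard + recalibrated, both tuned
indices, ISE-PLS on R_L and FDR, and optional station-exclusion reruns and
plots). Preprocessing, OC fitting, tuning and report writing are library
functions first; the CLI only orchestrates them.

## Known limitations

* The elimination loop refits LOO at every cycle; complexity is quadratic
  in band count. Fine at 501 bands, slow beyond a few thousand.
* Jaggedness ordering ignores gaps between retained bands; an alternative
  normalisation by wavelength gap is not implemented.
* The recalibrated OC comparison is honest only in log10 space; no
  bias-correction back-transform is applied.
* The generator's truth record exposes per-sample fluorescence centre and
  absorption magnitudes, but no inversion utilities are provided for them.
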