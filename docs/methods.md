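# Methods

This note records the models, defaults and numerical choices behind
optoflow, and what the synthetic validation does and does not establish.

## Signal model and conversions

Optical density is defined with the natural logarithm against the
geometric mean of the segment, `ΔOD = −(ln I − mean ln I)`, which makes
the conversion the exact inverse of the simulator's forward model
`I = I0·exp(−ΔOD)`; the choice of reference only shifts each channel by
a constant and is irrelevant after filtering.

The modified Beer-Lambert inversion solves, per channel, the 2×2 system
`ΔOD(λ)/(d·DPF(λ)) = ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR` for concentrations
in µM.  Extinction coefficients come from the Gratzer/Kollias
compilation (packaged in `data/extinction_hb.json` as decadic
cm⁻¹ M⁻¹ values; converted internally by ln 10 × 10⁻⁷ to natural-log
mm⁻¹ µM⁻¹).  The differential path length factor uses the general
age/wavelength equation `DPF(λ, A) = α + βA^γ + δλ³ + ελ² + ζλ` with
coefficients (223.3, 0.05624, 0.8493, −5.723e-7, 0.001245, −0.9025);
it was validated for frontotemporal probes and may be inaccurate
elsewhere (e.g., occipital cortex).  At age 25 it gives DPF ≈ 6.15 at
760 nm and ≈ 5.09 at 850 nm, consistent with the common fixed-value
convention that the shorter wavelength has the longer path.

## Synthetic recordings

The generator emulates a motor block-design acquisition: fs = 3.9062 Hz,
10 s task / 15 s rest × 10 blocks with a 15 s lead-in, 20 long (30 mm)
and 2 short (20 mm) channels, two wavelengths (760/850 nm), and a
4-channel motor ROI.  Latent hemoglobin components (µM) are summed per
channel, pushed through the forward Beer-Lambert model, exponentiated to
intensity at I0 = 1 and given additive white measurement noise
(sd 0.004):

* **Activation**: boxcar ⊗ double-gamma HRF (peak 6 s, undershoot 16 s,
  ratio 1/6, unit peak), ΔHbO +0.5 µM in ROI channels with ΔHbR −1/3 of
  that and 1 s extra delay.  No amplitudes are reported for the study
  conditions being emulated, so these are configuration defaults chosen
  in the typical range of motor responses.
* **Global LF**: a 0.1 Hz sinusoid (1.05 µM) plus band-limited Gaussian
  noise in 0.01–0.15 Hz (sd 0.525 µM), delayed per channel by a lag
  drawn uniformly in ±5 s; HbR receives 1/3 of the HbO amplitude with
  the same sign, which is what lets the combined activation criterion
  reject it.  These amplitudes were calibrated once so that the
  block-level max ROI Cohen's d under the no-de-noising pipeline is
  ≈ 0.8 (measured 0.85 ± 0.30 over 16 subjects), matching the magnitude
  the method comparison is designed around; they were fixed thereafter.
* **Cardiac** 1 Hz (0.6 µM), **respiration** 0.3 Hz (0.2 µM), **drift**:
  0.004 Hz triangle (0.15 µM).
* **Bad channels** receive no cardiac component and 10× noise.

Block metrics are computed over per-block window means (pre = [−4, 0) s,
dur = [5, 15) s): with stationary synthetic noise, block-averaged-trace
statistics collapse the denominator and make d arbitrary; block-to-block
variability is the meaningful noise floor here.

What the generator does **not** emulate: nonstationary physiology
(vasomotion bursts, posture changes), serially correlated measurement
noise, optode-coupling drift, heterogeneous per-channel SNR, partial
volume effects, or any anatomy.  Passing recovery tests on this
generator shows the pipeline is internally consistent and recovers known
truth under its stated assumptions — not that it is optimal on real
recordings.

## Channel quality

CV uses the sample (n−1) standard deviation and takes the worst of the
two wavelengths per channel (the conservative aggregation).  The
cardiac-coupling rule uses non-overlapping 3 s windows (the last partial
window is dropped), a 3rd-order 0.8–1.95 Hz Butterworth, SCI as the
zero-lag Pearson correlation of the two filtered wavelengths, and peak
cardiac power as the in-band maximum of the unit-normalized power
spectrum of the unit-energy windowed cross-correlation — normalizing by
energy makes the 0.1 threshold scale-free.  A window with essentially no
cardiac-band energy (<10⁻⁴ of its raw variance after filtering) is
assigned zero power rather than letting normalization amplify filter
leakage.  The acceptance fraction is computed over windows, and the rule
runs on optical density by default with a raw-intensity switch.

## Motion correction

Both wavelet corrections reflect-pad each channel to a power of two
(≥12.5% margin per side) and use an exactly invertible decomposition
('db2', periodization mode, maximal depth).  The IQR rule zeroes detail
coefficients outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`; quartiles are
computed over nonzero coefficients with a two-stage estimate (flag,
re-estimate quartiles from unflagged coefficients, re-flag) so the
artifact does not inflate its own threshold and a second application is
a near no-op.  Levels with fewer than 64 coefficients are left
untouched: quartiles estimated from fewer points are unstable enough to
delete genuine low-frequency signal.  The kurtosis variant trims the
largest-magnitude coefficients per level until the surviving
coefficients' Pearson kurtosis is ≤3.3 (stopping at 8 survivors).

A per-level outlier rule can only remove the part of an artifact that is
large *relative to the background at the same scale*.  Sub-second spikes
are therefore suppressed well (their energy is fine-scale), while the
portion of any artifact that falls inside the band occupied by large LF
physiology is irreducible by construction — spike-removal performance is
quantified on single-sample 10-SD spikes over an LF baseline, where the
mean amplitude reduction is ≥90%; on recordings whose variance is
dominated by strong in-band LF oscillations the residual is larger.
Baseline *shifts* load the coarse scales: the thin-level guard makes the
IQR rule leave them alone (it is the gentle correction), while the
kurtosis rule trims them aggressively — which is exactly the
over-correction contrast between the two methods that the comparison is
designed to expose.

## Filters

All three variants reflection-pad by 1/f_lo seconds to suppress edge
transients (exposed as `pad=False` for exact spectral tests).  The FFT
trapezoid's transition bands sit outside the passband by default (stop
edges at 0.009 and 0.22 Hz for a 0.01–0.2 Hz band); the alternative
orientation (transitions inside the passband) is available via
`widen_pass=True` since the edge naming convention is ambiguous.

## LF de-noising

The adaptive filter is a normalized LMS run offline over several epochs:
with the conventional step µ = 1e-4 a single pass over a ~1000-sample
task recording ends far from steady state, which would make the
short-separation and global-average regressions silent no-ops at this
recording length.  Signals are standardized internally (µ is therefore a
scale-free per-sample step), weights are carried across passes
(default: enough passes that µ·epochs·n ≈ 10), and the residual is
emitted on the final pass; µ = 0 is an exact identity.

GloAvg computes lags per wavelength on filtered OD; a comparison channel
is accepted at r > 0.37 with |lag| ≤ 5 s, aligned by whole samples
(zero-padded edges), averaged, and regressed out adaptively.  The 0.37
default is retained as the conventional value;
`correlation_threshold_simulation` recomputes the empirical null for any
length and band (for 977 samples in 0.01–0.15 Hz the 95% quantile is
≈ 0.3).  Two caveats are inherent to the method and visible in the
diagnostics: (1) when pairwise delays exceed the lag window, the search
can lock onto a period-aliased lag of the dominant oscillation, diluting
removal — the de-noising efficacy figure is therefore measured with
per-channel lags in ±2.5 s so that all pairwise delays stay inside the
±5 s window; (2) channels with no accepted partner are returned
unchanged and flagged.  PCA removes the first spatial component of the
long-channel OD matrix (SVD; least-squares removal, so residuals are
exactly orthogonal to the component).  SSD regresses each long channel
on its nearest short channel (by source index) per species on
concentrations; PCA/GloAvg run on OD and convert afterwards — the
operating-space asymmetry between the three methods is part of the
procedure being compared and is preserved deliberately.

## GLM

The design matrix holds an intercept, the boxcar ⊗ HRF main regressor
(unit peak), and its first and second temporal derivatives,
orthogonalized against the main column and rescaled to its norm so the
main-term beta keeps its amplitude interpretation.  Prewhitening fits
AR(p) to OLS residuals by Yule-Walker with BIC order selection up to
⌈4·fs⌉ (BIC rather than AIC: white noise should keep order 0–1);
unstable fits fall back to AR(1).  Both sides are filtered with
`1 − Σφ_kL^k` and the first p rows dropped.  The robust fit is
statsmodels RLM with Tukey bisquare (c = 4.685); only the main column's
t (two-sided, df = n − k) is used.  BH correction is applied across the
fitted long channels within subject, per species — a per-species family
matches the convention of reporting HbO and HbR separately.  Alpha
defaults to q < 0.05.  The decision rules: oxy-active = q_HbO < α and
β_HbO > 0; deoxy-active = q_HbR < α and β_HbR < 0; combined = both, so
the combined set is a subset of each by construction.

Filtering before the GLM (rather than inside the regression model)
follows the processing order being studied, even though prefiltering
inflates autocorrelation — that inflation is exactly what the
prewhitening comparison quantifies (type-I ≈ 0.04–0.06 with
prewhitening vs ≈ 0.45 without, on AR(1) noise with φ = 0.8).

## Problem sizes

Validation runs use one subject per fixture (265 s, 22 channels) and
16-subject cohorts for recovery statistics; null calibrations use
300–500 replicates; the full test suite and the acceptance script each
complete in well under a minute of compute per stage.  Scaling the
cohort or replicate counts up is a matter of the `n_subjects` /
`n_sims` arguments; all results in the examples and acceptance output
were produced at the sizes stated there.

## Known limitations

* The trimming of recordings to the task segment is a configuration
  knob (`PipelineConfig.trim`); no automatic segment detection.
* GloAvg assumes a single global component; multiple independent
  systemic sources are cleaned only within their correlated groups.
* The kurtosis motion correction's behavior on small levels depends on
  the sample kurtosis of few coefficients and is intentionally left as
  aggressive as its rule dictates.
* Group-level inference is limited to subject-count summaries and
  paired t-tests across methods; no mixed-effects models.
* SNIRF support covers continuous-wave amplitude data with one data
  block, which is the format this pipeline consumes and produces.
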