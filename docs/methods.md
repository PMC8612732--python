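# Methods

## Release model

Release is simulated per active zone (AZ) and per docking site. Sites are
binary (occupied/empty) and start occupied. On each stimulus an occupied
site fuses with probability `p_eff = p_v(1 − θ)`, where θ is the
Tomosyn-like inhibition factor; between stimuli an empty site refills with
probability ρ. Inhibition enters only through `p_eff` by default — the
phenotype being modelled is a slowed rate of vesicle usage, not a change in
refill — but `theta_scales_refill=True` optionally scales ρ by (1 − θ) to
explore docking-side effects. The expected pre-stimulus occupancy obeys
`o(n+1) = λ·o(n) + ρ` with `λ = (1 − p_eff)(1 − ρ)`, giving the fixed point
`o* = ρ/(1 − λ)` used as the simulator's analytic oracle, and a closed-form
asymptote of cumulative release: slope `N·p_eff·o*` and intercept
`N·p_eff(1 − o*)/(1 − λ)` for `N` total sites. When `slots_per_az = 1`, an
optional Beta(a, b) distribution replaces the common `p_eff` to emulate
between-AZ Pr heterogeneity; Beta(2, 10) (mean ≈ 0.17) matches the range
observed at these synapses.

Released vesicles get latencies from a Gaussian synchronous component
(mean 1.5 ms, SD 0.3 ms) with probability 1 − `f_async`, else the same
1.5 ms delay plus an exponential with constant `tau_async = 30 ms`. No
latency constants are published for this preparation; these are plausible
placeholders exposed in the config and the analyses never assume them.

## Trace rendering

A quantal current is a difference of exponentials
`exp(−t/τ_d) − exp(−t/τ_r)` normalized to unit peak **on the sampling
grid**, so a grid-aligned event of amplitude q produces an extremum of
exactly q. Defaults: τ_r = 1 ms, τ_d = 6 ms, quantal mean 0.58 nA (the
control mEJC mean rounded), CV 0.3 (chosen; not published), 10 kHz
sampling, Gaussian noise SD 0.05 nA. Minis are a homogeneous Poisson
process with the same amplitude law; superposition is linear; inward
current is negative. Sampling below 2 samples per τ_r is rejected.

## Mini detection

Baseline is a running median (500 ms window, computed as overlapping block
medians, linearly interpolated — O(n)). Detection is matched filtering: the
baseline-subtracted deflection is correlated with a unit-peak quantal
template, yielding a per-sample amplitude estimate thresholded at
k = 4 times its own robust (MAD) noise SD. Overlapping events merged by the
filter's correlation width are recovered by iterative peeling: peaks are
detected in the residual after subtracting the fitted model, amplitudes are
re-solved jointly against the template autocorrelation (up to five rounds).
A secondary confirmation — the lightly smoothed raw deflection around the
expected peak must exceed 6 times its own noise SD — rejects
threshold-grazing filter coincidences; with it the false-positive rate on
pure Gaussian noise is below 0.02 Hz while events well below the per-sample
noise threshold remain detectable. The refractory period (2 ms) sets the
minimum separation of resolved events. Amplitude estimates are the jointly
solved matched-filter amplitudes; areas integrate the raw deflection from
onset to return-to-baseline (10% of amplitude), capped at 50 ms or the next
event. At the control event rate the amplitude estimator is unbiased within
sampling error; at ~10 Hz the running median sits slightly below the true
baseline (events occupy ~20% of samples), giving a ~3% amplitude
underestimate — a known limitation shared by any percentile-type baseline.

## Evoked analysis

Baselines are 5 ms pre-stimulus means; stimulus artifacts are blanked by
linear interpolation over 1.5 ms. Quantal content divides peak by mean mini
amplitude or charge by mean mini area; the group-mean reference reproduces
the published ratio-of-means quantal contents exactly. t90 comes from the
normalized cumulative charge with linear interpolation between samples.

Charge decomposition fits `C(t) = w·L(t − t0; τ_f) + (1 − w)·L(t − t0; τ_s)`
with `L(t; τ) = ln(1 + t/τ)/ln(1 + T/τ)`, bounds 0 ≤ w ≤ 1 and τ in
log-space, labels swapped after fitting so τ_s > τ_f; a saturating
bi-exponential alternative is selectable (`form="biexp"`). The weighted-log
form is one reading of a "double logarithmic" cumulative fit; both forms
define `slow_percent = 100(1 − w)` identically. The shared onset delay t0
(0–20 ms) is fitted only for curves measured from traces
(`fit_onset_delay=True`): recorded responses accumulate no charge during
the synaptic delay and rise time, a lag neither component can represent —
without it the optimizer degenerates to near-zero time constants. For
trace-derived curves the bi-exponential form is the recommended choice
(residual RMS ~0.002 on simulated responses versus ~0.05 for the log
form, whose initial slope is unbounded); the recovered fast and slow
constants then track the quantal decay (~6 ms) and asynchronous latency
scale (~30–40 ms), and the slow share tracks the simulated asynchronous
charge fraction. Fitting is multi-start least-squares over a 27-point grid
plus five seeded jittered starts; non-convergence is reported as missing,
never silently defaulted.

Ca²⁺ cooperativity is the Hill coefficient of the 4-parameter logistic
`y = bottom + (top − bottom)/(1 + (ec50/x)^hill)` restricted to
0.1–0.75 mM. Paired-pulse ratios subtract a mono-exponential extrapolation
of response 1 before measuring P2; a first peak below 5 noise SDs flags the
ratio unreliable.

Train analysis holds the pre-train baseline fixed (a per-stimulus baseline
would absorb asynchronous build-up), measures per-stimulus quantal content
in inter-stimulus windows (charge-based by default — robust to latency
jitter), and derives: depression index DI(n) = qc_n/qc_2; IRP = Σ qc over
stimuli 1–30; steady state = mean over the final 20% of the train; RRP =
intercept of a line fit to cumulative quanta vs stimulus index over that
tail; recycling rate = slope × frequency. The single-train intercept is
unbiased for the closed-form asymptote but has a sampling SD of order
1,000 quanta at the study's train conditions (the tail slope error is
amplified by the mean stimulus index), so pool estimates are averaged
across simulated NMJs — 120 trains in the acceptance checks, giving a
relative error of a few percent.

## Optical Pr mapping

ROIs come from difference-of-Gaussians filtering of the PSD reference
channel plus local-maximum detection; the noise floor of the band-passed
image is the wavelet noise estimate of the raw image propagated through the
DoG kernel norm (a robust SD of the filtered image itself is inflated by
the spots at realistic density). Candidates closer than the minimum
separation keep the brighter peak, ties resolved by scanline order; ROIs
are equal circles (default radius 3 px at 0.26 µm/px) and a manual append
hook mirrors hand-added spots. For paired pharmacology sessions without a
usable reference, ROIs come from smoothed event-centroid density peaks.

Flash detection smooths each frame with a Gaussian matched to the PSF,
subtracts a rolling 20th-percentile per-pixel baseline (block percentiles
interpolated over time, re-centred to zero median — a low percentile sits a
fixed noise quantile below the quiescent mean), and thresholds at k = 4
per-pixel robust noise SDs of the smoothed ΔF. Connected components of at
least 4 px become candidate events, split by watershed at local maxima so
simultaneous releases at neighbouring AZs stay separate; components
overlapping in consecutive frames collapse to their peak frame. Because
indicator flashes decay over ~2 frames at 8 Hz while noise is temporally
white, a new event must persist above half-threshold at its peak pixel one
frame later; this persistence check brings false events on noise-only
movies below 1% of frames without sacrificing recall at flash SNR 5.

Events are assigned to the nearest ROI within twice the ROI radius (ties to
the lower id; unassigned events are counted, never dropped); per-time-block
rigid registration offsets from phase cross-correlation of re-imaged
references can be applied. Evoked frames are those with ≥ 3 simultaneous
events (or known stimulus frames); Pr = evoked events per ROI / number of
stimulations, silent ROIs included at Pr = 0. Paired pre/post comparison
reports per-ROI deltas, the fold change of mean Pr and the count of
recruited (silent→active) ROIs.

## EM geometry

All statistics are 2-D per single section. A vesicle is docked when its
center is strictly closer than 50 nm to the AZ electron-density polyline;
distance is point-to-segment orthogonal projection over the full contour
(not endpoints), cross-checked in tests against shapely and dense-sampling
oracles. Radial counts around the T-bar use the same strict inequality at
100/150 nm. Nearest-neighbor spacing averages per micrograph; density is
SV count over annotated bouton area. The synthetic generator places docked
vesicles below 50 nm and the reserve beyond a 60 nm guard band with a
minimum spacing of one vesicle diameter (33 ± 3 nm), rejecting infeasible
packings.

## Group statistics

Summaries report median, mean ± SEM and n (SEM missing at n = 1). Two
groups: two-sided Student's t, equal-variance by default with a Welch
switch. Three or more: one-way ANOVA, then Tukey HSD or Šidák-adjusted
pairwise t tests (`1 − (1 − p)^m`). Stars follow the ≤0.05/0.01/0.001/0.0001
convention. Fold changes carry centralized display rounding (fold to one
decimal, percent to integer) so printed-value comparisons are
deterministic. Outlier flagging is a modified z-score (|x − median| /
(1.4826·MAD) > 3.5) — a documented robust stand-in for proprietary
outlier-removal defaults, validated on the two published exclusions; it
only flags, removal is an explicit caller action.

## What the synthetic data does and does not capture

The generator reproduces the statistical structure the analyses rely on —
binomial per-site release with depletion/refill, quantal amplitude
variability, synchronous/asynchronous latency mixture, Poisson minis,
Gaussian recording noise, PSF-blurred single-vesicle flashes with
exponential indicator decay, shot-noise-free reference stacks, and docked/
reserve vesicle geometry. It does not model Ca²⁺-channel or sensor
biophysics, receptor saturation or nonlinear summation, baseline drift or
muscle movement, indicator bleaching, focal drift beyond rigid translation,
or 3-D ultrastructure. Passing recovery tests therefore demonstrates
estimator correctness under the stated noise models, not robustness to
every artifact of real recordings.

## Problem sizes and numerical choices

Acceptance-scale runs use: 300 AZs × 200 stimuli × SNR-5 movies (~5,300
frames, ~160×170 px) for Pr recovery; a 3×3 (p_eff, ρ) grid × 1,500 stimuli
× 200 AZs for the depletion oracle; 120 × 1,500-stimulus trains for pool
back-extrapolation; 100 trials per θ ∈ {0, 0.3, 0.6} for the tonic/phasic
direction; 100 noisy replicates for charge-decomposition recovery; 100
random EM fixtures for oracle equivalence; 120 s at 9.5 Hz and SNR 8 for
mini detection; 10⁴ null simulations for t-test calibration. One seed
drives every stream through a CRC-32-labelled SeedSequence split, so runs
are bit-reproducible and adding a consumer never perturbs existing
streams. Optimizer tolerances are scipy defaults; fits report convergence
flags and missing values rather than fabricated parameters.
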