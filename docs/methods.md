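# Methods

## The E–I rate model

The network is a lumped two-population rate model of one orientation column:

    tau_x dX/dt = -X + f_x(I_x),   x in {E, I}
    I_e = wee*E - wei*I + iE,      I_i = wie*E - wii*I + iI

with the shifted-logistic transfer `f_x(u) = expit(m_x(u - theta_x)) -
expit(-m_x theta_x)`, which is zero at zero drive so the origin is an exact
fixed point of the unstimulated network. Lateral recurrent (LR) inputs from
neighbouring columns of the hypercolumn, being themselves weighted functions
of E and I, are absorbed into the four effective weights
`w_xy = W_xy + W_x*LR`; a stimulus discontinuity removes part of the LR
drive, which `apply_discontinuity` models as multiplying one effective
weight by a scale in [0, 1] (the reduction is taken from the lateral gain
first and clamped at zero, since the base/lateral split is not uniquely
constrained — only their sum enters the dynamics).

Parameters and defaults:

| parameter | default | units | role |
|---|---|---|---|
| wee, wei, wie, wii | 16, 26, 20, 1 | – | effective synaptic gains |
| mE, mI | 1, 1 | – | transfer slopes |
| thetaE, thetaI | 5, 20 | input units | transfer half-activation |
| tauE, tauI | 20, 10 | ms | population time constants |
| iE, iI | — | input units | center (contrast-like) / surround (size-like) drive |

Time is interpreted in milliseconds; with tauE = 20 ms and tauI = 10 ms the
limit cycle at the reference operating point (iE=3, iI=7.5) runs at ~46 Hz,
i.e. in the gamma band. Activities are confined to the sigmoid's range
(lower offset `-expit(-m theta)` to one plus that offset) for any finite
input — the integrator inherits this boundedness.

## Numerics

* **Integration**: classical fixed-step RK4, default dt = 0.05 ms
  (dt ≤ tauI/50 is enforced). The integrator is vectorized over arrays of
  (iE, iI) so input-plane maps and sweeps run as single batched
  integrations. Halving dt changes the final 500 ms of the default-spec
  trajectory by < 1e-4 (sup-norm, verified over a 5×5 input probe grid).
  Simulations start from (0, 0) and are deterministic; an additive-noise
  hook (Euler–Maruyama increment after each RK4 step) exists but is off by
  default.
* **Fixed points**: multi-start damped Newton (50×50 seed grid over the
  closed activity box, steps capped at 0.2, iterates clamped to the box,
  deduplication at 1e-6, residual tolerance 1e-10). Saturated fixed points
  sit numerically *on* the box boundary — the sigmoid reaches its asymptote
  to double precision — which is why the box is closed, not open. Stability
  comes from the eigenvalues of the analytic Jacobian; |Re λ| < 1e-8 is
  labelled marginal and treated as non-oscillatory. An independent
  brute-force locator (`scan_fixed_points`) reduces the problem to one
  dimension — the I-nullcline value at each E is the unique root of a
  strictly increasing function, found by bisection, and fixed points are
  bracketed sign changes of the difference between the two nullclines over
  a dense E grid (resolution 2000), refined by bisection, plus an explicit
  residual check at the two boundary values. The two methods agree to
  better than 1e-5 on randomized weight sets; the scan serves as the oracle
  in tests and in the acceptance script.
* **Nullclines**: the E-nullcline is closed-form via the inverse sigmoid;
  the I-nullcline is the same monotone 1-D root solve. Grid points at or
  beyond sigmoid saturation are skipped with a warning.
* **Oscillation metrics**: the canonical frequency estimate is the
  reciprocal mean interval between linearly interpolated upward zero
  crossings of the mean-subtracted post-transient E series; the periodogram
  argmax is carried alongside as a cross-check (they agree within a bin for
  sustained cycles). Peak power is the periodogram integrated over ±2 Hz
  around the argmax rather than the single-bin maximum: the limit cycle's
  spectral line is much narrower than one bin, and a single-bin maximum
  scallops with the alignment of cycle and record length, which produced
  spurious non-monotonicity in input-plane maps. Amplitude is the median
  peak-to-trough per cycle. "Sustained" requires the last 500 ms window's
  peak-to-trough amplitude to exceed 1e-3 activity units *and* to differ
  from the preceding 500 ms window by < 5 %; near the Hopf point transients
  decay slowly, so sweeps use 5 s simulations — with this criterion the
  simulated oscillation onset brackets the eigenvalue zero crossing within
  one 0.1-unit sweep step on both sides of the oscillatory range.
* **Regime classification**: the operating regime in which surround drive
  boosts gamma and lowers its frequency is identified by a local-curvature
  criterion — E sublinear iff the E transfer's second derivative at the
  fixed-point drive is negative (drive above threshold), I superlinear iff
  the I curvature is positive — combined with the empirical sustained-
  oscillation test. This substitutes a closed-form regime condition derived
  elsewhere in the literature that is not reproduced here; the resulting
  boundary may differ quantitatively from published regime lines, but all
  qualitative monotonicity claims are verified inside it. Classification
  requires a unique fixed point and refuses multistable inputs explicitly.

## Spectral pipeline conventions

* Single Slepian (DPSS) taper, time-bandwidth product NW = 1, first
  sequence only; a 0.25 s window at 2 kHz gives 4 Hz resolution. Per-window
  mean removal only; no line-noise notch (the synthetic data has no mains
  component).
* Trial averaging happens on raw power *before* the logarithm; difference
  spectra are `10*(log10 stim − log10 baseline)` dB. Injected tone power
  ratios of 4/10/100 are reproduced within ±0.2 dB, comfortably inside the
  ±1 dB calibration contract.
* Sliding-window step 25 ms (the window length is the constraint; the step
  is a smoothness choice). Baseline windows are those lying fully inside
  [−0.5, 0] s; the stimulus PSD epoch is [0.25, 0.75] s — the two never
  overlap.
* Band power is the plain sum of PSD bin values with both edges inclusive
  (bin centers at multiples of the Rayleigh resolution). Normalized gamma
  power divides each condition by the per-site maximum, so the maximum is
  exactly 1. The configured gamma band shifts down 5 Hz when both center
  and surround contrasts are below 100 %.
* The session pipeline assigns a gamma peak frequency only where the in-band
  change from baseline reaches 4 dB: the per-bin dB noise of a 20-trial
  single-taper estimate is ~1.4 dB, so an argmax over a flat difference
  spectrum would be estimator noise, while a genuine bump at the
  generator's default ~10 dB in-band SNR clears 6 dB.
* The attenuation-constant refit uses *baseline-subtracted* band powers
  (stimulus PSD minus baseline PSD summed over the band): amplitude decays
  as exp(−d/λ), hence component band power as exp(−2d/λ), and removing the
  noise floor keeps the log-linear fit unbiased at strongly attenuated
  conditions. λ = −2 / (OLS slope of log power vs d).

## Spiking statistics

Units are kept if their stimulus-window ([0.25, 0.75] s) rate reaches
1 spike/s in at least one condition (boundary inclusive). Rate time courses
use 10 ms bins with a 50 ms boxcar, normalized per unit by the global
maximum over time and conditions; scalar per-condition tuning uses unbinned
window counts normalized by the maximum condition mean (normalizing by the
time-course maximum instead is available as an option — the two conventions
differ only by a common factor per unit, so slopes change scale but not
sign). Discontinuity sensitivity is the unweighted OLS slope of normalized
value on magnitude; symmetric layouts (orientation, phase) are regressed
per side on |magnitude| over a configurable subrange and the slope
magnitudes averaged. The Wilcoxon signed-rank test drops zero differences,
averages tied ranks, is exact (dynamic-programming enumeration on doubled
ranks) for n ≤ 25 and a tie-corrected normal approximation with continuity
correction above; the reported statistic is the z-value in both cases.

## Synthetic sessions: what they emulate, and what not

Each session is one recording site: per discontinuity condition, `n_trials`
LFP trials of spectrally shaped 1/f^β noise (β = 1, unit variance) plus a
stimulus-epoch (0–0.8 s) gamma component with 50 ms raised-cosine ramps and
a fresh uniform phase per trial (induced, not stimulus-locked), amplitude
`A0 exp(−|d|/λ)` and frequency `f0 + k|d|`; spike trains are
piecewise-constant-rate Poisson with stimulus rate `r0 (1 + s|d|)` scaled
by per-unit lognormal heterogeneity (σ = 0.3), which allows mixed-sign
per-unit rate effects. Defaults: levels {0, 0.025, 0.05, 0.1, 0.2}°,
20 trials, fs = 2 kHz, trials spanning [−1, 1] s, A0 = 1.25 (≈ 10 dB
in-band SNR against the default background in [35, 65] Hz), f0 = 50 Hz,
λ = 0.1°, k = 10 Hz/°, r0 = 20 /s with baseline 5 /s, s = 1 /°. The
model-driven mode instead takes post-transient E(t) simulated at
discontinuity-mapped effective weights (default: wee scaled), resampled
from the 20 kHz integration grid to 2 kHz, mean-subtracted, scaled by one
common gain so the least-attenuated condition matches A0, and circularly
offset per trial.

The generator reproduces the *statistical structure* the pipeline assumes —
1/f background, narrowband induced gamma whose amplitude falls and
frequency rises with discontinuity, modest heterogeneous rate effects — but
not the physiology around it: no harmonics, no slow-gamma band, no line
noise or artifacts, no eye movements, no cross-electrode correlation, no
evoked (phase-locked) components outside the RF-mapping deflection. Passing
recovery tests therefore demonstrates that the pipeline measures what it
claims under its own assumptions, not that real recordings meet those
assumptions.

RF grids are 9×9 samples of an axis-aligned 2D Gaussian plus i.i.d. noise.
"SNR 5" in the recovery study means the RMS of the noiseless Gaussian over
the grid is five times the noise SD (the image-domain convention; a
per-point peak-amplitude reading of the same words would be a much harsher
condition). RF size is reported as the geometric mean of the two fitted
SDs. Center-site selection is Euclidean distance with an inclusive
boundary.

## Problem sizes

Reference simulations use 5 s at dt = 0.05 ms (sweeps and perturbation
experiments) or 3 s (input-plane maps); the Hopf sweep covers iI ∈ [0, 15]
in steps of 0.1 at iE = 3. Recovery studies use 50 sessions for slope and
attenuation checks and 20 replicate studies of 30 sites for the
gamma-vs-rate comparison; RF recovery uses 200 seeded grids. These sizes
give stable statistics (binomial SE on a 95 % hit rate over 200 grids is
~1.5 %) while keeping a full run in the low minutes on one CPU.

## Known limitations

* The regime boundary is a local-curvature proxy, not the closed-form
  condition of the original derivation; regime *lines* should not be
  compared quantitatively against published figures.
* `find_fixed_points` is reliable for the bounded-sigmoid system it
  targets; pathological weight sets with near-tangent nullclines could in
  principle merge two roots within the 1e-6 deduplication radius.
* The spectral estimator is a single taper by design (matching the
  analysis convention it implements), not a full multitaper average; its
  variance is correspondingly higher.
* Absolute LFP units are arbitrary throughout; only ratios (dB,
  normalized power) are meaningful downstream.
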