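# Methods

This note documents the models, estimators and numerical conventions the
package implements, the choices made where the procedure was genuinely open,
and what the synthetic data can and cannot certify.

## Stimulus synthesis

Band-limited Gaussian white noise is drawn in the Fourier domain:
independent standard-normal real and imaginary parts for every positive
frequency bin up to the cutoff (150 Hz for ampullary-style stimulation,
300 or 400 Hz for P-unit RAMs), zero DC, inverse real FFT.  The Fourier
draw fixes the variance only in expectation, so each trace is rescaled
exactly to the requested contrast (the standard deviation of the AM
relative to the EOD amplitude); rescaling a realization by a scalar leaves
its spectrum flat.  Contrasts are dimensionless fractions internally and
percent in all reported units.

RAM stimulation multiplies the noise onto the carrier, y = (1+s)·cos(2πf_EOD t);
ampullary-style stimulation adds it, y = s + cos(2πf_EOD t); beats emerge
from superposing foreign-fish cosines at their own EOD frequencies.  The
`extract_am` helper recovers an envelope by threshold rectification,
4th-order zero-phase Butterworth low-pass below the carrier, and
multiplication by π (the inverse of the mean of a rectified unit cosine).

## P-unit model

The model chain is: threshold rectification ⌊y⌋₀ (synaptic transfer),
first-order dendritic low-pass V_d with time constant τ_d (extracts the AM
and attenuates the carrier), and a stochastic LIF spike generator

    τ_m dV_m/dt = −V_m + μ + β V_d − A + √(2D) ξ(t),
    τ_A dA/dt   = −A,

with threshold 1, reset 0, spike-triggered adaptation increment ΔA/τ_A,
and an absolute refractory period t_ref during which V_m and A are frozen
while V_d keeps following the stimulus.  Integration is forward Euler
(Euler–Maruyama) at Δt = 0.05 ms; the per-step noise increment is
√(2DΔt)/τ_m · N(0,1).  Per trial, V_m(0) ~ U(0,1) and the initial
adaptation is jittered (normal, 2 % of ΔA); the first 500 ms are discarded,
which an invariance test shows makes the initial adaptation level
immaterial.  Per-trial random streams are spawned from one root seed with
the trial index in the spawn key, so extending a simulation never changes
earlier trials.

Two reference parameter sets are frozen in `synthetic_data`:

* `exemplar_punit` — baseline rate ≈ 76 Hz, CV ≈ 0.21, vector strength
  ≈ 0.80, negative ISI serial correlation: a low-CV (low intrinsic noise)
  P-unit, the regime in which the triangular χ₂ structure is expected.
* `exemplar_punit_mid` — rate ≈ 227 Hz, CV ≈ 0.78: mid-population
  variability, used for contrast-sweep studies where the strong spike-time
  entrainment of a low-CV cell at its own rate would distort the scaling
  laws being measured.

Both were tuned by hand against the baseline statistics of the respective
cell class; the eight parameters are inputs to this package, not fitted
quantities.

## Spectral estimation

Spike trains are binned at Δt = 0.5 ms into binary rate-coded vectors
(1/Δt where at least one spike fell, zero otherwise; coincident spikes
count once and are logged).  Stimuli are decimated to the same grid by
within-bin averaging (anti-aliasing is unnecessary below a 400 Hz cutoff
against a 1 kHz Nyquist).  Segments are N = 512 samples (T = 256 ms,
resolution 3.90625 Hz), rectangular window, no overlap, no detrending, never
spanning a trial boundary; recordings discard the initial 200 ms per trial,
simulations 500 ms.  The estimator prefactors are Δt/N for power and
first-order cross-spectra and Δt²/N for the second-order cross-spectrum.
The DC bin is never indexed by susceptibility estimates; bins with zero
stimulus power are masked (NaN), not infinite.

χ₂ is computed on the positive quadrant (0 < f₁, f₂ ≤ f_max with
2·f_max ≤ Nyquist) by accumulating X(ω₁+ω₂)S*(ω₁)S*(ω₂) over segments in
constant memory, so 10⁶-segment runs stream.  The accumulated matrix is
analytically symmetric in (f₁, f₂); averaging with its transpose removes
last-bit rounding asymmetry from fused multiplies so |χ₂| is exactly
symmetric.  The difference (mixed) quadrant is available separately; its
estimator X(ω₂−ω₁)S(ω₁)S*(ω₂) uses Hermitian symmetry for negative response
frequencies and converges noticeably more slowly than the sum quadrant.

Calibration facts established by the test suite's oracles:

* For an inhomogeneous Poisson surrogate with rate r₀(1+g·s), χ₁ is flat at
  r₀·g, attenuated by the Bussgang factor e^(−r₀Δt) of binary binning
  (≈ 5 % at 100 Hz).
* For a quadratic surrogate r₀(1+g·s+q·s²), χ₂ is flat at r₀·q, and the
  two-sine sum-frequency response amplitude equals |χ₂|·c₁·c₂ — the
  convention constant K relating the estimator to two-sine experiments is 1
  for the printed normalization (derived analytically via Wick's theorem and
  confirmed numerically; a symmetrized-Volterra bookkeeping that would give
  K = 2 does not apply to this estimator).
* The finite-data magnitude floor of |χ₂| for stimulus-independent trains
  decays as n_segments^(−1/2); at experimentally realistic segment counts it
  dominates weak quadratic structure, which is the motivation for the noise
  split.

## Susceptibility index and other metrics

|χ₂| is projected onto the diagonal by averaging anti-diagonals, including
the shortened ones near the corners (full anti-diagonal convention; the
projection then conserves total mass exactly).  f_peak is the argmax of the
projection within ±50 Hz of the baseline rate r (closed intervals on bin
centers; ties break toward the bin nearest r, then toward lower frequency —
no tie rule is prescribed elsewhere).  The reference floor is the mean of
D over [f_peak−20, f_peak−10] and [f_peak+10, f_peak+20] Hz averaged, and
SI = D(f_peak)/D_ref with the single-bin peak value in the numerator.

Baseline statistics: rate = spike count / duration; CV = ISI std/mean;
serial correlation = Pearson correlation of consecutive ISI pairs (flagged
NaN below 3 pairs or for a constant series); vector strength = resultant
length of spike phases within the EOD cycle, with cycle boundaries from the
analytic cosine for simulations or from zero crossings of a recorded EOD
trace.  Firing rates convolve each trial with a normalized 1 ms Gaussian
kernel before trial averaging; the response modulation σ_s is the standard
deviation over time of that average.  Spectral peak amplitudes are read at
the nearest bin, above a local floor estimated as the median over ±5–15 Hz
flanks excluding ±2 bins around the target, and converted to sinusoid
amplitude via a = 2√(S·df).  Cell classification applies the published
threshold boxes verbatim (P-unit: vector strength 0.7–0.95, rate > 30 Hz,
negative serial correlation, baseline CV < 1.5, stimulated CV < 2;
ampullary: vector strength < 0.15, rate > 10 Hz, baseline CV < 0.18,
stimulated CV < 1, response modulation < 80 Hz), table-driven so the
thresholds live in configuration.

## Noise split

The intrinsic noise intensity is reduced to α_noise·D with α_noise = 0.1
and the removed fraction is re-introduced as a RAM stimulus s_ξ(t)
band-limited to 300 Hz, a fresh realization per trial.  Because s_ξ passes
through the rectifier and dendrite before reaching the spike generator, its
amplitude has no closed form; it is bisected until the ISI CV matches the
full-noise baseline CV.  Bisection details (unspecified in prior work, fixed
here): initial bracket [0, 0.5] contrast, at most 40 iterations, absolute
CV tolerance 0.01, each iterate evaluated on 4 × 10 s of simulation with a
fixed evaluation seed so the target function is deterministic; CV grows
monotonically with the amplitude over the bracket.  CV-only matching is
used, with the output rate checked afterwards (preserved within 5 % in
tests).  Susceptibilities are then cross-spectra between s_ξ and the spike
train.  For the low-CV exemplar the matched amplitude corresponds to ≈ 4.7 %
contrast and the χ₂ estimate converges around 10⁴ segments, versus ≳ 10⁶
under direct weak-RAM stimulation.

## Synthetic data

The population sampler draws P-unit-like parameters from log-uniform priors
over physiological decades (time constants, noise intensity) and uniform
priors (bias, gain), then rejection-samples on simulated baseline statistics
against the empirical ranges (rates 50–450 Hz, CVs 0.1–1.4).
Ampullary-like cells are mean-driven low-noise LIF units without carrier
coupling (β = 0, hence no phase locking); their bias is solved from a target
rate via the noise-free LIF rate equation with the steady-state adaptation
load r·ΔA compensated, and rejection keeps CVs in 0.03–0.15 at rates near
130 Hz.  The sampling distributions are conventions of this package; only
the acceptance ranges are anchored in physiology.  Sampled populations
reproduce the negative rank correlation between baseline CV and noise-split
SI(r).

Poisson surrogates (linear, quadratic, renewal-gamma, periodic) are
generated by thinning against an explicit rate bound; the fraction of
rate samples clipped at zero is logged and a warning attached above 1 %,
where the analytic transfer oracles degrade.

## Problem sizes

Default analysis runs use 10 FFT segments per simulated trial after the
500 ms transient.  The shipped studies use 10⁴ segments for noise-split and
strong-RAM susceptibilities (the split estimate has converged there; the
same comparison at 10⁶ segments changes SI by less than the seed-to-seed
scatter), 10⁴ segments for surrogate oracles, and 4000 × 4 s trials per
contrast for two-sine sweeps.  The two-sine sweep drives the mid-CV cell
with direct sinusoidal AMs at Δf₁ = 40 Hz and Δf₂ = 228 Hz (its baseline
rate): a superposed foreign EOD additionally distorts the envelope at
second order in the contrast, which contaminates the pure quadratic scaling
being measured, while the AM mode isolates the cell's own nonlinearity.
Linear-peak slopes are fitted on the four lowest contrasts (0.8–2.7 %,
below saturation) and nonlinear-peak slopes on the four highest
(1.2–4 %, above the measurement floor of the trial-averaged rate spectrum).

## Known limitations

* The LIF models do not burst; real P-unit populations reach higher CVs and
  response modulations than sampled populations.
* Binary 0.5 ms binning attenuates measured gains by e^(−rΔt) at rate r; at
  450 Hz this is ≈ 20 %.  This is a property of the printed estimator, not
  corrected for.
* Pointwise agreement between noise-split χ₂ and finite-contrast two-sine
  responses is limited by the vanishing-stimulus idealization of the split;
  the tests certify agreement within a factor of two at off-ridge frequency
  pairs (no systematic bias across pairs), and resonant enhancement on the
  f₁+f₂ = r ridge is expected and observed.
* Passing tests certify the estimators and the model pipeline on synthetic
  data with known ground truth; they do not certify recording artifacts
  (nonstationarity, electrode drift, spike-sorting errors) absent from the
  generator.
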