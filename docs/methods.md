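# Methods

This note documents the generative models, estimators, and design choices
behind `lfpcascade`, in the spirit of a methods appendix: what is being
simulated, why the defaults are what they are, and what the synthetic
results do and do not establish about real recordings.

## 1. Signal model

A simulated LFP channel is a sum of three components on a common 1 kHz time
base (all amplitudes in arbitrary units; every downstream statistic is
either normalized or scale-free):

**Power-law background.** Gaussian noise with expected spectrum
S(f) ∝ f^−α, generated by shaping white Fourier coefficients with
f^(−α/2) and inverting; the DC bin is zeroed and the realization is
rescaled to a target standard deviation. Default α = 2, matching the steep,
near-featureless spectrum of quiescent hippocampal LFP; α is recoverable
from generated data to ±0.1 (averaged periodograms, 20 × 300 s).

**Sawtooth theta.** The non-sinusoidal theta waveform is a phase-locked
harmonic stack

x(φ) = A · Σ_k (−1)^(k+1) · a^(k−1)/k · sin(kφ),  k = 1 … ⌊0.9·f_N/f₀⌋,

where a ∈ [0, 1] is the waveform-asymmetry parameter and φ = 2πf₀t. At
a = 0 this is a pure sinusoid; at a = 1 it is the exact Fourier series of an
ideal sawtooth, so the harmonic-to-fundamental amplitude ratio is exactly
1/k. We chose this construction over a warped-phase cosine because it makes
the harmonic law exact, guarantees that harmonic amplitude (and hence
bicoherence at (f₀, f₀)) grows monotonically with a, and lets Gaussian
smoothing be applied analytically — each harmonic is attenuated by
exp(−(2πkf₀σ)²/2), which is identical to circular convolution with a
Gaussian kernel of SD σ but free of edge artifacts. Defaults: f₀ = 8 Hz,
a = 0.5, σ = 12 ms (visibly rounds the 8 Hz sawtooth while preserving
harmonics through ~50 Hz). A kernel that attenuates the fundamental below
10⁻⁶ of its input power raises `DegenerateSignalError`.

**Theta-locked gamma bursts.** One burst per theta cycle, centered at a
preferred theta phase (default π) with Gaussian timing jitter (SD 3 ms) and
log-normal amplitude jitter (CV 0.5, mean 1). The envelope is a raised
cosine spanning half the theta cycle; the carrier frequency is
`gamma_center + gamma_drive_gain × drive` (defaults 65 Hz and 40 Hz per
unit drive), so drive 0 → 1 with a 25 Hz center sweeps the carrier from 25
to 65 Hz — the interneuron-network regime in which gamma frequency rises
with excitatory drive.

Three carrier-phase models are implemented, because the choice controls
what survives in cross-channel coherence:

- `theta_locked` (default): carrier phase is a deterministic function of
  the theta clock (referenced to the ideal burst center) plus a fixed
  random generator phase; jitter displaces the envelope only. This is
  theta-phase-reset gamma: a local generator whose timing is organized by
  the theta drive.
- `oscillator`: a free-running carrier with a fixed random phase; theta
  modulates amplitude only.
- `burst_locked`: carrier phase re-referenced to the *jittered* burst
  center, so timing jitter randomizes carrier phase directly; the
  cross-channel coherent amplitude at frequency f then decays as
  exp(−(2πfσ)²), the product of the two channels' per-burst
  phase-consistency factors exp(−(2πfσ)²/2). This closed form is verified
  by a dedicated test and makes `burst_locked` the reference mode for
  analytic jitter calibration.

## 2. The two-region toy model

Two channels share one theta phase process; channel 2 is delayed by a fixed
offset (default 25 ms). Each channel carries its own gamma generator —
independent timing jitter, amplitude jitter, and generator phase — plus
independent 1/f noise scaled so that 30–90 Hz noise power equals the
channel's gamma-burst power (gamma-band SNR 1, the model's declared
operating point). Nothing gamma-frequency is shared between channels.

With Welch MSC (1 s Hann segments, 50% overlap) averaged over 30–90 Hz and
20 seeds of 100 s, the default configuration yields mean coherence ≈ 0.12
(seed-to-seed SD ≈ 0.003) — inside the 0.1–0.25 range that matches empirical
inter-regional gamma coherence values, with no interregional gamma
synchronization in the model. The coherence is carried entirely by the
shared theta organization: with burst times drawn uniformly instead
(`theta_modulated=False`), measured coherence equals the Welch estimator's
small-sample bias floor 1/K (0.0055 vs 0.005 at K = 199). Increasing burst
timing jitter degrades the coherence monotonically (1 → 15 ms:
≈ 0.13 → 0.06). The `theta_locked` carrier is essential here: a
free-running `oscillator` carrier produces nearly the same coherence under
theta modulation but retains a spurious coherent line at the carrier bin
even without theta, because two fixed-phase oscillators at the same
frequency are trivially coherent; the default mode removes that artifact.

## 3. Cascade recording and drive mapping

Running speed maps to a dimensionless drive by `drive = v / 30 cm s⁻¹`,
clipped to [0, 1.5] — 30 cm/s is a brisk rat running speed, so drive ≈ 1 is
a strongly driven state. Drive acts multiplicatively on the theta amplitude
(factor 0.5 + drive), additively on waveform asymmetry
(a + 0.4·drive, clipped to [0, 1]), on gamma burst amplitude (∝ drive), and
on the gamma carrier (gain 40 Hz per unit drive). The 1/f background is
drive-independent. Consequences, all verified by tests: the fitted
broadband exponent flattens with speed (≈ 2.0 at rest → ≈ 1.4 at 30 cm/s
under defaults); windowed theta (6–10 Hz) and gamma (50–120 Hz) power are
positively correlated under a time-varying speed profile; and the gamma
spectral centroid rises continuously with drive.

## 4. Spike-train model

Units follow a burst-renewal process: a unit-specific preferred theta phase
(uniform across units), a per-cycle burst probability (uniform in
[0.3, 0.9] across units, giving rates of roughly 4–18 Hz), von Mises phase
jitter around the preferred phase (κ = 4, i.e. ≈ 10 ms timing SD at 8 Hz),
and 1–5 spikes per burst (truncated geometric, continuation probability
0.55) with intra-burst ISIs uniform in 3–8 ms. This construction guarantees
the two-regime ISI structure — intra-burst intervals < 10 ms and
inter-burst intervals near the 125 ms theta period (or multiples, for
skipped cycles) — with no preferred timescale in 20–50 ms: the measured ISI
mass in that band is < 1% under defaults.

The injected negative control is an intermittently rhythmic 40 Hz unit:
runs of five 25 ms intervals (0.5 ms jitter) separated by stretches of 6–16
irregular intervals drawn uniformly from 55–300 ms. The intermittency is
deliberate. A metronomic 40 Hz unit puts *all* its ISI mass in the 20–50 ms
block, so the outer-product independence baseline matches it exactly and
enrichment is 1 — formally present but undetectable as *clustering*. The
intermittent design keeps the marginal in-band fraction near 0.3 while
successive in-band intervals arrive in runs, giving enrichment ≈ 2.6 and a
dominant return-map cell at (40, 40) Hz, and separating control from
default units with AUROC > 0.95 on the block-mass score.

## 5. Estimators

**PSD / coherence.** scipy.signal Welch estimators; defaults 1 s Hann
segments, 50% overlap. PSD integrals satisfy Parseval within 5% on
stationary inputs. `CoherenceResult` records K and the bias floor 1/K;
independent-noise MSC matches 1/K in Monte Carlo (200 repeats).

**Spectral slope.** Least squares of log₁₀ power on log₁₀ f over 2–200 Hz
by default, excluding the theta fundamental and harmonics k·f₀ ± 1 Hz up to
32 Hz, so narrowband peaks and the broadband exponent remain distinct
observables. The fit is invariant to amplitude scaling; α is reported
positive for decaying spectra.

**Bicoherence.** b²(f₁, f₂) = |⟨X₁X₂X₁₊₂*⟩|² / (⟨|X₁X₂|²⟩⟨|X₁₊₂|²⟩) over
Hann-tapered Welch segments — the normalization bounded in [0, 1] by
Cauchy–Schwarz, chosen for comparability across signals. At least 16
segments are required. `bicoherence_at` evaluates a single triplet cheaply
for surrogate loops.

**Surrogate null.** Fourier phase randomization preserving the amplitude
spectrum; thresholds are the 95th percentile over ≥ 100 (default 200)
surrogates. For segment-averaged statistics the phases are randomized
independently per 1 s block: whole-trace randomization assigns one random
phase per spectral line, so every analysis segment of a strongly periodic
signal inherits the same triplet phase and b² stays at 1 under the "null" —
block-wise randomization restores the correct linear null while preserving
block amplitude spectra. Whole-trace surrogates remain available
(`seg_len=None`) and preserve the global spectrum exactly.

**Harmonic audit.** A fast band (default 16–32 Hz) is classified
`theta-coupled` / `independent` / `none` by combining (i) band mean
spectral density in excess (3×) of the power-law background predicted at
the band center by a slope fit that excludes theta harmonics and the band
itself, and (ii) surrogate-significant bicoherence at the triplet tying the
band's nearest harmonic to the fundamental, with an effect-size floor
b² > 0.1 so that chance exceedances of a 95th-percentile threshold are not
read as coupling. Classification accuracy across sawtooth /
sine-plus-independent-40 Hz / pure-sine constructions is 100% over 20 seeds.

**Windowing artifact.** Spectra of consecutive Hann-tapered windows; the
summary is the power ratio of the 1.5f₀–2.5f₀ band to the 0.5f₀–1.5f₀
band, reported as the *excess* over the same ratio computed for a pure f₀
tone under identical windows. The subtraction matters: at one-cycle windows
any taper leaks fundamental power into the harmonic band (a pure sine
scores 0.25 raw), so the raw ratio conflates leakage with waveform content.
The excess ratio is ~0 for a sinusoid at any window, is strongly inflated
for a sawtooth at 125 ms windows, and converges to the waveform's true
Fourier harmonic power ratio (a/2)² · attenuation² as the window grows.

**Spike-phase modulation.** Per frequency on a log-spaced grid (default 40
points, 2–120 Hz): Gaussian frequency-domain bandpass centered at f with
±f/4 half-width (2 SD), analytic-signal phase (phase 0 at the positive
peak), nearest-sample phase assignment, 24 equal phase bins, and the mean
resultant length of the binned distribution as modulation strength. The
binning attenuates R by sinc(π/24) ≈ 0.997 — negligible against the 0.02
calibration tolerance on the von Mises closed form I₁(κ)/I₀(κ). The
uniform-phase null mean √π/2/√n is matched in Monte Carlo. Population
summaries average per-unit curves by default (low-n entries excluded);
spike-count-weighted pooling is available because the averaging order is a
genuinely open choice.

**Speed binning.** 1 s segments labeled by mean speed with half-open edges
[0, 7), [7, 20), [20, ∞) cm/s: 7.0 cm/s is "moderate" and 20.0 cm/s is
"high". Segments without defined speed are dropped and logged. ISI return
maps use a 50 × 50 log-spaced grid over 1–500 Hz instantaneous frequency
(1000/ISI_ms); population averages peak-normalize each map (n/max n) and
weight by min(rate, 1 Hz), so sparse cells contribute proportionally to
their rate and active cells equally.

## 6. Experiments and verdicts

Each scripted experiment emits per-seed (or per-window) values, a bootstrap
percentile CI (1000 resamples) where the statistic is stochastic, and a
verdict against a stated expectation. Expectations are directional or
interval-based because the underlying predictions are qualitative; the
operationalizations are ours: the gamma *spectral centroid* (30–120 Hz) as
the continuity observable, a gap statistic (largest adjacent centroid jump
over the median jump, flagged above 3) as the discontinuity test, and
Spearman rank correlation ≈ 1 across band-power profiles as the
"proportional decline" test for hierarchical perturbation, with a
selectivity flag when one band falls > 50% while another moves < 10%. Both
constructed violations — discrete 40/80 Hz band switching and a post-hoc
50–120 Hz notch — are detected in ≥ 95% of seeds (20/20 in the shipped
tests); the 25–50 Hz range is always labeled "theta-harmonic band" in
outputs, never "slow gamma".

Problem sizes in the shipped tests (20 × 100 s toy-model seeds, 100 units ×
600 s spike populations, 200 surrogates, 20-seed violation screens) were
chosen so the full suite completes in about a minute while keeping
Monte-Carlo error well inside each tolerance.

## 7. What the synthetic data do not show

The generators reproduce the *statistical structure* the analyses assume —
harmonic phase-locking, theta-organized burst timing, two-regime ISI
statistics, drive-dependent spectral reshaping — not hippocampal
biophysics. There are no conductance-based neurons, no laminar geometry or
volume conduction, no current-source densities, and no behavioral
non-stationarity beyond the imposed speed profile. Passing tests therefore
establish that the estimators are calibrated and that the confound
mechanisms are sufficient to produce the reported effect sizes; they do not
establish that real "slow gamma" reports are harmonics, only that the audit
distinguishing the two works on signals where the truth is known. Real-data
idiosyncrasies the model omits include heteroskedastic noise, movement
artifacts, inter-animal variability in theta frequency, and spike-sorting
contamination. The toy model's parameters (65 Hz carrier, 3 ms jitter, CV
0.5, SNR 1, 25 ms offset) are declared operating points, not fits to any
dataset; the coherence range they produce is robust to the seed but not
asserted to be robust across the full parameter space.
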