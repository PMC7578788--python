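# Methods

`betaadapt` is a simulation-backed pipeline for a specific electrophysiology
question: does pre-movement beta-band (15–25 Hz) power over motor cortex
drop specifically while visuomotor adaptation is in progress, beyond
anything explained by reaction time or reach duration?  Because the package
ships no recorded data, every stage is built around a synthetic generator
with known ground truth; the tests establish that the analysis chain
recovers what the generator injects, with controlled false-positive rates.

## Behavioural model

Human sessions are three blocks of 200 reaches (baseline, rotation,
washout), four targets at 45°/135°/225°/315° from vertical presented
pseudorandomly in balanced 20-trial blocks.  Angles are degrees
counterclockwise from vertical; clockwise errors are negative.  During the
rotation block a clockwise rotation `r` (default 30°; the task is also run
in the literature at 35°, and the value is configurable) perturbs the
cursor.

Adaptation follows a single-rate state-space learner.  With internal
estimate `x_1 = 0`:

    e_n     = r_n − x_n            (noise-free error; r_n = r in the rotation block, else 0)
    x_{n+1} = A·x_n + B·e_n

The reported endpoint error is `−e_n − ε_n` with motor noise
`ε_n ~ N(0, σ²)`.  Closed forms used as test oracles: with `A = 1` the error
decays geometrically (`e_{n+1} = (1−B) e_n`); in general the adaptation
fixed point is `e* = r(1−A)/(1−A+B)` and
`e_n = e* + (A−B)^n (r − e*)`.  When `B > A` the update overshoots and the
error magnitude oscillates while converging, so the monotone-decay property
is only asserted for `B ≤ A`.

Defaults: `A = 0.98`, `B = 0.10`, `σ = 4°`.  These give an initial rotation
error of ~30°, an asymptote of `30·0.02/0.12 = 5°` and a first-washout
(negative aftereffect) error of ~+25°, matching the qualitative behavioural
curve of this task class (fast decay over tens of trials, small residual
error, sign-reversed aftereffect that washes out).  Reaction times and
reach durations are Gaussian (defaults 300 ± 40 ms and 350 ± 40 ms) with
additive per-epoch offsets (default: EA +15 ms RT, −8 ms duration),
reflecting the small but reliable kinematic differences across epochs that
motivate covariate adjustment.

A single-rate learner (not the two-state fast/slow model) is deliberate:
only the curve's shape matters downstream, and one state keeps the ground
truth trivial to reason about.

Cat sessions emulate a prism reach task: ~20 baseline trials, a prism block
whose miss probability starts high (default 0.9) and decays with time
constant 5 trials (adaptation), ending after 20 consecutive hits (capped
and flagged non-converged otherwise), then a short post block.  Epochs
follow the hit/miss mapping: Baseline = pre-prism hits, EA = prism misses,
LA = prism hits.  Trials are rejected by session-level rules: reaction time
< 150 ms, duration > mean + 2 SD for that session, or flagged corrections /
artifacts.

## Epochs

Human analysis epochs are five consecutive 72-trial sets: Baseline (last 72
baseline trials), EA / LA (first / last 72 rotation trials), EAft / LAft
(first / last 72 washout trials).  The "errors beyond baseline mean ± 2 SD"
characterisation of the early epochs is reported as a QC fraction on EA and
EAft, not used as a selection filter — a fixed 72-trial window and a
per-trial error criterion cannot jointly define a selection, and the fixed
window keeps epoch membership deterministic.  Strict inequalities are used
for the 2 SD rule and for the 5-pixel movement-initiation threshold
("exceeds" semantics).  Generated sessions shorter than the standard layout
shrink the epoch length to the shortest phase so reduced test sessions
still carry all five labels.

## Neural generator

Each behavioural session can be coupled to a continuous multichannel
record.  Movement-initiation markers are laid on a regular 2.5 s grid;
target onset precedes each marker by that trial's reaction time, movement
end follows by its duration.

Background noise is Gaussian `1/f^α` (default `α = 1`), synthesized by
spectral shaping and scaled by its *analytic* expected SD rather than the
realized SD — the realized variance of a 1/f record is dominated by a few
low-frequency components, and normalising by it would give every record a
random broadband gain that shifts all of its trials' log power coherently
(an artefactual session effect the earliest version of the generator did
exhibit).

The beta rhythm is a comb of equal-amplitude sinusoids spanning the band
interior (default 16, 18, 20, 22, 24 Hz), phases re-drawn midway between
trials, scaled to unit RMS and multiplied by an amplitude envelope.  Two
candidate models were evaluated against the package's own recovery targets
before the default was frozen:

* a *single 20 Hz carrier* concentrates power at one line of the 15–25 Hz
  analysis grid; the off-carrier wavelet bins stay noise-dominated and
  dilute the band-mean statistic, so an injected amplitude gain `g` is
  recovered as substantially less than `2 ln g`;
* *band-limited Gaussian noise* covers the grid evenly but makes band power
  itself a χ²-fluctuating quantity (log-power variance π²/6 per independent
  bin regardless of SNR), inflating per-trial variance.

The comb combines even grid coverage with a deterministic per-trial band
power, making the injected gain a recoverable target at realistic trial
counts.  The cost is realism: genuine sensorimotor beta is bursty and
stochastic, so recovery and power results on this generator certify the
*pipeline*, not expected sensitivity on real recordings.

The envelope per trial, in units of the base amplitude (`beta_rms`,
default 1.4):

* tonic level 1 between trials (idle rhythm);
* the epoch gain `g` from 150 ms before target onset (`premove_lead_ms`;
  the preparatory state is assumed to precede the imperative stimulus)
  until 50 ms after movement initiation;
* `1 − desync_depth` (default 0.4) during movement — the event-related
  desynchronization, epoch-independent;
* a rebound of 1.5 for 600 ms starting 300 ms after movement end,
  epoch-independent.

Transitions are smoothed over ~10 ms.  The epoch gain defaults to 0.8 on EA
and 1.0 elsewhere: the emulated finding is an early-adaptation-specific
amplitude drop, i.e. a true band log-power deficit of `2 ln 0.8 ≈ −0.446`.

Two deliberate features keep that deficit recoverable through the analysis
chain.  First, the comb covers the analysis grid (above).  Second, the
tonic, movement and rebound segments are epoch-independent, so most of each
2 s window's variance does not scale with the epoch gain; since windows are
z-scored by their own SD (see below), an envelope whose variance scaled
fully with `g` would largely cancel the injected change.  With the
defaults, the end-to-end recovered deficit is ≈ 75% of `2 ln g` (the
z-score and residual grid/temporal dilution absorb the rest), which the
recovery tolerance accommodates.  The base amplitude (beta band power ≈ 6×
the in-band background after derivation) was fixed once by this pilot
analysis and is documented here as the package's study condition.

The designated beta channel (C3 for the human montage) receives the full
rhythm; all other channels receive a 0.3-attenuated copy, so the Hjorth
derivation retains 70% of it while cancelling common-mode components.  The
cat montage is a two-site probe (bipolar derivation, 0.2 leak).  Default
acquisition rates are 2500 Hz (human EEG) and 30 kHz (cat LFP); tests and
the acceptance script run reduced rates (≥ 1 kHz) since the analysis chain
operates at 500 Hz regardless.

What the generator does **not** emulate: beta bursts and amplitude
stochasticity, eye/muscle artifacts (hence no artifact-removal stage),
electrode geometry and volume conduction beyond the single-leak
approximation, non-stationary noise floors, the cat animal whose effect
reverses sign, and EMG (the cat pre-movement window is a configuration
parameter rather than being placed from flexor-burst onset).

## Signal chain numerics

* Derivations: Hjorth Laplacian = centre − mean of its 4 mapped
  neighbours; bipolar = a − b.  Both are linear, so they commute with the
  filter chain (tested).
* Filter chain: zero-phase (forward–backward) 4th-order Butterworth
  low-pass at 30 Hz at the native rate, resampling to 500 Hz (plain
  decimation for integer ratios — the 30 Hz low-pass already anti-aliases
  against the 250 Hz Nyquist; polyphase otherwise), then zero-phase
  4th-order Butterworth high-pass at 10 Hz.  Zero-phase filtering preserves
  event alignment, which the pre-movement windowing requires; the effective
  order doubles (e.g. ~28 dB rather than 14 dB at 45 Hz).  The first/last
  0.25 s of a filtered record are excluded from downstream statistics;
  in practice the generator pads records well beyond this.
* Windows: 2 s, movement initiation at the centre sample; events closer
  than 1 s to a record edge are skipped with a logged reason.  Each window
  is z-scored by its own mean/SD (the normalisation is applied to the
  extracted window, before the wavelet transform; zero-variance windows are
  an error).
* Morlet transform: analytic Morlet, nondimensional frequency ω₀ = 6,
  Torrence–Compo unit-energy normalisation, scale
  `s = (ω₀ + √(2+ω₀²))/(4πf)`.  Computed by frequency-domain
  multiplication after zero-padding past the widest wavelet's support, so
  the result equals a linear (not circular) convolution; a direct
  convolution oracle agrees to < 1e−6 relative error.  Coefficients within
  one e-folding time (√2·s) of a window edge form the cone of influence
  and are excluded as NaN.
* Log power: natural log of |coefficient|² with a 1e−12 floor.  Natural
  log makes an amplitude ratio `g` an exact `2 ln g` shift, unit-free.
  No further baseline normalisation is applied beyond the per-window
  z-score.  For multi-trial stacks the power grid may be decimated in time
  (default ×4 in the pipeline) — the wavelet's temporal envelope makes
  adjacent 2 ms samples redundant.
* Pre-movement statistic: mean log power over the 15–25 Hz rows (1 Hz
  grid) and the trial's pre-movement interval — the trial's own
  [−RT, 0) in human mode, a fixed configured span (default [−400, −200) ms)
  in cat mode, where window placement from EMG is out of scope.  Intervals
  with no valid cells yield NaN (flagged missing, never zero); intervals
  longer than the extracted window are truncated with a log note.

## Statistics

* Spearman correlations (average-rank ties, t-approximation p) between the
  beta statistic and reaction time / duration.
* Simple regression of |endpoint error| on beta power; F = (R²/(1−R²))(n−2)
  with df (1, n−2).
* Epoch contrast: ordinary least squares
  `beta ~ C(epoch) + rt + duration (+ C(subject))`, type-II partial F for
  the epoch factor, all pairwise differences of covariate-adjusted epoch
  means with Bonferroni correction over the number of pairs (10 for the
  five human epochs, 3 for the cat Baseline/EA/LA).  This is a declared
  replacement for a repeated-measures GLMM: the original covariance
  structure is not recoverable from a methods description, while a
  fixed-effects ANCOVA with subject/session as a factor is fully specified
  and testable against a normal-equations oracle.  Rank-deficient designs
  raise an error naming the aliased columns.
* Balanced bootstrap: each of n_boot (default 1000) replicates draws
  m = min(group size) observations with replacement from every condition;
  reported are bootstrap means/SEs, 2.5/97.5 percentile CIs of pairwise
  mean differences, and two-sided empirical p-values with Bonferroni
  adjustment.  Bootstrapping condition means (rather than re-running the
  ANCOVA per replicate) is a deliberate simplification; single-trial
  conditions are flagged as degenerate rather than fatal.

## Reproducibility and problem sizes

A single run seed expands into per-stage seeds via `SeedSequence` spawning,
so stages can be re-run independently and full runs are bit-for-bit
reproducible (tested byte-wise on the written artifacts).  The Monte-Carlo
test battery uses standard 200/200/200 sessions at a 1 kHz acquisition
rate: 100 effect runs for parameter recovery/power, 200 null runs for the
type-I rate, and 200 runs with a +40 ms EA reaction-time shift (and no
beta change) for covariate immunity.  The acceptance script repeats the
same analyses at 30/40/40 runs and adds an 8-session pooled cat analysis.

## Known limitations

* The generator's comb beta understates real trial-to-trial variability;
  power figures are about the pipeline, not about real EEG/LFP.
* The ANCOVA treats trials as exchangeable within epoch; slow drifts in
  real recordings would violate this and are not modelled.
* The bootstrap and the ANCOVA are reported side by side, not integrated.
* No artifact simulation or removal; the Laplacian's common-mode
  cancellation is only exercised against the shared leak component.
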