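# Methods

This note documents the models, conventions and numerical choices behind
`cmephys`, stage by stage, including what the synthetic generators do and do
not emulate.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Conventions

Time is in seconds with 0-based sample indices; the time of sample *i* is
`t0_s + i/rate_hz`.  Analysis windows are half-open `[t_start, t_end)`.
Intracellular voltages are kept as recorded (negative diastole, mV); no
rescaling.  Wherever a "SD" is reported it is the sample standard deviation
(n−1), so summary blocks, CV and SD1/SD2 are mutually consistent.

All derivatives (AP upstroke velocity, Ca²⁺ rates) use one shared
Savitzky–Golay configuration — 5-point window, order 2 — so the generators'
calibration and the measurements agree on what "the derivative" means.

## Synthetic action potentials

The AP waveform is phenomenological, not ionic: a linear upstroke with an
exact per-sample increment (so the constructed slope equals the
`upstroke_vps` parameter exactly on the grid), a brief plateau (default
2 ms), and an exponential repolarization.  The decay constant is *solved*
per waveform so that the 90%-repolarization crossing, measured from the
activation time that the feature stage itself reports (argmax of the
smoothed derivative), lands exactly at the requested APD₉₀.  The tail is
clamped to MDP once within 0.5% of APA, which makes the diastole — and
hence the measured MDP — exact on clean traces.

Injected events are raised-cosine bumps (period 120 ms) on the diastole:
DADs as damped runs (amplitude ratio 0.55/cycle, first amplitude drawn
uniformly from 5–15 mV), OPPs as growing runs (ratio 1.3/cycle, compressed
in period when a long run would not fit the diastole), and failed beats as
a single bump replacing a scheduled AP.  These amplitudes and ratios are
declared conventions of this package — the source material describes the
morphologies only qualitatively — and they are exposed as parameters.
Injections that would collide with an AP or its refractory margin raise an
error rather than silently overlapping.

Default noise is band-limited Gaussian: 0.5 mV (AP), 5 µV (MEA), 2% of
baseline (Ca²⁺).  These defaults keep the SNR in the range where a
recall ≥ 0.95 detection bar is meaningful rather than trivially saturated
or impossible.

What the generators do *not* emulate: ionic-current dynamics, rate
adaptation of APD, cell-to-cell waveform variability, electrode drift
other than a sinusoidal wander, motion artifacts, and multi-cell image
fields (one cell per tile).  Passing tests therefore demonstrate correctness
of the measurement definitions and robustness at realistic SNR, not
performance on pathological real-world recordings.

## Beat detection

*AP*: upward threshold crossing (default 0 mV — spontaneous iPSC-CM APs
overshoot; configurable for non-overshooting cells) followed by the local
maximum, with a 0.2 s refractory period chosen from the fastest plausible
spontaneous rate.  *MEA*: a first-difference-based single-pole high-pass
(1 Hz corner; removes field-potential wander without ringing), noise scale
1.4826·MAD, detection at |x| > 5·MAD, spike time at the absolute extremum
of each supra-threshold run — polarity-invariant by construction.  *ECG*: a
Pan–Tompkins-style chain (10–45 Hz band-pass, derivative, squaring, 30 ms
integration) with a threshold at 20% of the 99.5th percentile of the
integrated signal and a 40 ms refractory period sized for rat rates
(sinus ≈ 5 Hz, VA up to ~12 Hz); each detection is refined to the extremum
of the band-passed waveform.

## AP features

APD₉₀ is referenced to activation (time of dV/dt_max), not to the peak;
both conventions exist in practice, and the choice is recorded in the
output metadata (`apd90_reference`).  The MDP search window runs from the
previous beat's APD₉₀ crossing to the current upstroke; the first beat uses
the trace start.  A beat whose repolarization never reaches the 90% level
before the next beat gets `NaN` APD₉₀ and a logged warning, never a
fabricated value.

## Event detection and classification

Candidates are diastolic local maxima of a ~15 ms local-polynomial-smoothed
trace with prominence in [2 mV, 0.5·median APA], excluding each beat's
upstroke and repolarization windows (20 ms margins).  Candidate amplitude
is the peak prominence; because the enclosing diastole still carries the
repolarization tail, this reads a few percent below the injected bump
height — a baseline convention, not an error, and irrelevant to the
within-run amplitude ordering the classifier uses.

Classification applies ordered rules per diastolic run: OPP (≥ 3 strictly
increasing amplitudes ending in a beat), then failed beat (enclosing IBI
> 1.5× the running median over the preceding 10 beats *and* a candidate
within ±25% of the expected beat time), then DAD (non-increasing after the
first, following a beat).  Anything else is kept as `unknown` with a
warning — runs are never silently dropped.  The run-length-3 boundary
between "a few damped oscillations" (DAD) and a short OPP is this package's
resolution of a genuinely underdetermined distinction.

Pacing response: a rate is flagged if a classified event falls inside its
post-train pause or the longest beat-free gap in the pause exceeds 2× the
median pre-pacing IBI (firing cessation).

## Whole-heart VA episodes

Baseline RR is the median over the first 60 s.  An RR below baseline/1.5 is
a VA interval; consecutive VA intervals form episodes, merged across gaps
< 2 s; an episode is sustained if longer than 30 s.  The episode *onset* is
reported as the midpoint of the RR interval preceding the first fast beat:
the true transition lies somewhere in that interval, and the midpoint is
the unbiased estimate (reporting the first fast beat instead biases the
onset late by up to one sinus RR).  VT and VF are pooled as VA; no
morphological discrimination is attempted.

## Ca²⁺ transients

The generated transient rises as a normalized saturating exponential
(τ_rise, reaching its amplitude exactly at the grid-aligned peak) and
decays as an end-anchored exponential (τ_decay, reaching baseline exactly
at the end of its interval), so overlapping tails never bias the measured
amplitude on clean traces.  `ca_analytic_rates` gives the closed-form
maximal rise/decay rates of this construction for tests.

A note on discretization: the maximal rise rate of an exponential onset
lives at a corner.  At the standard 100 points/s acquisition the 5-sample
derivative window spans 50 ms ≈ τ_rise, so the discrete rate maximum
underestimates the analytic value by tens of percent — *any* smoothing
estimator at that rate does.  The closed-form rate checks therefore run on
1 kHz clean traces (sampling rate is a generator parameter), where the same
5-sample window spans 5 ms and resolves the corner to within a few percent.
Time-constant recovery at 100 Hz with default noise instead uses per-segment
exponential fits: the decay by least squares on `c·exp(−t/τ)+d`, the rise by
log-linear regression on the unsaturated segment (10–85% of amplitude) —
the free-asymptote nonlinear fit is ill-posed on 20-odd points and was
replaced after inspection of its failure modes on clean + noise data.

"First measurable transient" after caffeine is the first peak reaching 25%
of the mean pre-caffeine amplitude (configurable); transient areas are
trapezoidal above each transient's own baseline from onset (5% level) to
95% return.  Whether rates should be read from single transients or from
the 20-transient ensemble average is ambiguous in practice, so both are
emitted.

## Imaging

Densities are RawIntDen/area per compartment; the N/C ratio divides them.
Thresholds are constant per dataset (a histogram-based suggestion helper
exists but is never applied silently).  The cell outline is taken from the
signal channel with a containment rule (largest component containing the
nucleus); a study could instead use a separate cytoskeletal marker channel
or manual ROIs — with uniform synthetic cytoplasm the difference is nil,
with real textured cells it would not be.  Gaussian noise is zero-mean, so
density ratios are recovered essentially unbiased; Poisson noise is also
supported.

## Statistics

Normality is tested per group with the one-sample KS test against a normal
with estimated mean/SD, because that is the named procedure being mirrored;
the estimated-parameter KS test is *anti-conservative* as a normality test,
and a Lilliefors-corrected variant is available behind a flag.  Constant
groups force the non-parametric branch.  Tukey's post hoc runs only on the
parametric ≥ 3-group branch.  No multiple-testing correction is applied
across features by default (Holm available).  The decision tree's empirical
type-I error under a three-group normal null is checked by simulation
(5000 datasets, n = 30/group) in the acceptance suite.

## Mixture-model decisions

Bimodality: 1- vs 2-component Gaussian mixtures on the IBIs; bimodal iff
the 2-component BIC is lower *and* the mode separation exceeds 2× the
pooled within-component SD.  Poincaré clouds: 2-D mixtures over k = 1…4,
lowest BIC wins, ties to the lowest k.  Fits use 5 restarts with a
deterministic seed derived from a hash of the data (so identical data give
identical fits in any process), and a variance floor of 1 ms² guards
degenerate fits.

## Problem sizes

The figure presets and validation benchmarks run at desk scale by choice:
6–12 cells or 8 hearts per group, 300–400 IBIs per series, 20–30 transients
per trace, 40–120 s electrophysiology recordings (full 90 min only for
whole-heart beat sequences, which are cheap), 20 seeds for stochastic
guarantees and 5000 simulations for the calibration check.  These sizes
make every stated tolerance testable in about a minute while keeping the
statistical checks meaningful.

## Known limitations

Classification thresholds are conventions, tuned for clarity of definition
rather than for any particular dataset; real recordings with drifting
baselines, EADs (out of scope), or fused events will need threshold review.
The ECG detector assumes rat-range rates and QRS-dominated morphology.  The
imaging stage handles one cell per tile and 2-D images only.  SD2 for short
noisy series is floored at zero where the alternation variance exceeds the
total variance, in which case the SD1²+SD2² identity intentionally does not
hold.
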