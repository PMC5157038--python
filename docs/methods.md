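# Methods

This note records the models, parameter choices and numerical decisions
behind `muresp`, in the spirit of a methods appendix: what is computed, why
the defaults are what they are, and what the synthetic-data tests do and do
not establish.

## Signal model and quantification

The pipeline treats the sensorimotor Mu rhythm as two narrow-band
processes, alpha (8–14 Hz) and beta (15–30 Hz), whose instantaneous
amplitude is modulated by each movement: a pre-/peri-movement suppression
(ERD) and a post-movement rebound (ERS).  Because movements repeat every
1–3 s, responses overlap and the envelope returns to a cyclic baseline
rather than a resting level; the quantification therefore uses the swing of
the movement-locked average envelope rather than a ratio to a pre-trial
baseline:

- Amp_min = min of the 60-epoch-averaged envelope over [−1.5, 0) s,
- Amp_max = max over [0, 2.0) s,
- Amp_resp = Amp_max − Amp_min (µV),
- PAmp_resp = 100 · Amp_resp / ((Amp_max + Amp_min)/2) (%).

The midpoint denominator makes PAmp_resp invariant to overall signal scale
and to the envelope estimator's gain (the rectified-smoothed envelope of a
tone is 2/π of its Hilbert envelope; the ratio cancels).  A `time_mean`
denominator (the time average of the block-averaged response) is available
as a configuration option, since "the mean of the event-related response"
admits both readings; the midpoint is canonical here.

The epoch extraction window is [−1.5, 2.0) s even though epochs are often
described as ending at +1.5 s: the Amp_max search extends to 2.0 s, so the
extraction window must too.  All windows are half-open in seconds with
t = 0 at the first sample; trigger times are kept as float seconds and
rounded to the nearest sample only at epoching.

### Envelope extraction

`rectify_smooth` (default): zero-phase band-pass → |·| → 0.1 s centred
moving average.  `hilbert_am`: zero-phase band-pass → magnitude of the
analytic signal.  The band-pass is a 6th-order Butterworth (the order of
the one-pass design; forward–backward application via `sosfiltfilt` cancels
phase and doubles the attenuation) with reflection padding, in
second-order-section form for numerical stability.

Numerical choice — the moving-average window: with the window realized as
`round(0.1·fs)` uniform taps (plus one to stay centred), a rectified 10 Hz
tone at 1 kHz is averaged over 2.02 rectified periods, which aliases a ~1 %
ripple onto what should be the exact 2/π plateau.  The window is therefore
built so its *support* is exactly `window_s`: an odd number of samples uses
uniform weights, an even number uses one extra tap with half-weight ends
(trapezoid quadrature).  This integrates whole rectified periods exactly
(plateau = 2/π to ~1e−6) and keeps the filter symmetric and centred.  The
impulse response consequently plateaus at `1/(window_s·fs)` (1/100 at
1 kHz) with half-weight end taps.

### Retention rules

An epoch is retained iff (strict inequalities on the retained side)
peak |EOG| over the epoch window < 300 µV and |inter-movement duration −
designated IMI| < 0.5 s.  The artifact rule takes precedence in the flag
bookkeeping.  The first movement of each run (or sub-session, when rest
boundaries are supplied) has no defined duration; it is excluded, and —
together with epochs whose window falls off the recording edge — excluded
from the retention-rate denominator, which is meant to describe
timing/artifact compliance: rate = 100·retained / (retained +
rejected_timing + rejected_artifact).  Whether peak-absolute or
peak-to-peak EOG was intended is not specifiable from the text; peak
absolute amplitude is used.

Blocks are consecutive, non-overlapping, chronological groups of exactly 60
retained epochs; a final partial block is discarded with a logged warning.
Across-block summaries use the sample sd (ddof = 1; 0 for a single block).

### Statistics

`one_way_anova` wraps the classic between/within decomposition
(`scipy.stats.f_oneway`) with explicit degenerate handling: all-identical
data give F = 0, p = 1 by convention; zero within-group variance with
unequal means is an error.  `anova_from_summary` implements the same
decomposition from group means, sds and sizes — the route for published
mean ± sd tables — and agrees with the raw-data ANOVA to floating-point
tolerance (property-tested).  Post-hoc comparisons are two-tailed t-tests
on all k(k−1)/2 pairs (pooled-variance independent tests by default; a
paired option exists because a within-subject design could be analysed
either way, and the reported df (2,57) for n = 60 observations indicates
the between-groups treatment), gated on ANOVA p < α and flagged against the
Bonferroni threshold α/m.

## The synthetic-data generator

`simulate_recording` builds C3/C4 as a sum over bands of
`a_base · g(t) · carrier(t)` plus 1/f background noise (spectral shaping)
and an optional power-line tone, and an EOG channel of Poisson blink
deflections (difference of two Gaussians, ~0.25 s wide) plus noise.  The
modulation gain is

    g(t) = 1 − d·Σ_k exp(−(t−t_k−t_erd)²/(2σ_erd²))
             + r·Σ_k exp(−(t−t_k−t_ers)²/(2σ_ers²)),   clipped at 0.05,

so for separated bumps the averaged-envelope extrema are (1−d)·a_base and
(1+r)·a_base and the expected response is the closed form
PAmp_resp = 200(d+r)/(2+r−d).  Defaults: t_erd = 0 s, σ_erd = 0.3 s
(suppression builds through the second before onset and is deepest at it),
t_ers = 1.0 s, σ_ers = 0.25 s (rebound 0.7–1 s after a brief finger lift
ends).  These widths keep ERD/ERS overlap below 1 %, which the closed form
requires; at the fast rate (IMI 1 s) bumps of neighbouring movements
overlap and the ground truth is instead computed numerically from the
realized mean gain trace over the epoch windows.  The ipsilateral channel
scales (d, r) by a laterality factor `lat` (1 = symmetric, LI = 0).

Carrier: the default is a constant-envelope cosine whose instantaneous
frequency performs a slow (< 0.5 Hz), clipped random walk over the central
half of the band.  Two properties motivate this over band-filtered Gaussian
noise: (i) its Hilbert envelope is exactly 1, so the recovered PAmp_resp
isolates pipeline fidelity — a Gaussian carrier's Rayleigh envelope
fluctuation survives 60-epoch averaging at ~7 % relative sd and biases the
window extrema systematically upward; (ii) keeping the instantaneous
frequency off the outer quarter of the band avoids the analysis filter's
skirts, which would otherwise compress the amplitude modulation by several
percent.  `kind="narrowband_noise"` reproduces the realistic fluctuating
envelope, and `kind="tone"` gives a fixed-frequency carrier.

Trigger streams have onset-to-onset gaps `IMI + N(0, jitter_sd)`, default
jitter 0.06 s — the realized inter-movement sd of healthy subjects at these
rates — with an optional fraction of ±0.8 s outliers to exercise the
timing filter, and a 0.2 s minimum gap.  Amplitude scale defaults
(alpha 15 µV, beta 6 µV baselines, 5 µV noise sd, blink peaks 100–350 µV)
are plausible values for adult central-channel EEG, not measured constants.
All randomness in one recording flows from a single seeded generator, so
(scenario, seed) is bit-reproducible.

What the generator does *not* emulate: volume conduction and channel
cross-talk, non-stationary baseline drift, real blink topography on C3/C4,
heavy-tailed timing errors, or the multi-channel montage.  Passing
recovery tests therefore establishes that the pipeline measures the
modulation it is pointed at — not that real recordings meet the model's
assumptions.

## Problem sizes and tolerances

Synthetic verification runs use fs = 250 Hz (well above 4× the highest band
edge; the format round-trip and closed-form tests use 1 kHz), runs of
66–100 movements (one 60-epoch block per recording), and a demonstration
bank of 3 rates × 20 subjects with rate-decreasing (d, r) and a subject
random effect (sd 0.04).  Parameter recovery across d ∈ {0.2, 0.4, 0.6},
r ∈ {0, 0.2} lands within ~3 percentage points of the analytic expectation
at noise up to 0.2·a_base (tolerances asserted: ±10 points there, ±5 at
0.05·a_base); symmetric scenarios give |LI| ≤ 0.05.  ANOVA type-I error is
calibrated at 10⁴ null replicates against [0.04, 0.06].  EDF output is
16-bit with per-channel physical scaling (a warning is emitted when the
quantization step exceeds 0.5 µV) and whole-second record padding;
BrainVision output is IEEE float32 with 1-based sample markers, so trigger
round-trips are exact to one sample.

## Known limitations

- Run metadata (designated IMI, moving hand) is not encoded in BrainVision/
  EDF output; callers re-attach it on load.
- The EDF writer pads the final data record to a whole second; round-trips
  of non-integer-second recordings gain up to fs−1 samples.
- The 16-channel montage, re-referencing and ICA-style artifact removal are
  out of scope; the EOG threshold rule is the only artifact defence.
- LI is computed from across-block mean PAmp per hemisphere (not per-block
  LI averaged); with one block the two coincide.
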