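# Methods

## Signal model

All calls analysed here are pulse trains: sequences of brief acoustic or
neural pulses whose *timing* carries the relevant structure. The
analysis is purely temporal — pulse repetition rate (PRR) is defined as
the reciprocal of the inter-pulse interval, never estimated from a
spectrum — so the synthetic generator makes no attempt at spectral or
harmonic realism, and no propagation or tank acoustics are modelled.

A synthetic call is parameterised by `CallSpec`:

| parameter | units | default(s) | meaning |
|---|---|---|---|
| `duration` | s | 0.2 (grunt) … 10 (hum) | span from first to last pulse |
| `prr_mean` | Hz | 80–120 by class | mean instantaneous pulse rate |
| `prr_cv` | – | 0.02–0.3 by class | CV of the inter-pulse intervals |
| `amp_cv` | – | 0.02–0.3 by class | CV of pulse amplitude about the envelope |
| `onset_ramp_frac` | – | 0.1 (hum), else 0 | fraction of the call over which amplitude ramps up |
| `pulse_shape_width` | s | 0.002 | width of the rendered pulse wavelet |

Inter-pulse intervals are drawn i.i.d. normal with mean `1/prr_mean` and
the stated CV, truncated at 10% of the mean to stay positive; pulses are
emitted until the duration is exceeded, so the pulse count tracks the
integrated rate within ±1. Amplitudes are unit-envelope draws with CV
`amp_cv`; the hum envelope ramps linearly from 0.3 to 1.0 over the onset
fraction (the 0.3 starting level keeps early hum pulses above the 25%
detection threshold while still giving the characteristic gradual
amplitude rise). Each pulse is rendered as a Ricker (Mexican-hat)
wavelet whose positive peak falls exactly on the ground-truth pulse
time; the wavelet's negative side lobes fall inside the detector's
minimum peak separation, so rectified detection does not double-count
them. Pulse morphology is otherwise a free choice since only peak times
matter downstream. Hum durations are capped at 60 s — natural hums run
to hours, but nothing in the temporal analysis depends on desk-scale vs
hour-scale durations.

Bouts place calls sequentially with inter-grunt intervals (IGIs) defined
from the **last pulse of call n to the first pulse of call n+1** (an
onset-to-onset convention would differ by one call duration; the
last-to-first convention is used consistently in the generator and the
analysis, so recovery is exact). The `stable` profile draws IGIs i.i.d.
around the mean; the `rise_fall` profile modulates the mean IGI with a
triangular bump peaking mid-bout (±50% of the mean) plus optional
jitter, producing sequences whose first differences change sign exactly
once, + to −. The default bout size for grunt trains is 5–7 calls.

Noise is zero-mean Gaussian and white, calibrated so signal RMS over
noise RMS matches the requested SNR in dB. White noise is sufficient
because the 1 kHz lowpass at the head of the analysis chain whitens any
plausible noise colour differences at the pulse rates of interest. A
stimulus (injection) artifact is modelled as a single large-amplitude
sample at a known time.

CatFISH cell populations are bivariate Bernoulli: each cell is active in
period 1 with probability `p1` (cytoplasmic label) and in period 2 with
probability `overlap` conditional on period-1 activity, with the
period-2 marginal constrained to `p2` (nuclear label). The implied
reactivation index is `100·p1·overlap/p2` percent. Specs whose
parameters admit no valid joint distribution are rejected.

Every generator is a pure function of (spec, seed).

## Detection pipeline

The preprocessing order is fixed: lowpass → (optional rectification) →
moving average → normalisation → peak detection.

* **Lowpass**: 4th-order Butterworth at 1 kHz, applied forward-backward
  (`sosfiltfilt`) for zero phase, giving ≥ 20 dB attenuation one octave
  above the cutoff and no peak-time shift.
* **Smoothing**: centred boxcar, default 1 ms, rounded to an odd sample
  count so it is symmetric about each sample (an even window puts the
  smoothed peak between samples and detection then lands ±1 sample
  inconsistently). Edges use shrunken windows; the window must be well
  below the inter-pulse interval or adjacent pulses merge.
* **Normalisation**: division by the maximum absolute value of the
  analysed segment; idempotent; the 25% detection threshold is therefore
  an absolute 0.25 after normalisation, referenced to the segment being
  analysed (not per call).
* **Detection**: local maxima strictly above the threshold, with peaks
  closer than `min_separation` (default 2 ms) pruned keeping the larger
  — this suppresses ringing-induced doubles. Rectification (absolute
  value before smoothing) is intended for biphasic vocal-nerve volleys
  and off by default for hydrophone traces.

On noiseless synthetic input the detector recovers ground-truth pulse
counts exactly and peak times within half the smoothing window plus one
sample; at 20 dB SNR counts stay within ±2%.

Latency is the time from the stimulus marker to the first pulse strictly
after it; a pulse exactly at the marker is the artifact itself and is
excluded. When no pulse follows, `measure_latency` returns `None` rather
than a numeric sentinel.

## Call analysis

Calls are pulse groups separated by gaps above `max_intra_call_gap`
(default 150 ms: grunts last hundreds of ms with intra-call gaps of tens
of ms, while IGIs are larger, so the partition is insensitive to the
exact value; segmentation recovers generated bouts exactly whenever the
mean IGI exceeds three gap thresholds). Single-pulse groups are kept for
counting and rate analyses but excluded from features — only calls with
more than one pulse are featurised.

The six features: duration (last − first pulse time); CV of peak
amplitudes; mean PRR as the **arithmetic mean of instantaneous rates**
(this differs from pulse count over duration for variable trains and is
the convention used throughout); CV of PRR; percent change in amplitude
from the lowest to the highest peak; percent change in PRR from the
slowest to the fastest gap. Percent changes use the minimum as
denominator (relative increase from the low value); all CVs use the
sample (n−1) standard deviation. Amplitude features are computed on
detected peak amplitudes (the pipeline detects peaks, not envelopes) and
are scale-invariant, so trace renormalisation does not affect them.

Bout IGI profiles report mean and SD, with a trend label: `rise_fall`
iff the IGI first differences change sign exactly once from + to −
(checked first), `stable` iff the IGI CV is below 0.15, else `other`.
Because `rise_fall` takes precedence, a jittered flat bout whose noise
happens to rise then fall is labelled `rise_fall`; at the default jitter
(IGI CV 0.04) this affects roughly 10% of flat bouts, while true
rise-fall bouts are recognised essentially always. Call rates use 1-min
half-open bins by call onset, zero-filled.

The rule-based classifier is a deterministic cascade: grunt if duration
< 0.5 s; else growl if CV(PRR) or CV(amp) exceeds 0.1; else hum-like
when an onset-ramp flag is supplied, buzz-like otherwise. On
ground-truth features from well-separated specs it agrees with generator
labels ≥ 95%. Two caveats: the ramp flag is external (the features do
not encode onset shape), and a hum's onset ramp inflates its amplitude
CV — a detected hum classified without the flag can land in the growl
branch. The classifier is a labelling convenience, not a claim about
natural-call taxonomy.

## Embedding and statistics

The six features are z-scored per column (so seconds, Hz and percents
contribute comparably) and reduced to 2-D with UMAP (umap-learn;
n_neighbors 15, min_dist 0.1, Euclidean metric, fixed seed). The
embedding is reproducible from (table, parameters, seed); no claim is
made about any particular published panel geometry, whose embedding
package and hyperparameters are not public.

**Overlap score**: the fraction of group-a points with at least one
group-b point among their k = 10 nearest embedding neighbours (self
excluded); the symmetric version averages both directions. It is
invariant under rigid motions of the embedding and equals 1 for
coincident clouds, ~0 for clouds separated by much more than their
diameter. It is this package's quantitative surrogate for the visual
overlap assessment of embedding plots and is labelled as such in
outputs.

**Conventions**: features are log(1+x) transformed before model fits
(they are non-negative; the transform symmetrises right-skewed
durations and rates); CV is sample SD over mean; multiple contrasts are
Benjamini–Hochberg adjusted (hand-implemented step-up, verified against
the literal definition and statsmodels).

**Group contrasts**: each pairwise contrast fits a linear mixed model
(statsmodels MixedLM, REML) of the transformed feature with group as a
fixed effect and animal identity as a random intercept. The Wald
statistic is referred to a t distribution with **between-animal degrees
of freedom** (number of animals − 2): group is a between-animal factor,
and with 3–5 animals per group the asymptotic normal reference is
anticonservative (empirical type-I ≈ 0.14 at nominal 0.05 in
simulation); the df correction brings it to ≈ 0.04 while leaving power
for a 2× duration effect at 30 calls/group essentially at 1. Singular
or non-convergent fits fall back to a fixed-effect OLS contrast with a
warning — this happens legitimately when a feature carries no animal
variance (e.g. PRR in the generator, where the animal effect acts on
duration only).

The synthetic feature tables used for these harnesses assign calls
round-robin to animals, each carrying a lognormal multiplicative effect
(σ = 0.1) on call duration — enough between-animal variance to make the
random effect meaningful without swamping group effects.

## catFISH quantification

Counts are exact tallies of boolean label combinations per zone (PAGrs,
PAGcs, PAGcd, VPP, other). The reactivation index is
`100 · n_both / n_nuclear`: of the cells transcribing during the recent
second period (nuclear intronic signal), the percentage that also
carries the earlier-period cytoplasmic signal. When a zone has no
nuclear-labelled cells the index is undefined and propagates as NaN —
never 0 — and is excluded from group means with a logged count. Counts
from multiple sections of one animal are summed within the animal
before the index is computed; group summaries are mean ± SEM over
per-animal indices, never pooled cells. The denominators are therefore
per-animal by construction.

`recover_overlap` treats n_both as binomial in n_nuclear and reports
the Clopper–Pearson (exact) interval, whose per-population coverage is
guaranteed ≥ the nominal 95%; a 100-seed empirical coverage estimate
fluctuates a few points around the true ≈ 95.3% (e.g. 92–97), which is
sampling noise of the estimate, not under-coverage of the interval.

## What the synthetic data does and does not show

The generator reproduces the *temporal* statistics the pipeline
measures: pulse counts and rates, rate/amplitude variability, onset
ramps, bout IGI profiles, two-period activation overlap. It does not
reproduce hydrophone frequency content, reverberation, amplitude
nonstationarity beyond the onset ramp, inter-animal repertoire
differences, or any image-level property of catFISH material (cell
segmentation is upstream of this package; inputs are already-scored
cell tables). Passing tests therefore demonstrate that the pipeline
recovers known temporal ground truth under realistic noise — not that
it would be robust to artefacts absent from the generator (overlapping
callers, transient clipping, electrode drift).

## Numerical choices and problem sizes

Detection tolerances follow from the chain: zero-phase filtering and an
odd symmetric smoothing window bound peak-time error by half the window
plus one sample. Ties in BH adjustment are handled by the cumulative
minimum of the step-up formula; stable sorts make the adjustment
order-preserving. Degenerate inputs raise typed errors (all-zero trace,
empty call list, single-pulse features, zero-mean CV, inconsistent
catFISH joints) rather than returning silent sentinels, except where a
sentinel is the documented contract (latency `None`, index NaN).

Validation problem sizes — 6×20-pulse trains, 10 s hums over 20 seeds,
100-seed bout and coverage runs, 300-call embeddings, 50-run error-rate
simulations at 30 calls/group — were chosen as the smallest sizes at
which binomial/sampling error is well inside the property margins being
checked.
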