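# Methods

## Problem and outcome statistic

`gaitdtw` quantifies how much a patient's gait improves after knee
rehabilitation (typically total knee arthroplasty, TKA) from force-plate
recordings alone.  The vertical ground-reaction force (vGRF) of a
healthy stance phase traces a characteristic two-peak "M" curve —
heel strike, loading-response peak, mid-stance valley, push-off peak,
toe-off.  An impaired knee flattens the middle three phases.

Each recorded step is compared to a healthy-reference step with dynamic
time warping (DTW).  For sequences `r[1:n]` (reference) and `t[1:m]`
(measured), the accumulated cost matrix is

    F(0,0) = 0,  F(i,0) = F(0,j) = +inf  (i,j >= 1)
    F(k,l) = |r_k - t_l| + min[F(k-1,l), F(k,l-1), F(k-1,l-1)]

and the distance is `F(n,m)`.  DTW is used precisely because the
reference and the measured steps have different lengths (e.g. 1025 vs
1180 samples): monotone warping absorbs tempo differences while
amplitude and shape differences accumulate cost.  No warping window,
slope constraint or path-length normalization is applied; the recurrence
is the plain unconstrained one, and the optimal path is recovered by
backtracking (deterministic tie-break: diagonal, then the predecessor
reducing k, then the one reducing l).

Per subject, the before- and after-surgery conditions are each scored as
the **mean** DTW distance of their steps to the reference (each
condition is recorded several times; the aggregation is configurable to
the median).  Distances are then normalized to the before condition:

    error_before = 1 (by construction)
    error_after  = D_after / D_before
    improvement  = round(100 * (1 - error_after))   [percent]

Improvement is 100 for a perfect post-surgery match to the reference, 0
for no change, and negative if the subject worsened.  Rounding is to the
nearest integer percent, ties away from zero.

A note on DTW invariants: with this cost accumulation, *every* path step
adds its local cost, so duplicating a sample of one sequence only leaves
the distance unchanged when the duplicate can be matched at zero cost.
Hence `dtw(r, r-with-repeats) = 0` (which is what makes unequal lengths
comparable), but duplicating a poorly matching sample can increase the
distance (`dtw([0],[1]) = 1` vs `dtw([0],[1,1]) = 2`).  The test suite
asserts the former and documents the latter.

## Preprocessing

Raw plate files are delimited text (time in seconds, vertical force in
newtons).  The preparation protocol, all 0-based half-open intervals:

1. **Trim** — keep a `[start, end)` window of the recording, discarding
   low-quality ends.
2. **Gap removal** — unparseable/missing samples are carried as an
   explicit gap mask at read time.  Interior gap runs of at most
   `max_gap` samples (default 5) are filled by linear interpolation;
   longer or edge runs split the trace and the longest contiguous valid
   stretch is kept.  Gaps are never interpolated silently at read time.
3. **Step detection** — maximal runs where force exceeds
   `threshold_fraction` (default 5%) of the recording's peak, kept only
   if their duration lies in a physiological stance band
   (default 0.3–1.5 s).  The relative threshold makes segmentation
   invariant to uniform force rescaling; out-of-band contacts (double
   placements, clipped edge contacts) are rejected and logged.
4. **Amplitude normalization** — steps are expressed in units of body
   weight (BW) when the subject's body weight is known, making curves
   comparable across subjects of different mass (the reference usually
   comes from a different person).  Without a body weight the step is
   scaled to unit peak.  BW units are the default: peak normalization
   erases the amplitude component of an impairment (a flattened curve
   rescaled to unit peak looks deceptively healthy) and measurably
   compresses the before/after contrast.
5. **Smoothing** — an optional centered moving average (shrinking
   windows at the edges) is available for high-frequency sensor noise
   but is **off by default**; the intended noise handling is selecting
   clean movement windows, not filtering.

The healthy reference used by the `analyze` pipeline is passed through
the same step detector as the measured trials, so both sides are
truncated identically at the detection threshold.  Comparing truncated
steps against an untruncated reference would charge every subject a
constant edge-mismatch cost unrelated to gait quality.

## Synthetic vGRF generator

No public per-patient force data exist for this problem, so the package
ships a generator that emulates the study conditions with known ground
truth.

**Healthy stance.**  Three Gaussian bumps (width 12% of stance) whose
coefficients are solved, via a 3×3 linear system, so the curve passes
exactly through the canonical control points: loading-response peak
1.15 BW at 25% of stance, mid-stance valley 0.75 BW at 50%, push-off
peak 1.10 BW at 75%.  Fast smoothstep ramps (3% of stance) pin heel
strike and toe-off to exactly zero — heel strike loads quickly in real
gait, and the short ramp keeps threshold-detected contact edges within
±2 samples of the true window at the default 100 Hz.  Defaults: body
weight 700 N, stance 1.0 s, 100 Hz (so one step is 100 samples).

**Impairment.**  Each of the three middle phases carries an attenuation
in [0, 1].  Around an attenuated phase center the curve is blended
(Gaussian localization, same 12% width) toward a flat weight-support
plateau of 0.85 BW: a defective limb still bears load, but the peaks and
valley that characterize the phase dynamics flatten away.  Severity `s`
sets all three attenuations at once.  Zero impairment reproduces the
healthy curve bit-exactly, and the DTW distance to the healthy reference
is non-decreasing in severity (tested over {0, 0.1, …, 1} with noise
off).  An earlier candidate — multiplicative attenuation toward zero
force — was rejected as unphysical (it implies the stance foot unloads
completely, which also fragments threshold-based step detection).

**Acquisition chain.**  Trials concatenate stance curves separated by
1 s of zero-force baseline, then apply, in order: additive Gaussian
sensor noise (default SD 0.002 BW ≈ 1.4 N for a 700 N subject, i.e. a
few quantization steps — consistent with a laboratory plate specified at
0.3 N resolution), quantization to 0.3 N, and saturation at 3500 N
compression / −900 N tension.  Each trial draws from a single seeded
generator; before/after trials of one subject use independent streams
spawned deterministically from the subject seed.

**What the generator does not emulate:** left/right asymmetry beyond
independent severities, step-to-step biological variability (all steps
of a trial share one curve), drift/low-frequency artifacts, swing-phase
or kinematic signals, and double-support overlap across plates.  Passing
the synthetic end-to-end test therefore shows the pipeline recovers
known impairment contrasts under plate-realistic acquisition noise; it
does not validate against real patient variability.

## Bundled cohort dataset

`gaitdtw.datasets` bundles an 18-volunteer TKA cohort: per-volunteer
sex, age and BMI, and each volunteer's normalized after-surgery error.
Derived demographics reproduced by `cohort_stats.summarize`: mean age
68.0, sample SD 6.598 (n−1 denominator; the population SD 6.41 does not
match the conventionally reported 6.59), and — with the obesity cutoff
at BMI ≥ 28 kg/m² — 22% obese, of whom 75% are women.  Two
documented quirks:

* The obesity cutoff defaults to 28, not the WHO's 30: only BMI ≥ 28
  (4/18: BMIs 30, 29, 30.5, 28) reproduces the cohort's reported 22%
  obese and 75%-female obese subgroup.  The threshold is configurable.
* The per-volunteer rows contain 11 women and 7 men (61%/39%), although
  the cohort is conventionally described as 56%/44%; the two are
  arithmetically irreconcilable, and `summarize` reports what the rows
  contain.

The mean of the 18 improvement percentages is 93.56%; a sometimes-quoted
95.6% mean does not follow from the per-volunteer values, and this
package reports only the computed mean.

## Numerical and design choices

* Local DTW cost is the absolute difference (the signed form would let
  positive and negative deviations cancel along a path).
* `dtw()` retains the full (n+1)×(m+1) matrix and path;
  `dtw_distance()` is a two-row variant contractually returning the
  identical value (tested).  The brute-force oracle enumerates every
  monotone path explicitly and shares no code with the recurrence.
* Degenerate inputs: empty sequences, all-gap signals, zero-peak
  segments in peak mode, and a zero before-distance (normalization
  undefined) all raise `ValueError` rather than returning sentinels.
* Percentages round to the nearest integer, ties away from zero;
  truncation (not rounding) at 2 decimals is used where a truncated SD
  is conventional.
* Problem sizes in tests and the acceptance script: 100-sample steps,
  3 recordings per condition, 18 synthetic subjects — small enough for
  the exact O(nm) DTW in pure Python while preserving every contrast the
  pipeline must detect; the 1025/1010/1180-sample unequal-length check
  uses those exact lengths once.

## Known limitations

* Scoring is per-foot and per-step; no gait-line reconstruction, swing
  analysis, cadence or stride length.
* Only the vertical force channel is modelled; no 3-D forces, moments
  or center of pressure.
* Whether to score one step or a concatenation of steps is an open
  interpretation; this package scores per-step and averages.
* No inferential statistics across the cohort are computed — the
  demographics summary is descriptive only.
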