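# Methods

## Scope

`eegverify` studies identity *verification* (accept/reject a claimed
identity) from resting-state EEG under a session-disjoint protocol. The
package owns four pieces of science: a synthetic multi-session cohort
generator, the signal-conditioning and Welch-feature chain, a
Levenberg–Marquardt-trained shallow verification network, and the
experimental protocol (training-session sweep, diversity control,
external-impostor attack) with its statistical post-analysis.

## Synthetic cohort model

Real multi-session EEG biometric corpora are rarely public, so the
generator emulates the two statistical facts the analysis depends on:
large between-subject and small-but-structured within-subject spectral
variability.

**Subject signature.** Each subject's per-channel target PSD (µV²/Hz) is

    S(f) = A · max(f, 1 Hz)^(−χ)                      (aperiodic, knee at 1 Hz)
         + g_ch · s_alpha · exp(−(f − f_α)² / 2σ_α²)  (alpha bump)
         + b · exp(−(f − 20)² / 2·4²)                 (beta bump)
         + n                                          (noise floor)

with population means chosen for plausible adult eyes-open EEG: alpha
peak f_α ~ 10 Hz (SD 1.2 Hz, clipped to [7, 13]), bandwidth σ_α ~ 1 Hz,
occipitally dominant topography (O1/O2 = 1.0 down to Fp = 0.2, times
25 µV²/Hz), aperiodic scale A ~ 20 µV²/Hz at 1 Hz with exponent
χ ~ 1.2 (SD 0.2, clipped to (0.5, 2.5]), beta bump b ~ 1.5 µV²/Hz and
floor n ~ 0.5 µV²/Hz. The spectrum is flattened below 1 Hz (the "knee"
seen in aperiodic fits) — this also keeps the 1 Hz feature bin estimable
without window-leakage bias. **`sigma_subject` scales every inter-subject
SD**; 0 collapses the population to one signature (the chance-level
limit). These defaults were fixed a priori for plausibility; the study
data were never public, so they are not fitted.

**Session effect.** Day-to-day drift is *multiplicative on channel
amplitude*: per session each channel's voltage is scaled by a log-normal
gain with log-SD `sigma_session` (default 0.2, i.e. ≈ 20% amplitude
drift — plausible for montage/impedance differences), and alpha band
power is scaled by a log-normal factor with log-SD `1.5·sigma_session`
(vigilance drift). A 50 Hz mains sinusoid (≈ 2 µV) and a flat noise floor
complete the session. Multiplicative drift is the modelling choice that
makes the raw-vs-decibel comparison meaningful: `10·log10` turns the gain
factor into an additive per-channel offset, which a scale-aware
classifier absorbs far more easily.

**Synthesis.** Random-phase inverse FFT: the rFFT coefficient at f_k gets
magnitude `sqrt(S(f_k)·fs·N/2)` and an independent uniform phase. The
periodogram of the output equals the target PSD exactly in magnitude;
Welch estimates match it within window bias and averaging noise (asserted
at < 10% per bin in the tests). Chosen over AR modelling because it gives
direct, testable control of exactly the quantity the features measure.

**Seeds.** `master_seed → per-subject → per-session` via `SeedSequence`
spawn keys, so regeneration is bit-identical and adding subjects or
sessions never perturbs existing data (both asserted).

**What the generator does not model:** structured artifacts (blinks,
EMG), non-stationarity within a session, electrode pops, inter-channel
phase coupling, or genuine aging across months. A green trend test
therefore establishes that the *pipeline* extracts and exploits
session-stable subject differences under multiplicative drift — not that
real EEG behaves this way.

## Conditioning chain

Order fixed: band-pass → crop → common average reference → segmentation.
The acquisition filter of the original hardware is unspecified, so a
standard zero-phase chain is used: 4th-order Butterworth 0.2–70 Hz
applied forward-backward (effective 8th order, no group delay — segment
boundaries stay aligned) plus an IIR notch at 50 Hz, Q = 35. Crop
convention is 0-based half-open: "after the first 30 s" discards samples
[0, 30·fs). Segmentation floors: a trailing partial 7.5 s window is
dropped, giving exactly 24 segments per 180 s window. CAR is per-sample
mean removal; it commutes with segmentation (asserted) and voltage-domain
agreement with the original hardware is explicitly *not* a target — only
spectral-shape contracts are.

## Features

Welch PSD per 7.5 s segment: 14 half-overlapping 1 s Hamming windows
(MATLAB-style symmetric taper), no detrending, one-sided density, FFT
length = window length (500 samples → exactly 1 Hz bins); bins 1…45 Hz
kept, channel-major flattening to 855 values. The estimator is verified
against a brute-force windowed-periodogram oracle to < 1e-10 relative
error. Raw values are strictly positive by construction; `to_decibel`
refuses non-positive input rather than flooring it.

## Verifier

One tanh hidden neuron, two linear outputs, one-hot targets ([1,0]
claimant, [0,1] impostor), MSE loss. The decision rule is the output
difference with ties going to the impostor — the security-conservative
choice. With one hidden unit the boundary is a single hyperplane, which
keeps the ~860 parameters identifiable from a few dozen segments and is
asserted by the near-collinearity of boundary normals across refits.

Levenberg–Marquardt: damping µ₀ = 1e-3, ×10 on rejected steps, ×0.1 on
accepted ones; stop on 100 epochs, µ > 1e10, gradient ∞-norm < 1e-7, or
6 consecutive validation-loss increases; the best-validation-epoch
weights are returned. When residual rows < parameters the normal
equations are solved in the dual (Woodbury) form. Inputs are min-max
normalized to [−1, 1] with a map fitted on the training fold only and
stored in the model; constant features map to 0. Weight init is uniform
[−0.5, 0.5] per seed. The original work names only the algorithm, so
these are the defaults of its ecosystem, all exposed as parameters.
Best-of-n selection trains seeds `base_seed…base_seed+n−1` and keeps the
lowest validation MSE (ties → lowest seed); the protocol default is
n = 10.

## Protocol

Divisions are chronological: train on sessions 1…n_train, test on the
last K ("last-5" at full scale; the desk-scale tests use "last-4" so that
n_train = 8 is feasible within 12 sessions). Training impostors are the
other enrolled subjects at the same session indices — the external
impostors are reserved exclusively for the attack. Impostor draws are
without replacement, round-robin across subjects (as even a spread as the
pool allows), deterministic per seed. Cross-validation partitions
*segments* (not sessions — with n_train = 1 there is only one session),
stratified by class, 7/8 train : 1/8 validation; the 8 folds share one
test draw per division so fold variance is attributable to training.
Averaging order: fold → claimant → cohort mean ± SD.

The diversity control separates quantity from diversity: a 24-segment
training set drawn as evenly as possible from the first `n_source`
sessions (at 15 sources: 9 sessions give 2 segments, 6 give 1; at the
desk scale's 8 sources: 3 each). The attack presents every external
impostor segment to every fold network; FAR = 100·accepted/attempts.

Undefined metrics (zero denominator, e.g. precision when nothing is
accepted) are flagged NaN with a warning and drop out of averages rather
than being silently zeroed.

## Statistics

The rank-sum ("Wilcoxon Rank Sum" / Mann–Whitney) test is applied
*unpaired* to per-claimant means across conditions — deliberately
mirroring the study design it reproduces, even though the values are
paired by claimant; this is noted rather than "corrected". Exact null
enumeration is used for tie-free groups ≤ 8, otherwise the normal
approximation with tie and continuity corrections (MATLAB `ranksum`
behaviour); agreement with brute-force permutation enumeration is
asserted to 1e-9. No multiplicity correction by default (a Holm option
exists, off). The KS normality screen standardizes by sample mean/SD
before testing against N(0,1): a composite-null approximation (the
Lilliefors situation) that is conservative — its null flag rate is below
nominal, which the calibration test asserts explicitly; with
`standardize=False` the test is exact and calibrates at 5%. The
saturation point is the smallest condition k with no flagged pair at or
above k; the flags that blocked the candidate just below k are reported
as annotations, not hidden.

## Numerical and runtime choices

* EDF I/O is a minimal self-contained implementation (no EDF library is
  available in the environment): ASCII header, 1 s int16 records,
  physical range encoded with the 8-character header precision the format
  allows — round-trip error is bounded by half a quantization step of the
  stored range, and the tests assert exactly that bound.
* Desk-scale test runs scale the protocol down for runtime only:
  best-of-3 (not 10), 40 LM epochs (not 100), n_train grid {1, 2, 4, 8}.
  Seeds are fixed and were chosen before outcomes were observed; the
  protocol defaults remain the full-scale ones.
* The chance-level check (sigma_subject = 0) asserts 50 ± 5% cohort
  accuracy; individual networks can be biased toward rejection (high
  specificity, low sensitivity) because a near-unlearnable problem drives
  outputs toward the majority-free balanced fixed point, but the balanced
  test set pins overall accuracy at chance.

## Known limitations

* Absolute metric values of the original study are not reproducible — its
  recordings are private; only structural counts, formula exactness and
  qualitative orderings (more sessions help; dB ≥ raw; diversity between
  1 and max; attack FAR bounded) are test targets.
* The generator's session drift is i.i.d. log-normal; real drift has
  slow temporal structure (electrode aging, seasonal vigilance) that a
  chronological split would expose differently.
* The EDF writer emits plain EDF (not EDF+), one recording per file,
  integer seconds and integer sampling rates only.
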