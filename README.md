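# eegverify

Session-disjoint EEG biometric verification: how many distinct recording
days does a spectral verifier need?

## The problem

Resting-state EEG carries stable individual traits — most prominently the
individual alpha peak and its occipital topography — which makes it a
candidate biometric. But EEG also drifts from day to day: electrode
montage, impedance and vigilance shift the measured power spectrum between
sessions, so a verifier trained and tested on the *same* recording session
badly overestimates its real accuracy. The honest question is
session-disjoint: train on the earliest sessions, test on strictly later
ones, and ask how verification accuracy, sensitivity, specificity,
precision and the impostor False Acceptance Rate (FAR) depend on the
number of distinct training sessions.

`eegverify` implements that study as a tested pipeline, with a synthetic
cohort generator standing in for the (non-public) multi-session
recordings. It is a library: import it from Python, or run the short
narrative scripts in `examples/`.

## The method

For each 19-channel (10–20 montage, 500 Hz) recording:

1. **Conditioning** — 0.2–70 Hz band-pass + 50 Hz notch (zero phase), crop
   to 3 minutes after the first 30 s, common average reference
   `x[i,ch] ← x[i,ch] − (1/CH) Σ_ch x[i,ch]`, and 7.5 s segmentation
   (24 segments per session).
2. **Features** — Welch PSD per segment (1 s Hamming windows, 0.5 s
   overlap) at the integer frequencies 1…45 Hz for each channel:
   an 855-vector, either raw (µV²/Hz) or decibel, `P_dB = 10·log10 P`.
3. **Verifier** — per claimant, a feed-forward network with one tanh
   hidden neuron and two linear outputs (claimant, impostor), trained by
   Levenberg–Marquardt to one-hot targets under MSE; ten networks are
   trained per fold and the best validation one kept. Decision: accept iff
   `out_claimant − out_impostor > 0`.
4. **Protocol** — training impostor segments come from the *other*
   enrolled subjects, matched 1:1; 8-fold stratified cross-validation
   within the training sessions; evaluation on the held-out final
   sessions; metrics `ACC = (TP+TN)/total`, `SEN = TP/(TP+FN)`,
   `SPEC = TN/(TN+FP)`, `PREC = TP/(TP+FP)`. External single-session
   impostors, never used in training, attack every trained network:
   `FAR = 100·accepted/attempts`.
5. **Statistics** — per-condition KS normality screen, pairwise Wilcoxon
   rank-sum matrix over numbers of training sessions, and the saturation
   point beyond which more sessions no longer help.

The synthetic cohort (`CohortConfig`, `generate_cohort`) gives every
subject a stable spectral signature (alpha peak frequency/bandwidth/
topography, 1/f exponent and scale, beta bump) and every session a
multiplicative log-normal channel-gain drift plus alpha band-power drift —
exactly the covariance-shift structure that makes the session count and
the dB conversion matter. Signals are synthesized by random-phase inverse
FFT from the analytic target PSD, so the realized spectrum is testable
against its target. Default geometry mirrors the full study (29 genuine
subjects × 20 sessions + 23 single-session impostors); everything is
configurable and bit-reproducible from one master seed.

## Worked example

```python
import eegverify as ev

cfg = ev.CohortConfig(n_genuine=4, n_sessions=6, n_impostors=0, master_seed=4)
cohort = ev.generate_cohort(cfg)
store = ev.assemble_features(cohort, scale="dB")
sweep = ev.session_sweep(cohort, store, [1, 2, 4], "last-2",
                         folds=8, n_best=3, seed=8, max_epochs=40)
print(sweep.summary[["n_train", "acc_mean", "acc_std"]])
```

prints (`python examples/04_session_sweep.py`, dB block):

```
dB features (cohort mean +/- SD over 4 claimants):
  1 training session(s): ACC 58.8 +/- 19.7%   SEN 44.3%   SPEC 73.2%
  2 training session(s): ACC 59.9 +/- 14.9%   SEN 45.3%   SPEC 74.5%
  4 training session(s): ACC 82.0 +/- 9.0%   SEN 77.9%   SPEC 86.1%
```

Each row evaluates the *same* held-out final sessions; accuracy rises with
the number of training sessions because only then does the verifier see
the day-to-day drift it must become invariant to, and sensitivity (the
rate at which the genuine claimant is accepted on a new day) is the
metric that suffers most with few sessions. The dB-vs-raw advantage and
the significance of the session trend are asserted at cohort scale in the
test suite. `examples/05_impostor_attack.py` adds the external-impostor
FAR, and `examples/06_stats_compare.py` the rank-sum comparison matrix
with its saturation point.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch: full-scale design
bookkeeping (recording/segment/attack-attempt counts), then a seeded small
cohort through synthesis → conditioning → features (raw and dB) →
session-sweep with 8-fold cross-validated verifiers → external impostor
attack, printing the cohort summaries and writing the results JSON to
`--out`.
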