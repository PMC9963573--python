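"""Train one claimant's verification network and test it session-disjointly.

A 1-hidden-neuron tanh network with two linear outputs is trained with
Levenberg-Marquardt on segments of the claimant's first sessions (plus an
equal impostor draw from the other subjects), then evaluated on the
claimant's *later* sessions - the session-disjoint protocol that prevents
day-specific leakage.
"""

import numpy as np

import eegverify as ev

cfg = ev.CohortConfig(n_genuine=4, n_sessions=4, n_impostors=0,
                      master_seed=3)
cohort = ev.generate_cohort(cfg)
store = ev.assemble_features(cohort, scale="dB")

division = ev.build_division("sub01", n_train=2, test_spec="last-2",
                             manifest=cohort, seed=5)
print(f"claimant sub01: train on sessions {division.train_sessions}, "
      f"test on sessions {division.test_sessions}")

cv = ev.crossvalidate_claimant(division, store, folds=8, n_best=3,
                               max_epochs=40)
for r in cv.results[:3]:
    c = r.counts
    print(f"  fold {r.fold}: TP={c.TP} TN={c.TN} FP={c.FP} FN={c.FN} "
          f"-> ACC {r.acc:.1f}%  SEN {r.sen:.1f}%  SPEC {r.spec:.1f}%")
mean_acc = np.mean([r.acc for r in cv.results])
print(f"fold-averaged accuracy: {mean_acc:.1f}% - the fraction of held-out"
      " genuine and impostor segments classified correctly on unseen days")

net = cv.networks[0]
print(f"network: {net.input_dim} inputs -> {net.hidden_units} tanh unit -> "
      f"2 linear outputs; selected validation MSE "
      f"{net.training_meta['final_validation_loss']:.2e}")
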