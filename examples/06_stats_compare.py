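"""Compare conditions statistically: KS screen, rank-sum matrix, saturation.

Per-claimant mean accuracies for each number of training sessions are
screened for normality (one-sample KS on standardized values) and compared
pairwise with the Wilcoxon rank-sum test; the saturation point is the
smallest session count beyond which no larger count differs significantly.
"""

import numpy as np
import pandas as pd

import eegverify as ev

# per-claimant mean accuracies for 4 conditions; a synthetic sweep result
# shaped like the real per-claimant table (claimants x n_train)
rng = np.random.default_rng(0)
n_claimants = 29
conditions = {1: 79.0, 2: 86.0, 4: 92.0, 8: 93.0}  # saturating trend
acc = pd.DataFrame({k: np.clip(rng.normal(mu, 5.0, n_claimants), 0, 100)
                    for k, mu in conditions.items()})

print("KS normality screen (p-values; high = no evidence against "
      "normality):")
for k in acc.columns:
    print(f"  {k} training session(s): p = "
          f"{ev.ks_normality(acc[k].to_numpy()):.3f}")

matrix = ev.pairwise_wilcoxon(acc)
print("\npairwise rank-sum p-values (upper triangle):")
print(matrix.p_values.round(4).to_string())

k, exceptions = ev.saturation_point(matrix)
print(f"\nsaturation point: {k} training sessions "
      f"(no significant difference among conditions >= {k}; "
      f"exceptions: {exceptions or 'none'})")
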