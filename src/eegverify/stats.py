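"""Statistical post-analysis of the sweep results.

Two steps, mirroring common practice in EEG biometrics papers: first a
one-sample Kolmogorov-Smirnov screen of the per-claimant mean accuracies
for each condition (number of training sessions), then a pairwise
Wilcoxon rank-sum (Mann-Whitney) comparison matrix across conditions, with
no multiple-comparison correction by default (a Holm option is provided).

A note on the KS screen: the sample is standardized (centered, scaled by
its own SD) before testing against N(0, 1). Estimating the parameters
from the sample makes the test conservative — the classic Lilliefors
situation — so its p-values understate non-normality; it is a screening
device, not a calibrated size-alpha test. Set ``standardize=False`` to test
against a fully specified standard normal, where the size is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .recording import ConfigurationError, DataError

__all__ = ["ComparisonMatrix", "ks_normality", "pairwise_wilcoxon",
           "saturation_point"]


@dataclass
class ComparisonMatrix:
    """Upper-triangular matrix of pairwise p-values over conditions."""

    condition_labels: tuple[int, ...]
    p_values: pd.DataFrame  # upper triangle filled, rest NaN
    alpha: float = 0.05

    @property
    def flags(self) -> pd.DataFrame:
        """Boolean upper-triangular matrix of significant pairs."""
        return self.p_values < self.alpha

    def flagged_pairs(self) -> list[tuple[int, int]]:
        f = self.flags
        return [(i, j) for i in f.index for j in f.columns
                if bool(f.loc[i, j])]

    def to_csv(self, path) -> None:
        self.p_values.to_csv(path)


def ks_normality(sample: np.ndarray, standardize: bool = True) -> float:
    """One-sample Kolmogorov-Smirnov p-value against the standard normal.

    With ``standardize`` (default) the sample is first centered and scaled
    by its own SD, matching the usual screening usage (conservative; see
    module docstring). A zero-variance sample is an error.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise DataError("need at least 5 values for the KS screen")
    if standardize:
        sd = x.std(ddof=1)
        if sd == 0:
            raise DataError("degenerate (zero-variance) sample")
        x = (x - x.mean()) / sd
    return float(sps.kstest(x, "norm").pvalue)


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null enumeration for tie-free groups of <= 8 each, otherwise the
    normal approximation with tie and continuity corrections (the behaviour
    of MATLAB's ``ranksum``).
    """
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and max(len(a), len(b)) <= 8) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def pairwise_wilcoxon(results: pd.DataFrame, alpha: float = 0.05,
                      holm: bool = False) -> ComparisonMatrix:
    """Pairwise rank-sum comparison of all condition columns.

    ``results`` holds one row per claimant and one column per condition
    (e.g. per number of training sessions); every condition must cover the
    same claimants. No multiplicity correction unless ``holm=True``.
    """
    if results.shape[1] < 2:
        raise ConfigurationError("need at least two conditions to compare")
    if results.shape[0] < 5:
        raise DataError("need at least 5 claimants per condition")
    if results.isna().any().any():
        raise DataError("conditions cover unequal claimant sets (NaNs found)")
    labels = tuple(int(c) for c in results.columns)
    n = len(labels)
    p = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            p[i, j] = _ranksum_p(results.iloc[:, i].to_numpy(),
                                 results.iloc[:, j].to_numpy())
    if holm:
        iu = np.triu_indices(n, k=1)
        raw = p[iu]
        order = np.argsort(raw)
        m = len(raw)
        adj = np.empty(m)
        running = 0.0
        for rank, k in enumerate(order):
            running = max(running, (m - rank) * raw[k])
            adj[k] = min(1.0, running)
        p[iu] = adj
    mat = pd.DataFrame(p, index=labels, columns=labels)
    return ComparisonMatrix(condition_labels=labels, p_values=mat,
                            alpha=alpha)


def saturation_point(matrix: ComparisonMatrix) -> tuple[int, list[tuple[int, int]]]:
    """Smallest condition beyond which no larger condition differs.

    Returns ``(k, exceptions)`` where ``k`` is the smallest label such that
    no pair ``(i, j)`` with both labels ``>= k`` is flagged. ``exceptions``
    reports any flagged pairs at or above the *next smaller* candidate, so
    borderline patterns are annotated rather than hidden. With no flags at
    all the smallest label is returned; with every pair flagged, the
    largest.
    """
    labels = sorted(matrix.condition_labels)
    flagged = matrix.flagged_pairs()

    def blocked(c: int) -> list[tuple[int, int]]:
        return [(i, j) for i, j in flagged if i >= c and j >= c]

    k = labels[-1]
    prev = None
    for cand in labels:
        if not blocked(cand):
            k = cand
            break
        prev = cand
    exceptions = blocked(prev) if prev is not None else []
    return k, exceptions
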