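"""The study's experimental machinery.

Everything here enforces *session-disjoint* evaluation: a claimant's
verifier is trained on segments from their earliest sessions and tested
only on segments from strictly later sessions, so day-to-day covariance
shifts cannot leak from test into training. The central experiment sweeps
the number of distinct training sessions and measures accuracy,
sensitivity, specificity and precision on the held-out final sessions;
the attack experiment presents every segment of external single-session
impostors to every trained network and reports the False Acceptance Rate.

Conventions (fixed throughout):

* training impostors are the *other genuine subjects* (the external
  impostors are reserved for the attack and never touch training);
* every training fold and every test evaluation is balanced — impostor
  segments are drawn without replacement, round-robin across impostor
  subjects, to match the claimant segment count exactly;
* 8-fold cross-validation partitions the training *segments* (stratified
  by class); the 8 folds share one test set drawn per division, so fold
  variance is attributable to training;
* averaging order: metrics per fold -> mean per claimant -> mean +/- SD
  across claimants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import Cohort, CohortConfig, _iter_cohort_entries
from .features import FeatureStore, welch_psd
from .preprocess import KEEP_S, SEGMENT_S, SKIP_S, crop_analysis_window, segmentize
from .recording import (CHANNELS_1020, ConfigurationError, DataError,
                        N_CHANNELS, Recording)
from .verifier import VerifierNetwork, best_of_n, predict

__all__ = [
    "DataDivision", "ConfusionCounts", "EvalResult", "AttackSummary",
    "SweepResult", "build_division", "stratified_impostor_sample",
    "compute_metrics", "crossvalidate_claimant", "session_sweep",
    "diversity_control", "simulate_attack", "design_counts",
]

METRIC_NAMES = ("acc", "sen", "spec", "prec")


@dataclass(frozen=True)
class DataDivision:
    """One claimant's session-disjoint train/test split with impostor pools."""

    claimant_id: str
    train_sessions: tuple[int, ...]
    test_sessions: tuple[int, ...]
    impostor_train_pool: tuple[tuple[str, int], ...]
    impostor_test_pool: tuple[tuple[str, int], ...]
    rng_seed: int

    def __post_init__(self) -> None:
        train, test = set(self.train_sessions), set(self.test_sessions)
        if train & test:
            raise ConfigurationError("train and test sessions overlap")
        if train and test and max(train) >= min(test):
            raise ConfigurationError("test sessions must be strictly later "
                                     "than all train sessions")
        for pool in (self.impostor_train_pool, self.impostor_test_pool):
            if any(sid == self.claimant_id for sid, _ in pool):
                raise ConfigurationError(
                    "claimant's own sessions found in an impostor pool")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class EvalResult:
    """Metrics of one (claimant, fold, condition) evaluation, in percent."""

    claimant_id: str
    n_train_sessions: int
    fold: int
    scale: str
    counts: ConfusionCounts
    acc: float
    sen: float
    spec: float
    prec: float

    def as_row(self) -> dict:
        c = self.counts
        return {
            "claimant": self.claimant_id,
            "n_train": self.n_train_sessions,
            "fold": self.fold,
            "scale": self.scale,
            "TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN,
            "acc": self.acc, "sen": self.sen, "spec": self.spec,
            "prec": self.prec,
        }


@dataclass(frozen=True)
class AttackSummary:
    """External-impostor attack outcome for one claimant and condition."""

    claimant_id: str
    n_train_sessions: int
    attempts: int
    accepted: int

    @property
    def far(self) -> float:
        return 100.0 * self.accepted / self.attempts


def _genuine_sessions(manifest: list[dict]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for e in manifest:
        if e["role"] == "genuine":
            out.setdefault(e["subject_id"], []).append(e["session_index"])
    return {k: sorted(v) for k, v in out.items()}


def _parse_test_spec(test_spec: str | int) -> int:
    if isinstance(test_spec, int):
        return test_spec
    if isinstance(test_spec, str) and test_spec.startswith("last-"):
        return int(test_spec.split("-", 1)[1])
    raise ConfigurationError(f"unrecognized test_spec {test_spec!r}")


def build_division(claimant: str, n_train: int, test_spec: str | int,
                   manifest: "list[dict] | Cohort", seed: int = 0) -> DataDivision:
    """Chronological division: train on sessions ``1..n_train``, test on the
    last ``K`` sessions (``test_spec`` = ``"last-K"``).

    Impostor pools are the same session indices of all *other* genuine
    subjects; external (single-session) impostors are never included.
    """
    entries = manifest.manifest if isinstance(manifest, Cohort) else manifest
    sessions = _genuine_sessions(entries)
    if claimant not in sessions:
        raise ConfigurationError(f"unknown genuine subject {claimant!r}")
    ordered = sessions[claimant]
    n_test = _parse_test_spec(test_spec)
    if n_train < 1 or n_train + n_test > len(ordered):
        raise ConfigurationError(
            f"{claimant}: n_train={n_train} + test={n_test} exceeds the "
            f"{len(ordered)} available sessions"
        )
    train = tuple(ordered[:n_train])
    test = tuple(ordered[-n_test:])
    others = [s for s in sessions if s != claimant]
    train_pool = tuple((s, sess) for s in others for sess in train
                       if sess in sessions[s])
    test_pool = tuple((s, sess) for s in others for sess in test
                      if sess in sessions[s])
    return DataDivision(
        claimant_id=claimant, train_sessions=train, test_sessions=test,
        impostor_train_pool=train_pool, impostor_test_pool=test_pool,
        rng_seed=int(seed),
    )


def stratified_impostor_sample(division: DataDivision, n_needed: int,
                               pool: str, store: FeatureStore,
                               seed: int = 0) -> list[tuple[str, int, int]]:
    """Draw ``n_needed`` impostor segment ids without replacement, spread
    round-robin across impostor subjects (random order and random
    within-subject order, deterministic per seed)."""
    if pool not in ("train", "test"):
        raise ConfigurationError("pool must be 'train' or 'test'")
    sessions = (division.impostor_train_pool if pool == "train"
                else division.impostor_test_pool)
    rng = np.random.default_rng(seed)
    by_subject: dict[str, list[tuple[str, int, int]]] = {}
    for sid, sess in sessions:
        try:
            rows = store.df.xs((sid, sess), level=("subject", "session"),
                               drop_level=False)
        except KeyError:
            continue
        ids = [(i[0], i[1], i[2]) for i in rows.index]
        by_subject.setdefault(sid, []).extend(ids)
    total = sum(len(v) for v in by_subject.values())
    if total < n_needed:
        raise DataError(
            f"impostor {pool} pool has {total} segments, need {n_needed} "
            f"(shortfall {n_needed - total})"
        )
    subjects = sorted(by_subject)
    rng.shuffle(subjects)
    queues = {s: [by_subject[s][i] for i in rng.permutation(len(by_subject[s]))]
              for s in subjects}
    chosen: list[tuple[str, int, int]] = []
    while len(chosen) < n_needed:
        progressed = False
        for s in subjects:
            if queues[s]:
                chosen.append(queues[s].pop())
                progressed = True
                if len(chosen) == n_needed:
                    break
        if not progressed:  # pragma: no cover - guarded by the total check
            break
    return chosen


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision in percent.

    A zero denominator flags the metric as undefined (NaN) with a warning;
    downstream averages use ``nanmean`` so undefined values drop out.
    """
    out: dict[str, float] = {}
    pairs = {
        "acc": (counts.TP + counts.TN, counts.total),
        "sen": (counts.TP, counts.TP + counts.FN),
        "spec": (counts.TN, counts.TN + counts.FP),
        "prec": (counts.TP, counts.TP + counts.FP),
    }
    for name, (num, den) in pairs.items():
        if den == 0:
            warnings.warn(f"metric {name} undefined (zero denominator)",
                          RuntimeWarning, stacklevel=2)
            out[name] = float("nan")
        else:
            out[name] = 100.0 * num / den
    return out


def _ids_and_values(df: pd.DataFrame) -> tuple[list[tuple], np.ndarray]:
    return [tuple(i) for i in df.index], df.to_numpy()


@dataclass
class ClaimantCV:
    """Per-fold results and networks of one claimant's cross-validation."""

    division: DataDivision
    results: list[EvalResult]
    networks: list[VerifierNetwork]


def _evaluate(net: VerifierNetwork, X_pos: np.ndarray,
              X_neg: np.ndarray) -> ConfusionCounts:
    dec_pos, _ = predict(net, X_pos)
    dec_neg, _ = predict(net, X_neg)
    return ConfusionCounts(
        TP=int(np.sum(dec_pos)), FN=int(np.sum(~dec_pos)),
        FP=int(np.sum(dec_neg)), TN=int(np.sum(~dec_neg)),
    )


def crossvalidate_claimant(division: DataDivision, store: FeatureStore,
                           folds: int = 8, n_best: int = 10,
                           seed: int | None = None,
                           train_override: pd.DataFrame | None = None,
                           **lm_kwargs) -> ClaimantCV:
    """Stratified k-fold cross-validation of one claimant's verifier.

    Claimant training segments (all segments of the training sessions, or
    ``train_override`` rows) are matched 1:1 with impostor segments drawn
    from the training pool; the combined set is split into ``folds``
    stratified folds. Each fold trains a best-of-``n_best`` network on 7/8
    of the data with 1/8 as validation, then evaluates on the shared test
    set: all claimant test-session segments as positives plus an equal
    stratified impostor draw as negatives.
    """
    seed = division.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    s_train, s_test, s_fold, s_net = rng.integers(2 ** 31, size=4)

    if train_override is not None:
        train_df = train_override
    else:
        train_df = store.select(division.claimant_id,
                                list(division.train_sessions))
    n_pos = len(train_df)
    if n_pos < folds:
        raise DataError(f"{n_pos} claimant training segments cannot fill "
                        f"{folds} folds")
    imp_train_ids = stratified_impostor_sample(division, n_pos, "train",
                                               store, seed=int(s_train))
    X_pos_train = train_df.to_numpy()
    X_neg_train = store.df.loc[imp_train_ids].to_numpy()
    X = np.vstack([X_pos_train, X_neg_train])
    y = np.concatenate([np.ones(n_pos, bool), np.zeros(n_pos, bool)])

    test_df = store.select(division.claimant_id, list(division.test_sessions))
    imp_test_ids = stratified_impostor_sample(division, len(test_df), "test",
                                              store, seed=int(s_test))
    X_pos_test = test_df.to_numpy()
    X_neg_test = store.df.loc[imp_test_ids].to_numpy()

    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(s_fold % (2 ** 32 - 1)))
    results: list[EvalResult] = []
    networks: list[VerifierNetwork] = []
    for fold, (tr_idx, va_idx) in enumerate(skf.split(X, y), start=1):
        net = best_of_n(X[tr_idx], y[tr_idx], X[va_idx], y[va_idx],
                        n=n_best, base_seed=int(s_net) + fold * n_best,
                        **lm_kwargs)
        counts = _evaluate(net, X_pos_test, X_neg_test)
        m = compute_metrics(counts)
        results.append(EvalResult(
            claimant_id=division.claimant_id,
            n_train_sessions=len(division.train_sessions),
            fold=fold, scale=store.scale, counts=counts, **m,
        ))
        networks.append(net)
    return ClaimantCV(division=division, results=results, networks=networks)


@dataclass
class SweepResult:
    """Tidy per-fold results plus cohort summaries of a training-session sweep."""

    per_fold: pd.DataFrame  # one row per claimant x n_train x fold
    per_claimant: pd.DataFrame  # fold-averaged metrics
    summary: pd.DataFrame  # cohort mean +/- SD per n_train
    networks: dict[tuple[str, int], list[VerifierNetwork]] = field(
        default_factory=dict)

    @property
    def scale(self) -> str:
        return str(self.per_fold["scale"].iloc[0])


def _summarize(per_fold: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    per_claimant = (per_fold
                    .groupby(["claimant", "n_train"], as_index=False)
                    [list(METRIC_NAMES)].mean())
    agg = per_claimant.groupby("n_train")[list(METRIC_NAMES)].agg(
        ["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return per_claimant, agg.reset_index()


def session_sweep(cohort: Cohort, store: FeatureStore,
                  n_train_range: list[int], test_spec: str | int,
                  folds: int = 8, n_best: int = 10, seed: int = 0,
                  keep_networks: bool = False, **lm_kwargs) -> SweepResult:
    """The central experiment: vary the number of distinct training sessions.

    For every claimant and every ``n_train`` builds the chronological
    division, cross-validates, and averages metrics over folds; the cohort
    summary reports mean +/- SD across claimants per ``n_train``.
    """
    rows: list[dict] = []
    networks: dict[tuple[str, int], list[VerifierNetwork]] = {}
    claimants = cohort.genuine_ids
    for ci, claimant in enumerate(claimants):
        for n_train in n_train_range:
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(ci, n_train))
            div_seed = int(ss.generate_state(1)[0] % (2 ** 31))
            division = build_division(claimant, n_train, test_spec,
                                      cohort, seed=div_seed)
            cv = crossvalidate_claimant(division, store, folds=folds,
                                        n_best=n_best, **lm_kwargs)
            rows.extend(r.as_row() for r in cv.results)
            if keep_networks:
                networks[(claimant, n_train)] = cv.networks
    per_fold = pd.DataFrame(rows)
    per_claimant, summary = _summarize(per_fold)
    return SweepResult(per_fold=per_fold, per_claimant=per_claimant,
                       summary=summary, networks=networks)


def _spread_counts(target: int, n_sources: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Split ``target`` into ``n_sources`` parts of floor or floor+1, the
    +1 sessions chosen at random. 24 over 15 sources gives the 9x2 + 6x1
    pattern; every source contributes at least floor(target/n) >= 1."""
    if target < n_sources:
        raise ConfigurationError("target_size must cover every source session")
    base = target // n_sources
    counts = np.full(n_sources, base, dtype=int)
    extra = rng.choice(n_sources, size=target - base * n_sources,
                       replace=False)
    counts[extra] += 1
    return counts


def diversity_control(cohort: Cohort, store: FeatureStore,
                      n_source_sessions: int = 15, target_size: int = 24,
                      test_spec: str | int = "last-5", folds: int = 8,
                      n_best: int = 10, seed: int = 0,
                      **lm_kwargs) -> SweepResult:
    """Single-session-sized training set drawn from many sessions.

    Separates data *quantity* from data *diversity*: the training set has
    the size of one session (24 segments) but draws one-to-two segments
    (at 15 source sessions) from each of the first ``n_source_sessions``
    sessions. Everything else matches :func:`session_sweep`.
    """
    rows: list[dict] = []
    for ci, claimant in enumerate(cohort.genuine_ids):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(ci, 77))
        rng = np.random.default_rng(ss)
        division = build_division(claimant, n_source_sessions, test_spec,
                                  cohort,
                                  seed=int(ss.generate_state(1)[0] % 2 ** 31))
        counts = _spread_counts(target_size, n_source_sessions, rng)
        picked: list[pd.DataFrame] = []
        for sess, k in zip(division.train_sessions, counts):
            seg_df = store.select(claimant, [sess])
            idx = rng.choice(len(seg_df), size=int(k), replace=False)
            picked.append(seg_df.iloc[np.sort(idx)])
        train_df = pd.concat(picked)
        cv = crossvalidate_claimant(division, store, folds=folds,
                                    n_best=n_best, train_override=train_df,
                                    **lm_kwargs)
        rows.extend(r.as_row() for r in cv.results)
    per_fold = pd.DataFrame(rows)
    per_fold["n_train"] = 0  # marker: diversity-control condition
    per_claimant, summary = _summarize(per_fold)
    return SweepResult(per_fold=per_fold, per_claimant=per_claimant,
                       summary=summary)


def simulate_attack(sweep: SweepResult, store: FeatureStore,
                    cohort: Cohort) -> tuple[list[AttackSummary], pd.DataFrame]:
    """Present every external impostor segment to every trained network.

    Requires a sweep run with ``keep_networks=True``. Each claimant's
    ``folds`` cross-validated networks for each ``n_train`` see all
    segments of the external (single-session) impostors; an accepted
    segment is a successful attack. Returns per-claimant summaries and a
    cohort FAR table (mean +/- SD per ``n_train``).
    """
    if not sweep.networks:
        raise ConfigurationError("sweep was run without keep_networks=True")
    ext_ids = cohort.impostor_ids
    if not ext_ids:
        raise ConfigurationError("cohort has no external impostors")
    mask = store.df.index.get_level_values("subject").isin(ext_ids)
    X_ext = store.df[mask].to_numpy()
    if len(X_ext) == 0:
        raise DataError("no external impostor segments in the feature store")
    summaries: list[AttackSummary] = []
    for (claimant, n_train), nets in sorted(sweep.networks.items()):
        accepted = 0
        attempts = 0
        for net in nets:
            dec, _ = predict(net, X_ext)
            accepted += int(np.sum(dec))
            attempts += len(dec)
        summaries.append(AttackSummary(
            claimant_id=claimant, n_train_sessions=n_train,
            attempts=attempts, accepted=accepted,
        ))
    df = pd.DataFrame([{
        "claimant": s.claimant_id, "n_train": s.n_train_sessions,
        "attempts": s.attempts, "accepted": s.accepted, "far": s.far,
    } for s in summaries])
    table = df.groupby("n_train")["far"].agg(["mean", "std"]).rename(
        columns={"mean": "far_mean", "std": "far_std"}).reset_index()
    return summaries, table


def design_counts(config: CohortConfig, folds: int = 8,
                  skip_s: float = SKIP_S, keep_s: float = KEEP_S,
                  seg_s: float = SEGMENT_S) -> dict[str, int]:
    """Structural bookkeeping of a study design, via the pipeline's own code
    paths (manifest enumeration, crop + segmentation, Welch bin selection)
    rather than re-derived formulas."""
    entries = list(_iter_cohort_entries(config))
    genuine = sum(1 for _, _, role, _ in entries if role == "genuine")
    impostor = sum(1 for _, _, role, _ in entries if role == "impostor")

    n = int(round(config.duration_s * config.fs))
    blank = Recording(subject_id="blank", session_index=1,
                      data=np.zeros((N_CHANNELS, n)), fs=config.fs)
    segs = segmentize(crop_analysis_window(blank, skip_s, keep_s), seg_s)
    segments_per_session = len(segs)
    freqs, psd = welch_psd(segs[0])
    feature_dim = psd.size

    attempts_per_claimant = impostor * segments_per_session
    return {
        "genuine_recordings": genuine,
        "impostor_recordings": impostor,
        "total_examinations": genuine + impostor,
        "segments_per_session": segments_per_session,
        "genuine_segments": genuine * segments_per_session,
        "feature_dim": int(feature_dim),
        "attack_attempts_per_claimant": attempts_per_claimant,
        "total_attack_attempts": attempts_per_claimant * config.n_genuine * folds,
    }
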