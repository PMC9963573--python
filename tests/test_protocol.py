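"""Experimental protocol: division geometry, stratified sampling, metric
formulas, cross-validation bookkeeping, and the attack machinery."""

import numpy as np
import pandas as pd
import pytest

import eegverify as ev
from eegverify.protocol import _spread_counts


class TestBuildDivision:
    @pytest.mark.parametrize("n_train,test_spec,train,test", [
        (15, "last-5", range(1, 16), range(16, 21)),
        (8, "last-12", range(1, 9), range(9, 21)),
        (1, "last-19", range(1, 2), range(2, 21)),
    ])
    def test_chronological_splits(self, fake_manifest, n_train, test_spec,
                                  train, test):
        div = ev.build_division("sub01", n_train, test_spec, fake_manifest)
        assert div.train_sessions == tuple(train)
        assert div.test_sessions == tuple(test)

    def test_session_disjointness_and_pool_hygiene(self, fake_manifest):
        div = ev.build_division("sub03", 8, "last-5", fake_manifest)
        assert not set(div.train_sessions) & set(div.test_sessions)
        assert max(div.train_sessions) < min(div.test_sessions)
        for sid, _ in div.impostor_train_pool + div.impostor_test_pool:
            assert sid != "sub03"
            assert not sid.startswith("imp")  # externals never in pools
        # pools mirror the claimant's session indices across 28 others
        assert len(div.impostor_train_pool) == 28 * 8
        assert len(div.impostor_test_pool) == 28 * 5

    def test_insufficient_sessions_rejected(self, fake_manifest):
        with pytest.raises(ev.ConfigurationError):
            ev.build_division("sub01", 16, "last-5", fake_manifest)


class TestStratifiedSample:
    def test_whole_pool_when_n_equals_pool(self, fake_manifest, fake_store):
        div = ev.build_division("sub01", 1, "last-5", fake_manifest)
        pool_size = 28 * 1 * 4  # 28 subjects x 1 session x 4 segments
        ids = ev.stratified_impostor_sample(div, pool_size, "train",
                                            fake_store, seed=0)
        assert len(ids) == pool_size == len(set(ids))

    def test_round_robin_spread(self, fake_manifest, fake_store):
        div = ev.build_division("sub01", 8, "last-5", fake_manifest)
        ids = ev.stratified_impostor_sample(div, 24, "train", fake_store,
                                            seed=1)
        per_subject = pd.Series([s for s, _, _ in ids]).value_counts()
        assert per_subject.max() <= 1  # 24 draws over 28 subjects

    def test_deterministic_per_seed(self, fake_manifest, fake_store):
        div = ev.build_division("sub01", 4, "last-5", fake_manifest)
        a = ev.stratified_impostor_sample(div, 30, "test", fake_store, seed=9)
        b = ev.stratified_impostor_sample(div, 30, "test", fake_store, seed=9)
        assert a == b

    def test_shortfall_reported(self, fake_manifest, fake_store):
        div = ev.build_division("sub01", 1, "last-5", fake_manifest)
        with pytest.raises(ev.DataError, match="shortfall"):
            ev.stratified_impostor_sample(div, 10_000, "train", fake_store)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = ev.compute_metrics(ev.ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert all(m[k] == 100.0 for k in ("acc", "sen", "spec", "prec"))

    def test_hand_arithmetic(self):
        m = ev.compute_metrics(ev.ConfusionCounts(TP=90, TN=80, FP=20, FN=10))
        assert m["sen"] == pytest.approx(90.0)
        assert m["spec"] == pytest.approx(80.0)
        assert m["acc"] == pytest.approx(85.0)
        assert m["prec"] == pytest.approx(100 * 90 / 110)

    def test_zero_denominator_flagged_undefined(self):
        with pytest.warns(RuntimeWarning, match="sen"):
            m = ev.compute_metrics(ev.ConfusionCounts(TP=0, TN=5, FP=5, FN=0))
        assert np.isnan(m["sen"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ev.DataError):
            ev.ConfusionCounts(TP=-1, TN=0, FP=0, FN=0)


@pytest.fixture(scope="module")
def cv(tiny_cohort, tiny_store):
    div = ev.build_division("sub01", 1, "last-1", tiny_cohort, seed=5)
    return ev.crossvalidate_claimant(div, tiny_store, folds=8, n_best=1,
                                     max_epochs=10)


class TestCrossValidation:
    def test_fold_count_and_test_bookkeeping(self, cv):
        assert len(cv.results) == len(cv.networks) == 8
        for r in cv.results:
            # positives: the claimant's 24 test-session segments
            assert r.counts.TP + r.counts.FN == 24
            assert r.counts.TN + r.counts.FP == 24
            assert r.counts.total == 48

    def test_metrics_consistent_with_counts(self, cv):
        for r in cv.results:
            m = ev.compute_metrics(r.counts)
            assert r.acc == pytest.approx(m["acc"])
            assert r.prec == pytest.approx(m["prec"], nan_ok=True)

    def test_too_few_segments_for_folds(self, tiny_cohort, tiny_store):
        div = ev.build_division("sub01", 1, "last-1", tiny_cohort, seed=5)
        with pytest.raises(ev.DataError):
            ev.crossvalidate_claimant(
                div, tiny_store, folds=30, n_best=1)


@pytest.fixture(scope="module")
def sweep(tiny_cohort, tiny_store):
    return ev.session_sweep(tiny_cohort, tiny_store, [1, 2], "last-1",
                            folds=4, n_best=1, seed=3,
                            keep_networks=True, max_epochs=10)


class TestSweepAndAttack:
    def test_sweep_shapes(self, tiny_cohort, sweep):
        assert len(sweep.summary) == 2  # one cohort row per n_train
        assert len(sweep.per_fold) == 3 * 2 * 4  # claimants x n_train x folds
        assert set(sweep.per_claimant["n_train"]) == {1, 2}
        assert set(sweep.networks) == {(c, n) for c in tiny_cohort.genuine_ids
                                       for n in (1, 2)}

    def test_separable_limit_every_fold_perfect(self):
        # zero session drift + distinct subjects: train and test sessions
        # are identically distributed, so every fold classifies perfectly
        cfg = ev.CohortConfig(n_genuine=3, n_sessions=2, n_impostors=0,
                              sigma_session=0.0, sigma_subject=3.0,
                              master_seed=21)
        cohort = ev.generate_cohort(cfg)
        store = ev.assemble_features(cohort, scale="dB")
        sweep = ev.session_sweep(cohort, store, [1], "last-1", folds=4,
                                 n_best=3, seed=9, max_epochs=30)
        assert (sweep.per_fold["acc"] == 100.0).all()

    def test_no_session_variance_flat_accuracy(self):
        # with sigma_session = 0 there is nothing extra to learn from a
        # second training session
        cfg = ev.CohortConfig(n_genuine=3, n_sessions=3, n_impostors=0,
                              sigma_session=0.0, sigma_subject=1.5,
                              master_seed=22)
        cohort = ev.generate_cohort(cfg)
        store = ev.assemble_features(cohort, scale="dB")
        sweep = ev.session_sweep(cohort, store, [1, 2], "last-1", folds=4,
                                 n_best=1, seed=9, max_epochs=15)
        accs = sweep.summary.set_index("n_train")["acc_mean"]
        assert abs(accs[1] - accs[2]) < 5.0

    def test_attack_far_and_attempt_bookkeeping(self, tiny_cohort, tiny_store,
                                                sweep):
        summaries, table = ev.simulate_attack(sweep, tiny_store, tiny_cohort)
        for s in summaries:
            assert s.attempts == 24 * 4  # 1 impostor x 24 segments x 4 folds
            assert 0 <= s.far <= 100
            assert s.far == pytest.approx(100 * s.accepted / s.attempts)
        assert set(table["n_train"]) == {1, 2}

    def test_degenerate_always_reject_network_gives_zero_far(
            self, tiny_cohort, tiny_store, sweep):
        reject_all = ev.VerifierNetwork(
            w_hidden=np.zeros((1, 855)), b_hidden=np.zeros(1),
            w_out=np.zeros((2, 1)), b_out=np.array([0.0, 1.0]),
            norm_scale=np.ones(855), norm_offset=np.zeros(855))
        fake = ev.SweepResult(per_fold=sweep.per_fold,
                              per_claimant=sweep.per_claimant,
                              summary=sweep.summary,
                              networks={("sub01", 1): [reject_all]})
        summaries, _ = ev.simulate_attack(fake, tiny_store, tiny_cohort)
        assert summaries[0].far == 0.0


class TestDiversityControl:
    def test_spread_counts_paper_pattern(self):
        rng = np.random.default_rng(0)
        counts = _spread_counts(24, 15, rng)
        assert counts.sum() == 24
        assert sorted(counts)[:6] == [1] * 6 and sorted(counts)[6:] == [2] * 9

    def test_spread_counts_desk_pattern(self):
        rng = np.random.default_rng(0)
        counts = _spread_counts(24, 8, rng)
        assert counts.tolist() == [3] * 8

    def test_every_source_session_represented(self, tiny_cohort, tiny_store):
        res = ev.diversity_control(tiny_cohort, tiny_store,
                                   n_source_sessions=2, target_size=24,
                                   test_spec="last-1", folds=4, n_best=1,
                                   max_epochs=10, seed=1)
        assert len(res.per_fold) == 3 * 4
        assert res.per_fold["n_train"].eq(0).all()


def test_design_counts_desk_scale():
    counts = ev.design_counts(ev.CohortConfig.desk_scale())
    assert counts["genuine_recordings"] == 96
    assert counts["impostor_recordings"] == 5
    assert counts["total_examinations"] == 101
    assert counts["segments_per_session"] == 24
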