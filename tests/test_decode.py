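"""Decoding pipeline: condition construction, equalization, SVM oracle,
shuffle null, planted effects on feature-level synthetic data."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize

import adaptdecode as ad
from adaptdecode.decode import (
    CONDITIONS,
    FeatureSet,
    PenetrationRejected,
    SubDataset,
    ConditionDataset,
    _score,
)


def toy_table(n_per_seq=2):
    rows = []
    tid = 0
    for seq in ("AA", "BB", "AB", "BA"):
        for _ in range(n_per_seq):
            rows.append((tid, seq, seq[0], seq[1], False))
            tid += 1
    return pd.DataFrame(
        rows,
        columns=["trial_id", "sequence_type", "adapter_stim", "test_stim",
                 "aborted"],
    )


def gaussian_features(rng, ids_by_seq, n_sites, mu_by_seq, sd=1.0):
    """FeatureSet with per-sequence mean vectors for adapter/test epochs."""
    frames = {}
    all_ids = np.concatenate(list(ids_by_seq.values()))
    order = np.argsort(all_ids)
    for ei, epoch in enumerate(("adapter", "test")):
        X = []
        for seq, ids in ids_by_seq.items():
            mu = mu_by_seq[seq][ei]
            X.append(mu + sd * rng.standard_normal((len(ids), n_sites)))
        X = np.vstack(X)[order]
        frames[epoch] = pd.DataFrame(X, index=np.sort(all_ids))
    return FeatureSet(frames)


class TestBuildConditions:
    def test_toy_table_structure(self):
        conds = ad.build_conditions(toy_table(2))
        assert set(conds) == set(CONDITIONS)
        adapter = conds["Adapter"]
        assert [len(s.ids_a) + len(s.ids_b) for s in adapter.sub_datasets] == [4, 4]
        test_rep = conds["Test_rep"].sub_datasets[0]
        assert len(test_rep.ids_a) == len(test_rep.ids_b) == 2

    def test_alternation_labels_follow_test_stimulus(self):
        t = toy_table(2)
        conds = ad.build_conditions(t)
        sub = conds["Test_alt"].sub_datasets[0]
        ba = set(t.loc[t.sequence_type == "BA", "trial_id"])
        ab = set(t.loc[t.sequence_type == "AB", "trial_id"])
        assert set(sub.ids_a) == ba  # BA trials show test stimulus A
        assert set(sub.ids_b) == ab

    def test_missing_sequence_type_rejected(self):
        t = toy_table(2)
        t = t[t.sequence_type != "AB"]
        with pytest.raises(PenetrationRejected):
            ad.build_conditions(t)

    def test_aborted_trials_must_be_excluded(self):
        t = toy_table(2)
        t.loc[0, "aborted"] = True
        with pytest.raises(ValueError, match="aborted"):
            ad.build_conditions(t)


def _conditions_with_minima(minima):
    """Synthetic ConditionDatasets whose per-class counts are the minima."""
    out = {}
    start = 0
    for name, m in zip(CONDITIONS, minima):
        ids_a = np.arange(start, start + m)
        ids_b = np.arange(start + m, start + 2 * m)
        start += 2 * m
        out[name] = ConditionDataset(name, (SubDataset("test", ids_a, ids_b),))
    return out


class TestEqualizeNTot:
    def test_floor_to_even_of_minimum(self):
        conds = _conditions_with_minima([120, 118, 117, 119])
        assert ad.equalize_n_tot(conds) == 116

    def test_even_minimum_unchanged(self):
        conds = _conditions_with_minima([112, 112, 112, 112])
        assert ad.equalize_n_tot(conds) == 112

    def test_too_few_trials_rejected(self):
        conds = _conditions_with_minima([3, 10, 10, 10])
        with pytest.raises(PenetrationRejected):
            ad.equalize_n_tot(conds)


class TestSplitHalf:
    def test_sizes_and_disjointness(self, rng):
        tr, te = ad.split_half(np.arange(10), 4, rng)
        assert len(tr) == len(te) == 2
        assert not set(tr) & set(te)

    def test_same_rng_state_identical(self):
        r1 = np.random.default_rng(3)
        r2 = np.random.default_rng(3)
        s1 = ad.split_half(np.arange(20), 10, r1)
        s2 = ad.split_half(np.arange(20), 10, r2)
        assert np.array_equal(s1[0], s2[0]) and np.array_equal(s1[1], s2[1])

    def test_inclusion_frequency_matches_hypergeometric(self, rng):
        # P(train) = (n_tot / N) * 1/2 per trial; check binomial 99.9% bounds
        pool, n_tot, n_draws = np.arange(20), 10, 1000
        counts = np.zeros(20)
        for _ in range(n_draws):
            tr, _ = ad.split_half(pool, n_tot, rng)
            counts[tr] += 1
        p = (n_tot / pool.size) * 0.5
        lo, hi = sps.binom.interval(0.999, n_draws, p)
        assert ((counts >= lo) & (counts <= hi)).all()

    def test_insufficient_trials_rejected(self, rng):
        with pytest.raises(PenetrationRejected):
            ad.split_half(np.arange(3), 4, rng)


class TestZNormalize:
    def test_two_point_standardization(self):
        tr, te = ad.z_normalize(np.array([[1.0], [3.0]]), np.array([[2.0]]))
        assert np.allclose(tr.ravel(), [-1.0, 1.0])
        assert te[0, 0] == pytest.approx(0.0)  # test at train mean -> 0

    def test_training_moments(self, rng):
        train = rng.normal(5, 3, size=(40, 6))
        test = rng.normal(5, 3, size=(10, 6))
        ztr, _ = ad.z_normalize(train, test)
        np.testing.assert_allclose(ztr.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(ztr.std(axis=0), 1.0, rtol=1e-12)

    def test_not_idempotent_unless_standardized(self, rng):
        train = rng.normal(5, 3, size=(20, 2))
        test = rng.normal(5, 3, size=(5, 2))
        z1tr, z1te = ad.z_normalize(train, test)
        z2tr, z2te = ad.z_normalize(z1tr, z1te)
        assert np.allclose(z1tr, z2tr)  # already standardized: no change
        raw_again, _ = ad.z_normalize(train, test)
        assert not np.allclose(train, raw_again)

    def test_zero_variance_site_zeroed(self):
        train = np.array([[1.0, 2.0], [1.0, 4.0]])
        test = np.array([[7.0, 3.0]])
        ztr, zte = ad.z_normalize(train, test)
        assert (ztr[:, 0] == 0).all() and zte[0, 0] == 0


class TestLinearSvm:
    def test_symmetric_1d_boundary(self):
        clf = ad.train_linear_svm(np.array([[-1.0], [1.0]]), np.array(["A", "B"]))
        assert clf.decision_function([[0.0]])[0] == pytest.approx(0.0, abs=1e-9)
        assert _score(clf, np.array([[-1.0], [1.0]]), np.array(["A", "B"])) == 1.0

    def test_separable_cloud_perfect_training(self, rng):
        X = np.vstack([rng.normal(-5, 0.3, (20, 3)), rng.normal(5, 0.3, (20, 3))])
        y = np.array(["A"] * 20 + ["B"] * 20)
        clf = ad.train_linear_svm(X, y)
        assert _score(clf, X, y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ad.train_linear_svm(np.zeros((4, 2)), np.array(["A"] * 4))

    def test_weights_match_qp_oracle(self):
        """Dual soft-margin QP solved by brute-force SLSQP on 6 points."""
        X = np.array(
            [[-1.2, 0.3], [-0.8, -0.6], [-1.5, -0.1],
             [1.0, 0.4], [1.4, -0.3], [0.7, 0.9]]
        )
        y = np.array([-1, -1, -1, 1, 1, 1], dtype=float)
        K = (X * y[:, None]) @ (X * y[:, None]).T

        def neg_dual(a):
            return -a.sum() + 0.5 * a @ K @ a

        cons = [{"type": "eq", "fun": lambda a: a @ y}]
        res = minimize(
            neg_dual, np.full(6, 0.1), bounds=[(0, 1.0)] * 6,
            constraints=cons, method="SLSQP",
            options={"ftol": 1e-14, "maxiter": 500},
        )
        w_oracle = (res.x * y) @ X
        clf = ad.train_linear_svm(X, np.where(y < 0, "A", "B"))
        np.testing.assert_allclose(clf.coef_.ravel(), w_oracle, atol=1e-6)


def two_class_condition(n_per_class=40):
    ids_a = np.arange(n_per_class)
    ids_b = np.arange(n_per_class, 2 * n_per_class)
    return ConditionDataset("Test_rep", (SubDataset("test", ids_a, ids_b),))


def feature_set_from_means(rng, n_per_class, n_sites, delta, sd=1.0):
    ids = np.arange(2 * n_per_class)
    X = sd * rng.standard_normal((2 * n_per_class, n_sites))
    X[n_per_class:] += delta
    frame = pd.DataFrame(X, index=ids)
    return FeatureSet({"adapter": frame, "test": frame})


class TestDecodeCondition:
    def test_no_signal_chance_level(self, rng):
        # a single fixed null dataset has a dataset-specific cross-validated
        # accuracy a few points off 50; the expectation over datasets is 50
        accs = [
            ad.decode_condition(
                fs := feature_set_from_means(rng, 40, 8, delta=0.0),
                two_class_condition(40), 40, 60, rng,
            ).mean_accuracy
            for _ in range(12)
        ]
        assert np.mean(accs) == pytest.approx(50.0, abs=3.0)

    def test_strong_signal_saturates(self, rng):
        fs = feature_set_from_means(rng, 40, 8, delta=8.0)
        res = ad.decode_condition(fs, two_class_condition(40), 40, 50, rng)
        assert res.mean_accuracy > 99.0

    def test_accuracy_close_to_bayes_oracle(self, rng):
        # single informative site, Gaussian classes: Bayes acc = Phi(d/2)
        delta = 2.0 * sps.norm.ppf(0.75)  # d' chosen for 75% Bayes accuracy
        X = rng.standard_normal((200, 1))
        X[100:] += delta
        frame = pd.DataFrame(X, index=np.arange(200))
        fs = FeatureSet({"adapter": frame, "test": frame})
        res = ad.decode_condition(fs, two_class_condition(100), 100, 300, rng)
        assert res.mean_accuracy == pytest.approx(75.0, abs=5.0)

    def test_affine_rescaling_invariance(self):
        # per-site affine feature maps are absorbed by z-normalization
        rng = np.random.default_rng(5)
        fs = feature_set_from_means(rng, 30, 6, delta=0.7)
        scale = np.array([3.0, 0.2, 11.0, 1.0, 0.01, 5.0])
        shift = np.array([-4.0, 0.0, 100.0, 2.0, -0.5, 7.0])
        fs2 = FeatureSet(
            {e: f * scale + shift for e, f in fs.frames.items()}
        )
        cond = two_class_condition(30)
        r1 = ad.decode_condition(fs, cond, 30, 60, np.random.default_rng(9))
        r2 = ad.decode_condition(fs2, cond, 30, 60, np.random.default_rng(9))
        np.testing.assert_allclose(r1.per_repetition, r2.per_repetition)


class TestShuffleControl:
    def test_strong_signal_shuffles_to_chance(self, rng):
        fs = feature_set_from_means(rng, 40, 8, delta=3.0)
        mean, dist = ad.shuffle_control(fs, two_class_condition(40), 40, 300, rng)
        assert mean == pytest.approx(50.0, abs=3.0 * dist.std() / np.sqrt(dist.size) + 1.0)

    def test_permutation_sd_shrinks_with_test_size(self, rng):
        fs = feature_set_from_means(rng, 60, 4, delta=0.0)
        _, d_small = ad.shuffle_control(fs, two_class_condition(60), 8, 300, rng)
        _, d_large = ad.shuffle_control(fs, two_class_condition(60), 32, 300, rng)
        # binomial oracle: sd ratio ~ sqrt(32/8) = 2
        ratio = d_small.std() / d_large.std()
        assert ratio == pytest.approx(2.0, rel=0.4)


class TestAveragePairedScores:
    def test_identical_vectors(self):
        s = np.array([60.0, 61.0, 59.0, 62.0, 58.0])
        avg, report = ad.average_paired_scores(s, s)
        np.testing.assert_allclose(avg, s)
        assert report["p"] == 1.0 and not report["rejects"]

    def test_elementwise_average(self):
        avg, _ = ad.average_paired_scores(
            np.array([55.0, 60.0]), np.array([57.0, 62.0])
        )
        np.testing.assert_allclose(avg, [56.0, 61.0])

    def test_detects_planted_shift(self, rng):
        # n=20 pairs, shift 5, sd 3: Wilcoxon at alpha=0.025 has power >= 0.8
        rejections = 0
        for _ in range(100):
            base = rng.normal(60, 5, 20)
            shifted = base + rng.normal(5, 3, 20)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, rep = ad.average_paired_scores(base, shifted)
            rejections += rep["rejects"]
        assert rejections >= 80

    def test_warns_when_scores_differ(self, rng):
        base = rng.normal(60, 1, 20)
        with pytest.warns(UserWarning, match="differ"):
            ad.average_paired_scores(base, base + 10.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            ad.average_paired_scores(np.zeros(3), np.zeros(4))


class TestSubsampleSites:
    @pytest.mark.parametrize("n_sites,expected", [(15, 5), (16, 5), (12, 4)])
    def test_one_third_rounding(self, n_sites, expected):
        idx = ad.subsample_site_indices(n_sites)
        assert len(idx) == expected
        assert len(set(idx)) == len(idx)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            ad.subsample_site_indices(2)

    def test_deterministic_default_random_option(self, rng):
        assert np.array_equal(
            ad.subsample_site_indices(16), ad.subsample_site_indices(16)
        )
        r = ad.subsample_site_indices(16, mode="random", rng=rng)
        assert len(r) == 5

    def test_reduced_sites_lose_accuracy_on_private_signal(self, rng):
        """With independent per-site signal, 1/3 of sites must decode worse
        on average (20 synthetic penetrations)."""
        full, reduced = [], []
        cond = two_class_condition(30)
        for _ in range(20):
            fs = feature_set_from_means(rng, 30, 12, delta=0.45)
            idx = ad.subsample_site_indices(12)
            fs_red = fs.select_sites(idx)
            full.append(ad.decode_condition(fs, cond, 30, 40, rng).mean_accuracy)
            reduced.append(
                ad.decode_condition(fs_red, cond, 30, 40, rng).mean_accuracy
            )
        assert np.mean(full) > np.mean(reduced)

    def test_session_subsampling(self, small_session):
        red = ad.subsample_sites(small_session, 1.0 / 3.0)
        assert red.n_sites == max(round(small_session.n_sites / 3), 1)
        assert red.lfp.shape[0] == small_session.lfp.shape[0]


class TestDecodeMua:
    @staticmethod
    def _spike_featureset(cfg, table, rng):
        records = [
            ad.TrialRecord(int(r.trial_id), r.sequence_type)
            for r in table.itertuples()
        ]
        counts = np.stack(
            [ad.generate_spikes(rec, cfg, rng) for rec in records]
        )
        return FeatureSet.from_spike_counts(
            counts, table["trial_id"].to_numpy()
        )

    def test_zero_rates_chance(self, rng):
        cfg = ad.SimulationConfig(
            spike_rate={"A": 10.0, "B": 10.0}, n_sites=6,
            spike_adaptation_factor=1.0,
        )
        table = toy_table(20)
        fs = self._spike_featureset(cfg, table, rng)
        conds = ad.build_conditions(table)
        res = ad.decode_condition(fs, conds["Adapter"], 20, 150, rng)
        assert res.mean_accuracy == pytest.approx(50.0, abs=5.0)

    def test_rate_ratio_two_to_one_above_chance(self, rng):
        cfg = ad.SimulationConfig(
            spike_rate={"A": 40.0, "B": 20.0}, n_sites=6,
            spike_adaptation_factor=1.0,
        )
        table = toy_table(20)
        fs = self._spike_featureset(cfg, table, rng)
        conds = ad.build_conditions(table)
        res = ad.decode_condition(fs, conds["Adapter"], 20, 200, rng)
        # one-sided binomial test against chance on the pooled test trials
        n_test = 20 * res.per_repetition.size
        k = int(round(res.mean_accuracy / 100.0 * n_test))
        p = sps.binomtest(k, n_test, 0.5, alternative="greater").pvalue
        assert p < 0.01

    def test_spike_adaptation_reduces_repetition_accuracy(self, rng):
        adapter_acc, rep_acc = [], []
        cfg = ad.SimulationConfig(
            spike_rate={"A": 30.0, "B": 22.0}, n_sites=8,
            spike_adaptation_factor=0.55,
        )
        for _ in range(20):
            table = toy_table(16)
            fs = self._spike_featureset(cfg, table, rng)
            conds = ad.build_conditions(table)
            adapter_acc.append(
                ad.decode_condition(fs, conds["Adapter"], 16, 30, rng).mean_accuracy
            )
            rep_acc.append(
                ad.decode_condition(fs, conds["Test_rep"], 16, 30, rng).mean_accuracy
            )
        assert np.mean(rep_acc) < np.mean(adapter_acc)

    def test_missing_spikes_rejected(self, small_session):
        sess = ad.SessionRecording(
            lfp=small_session.lfp,
            trials=small_session.trials,
            sampling_rate=small_session.sampling_rate,
            spikes=None,
        )
        with pytest.raises(ValueError, match="spike"):
            ad.decode_mua(sess, {}, 4)
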