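"""Decision fusion, voting, metrics, cross-validation fitness and PSO."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pigsound import multisvdd as ms
from pigsound.synthetic import gen_feature_set
from pigsound.wsvdd import fit_wsvdd


class TestFusion:
    @pytest.mark.parametrize(
        "d1,d2,expected",
        [(1, -1, "cough"), (-1, 1, "scream"), (-1, -1, "other"), (1, 1, "unknown")],
    )
    def test_lookup_table(self, d1, d2, expected):
        assert ms.fuse(d1, d2) == expected

    def test_exhaustive_totality(self):
        outcomes = {ms.fuse(a, b) for a, b in itertools.product((1, -1), repeat=2)}
        assert outcomes == {"cough", "scream", "other", "unknown"}

    @given(st.integers(-3, 3), st.integers(-3, 3))
    @settings(max_examples=49, deadline=None)
    def test_rejects_non_sign_inputs(self, a, b):
        if a in (1, -1) and b in (1, -1):
            assert ms.fuse(a, b) in ms.LABELS
        else:
            with pytest.raises(ValueError):
                ms.fuse(a, b)


class TestMajorityVote:
    def test_strict_majority(self):
        assert ms.majority_vote(["cough", "cough", "other"]) == "cough"

    def test_unanimous(self):
        assert ms.majority_vote(["other"] * 10) == "other"

    def test_unknown_excluded_unless_unanimous(self):
        assert ms.majority_vote(["unknown", "unknown", "scream"]) == "scream"
        assert ms.majority_vote(["unknown", "unknown"]) == "unknown"

    def test_tie_priority_favors_abnormal(self):
        assert ms.majority_vote(["scream", "other", "scream", "other"]) == "scream"
        assert ms.majority_vote(["cough", "scream"]) == "cough"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ms.majority_vote([])

    def test_matches_counting_oracle(self, rng):
        labels = ["cough", "scream", "other"]
        for _ in range(100):
            seq = list(rng.choice(labels, size=rng.integers(1, 30)))
            counts = {lab: seq.count(lab) for lab in labels}
            best = max(counts.values())
            winners = [lab for lab in labels if counts[lab] == best]
            assert ms.majority_vote(seq) == winners[0]  # list order = priority


class TestEvaluate:
    def test_perfect_predictions(self):
        labels = ["cough"] * 5 + ["scream"] * 5 + ["other"] * 5
        rep = ms.evaluate(labels, labels)
        assert all(v == 100.0 for v in rep.accuracy.values())
        assert all(v == 100.0 for v in rep.precision.values())
        assert all(v == 100.0 for v in rep.recall.values())

    def test_hand_computed_confusion(self):
        # target class with TP=9, FP=1, FN=3, TN=7
        truth = ["cough"] * 12 + ["other"] * 8
        pred = ["cough"] * 9 + ["other"] * 3 + ["cough"] * 1 + ["other"] * 7
        rep = ms.evaluate(pred, truth, classes=("cough",))
        assert rep.counts["cough"] == {"tp": 9, "tn": 7, "fp": 1, "fn": 3}
        assert rep.precision["cough"] == pytest.approx(90.0)
        assert rep.recall["cough"] == pytest.approx(75.0)
        assert rep.accuracy["cough"] == pytest.approx(80.0)

    def test_zero_predicted_positives_undefined(self):
        rep = ms.evaluate(["other"] * 4, ["cough"] * 2 + ["other"] * 2, classes=("cough",))
        assert rep.precision["cough"] is None
        assert rep.recall["cough"] == 0.0

    def test_pairwise_permutation_invariance(self, rng):
        labels = ["cough", "scream", "other"]
        pred = list(rng.choice(labels, 30))
        truth = list(rng.choice(labels, 30))
        rep1 = ms.evaluate(pred, truth)
        order = rng.permutation(30)
        rep2 = ms.evaluate([pred[i] for i in order], [truth[i] for i in order])
        assert rep1.accuracy == rep2.accuracy
        assert rep1.counts == rep2.counts

    def test_metrics_recompute_from_counts(self, rng):
        labels = ["cough", "scream", "other"]
        pred = list(rng.choice(labels, 50))
        truth = list(rng.choice(labels, 50))
        rep = ms.evaluate(pred, truth)
        for cls in rep.classes:
            c = rep.counts[cls]
            if c["tp"] + c["fp"]:
                assert rep.precision[cls] == pytest.approx(100 * c["tp"] / (c["tp"] + c["fp"]))
            if c["tp"] + c["fn"]:
                assert rep.recall[cls] == pytest.approx(100 * c["tp"] / (c["tp"] + c["fn"]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ms.evaluate(["cough"], ["cough", "other"])


class TestCrossValidation:
    def test_folds_partition_indices(self):
        folds = ms._fold_indices(47, 10)
        all_test = np.concatenate([test for _, test in folds])
        assert sorted(all_test) == list(range(47))
        sizes = [len(test) for _, test in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_group_folds_keep_clips_together(self):
        groups = np.repeat(np.arange(20), 5)  # 20 clips x 5 frames
        folds = ms._fold_indices(100, 10, groups)
        for _, test in folds:
            test_groups = set(groups[test])
            train_groups = set(groups[np.setdiff1d(np.arange(100), test)])
            assert not test_groups & train_groups

    def test_fitness_matches_manual_loop(self, rng):
        x, _ = gen_feature_set(30, seed=rng)
        x = x[:50]
        fit = ms.cv_fitness(x, C=0.2, sigma=4.0, n_folds=5, weighted=False)
        # independent manual loop over the same deterministic folds
        accs = []
        for train_idx, test_idx in ms._fold_indices(50, 5):
            from pigsound.wsvdd import TrainingSet, decide_batch, train_wsvdd

            model = train_wsvdd(TrainingSet(x[train_idx]), C=0.2, sigma=4.0)
            accs.append(np.mean(decide_batch(model, x[test_idx]) == 1))
        assert fit == pytest.approx(-np.mean(accs), abs=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            ms.cv_fitness(np.ones((5, 3)), 1.0, 1.0, n_folds=10)


class TestPSO:
    def test_degenerate_single_particle(self, rng):
        x, _ = gen_feature_set(20, seed=rng)
        x0 = x[:30]
        cfg = ms.PSOConfig(swarm_size=1, max_iter=0, n_folds=3, velocity_clamp=0.0, seed=1)
        c, sigma, trace = ms.pso_tune(x0, cfg)
        assert cfg.c_bounds[0] <= c <= cfg.c_bounds[1]
        assert cfg.sigma_bounds[0] <= sigma <= cfg.sigma_bounds[1]
        assert len(trace) == 1
        assert trace[0] == pytest.approx(ms.cv_fitness(x0, c, sigma, 3))

    def test_reproducible_and_monotone_trace(self, rng):
        x, _ = gen_feature_set(25, seed=rng)
        x0 = x[:40]
        cfg = ms.PSOConfig(swarm_size=4, max_iter=4, n_folds=4, seed=7)
        out1 = ms.pso_tune(x0, cfg)
        out2 = ms.pso_tune(x0, cfg)
        assert out1 == out2
        trace = out1[2]
        assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))

    def test_reaches_good_fitness_on_easy_landscape(self):
        # low-dimensional, widely separated: the CV acceptance ceiling is
        # high and the swarm should find it quickly
        x, _ = gen_feature_set(60, separation=10.0, d=2, seed=42)
        x0 = x[:60]
        cfg = ms.PSOConfig(swarm_size=8, max_iter=30, n_folds=10, seed=0)
        _, _, trace = ms.pso_tune(x0, cfg)
        assert min(trace) <= -0.9


class TestRecognition:
    def test_trained_spheres_recognize_their_class(self, rng):
        x, y = gen_feature_set(80, separation=8.0, seed=rng)
        mm = ms.MultiSVDDModel(
            model_cough=fit_wsvdd(x[y == 0][:60], C=0.05),
            model_scream=fit_wsvdd(x[y == 1][:60], C=0.05),
        )
        vote_c, trace_c = ms.recognize_features(mm, x[y == 0][60:])
        vote_s, _ = ms.recognize_features(mm, x[y == 1][60:])
        assert vote_c == "cough"
        assert vote_s == "scream"
        assert len(trace_c) == 20

    def test_distant_points_are_other(self, rng):
        x, y = gen_feature_set(40, separation=8.0, seed=rng)
        mm = ms.MultiSVDDModel(
            model_cough=fit_wsvdd(x[y == 0], C=0.05),
            model_scream=fit_wsvdd(x[y == 1], C=0.05),
        )
        far = 30.0 + np.abs(rng.standard_normal((10, 24)))
        vote, _ = ms.recognize_features(mm, far)
        assert vote == "other"
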