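"""chi_new trajectories, descriptors, training, calibration, prediction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftriage.completion import (
    CONTINUE,
    GAS_CONSTANT_KCAL,
    STOP,
    CompletionModel,
    CompletionTrajectory,
    assign_label,
    build_trajectory,
    calibrate_confidence,
    chi_new,
    extract_features,
    predict,
    train_model,
)
from conftriage.ensemble import OptimizedResult
from conftriage.synthetic import make_planted_signal_corpus

RT = GAS_CONSTANT_KCAL * 298.15


class TestChiNew:
    def test_new_minimum_scores_one(self):
        assert chi_new(0.0) == 1.0

    def test_duplicate_scores_zero_regardless_of_energy(self):
        assert chi_new(0.0, is_duplicate=True) == 0.0
        assert chi_new(3.7, is_duplicate=True) == 0.0

    def test_half_population_at_rt_ln2(self):
        assert chi_new(RT * math.log(2)) == pytest.approx(0.5, abs=1e-12)
        assert RT * math.log(2) == pytest.approx(0.4107, abs=5e-4)

    def test_negative_gap_is_contract_violation(self):
        with pytest.raises(ValueError):
            chi_new(-0.1)


def _stream(energies, coords_fn=None):
    return [OptimizedResult(i, np.zeros((2, 3)), e)
            for i, e in enumerate(energies)]


class TestBuildTrajectory:
    def test_first_point_is_running_minimum(self):
        traj = build_trajectory(_stream([5.0]), 10, duplicate_flags=[False])
        assert traj.points == [(0.1, 1.0)]

    def test_duplicate_point_zero(self):
        traj = build_trajectory(_stream([0.0, 0.0]), 10,
                                duplicate_flags=[False, True])
        assert traj.points[1] == (0.2, 0.0)

    def test_matches_sequential_running_minimum_oracle(self):
        rng = np.random.default_rng(2)
        energies = rng.uniform(0, 6, size=10)
        flags = (rng.random(10) < 0.3).tolist()
        flags[0] = False
        traj = build_trajectory(_stream(energies), 12, duplicate_flags=flags)
        running = np.inf
        for k, (r_opt, chi) in enumerate(traj.points):
            assert r_opt == pytest.approx((k + 1) / 12)
            running = min(running, energies[k])
            expect = 0.0 if flags[k] else math.exp(
                -(energies[k] - running) / RT)
            assert chi == pytest.approx(expect, abs=1e-12)

    def test_new_minimum_rezeroes_subsequent_gaps(self):
        energies = [2.0, 0.5, 1.0]  # second structure sets a new minimum
        traj = build_trajectory(_stream(energies), 3,
                                duplicate_flags=[False] * 3)
        assert traj.points[1][1] == 1.0  # new running minimum
        assert traj.points[2][1] == pytest.approx(math.exp(-0.5 / RT))

    def test_geometric_duplicate_detection(self):
        from conftest import embedded
        mol = embedded("CCC")
        c = np.array(mol.GetConformer().GetPositions())
        far = c.copy()
        far[0] += 1.0  # internal distortion, not a rigid motion
        results = [OptimizedResult(0, c, 0.0),
                   OptimizedResult(1, c + 0.0005, 0.01),
                   OptimizedResult(2, far, 0.5)]
        traj = build_trajectory(results, 3, mol=mol)
        assert traj.points[0][1] == 1.0
        assert traj.points[1][1] == 0.0  # within 0.005 A of the first
        assert traj.points[2][1] > 0.0


class TestExtractFeatures:
    def test_all_ones_trajectory(self):
        traj = CompletionTrajectory([((k + 1) / 10, 1.0) for k in range(5)], 10)
        f = extract_features(traj)
        assert f[1] == 1.0 and f[6] == 1.0       # frac(chi=1), whole + tail
        assert f[10] == 0.5 and f[11] == 0.5     # highest r_opt at 1; last
        assert f[12] == 5

    def test_all_zero_after_first(self):
        pts = [(0.1, 1.0)] + [((k + 2) / 10, 0.0) for k in range(4)]
        f = extract_features(CompletionTrajectory(pts, 10))
        assert f[0] == pytest.approx(4 / 5)
        assert f[10] == pytest.approx(0.1)

    def test_matches_direct_recount(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            k = int(rng.integers(1, 25))
            m = k + int(rng.integers(0, 10))
            chi = rng.choice([0.0, 1.0, *rng.random(4)], size=k)
            pts = [((i + 1) / m, float(c)) for i, c in enumerate(chi)]
            f = extract_features(CompletionTrajectory(pts, m))
            tail = chi[k - math.ceil(0.4 * k):]
            assert f[0] == pytest.approx(np.mean(chi == 0))
            assert f[4] == pytest.approx(np.mean(chi <= 0.5))
            assert f[9] == pytest.approx(np.mean(tail <= 0.5))
            ones = [p for p, c in pts if c == 1.0]
            assert f[10] == pytest.approx(max(ones) if ones else 0.0)
            assert f[12] == k

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_threshold_fractions_nested(self, chis):
        pts = [((i + 1) / (len(chis) + 3), c) for i, c in enumerate(chis)]
        f = extract_features(CompletionTrajectory(pts, len(chis) + 3))
        assert f[2] <= f[3] <= f[4]
        assert f[7] <= f[8] <= f[9]
        assert f[10] <= f[11]


class TestAssignLabel:
    def test_boundary_is_stop(self):
        traj = CompletionTrajectory([(0.2, 1.0), (0.4, 0.5)], 5)
        assert assign_label(traj, 0.4) == STOP
        assert assign_label(traj, 0.4 + 1 / 5) == CONTINUE

    def test_full_trajectory_always_stop(self):
        pts = [((k + 1) / 4, 1.0) for k in range(4)]
        traj = CompletionTrajectory(pts, 4)
        assert assign_label(traj, 1.0) == STOP


class TestTrainModel:
    def test_separable_corpus_perfect_holdout(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(600, 13))
        x = x[np.abs(x[:, 3]) > 0.5][:400]  # separable with a clear margin
        y = [STOP if v > 0 else CONTINUE for v in x[:, 3]]
        model = train_model(x, y, seed=0, calibrate=False)
        assert model.holdout_accuracy == 1.0

    def test_uninformative_features_near_prior(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2000, 13))
        y = [STOP if rng.random() < 0.7 else CONTINUE for _ in range(2000)]
        model = train_model(x, y, seed=1, calibrate=False)
        assert abs(model.holdout_accuracy - 0.7) < 0.06  # ~3 sigma binomial

    def test_single_class_corpus_rejected(self):
        x = np.zeros((10, 13))
        with pytest.raises(ValueError, match="both labels"):
            train_model(x, [STOP] * 10)

    def test_planted_signal_recovered(self):
        corpus = make_planted_signal_corpus(2000, seed=0)
        model = train_model(corpus.features, corpus.labels, seed=0)
        assert model.holdout_accuracy > 0.9

    def test_weight_recovery_from_known_logistic_model(self):
        rng = np.random.default_rng(3)
        w_true = rng.normal(size=13)
        w_true /= np.linalg.norm(w_true)
        x = rng.normal(size=(10000, 13))
        p = 1 / (1 + np.exp(-(x @ (w_true * 4.0))))
        y = [STOP if rng.random() < pi else CONTINUE for pi in p]
        model = train_model(x, y, seed=3, calibrate=False)
        w = model.clf.coef_.ravel()
        cos = float(w @ w_true / np.linalg.norm(w))
        assert cos > 0.95

    def test_json_round_trip_preserves_predictions(self):
        corpus = make_planted_signal_corpus(400, seed=1)
        model = train_model(corpus.features, corpus.labels, seed=1)
        clone = CompletionModel.from_json(model.to_json())
        for row in corpus.features[:20]:
            assert clone.predict_proba(row) == pytest.approx(
                model.predict_proba(row), abs=1e-12)


class TestCalibration:
    def test_self_calibrated_data_close_to_diagonal(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.02, 0.98, size=4000)
        correct = rng.random(4000) < p  # fraction-correct equals p
        cal = calibrate_confidence(p, correct)
        assert cal.monotone
        grid = np.linspace(0.1, 0.9, 17)
        mae = np.mean(np.abs([cal(v) - 100 * v for v in grid]))
        assert mae <= 3.0

    def test_all_correct_plateaus_high(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.5, 1.0, size=500)
        cal = calibrate_confidence(p, np.ones(500, bool))
        assert cal(0.9) > 95.0

    def test_anti_calibrated_flagged(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.02, 0.98, size=2000)
        correct = rng.random(2000) < (1 - p)
        with pytest.warns(UserWarning, match="anti-calibrated"):
            cal = calibrate_confidence(p, correct)
        assert not cal.monotone

    def test_monotone_output(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, size=3000)
        cal = calibrate_confidence(p, rng.random(3000) < p)
        grid = np.linspace(0, 1, 50)
        vals = [cal(v) for v in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestPredict:
    def test_probability_boundary_counts_as_stop(self):
        corpus = make_planted_signal_corpus(500, seed=2)
        model = train_model(corpus.features, corpus.labels, seed=2)
        # construct trajectories on both sides of the decision
        stop_traj = CompletionTrajectory(
            [(1 / 20, 1.0)] + [((k + 2) / 20, 0.0) for k in range(10)], 20)
        label, p, conf = predict(model, stop_traj)
        assert label == (STOP if p >= 0.5 else CONTINUE)
        assert 0 < conf <= 100

    def test_batchwise_confidence_grows_with_evidence(self):
        corpus = make_planted_signal_corpus(1500, seed=3)
        model = train_model(corpus.features, corpus.labels, seed=3)
        m = 40
        # long duplicate-heavy tail: evidence for stopping accumulates
        chis = [1.0] + [0.0] * (m - 1)
        confs = []
        for k in (4, 12, 24, 36):
            traj = CompletionTrajectory(
                [((i + 1) / m, chis[i]) for i in range(k)], m)
            _lab, p, _conf = predict(model, traj)
            confs.append(p)
        assert confs[-1] > confs[0]
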