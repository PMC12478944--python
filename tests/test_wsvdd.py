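"""Confidence weighting and the weighted-SVDD dual solver."""

import numpy as np
import pytest

from pigsound import wsvdd as wv
from pigsound.synthetic import gen_feature_set

from .oracles import densities_loop, neighbouring_radius_loop, radius_from_alpha, svdd_dual_qp


class TestSubtractiveDensities:
    def test_two_point_closed_form(self):
        # distance t: r_a = t/2, P_i = 1 + exp(-t^2 / (t/4)^2) = 1 + e^-16
        t = 3.0
        x = np.array([[0.0], [t]])
        p = wv.subtractive_densities(x)
        assert np.allclose(p, 1.0 + np.exp(-16.0), rtol=1e-12)

    def test_self_term_lower_bound(self, rng):
        x = rng.standard_normal((25, 4))
        p = wv.subtractive_densities(x)
        assert np.all(p >= 1.0)
        assert np.all(p <= 25.0)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.standard_normal((30, 2))
        r_a = neighbouring_radius_loop(x)
        expected = densities_loop(x, r_a)
        assert np.allclose(wv.subtractive_densities(x), expected, rtol=1e-12, atol=1e-12)

    def test_duplicate_data_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            wv.subtractive_densities(np.ones((5, 3)))

    def test_alternative_radius_mode_differs(self, rng):
        x = rng.standard_normal((20, 3))
        p1 = wv.subtractive_densities(x, "min_max")
        p2 = wv.subtractive_densities(x, "max_min")
        assert not np.allclose(p1, p2)


class TestConfidences:
    def test_density_centre_gets_one(self):
        w = wv.confidences(np.array([2.0, 5.0, 3.0])).w
        assert w[1] == 1.0
        assert np.max(w) == 1.0

    def test_hand_evaluated_pair(self):
        w = wv.confidences(np.array([4.0, 2.0])).w
        assert w[0] == pytest.approx(1.0)
        assert w[1] == pytest.approx(0.8, rel=1e-12)

    def test_isolated_point_limit(self):
        w = wv.confidences(np.array([1e12, 1e-9])).w
        assert w[1] == pytest.approx(0.5, rel=1e-6)

    def test_range_and_errors(self, rng):
        p = rng.uniform(0.5, 10.0, 40)
        w = wv.confidences(p).w
        assert np.all((w > 0) & (w <= 1))
        with pytest.raises(ValueError):
            wv.confidences(np.array([1.0, 0.0]))


class TestKernel:
    def test_identity_and_known_value(self):
        a = np.array([1.0, 2.0])
        assert wv.rbf_kernel(a, a, 2.0) == 1.0
        b = a + np.array([2.0, 0.0])  # ||a-b||^2 = 4 = 2 sigma^2 for sigma = sqrt(2)
        assert wv.rbf_kernel(a, b, np.sqrt(2.0)) == pytest.approx(np.exp(-1.0))

    def test_symmetry(self, rng):
        for _ in range(5):
            a, b = rng.standard_normal((2, 6))
            assert wv.rbf_kernel(a, b, 1.3) == pytest.approx(wv.rbf_kernel(b, a, 1.3))

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            wv.rbf_kernel(np.ones(2), np.ones(2), 0.0)


class TestTrainWSVDD:
    def test_two_point_closed_form(self):
        # two distinct points, large C, unit weights: alpha = (1/2, 1/2)
        x = np.array([[0.0, 0.0], [1.0, 0.0]])
        m = wv.train_wsvdd(wv.TrainingSet(x), C=10.0, sigma=1.0, normalize=False)
        assert np.allclose(np.sort(m.alphas), [0.5, 0.5], atol=1e-8)
        k12 = np.exp(-0.5)
        # r^2 = 1 - 2(a1 K11 + a2 K12) + a'Ka evaluated at a support vector
        expected_r2 = 1.0 - 2 * (0.5 + 0.5 * k12) + (0.5 + 0.5 * k12)
        assert m.r_squared == pytest.approx(expected_r2, abs=1e-8)

    def test_unit_weights_match_generic_qp(self, rng):
        x = rng.standard_normal((50, 24))
        m = wv.train_wsvdd(wv.TrainingSet(x), C=0.2, sigma=None)
        xn = (x - x.mean(0)) / x.std(0)
        kernel = wv.rbf_kernel_matrix(xn, xn, m.sigma)
        upper = np.full(50, 0.2)
        a_oracle = svdd_dual_qp(kernel, upper)
        a_full = np.zeros(50)
        # reconstruct dense alpha from stored support vectors by re-solving
        a_full = wv._solve_dual_smo(kernel, upper)
        assert np.max(np.abs(a_full - a_oracle)) < 1e-6
        assert m.r_squared == pytest.approx(radius_from_alpha(kernel, a_oracle, upper), abs=1e-8)

    def test_dual_feasibility(self, rng):
        x, _ = gen_feature_set(40, seed=rng)
        w = wv.confidences(wv.subtractive_densities(x))
        m = wv.train_wsvdd(wv.TrainingSet(x), w, C=0.1)
        assert np.all(m.alphas > 0)
        xn = (x - x.mean(0)) / np.where(x.std(0) > 1e-12, x.std(0), 1)
        kernel = wv.rbf_kernel_matrix(xn, xn, m.sigma)
        alpha = wv._solve_dual_smo(kernel, 0.1 * w.w)
        assert abs(alpha.sum() - 1.0) < 1e-8
        assert np.all(alpha >= -1e-10)
        assert np.all(alpha <= 0.1 * w.w + 1e-10)

    def test_radius_consistent_across_unbounded_svs(self, rng):
        x = rng.standard_normal((40, 5))
        m = wv.train_wsvdd(wv.TrainingSet(x), C=0.2, sigma=2.0)
        xn = (x - x.mean(0)) / x.std(0)
        kernel = wv.rbf_kernel_matrix(xn, xn, 2.0)
        alpha = wv._solve_dual_smo(kernel, np.full(40, 0.2))
        eps = 1e-6 * 0.2
        interior = (alpha > eps) & (alpha < 0.2 - eps)
        offset = alpha @ kernel @ alpha
        radii = np.diag(kernel)[interior] - 2 * (kernel @ alpha)[interior] + offset
        assert interior.sum() >= 2
        assert np.ptp(radii) < 1e-6

    def test_low_confidence_outlier_pinned_at_box(self, rng):
        inliers = rng.standard_normal((20, 3))
        outlier = np.full((1, 3), 8.0)
        x = np.vstack([inliers, outlier])
        w_vec = np.ones(21)
        w_vec[-1] = 0.05
        m_weighted = wv.train_wsvdd(
            wv.TrainingSet(x), wv.ConfidenceVector(w_vec), C=1.0, sigma=2.0, normalize=False
        )
        m_unit = wv.train_wsvdd(wv.TrainingSet(x), C=1.0, sigma=2.0, normalize=False)
        kernel = wv.rbf_kernel_matrix(x, x, 2.0)
        alpha_w = wv._solve_dual_smo(kernel, 1.0 * w_vec)
        assert alpha_w[-1] == pytest.approx(0.05, abs=1e-9)  # pinned at C * w
        assert m_weighted.r_squared < m_unit.r_squared

    def test_lowering_confidence_never_raises_alpha(self, rng):
        x = np.vstack([rng.standard_normal((15, 2)), [[6.0, 6.0]]])
        kernel = wv.rbf_kernel_matrix(x, x, 1.5)
        alphas = []
        for w_out in [1.0, 0.8, 0.6, 0.4, 0.2]:
            upper = np.ones(16)
            upper[-1] = w_out
            alphas.append(wv._solve_dual_smo(kernel, 0.6 * upper)[-1])
        assert all(a2 <= a1 + 1e-10 for a1, a2 in zip(alphas, alphas[1:]))

    def test_infeasible_box_rejected(self):
        x = np.random.default_rng(0).standard_normal((5, 2))
        with pytest.raises(ValueError, match="infeasible"):
            wv.train_wsvdd(wv.TrainingSet(x), C=0.1, sigma=1.0)


class TestDecide:
    @pytest.fixture(scope="class")
    def toy_model(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((30, 2))
        return x, wv.train_wsvdd(wv.TrainingSet(x), C=0.3, sigma=1.5, normalize=False)

    def test_unbounded_sv_on_boundary_inside(self, toy_model):
        x, m = toy_model
        eps = 1e-6 * m.C
        for sv, a in zip(m.support_vectors, m.alphas):
            if eps < a < m.C - eps:
                assert wv.decide(m, sv) == 1
                assert abs(wv.decision_value(m, sv)) < 1e-6

    def test_far_point_outside(self, toy_model):
        _, m = toy_model
        assert wv.decide(m, np.array([50.0, -40.0])) == -1

    def test_sign_matches_explicit_expansion(self, toy_model):
        x, m = toy_model
        kernel = wv.rbf_kernel_matrix(x, x, 1.5)
        alpha = wv._solve_dual_smo(kernel, np.full(30, 0.3))
        rng = np.random.default_rng(9)
        grid = rng.uniform(-3, 3, size=(100, 2))
        for z in grid:
            kz = wv.rbf_kernel_matrix(z[None, :], x, 1.5)[0]
            # ||phi(z) - o||^2 = K(z,z) - 2 sum a_i K(z,x_i) + a'Ka
            dist2 = 1.0 - 2 * alpha @ kz + alpha @ kernel @ alpha
            expected = 1 if m.r_squared - dist2 >= 0 else -1
            assert wv.decide(m, z) == expected

    def test_dimension_mismatch(self, toy_model):
        _, m = toy_model
        with pytest.raises(ValueError):
            wv.decide(m, np.ones(5))


class TestSerialization:
    def test_roundtrip(self, tmp_path, rng):
        x, _ = gen_feature_set(20, seed=rng)
        m = wv.fit_wsvdd(x, C=0.2)
        path = tmp_path / "model.json"
        m.save(path)
        m2 = wv.WSVDDModel.load(path)
        z = rng.standard_normal(24)
        assert wv.decision_value(m, z) == pytest.approx(wv.decision_value(m2, z), rel=1e-12)
        assert m2.r_squared == m.r_squared


class TestLabelNoiseRobustness:
    def test_weighted_beats_classical_under_contamination(self):
        from pigsound.experiments import label_noise_experiment

        res = label_noise_experiment(n_reps=8, seed=3)
        gaps = res.gaps
        # weighted at least matches classical wherever labels are corrupted
        assert np.all(gaps[1:] >= -0.5)  # percent; sampling slack at 8 reps
        assert np.all(gaps[2:] > 0)
        # both variants degrade as contamination grows (allowing sampling noise)
        assert np.all(np.diff(res.weighted_accuracy[1:]) < 2.0)
        assert np.all(np.diff(res.classical_accuracy[1:]) < 2.0)
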