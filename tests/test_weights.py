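import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maic import (
    ConvergenceError,
    UsageError,
    build_moment_matrix,
    check_equivalence,
    effective_sample_size,
    entropy_distance,
    objective_eb,
    objective_mom,
    random_moment_instance,
    solve_weights,
)

from conftest import make_ipd, make_target, qp_feasible_weights


def random_Z(n, p, seed):
    """Centered matrix of a feasible instance (every column straddles 0)."""
    return random_moment_instance(n, p, seed=seed).Z


class TestObjectives:
    def test_mom_at_zero_alpha(self):
        Z = random_Z(30, 3, seed=0)
        value, grad = objective_mom(np.zeros(3), Z)
        assert value == pytest.approx(30.0)
        np.testing.assert_allclose(grad, Z.sum(axis=0), rtol=1e-12)

    def test_mom_scalar_hand_example(self):
        Z = np.array([[-1.0], [1.0]])
        value, grad = objective_mom([0.5], Z)
        assert value == pytest.approx(np.exp(-0.5) + np.exp(0.5), rel=1e-12)
        assert grad[0] == pytest.approx(-np.exp(-0.5) + np.exp(0.5), rel=1e-12)

    def test_eb_at_zero_alpha_uniform_base_is_zero(self):
        Z = random_Z(25, 2, seed=1)
        value, _ = objective_eb(np.zeros(2), Z)
        assert value == pytest.approx(0.0, abs=1e-14)

    def test_eb_base_weight_hand_example(self):
        Z = np.array([[-1.0], [1.0]])
        value, _ = objective_eb([1.0], Z, base_weights=[0.9, 0.1])
        expected = np.log(0.9 * np.exp(-1.0) + 0.1 * np.exp(1.0))
        assert value == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("which", ["mom", "eb"])
    def test_gradients_match_central_finite_differences(self, which):
        rng = np.random.default_rng(42)
        Z = random_Z(40, 4, seed=7)
        b = rng.uniform(0.5, 1.5, 40)
        b /= b.sum()
        f = (
            (lambda a: objective_mom(a, Z))
            if which == "mom"
            else (lambda a: objective_eb(a, Z, b))
        )
        for _ in range(5):
            alpha = rng.normal(scale=0.5, size=4)
            _, grad = f(alpha)
            h = 1e-6
            for j in range(4):
                e = np.zeros(4)
                e[j] = h
                fd = (f(alpha + e)[0] - f(alpha - e)[0]) / (2 * h)
                assert grad[j] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_log_identity_between_objectives(self):
        """H_EB(α) = log H_MM(α) − log N for every α, uniform base."""
        rng = np.random.default_rng(0)
        worst = 0.0
        for k in range(100):
            n, p = int(rng.integers(5, 200)), int(rng.integers(1, 6))
            Z = rng.normal(size=(n, p))
            alpha = rng.normal(scale=0.7, size=p)
            h_mm, _ = objective_mom(alpha, Z)
            h_eb, _ = objective_eb(alpha, Z)
            worst = max(worst, abs(h_eb - (np.log(h_mm) - np.log(n))))
        assert worst < 1e-12

    def test_non_finite_alpha_rejected(self):
        with pytest.raises(UsageError):
            objective_mom([np.nan], np.array([[1.0], [2.0]]))

    def test_unnormalized_base_weights_rejected(self):
        with pytest.raises(UsageError, match="sum to 1"):
            objective_eb([0.0], np.array([[1.0], [-1.0]]), base_weights=[1.0, 2.0])


class TestDiagnostics:
    def test_entropy_distance_identity_case(self):
        u = np.full(4, 0.25)
        assert entropy_distance(u, u) == 0.0

    def test_entropy_distance_hand_example(self):
        val = entropy_distance([0.3, 0.7], [0.5, 0.5])
        expected = 0.3 * np.log(0.6) + 0.7 * np.log(1.4)
        assert val == pytest.approx(expected, rel=1e-12)
        assert val == pytest.approx(0.08228, abs=5e-6)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_entropy_distance_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        w = rng.uniform(0.01, 1.0, n)
        b = rng.uniform(0.01, 1.0, n)
        assert entropy_distance(w / w.sum(), b / b.sum()) >= 0.0

    def test_entropy_distance_requires_normalized_inputs(self):
        with pytest.raises(UsageError):
            entropy_distance([0.3, 0.8], [0.5, 0.5])

    def test_ess_uniform(self):
        assert effective_sample_size(np.full(10, 0.1)) == pytest.approx(10.0)

    def test_ess_hand_example(self):
        assert effective_sample_size([0.3, 0.7]) == pytest.approx(
            1 / (0.09 + 0.49), rel=1e-12
        )

    def test_ess_rescaling_invariant(self):
        w = np.array([0.2, 0.3, 0.5])
        assert effective_sample_size(w) == pytest.approx(
            effective_sample_size(17.0 * w), rel=1e-12
        )

    def test_ess_limit_one_dominant_weight(self):
        w = np.array([1.0 - 1e-9, 1e-9])
        assert effective_sample_size(w) == pytest.approx(1.0, abs=1e-8)


class TestSolve:
    def test_already_balanced_gives_uniform_weights(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        mm = build_moment_matrix(
            make_ipd({"x": x}), make_target({"x": float(x.mean())})
        )
        sol = solve_weights(mm)
        np.testing.assert_allclose(sol.alpha, 0.0, atol=1e-10)
        np.testing.assert_allclose(sol.weights, 1 / 20, atol=1e-10)
        assert sol.converged

    def test_closed_form_binary_instance(self, micro_ipd, micro_target):
        mm = build_moment_matrix(micro_ipd, micro_target)
        for method in ("method_of_moments", "entropy_balancing"):
            sol = solve_weights(mm, method=method)
            np.testing.assert_allclose(sol.weights, [0.3, 0.7], atol=1e-10)
            assert sol.alpha[0] == pytest.approx(np.log(7 / 3), abs=1e-10)

    def test_dual_route_weights_agree(self):
        for seed in range(5):
            Z = random_Z(100, 3, seed=seed)
            w_mom = solve_weights(Z, method="method_of_moments").weights
            w_eb = solve_weights(Z, method="entropy_balancing").weights
            assert np.max(np.abs(w_mom - w_eb)) < 1e-8

    def test_moment_balance_at_convergence(self):
        for seed in (3, 4):
            mm = random_moment_instance(150, 4, seed=seed)
            sol = solve_weights(mm)
            assert np.max(np.abs(sol.weights @ mm.Z)) < 1e-8

    def test_mom_rejects_nonuniform_base_weights(self):
        Z = random_Z(10, 1, seed=5)
        b = np.linspace(1, 2, 10)
        with pytest.raises(UsageError, match="entropy_balancing"):
            solve_weights(Z, method="method_of_moments", base_weights=b)

    def test_base_weight_consistency(self):
        """Targets at the base-weighted sample moments return the base
        weights themselves (α̂ = 0): the solver preserves a prior
        adjustment when no further tilting is needed."""
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        b = rng.uniform(0.5, 2.0, size=50)
        b /= b.sum()
        mm = build_moment_matrix(
            make_ipd({"x": x}), make_target({"x": float(b @ x)})
        )
        sol = solve_weights(mm, base_weights=b)
        np.testing.assert_allclose(sol.weights, b, atol=1e-8)
        np.testing.assert_allclose(sol.alpha, 0.0, atol=1e-8)

    def test_base_weight_scale_invariance(self):
        Z = random_Z(40, 2, seed=6)
        rng = np.random.default_rng(10)
        b = rng.uniform(0.5, 2.0, size=40)
        w1 = solve_weights(Z, base_weights=b).weights
        w2 = solve_weights(Z, base_weights=123.0 * b).weights
        np.testing.assert_allclose(w1, w2, atol=1e-13)

    def test_uniform_base_weights_recover_standard_solution(self):
        Z = random_Z(60, 2, seed=8)
        default = solve_weights(Z).weights
        explicit = solve_weights(Z, base_weights=np.full(60, 1 / 60)).weights
        np.testing.assert_array_equal(default, explicit)

    def test_nonconvergence_raises_with_best_iterate(self):
        Z = random_Z(50, 3, seed=11)
        with pytest.raises(ConvergenceError, match="poor overlap") as exc_info:
            solve_weights(Z, max_iter=0)
        sol = exc_info.value.solution
        assert sol is not None and not sol.converged
        np.testing.assert_allclose(sol.alpha, 0.0)

    def test_weights_sum_to_one(self):
        for seed in range(3):
            sol = solve_weights(random_Z(35, 2, seed=seed))
            assert abs(sol.weights.sum() - 1.0) < 1e-12
            assert np.all(sol.weights > 0)

    @pytest.mark.parametrize("method", ["method_of_moments", "entropy_balancing"])
    def test_midpoint_convexity_along_random_segments(self, method):
        Z = random_Z(30, 3, seed=12)
        f = (
            (lambda a: objective_mom(a, Z)[0])
            if method == "method_of_moments"
            else (lambda a: objective_eb(a, Z)[0])
        )
        rng = np.random.default_rng(13)
        for _ in range(20):
            a1 = rng.normal(scale=0.5, size=3)
            a2 = rng.normal(scale=0.5, size=3)
            mid = f((a1 + a2) / 2)
            assert mid <= (f(a1) + f(a2)) / 2 + 1e-10 * (1 + abs(mid))


class TestEntropyOptimality:
    def test_solved_weights_beat_least_squares_oracle(self):
        """Among weight vectors satisfying the same moment constraints, the
        solved weights have the smallest entropy distance from uniform —
        checked against the closed-form constrained least-squares vector."""
        checked = 0
        for seed in range(12):
            mm = random_moment_instance(80, 3, seed=100 + seed)
            w_qp = qp_feasible_weights(mm.Z)
            if np.any(w_qp <= 0):
                continue
            w = solve_weights(mm).weights
            n = mm.n
            uniform = np.full(n, 1.0 / n)
            assert entropy_distance(w, uniform) <= (
                entropy_distance(w_qp / w_qp.sum(), uniform) + 1e-12
            )
            checked += 1
        assert checked >= 5


class TestCheckEquivalence:
    def test_identity_and_weight_agreement(self):
        mm = random_moment_instance(200, 3, seed=21)
        rep = check_equivalence(mm, seed=21)
        assert rep.passed
        assert rep.max_identity_gap < 1e-12
        assert rep.max_weight_discrepancy < 1e-8

    def test_balanced_sample_gives_uniform_from_both_routes(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=30)
        mm = build_moment_matrix(
            make_ipd({"x": x}), make_target({"x": float(x.mean())})
        )
        rep = check_equivalence(mm, seed=22)
        assert rep.passed
        np.testing.assert_allclose(rep.alpha_mom, 0.0, atol=1e-10)
        np.testing.assert_allclose(rep.alpha_eb, 0.0, atol=1e-10)
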