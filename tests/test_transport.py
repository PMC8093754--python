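import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecotransport as et
from ecotransport.netio import ValidationError
from ecotransport.transport import FeasibilityError

from _oracles import direct_transport_maximum, kantorovich_lp, random_instance

E = np.e
HALF = np.array([0.5, 0.5])


def both_fixed(M, a, b, lam=1.0, **kw):
    return et.solve(
        et.TransportProblem(et.UtilityMatrix(np.asarray(M, dtype=float)),
                            lam=lam, mode="both-fixed",
                            a=np.asarray(a, float), b=np.asarray(b, float)),
        **kw,
    )


class TestFunctionals:
    @pytest.mark.parametrize(
        "M, Q, expected",
        [
            ([[1, 1], [1, 1]], [[0.3, 0.2], [0.1, 0.4]], 1.0),
            ([[1, 0], [0, 1]], [[0.5, 0], [0, 0.5]], 1.0),
            ([[2, -1], [0, 1]], [[0.25] * 2] * 2, 0.5),
        ],
    )
    def test_average_utility(self, M, Q, expected):
        got = et.average_utility(et.UtilityMatrix(np.array(M, float)),
                                 np.array(Q, float))
        assert got == pytest.approx(expected)

    def test_average_utility_forbidden_cells_contribute_zero(self):
        M = et.UtilityMatrix(np.array([[1.0, -np.inf], [0.0, 1.0]]))
        Q = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert et.average_utility(M, Q) == pytest.approx(1.0)

    def test_average_utility_shape_mismatch(self):
        with pytest.raises(ValidationError):
            et.average_utility(et.UtilityMatrix(np.ones((2, 3))), np.ones((2, 2)) / 4)

    @pytest.mark.parametrize(
        "Q, expected",
        [
            (np.full((2, 3), 1 / 6), np.log(6)),
            (np.array([[1.0, 0.0], [0.0, 0.0]]), 0.0),
            (np.array([[0.5, 0.5]]), np.log(2)),
        ],
    )
    def test_entropy(self, Q, expected):
        assert et.entropy(Q) == pytest.approx(expected, abs=1e-12)

    def test_entropy_rejects_negative(self):
        with pytest.raises(ValidationError):
            et.entropy(np.array([[1.5, -0.5]]))

    @pytest.mark.parametrize(
        "M, Q, lam, expected",
        [
            ([[0, 0], [0, 0]], [[0.25] * 2] * 2, 1.0, np.log(4)),
            ([[1, 0], [0, 1]], [[0.5, 0], [0, 0.5]], 1.0, 1 + np.log(2)),
            ([[1, 0], [0, 1]], [[0.25] * 2] * 2, 1.0, 0.5 + np.log(4)),
        ],
    )
    def test_objective(self, M, Q, lam, expected):
        got = et.objective(et.UtilityMatrix(np.array(M, float)),
                           np.array(Q, float), lam)
        assert got == pytest.approx(expected)

    def test_objective_requires_positive_lam(self):
        with pytest.raises(ValidationError):
            et.objective(et.UtilityMatrix(np.zeros((2, 2))),
                         np.full((2, 2), 0.25), 0.0)

    @pytest.mark.parametrize(
        "P, Q, expected",
        [
            ([[0.25] * 2] * 2, [[0.25] * 2] * 2, 0.0),
            ([[0.25] * 2] * 2, [[0.4, 0.1], [0.1, 0.4]],
             0.5 * np.log(0.25 ** 2 / (0.4 * 0.1))),
            ([[1.0, 0.0]], [[0.5, 0.5]], np.log(2)),
        ],
    )
    def test_kl_divergence(self, P, Q, expected):
        got = et.kl_divergence(np.array(P, float), np.array(Q, float))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got >= 0

    def test_kl_absolute_continuity(self):
        assert et.kl_divergence(np.array([[0.5, 0.5]]),
                                np.array([[1.0, 0.0]])) == np.inf


class TestSolveExamples:
    def test_constant_utility_gives_neutral_coupling(self, rng):
        a = rng.dirichlet(np.ones(4))
        b = rng.dirichlet(np.ones(3))
        for lam in (0.0, 1.0, 7.0):
            sol = both_fixed(np.full((4, 3), 2.5), a, b, lam=lam)
            np.testing.assert_allclose(sol.coupling.matrix, np.outer(a, b),
                                       atol=1e-12)

    def test_lambda_zero_is_exact_outer_product(self, rng):
        M, a, b = random_instance(rng, 5, 4)
        sol = both_fixed(M, a, b, lam=0.0)
        assert np.array_equal(sol.coupling.matrix, np.outer(a, b))

    def test_symmetric_two_by_two(self):
        sol = both_fixed([[1, 0], [0, 1]], HALF, HALF)
        q = 0.5 * E / (1 + E)
        np.testing.assert_allclose(
            sol.coupling.matrix, [[q, 0.5 - q], [0.5 - q, q]], atol=1e-9
        )

    def test_forbidden_link_forces_support(self):
        M = np.array([[0.0, -np.inf], [0.0, 0.0]])
        sol = both_fixed(M, HALF, HALF, max_iter=400_000)
        np.testing.assert_allclose(
            sol.coupling.matrix, [[0.5, 0.0], [0.0, 0.5]], atol=1e-5
        )
        assert sol.coupling.matrix[0, 1] == 0.0  # exact zero, not epsilon

    def test_free_mode_softmax(self):
        M = et.UtilityMatrix(np.array([[np.log(3), 0.0], [0.0, 0.0]]))
        sol = et.solve(et.TransportProblem(M, lam=1.0, mode="free"))
        np.testing.assert_allclose(
            sol.coupling.matrix, [[0.5, 1 / 6], [1 / 6, 1 / 6]], atol=1e-12
        )
        assert sol.free_normalizer == pytest.approx(1 / 6)

    def test_row_fixed_closed_form(self, rng):
        M, a, _ = random_instance(rng, 3, 4)
        sol = et.solve(et.TransportProblem(et.UtilityMatrix(M), lam=2.0,
                                           mode="row-fixed", a=a))
        expected = a[:, None] * np.exp(2 * M) / np.exp(2 * M).sum(axis=1,
                                                                  keepdims=True)
        np.testing.assert_allclose(sol.coupling.matrix, expected, atol=1e-12)

    def test_col_fixed_closed_form(self, rng):
        M, _, b = random_instance(rng, 3, 4)
        sol = et.solve(et.TransportProblem(et.UtilityMatrix(M), lam=0.7,
                                           mode="col-fixed", b=b))
        expected = b[None, :] * np.exp(0.7 * M) / np.exp(0.7 * M).sum(axis=0,
                                                                      keepdims=True)
        np.testing.assert_allclose(sol.coupling.matrix, expected, atol=1e-12)

    def test_zero_abundance_species_dropped_and_reinserted(self, rng):
        M, a, b = random_instance(rng, 4, 3)
        a = np.array([0.0, *(a[1:] / a[1:].sum())])
        sol = both_fixed(M, a, b)
        assert np.all(sol.coupling.matrix[0] == 0)
        np.testing.assert_allclose(sol.coupling.matrix.sum(axis=0), b, atol=1e-8)

    def test_infeasible_forbidden_pattern_detected(self):
        M = np.array([[-np.inf, 0.0], [0.0, -np.inf]])
        with pytest.raises(FeasibilityError):
            both_fixed(M, [0.7, 0.3], HALF)

    def test_fully_forbidden_row_detected(self):
        M = np.array([[-np.inf, -np.inf], [0.0, 0.0]])
        with pytest.raises(FeasibilityError):
            both_fixed(M, HALF, HALF)


class TestSolveProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(2, 8),
        m=st.integers(2, 8),
        lam=st.sampled_from([0.1, 1.0, 10.0]),
    )
    def test_marginal_feasibility(self, seed, n, m, lam):
        rng = np.random.default_rng(seed)
        M, a, b = random_instance(rng, n, m)
        sol = both_fixed(M, a, b, lam=lam)
        assert sol.converged
        assert np.abs(sol.coupling.matrix.sum(axis=1) - a).max() < 1e-8
        assert np.abs(sol.coupling.matrix.sum(axis=0) - b).max() < 1e-8

    def test_log_coupling_is_rank_one_shift_of_utility(self, rng):
        M, a, b = random_instance(rng, 5, 6)
        sol = both_fixed(M, a, b, lam=1.7)
        R = np.log(sol.coupling.matrix) - 1.7 * M
        centered = R - R.mean(axis=1, keepdims=True) \
            - R.mean(axis=0, keepdims=True) + R.mean()
        assert np.abs(centered).max() < 1e-8

    @pytest.mark.parametrize("c", [-3.0, 0.7, 100.0])
    def test_shift_invariance(self, rng, c):
        M, a, b = random_instance(rng, 4, 5)
        sol = both_fixed(M, a, b)
        shifted = both_fixed(M + c, a, b)
        np.testing.assert_allclose(sol.coupling.matrix,
                                   shifted.coupling.matrix, atol=1e-8)

    @pytest.mark.parametrize("s", [0.25, 4.0])
    def test_scale_temperature_invariance(self, rng, s):
        M, a, b = random_instance(rng, 4, 5)
        sol = both_fixed(M, a, b, lam=2.0)
        rescaled = both_fixed(s * M, a, b, lam=2.0 / s)
        np.testing.assert_allclose(sol.coupling.matrix,
                                   rescaled.coupling.matrix, atol=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_direct_numerical_maximization(self, seed):
        rng = np.random.default_rng(seed)
        M, a, b = random_instance(rng, 3, 3)
        lam = [0.5, 1.0, 2.0, 5.0][seed]
        Q_direct = direct_transport_maximum(M, a, b, lam)
        sol = both_fixed(M, a, b, lam=lam)
        assert np.abs(sol.coupling.matrix - Q_direct).max() < 1e-5

    def test_utility_monotone_entropy_antitone_in_lambda(self, rng):
        M, a, b = random_instance(rng, 5, 5)
        lams = [0.1, 0.5, 1.0, 2.0, 5.0, 10.0]
        sols = [both_fixed(M, a, b, lam=lam) for lam in lams]
        utils = [s.attained_utility for s in sols]
        ents = [s.entropy for s in sols]
        assert all(u2 >= u1 - 1e-12 for u1, u2 in zip(utils, utils[1:]))
        assert all(h2 <= h1 + 1e-12 for h1, h2 in zip(ents, ents[1:]))

    def test_kantorovich_limit(self, rng):
        M, a, b = random_instance(rng, 3, 3)
        lp_value = kantorovich_lp(M, a, b)
        sol = both_fixed(M, a, b, lam=1000.0, max_iter=300_000)
        assert abs(sol.attained_utility - lp_value) < 1e-3

    def test_free_mode_consistent_with_fixed_modes(self, rng):
        M, _, _ = random_instance(rng, 4, 3)
        free = et.solve(et.TransportProblem(et.UtilityMatrix(M), lam=1.3,
                                            mode="free"))
        a_free = free.coupling.matrix.sum(axis=1)
        b_free = free.coupling.matrix.sum(axis=0)
        row = et.solve(et.TransportProblem(et.UtilityMatrix(M), lam=1.3,
                                           mode="row-fixed", a=a_free))
        col = et.solve(et.TransportProblem(et.UtilityMatrix(M), lam=1.3,
                                           mode="col-fixed", b=b_free))
        np.testing.assert_allclose(free.coupling.matrix, row.coupling.matrix,
                                   atol=1e-10)
        np.testing.assert_allclose(free.coupling.matrix, col.coupling.matrix,
                                   atol=1e-10)

    def test_solution_reports_consistent_functionals(self, rng):
        M, a, b = random_instance(rng, 4, 4)
        sol = both_fixed(M, a, b, lam=2.0)
        assert sol.attained_utility == pytest.approx(
            et.average_utility(et.UtilityMatrix(M), sol.coupling))
        assert sol.entropy == pytest.approx(et.entropy(sol.coupling))


class TestProblemValidation:
    def test_marginal_required_by_mode(self):
        M = et.UtilityMatrix(np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            et.TransportProblem(M, mode="both-fixed", a=HALF)  # b missing
        with pytest.raises(ValidationError):
            et.TransportProblem(M, mode="free", a=HALF)  # a must be absent

    def test_marginal_must_be_simplex(self):
        M = et.UtilityMatrix(np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            et.TransportProblem(M, mode="both-fixed",
                                a=np.array([0.6, 0.6]), b=HALF)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValidationError):
            et.TransportProblem(et.UtilityMatrix(np.zeros((2, 2))), lam=-1.0,
                                mode="free")
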