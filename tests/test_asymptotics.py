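"""Delta-method machinery: flattening, covariance, gradients, z-test."""

import math

import numpy as np
import pytest

from ordspear._batch import batch_rho_avar
from ordspear.asymptotics import (
    FlatProbVector,
    asymptotic_variance,
    flatten,
    grad_A,
    grad_B,
    grad_rho,
    multinomial_cov,
    unflatten,
    z_test,
)
from ordspear.core import CountTable, ProbabilityTable, population_rho
from ordspear.errors import DegenerateMarginError, ValidationError

from conftest import random_interior_table, random_prob_table


def finite_difference(fn, table, step=1e-6):
    """Central finite differences of fn(unflatten(.)) at the flattened table.

    Independent oracle for the analytic gradients: perturbs one free cell
    at a time, absorbing the change in the implied last cell.
    """
    v = flatten(table)
    base = v.hvec
    g = np.empty(len(base))
    for k in range(len(base)):
        up, dn = base.copy(), base.copy()
        up[k] += step
        dn[k] -= step
        g[k] = (
            fn(unflatten(FlatProbVector(up, v.I, v.J)))
            - fn(unflatten(FlatProbVector(dn, v.I, v.J)))
        ) / (2 * step)
    return g


def _A(table):
    h = table.h
    p, q = h.sum(axis=1), h.sum(axis=0)
    vF = 2 * np.cumsum(p) - p
    vG = 2 * np.cumsum(q) - q
    return float(vF @ h @ vG)


def _B(table):
    p, q = table.h.sum(axis=1), table.h.sum(axis=0)
    return math.sqrt((1 - np.sum(p**3)) * (1 - np.sum(q**3)))


class TestFlattening:
    def test_definition_2x2(self):
        v = flatten(ProbabilityTable(np.array([[0.4, 0.1], [0.1, 0.4]])))
        assert np.allclose(v.hvec, [0.4, 0.1, 0.1])
        assert v.h_last == pytest.approx(0.4)

    def test_roundtrip_and_length(self, rng):
        for _ in range(10):
            t = random_prob_table(rng)
            v = flatten(t)
            assert len(v.hvec) == t.I * t.J - 1
            assert np.allclose(unflatten(v).h, t.h, atol=1e-15)

    def test_negative_implied_last_cell_rejected(self):
        with pytest.raises(ValidationError, match="last cell"):
            FlatProbVector(np.array([0.7, 0.4, 0.2]), 2, 2)


class TestMultinomialCov:
    def test_uniform_2x2_closed_form(self):
        s = multinomial_cov(flatten(ProbabilityTable(np.full((2, 2), 0.25))))
        assert np.allclose(np.diag(s), 0.1875)
        off = s[~np.eye(3, dtype=bool)]
        assert np.allclose(off, -0.0625)

    def test_row_sum_identity(self, rng):
        # (diag(h) - h h') 1 = h (1 - sum h) = h * h_last
        for _ in range(10):
            v = flatten(random_prob_table(rng))
            s = multinomial_cov(v)
            assert np.allclose(s @ np.ones(len(v.hvec)), v.hvec * v.h_last,
                               atol=1e-14)
            assert np.allclose(s, s.T)
            assert np.all(np.linalg.eigvalsh(s) > -1e-12)

    def test_matches_empirical_indicator_covariance(self, rng):
        t = ProbabilityTable(np.array([[0.5, 0.2], [0.2, 0.1]]))
        v = flatten(t)
        m = 200_000
        draws = rng.multinomial(1, np.append(v.hvec, v.h_last), size=m)[:, :3]
        emp = np.cov(draws.T)
        # entrywise MC standard error of a covariance of indicators is
        # below sqrt(1/m); allow 4 of them
        assert np.max(np.abs(emp - multinomial_cov(v))) < 4 / math.sqrt(m)


class TestGradients:
    def test_grad_A_matches_finite_differences(self, rng):
        worst = 0.0
        for _ in range(100):
            t = random_interior_table(rng, max_dim=5)
            worst = max(worst, np.max(np.abs(grad_A(t) - finite_difference(_A, t))))
        assert worst < 1e-6

    def test_grad_B_matches_finite_differences(self, rng):
        worst = 0.0
        for _ in range(100):
            t = random_interior_table(rng, max_dim=5)
            worst = max(worst, np.max(np.abs(grad_B(t) - finite_difference(_B, t))))
        assert worst < 1e-6

    def test_grad_rho_matches_finite_differences(self, rng):
        worst = 0.0
        for _ in range(100):
            t = random_interior_table(rng, max_dim=5)
            fd = finite_difference(population_rho, t)
            worst = max(worst, np.max(np.abs(grad_rho(t) - fd)))
        assert worst < 1e-6

    def test_grad_A_transpose_symmetry(self, rng):
        h = np.random.default_rng(3).dirichlet(np.ones(9)).reshape(3, 3)
        h = (h + h.T) / 2
        t = ProbabilityTable(h / h.sum())
        g = np.append(grad_A(t), 0.0).reshape(3, 3)
        assert np.allclose(g, g.T, atol=1e-12)

    def test_grad_B_vanishes_for_uniform_margins(self):
        t = ProbabilityTable(np.full((3, 3), 1 / 9))
        assert np.allclose(grad_B(t), 0.0, atol=1e-14)

    def test_grad_B_last_row_depends_only_on_column_margin(self, rng):
        # for r = I the p-bracket vanishes, leaving (3B/2)(q_J^2-q_s^2)/bq
        t = random_interior_table(rng, max_dim=4, min_dim=3)
        q = t.h.sum(axis=0)
        bq = 1 - np.sum(q**3)
        g = np.append(grad_B(t), 0.0).reshape(t.I, t.J)
        expected = 1.5 * _B(t) * (q[-1] ** 2 - q[:-1] ** 2) / bq
        assert np.allclose(g[-1, :-1], expected, atol=1e-12)

    def test_degenerate_margin_raises(self):
        h = np.zeros((2, 2))
        h[0] = [0.4, 0.6]
        with pytest.raises(DegenerateMarginError):
            grad_B(ProbabilityTable(h))


class TestAsymptoticVariance:
    def test_one_over_n_scaling(self, rng):
        t = random_prob_table(rng)
        a = asymptotic_variance(t, n=100)
        b = asymptotic_variance(t, n=200)
        assert a.variance == pytest.approx(2 * b.variance, rel=1e-14)
        assert a.avar == pytest.approx(b.avar, rel=1e-14)

    def test_count_table_uses_plug_in_proportions(self):
        ct = CountTable(np.array([[30, 10], [10, 30]]))
        dv = asymptotic_variance(ct)
        assert dv.n == 80
        dv2 = asymptotic_variance(ct.to_probability(), n=80)
        assert dv.variance == pytest.approx(dv2.variance, rel=1e-14)

    def test_quadratic_form_consistency(self, rng):
        t = random_prob_table(rng)
        dv = asymptotic_variance(t, n=50)
        assert dv.avar == pytest.approx(
            float(dv.gradient @ dv.sigma @ dv.gradient), abs=1e-14
        )

    def test_batch_kernel_agrees_with_scalar_path(self, rng):
        counts = rng.multinomial(
            120, np.full(9, 1 / 9), size=8
        ).reshape(8, 3, 3)
        rho_b, avar_b = batch_rho_avar(counts)
        for k in range(8):
            ct = CountTable(counts[k])
            dv = asymptotic_variance(ct)
            assert avar_b[k] == pytest.approx(dv.avar, abs=1e-12)

    def test_probability_table_requires_n(self, rng):
        with pytest.raises(ValidationError, match="n is required"):
            asymptotic_variance(random_prob_table(rng))


class TestZTest:
    def test_null_equals_estimate(self):
        r = z_test(0.4, 0.4, 0.01)
        assert r.z == 0.0 and r.p_value == pytest.approx(1.0)
        assert not r.reject

    def test_hand_arithmetic(self):
        r = z_test(0.5, 0.3, 0.01)
        assert r.z == pytest.approx(2.0)
        assert r.p_value == pytest.approx(0.0455, abs=5e-4)
        assert r.reject

    def test_ci_brackets_estimate_and_matches_se(self):
        r = z_test(0.24, 0.0, 0.0009369)  # SE ~ 0.0306 -> CI ~ (0.18, 0.30)
        assert r.ci_low < r.rho_hat < r.ci_high
        assert r.ci_low == pytest.approx(0.18, abs=0.01)
        assert r.ci_high == pytest.approx(0.30, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            z_test(0.5, 0.0, 0.0)
        with pytest.raises(ValidationError):
            z_test(0.5, 0.0, 0.1, alpha=1.5)
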