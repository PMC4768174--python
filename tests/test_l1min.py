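import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netinfer import l1min, netsim
from netinfer.deconv import build_linear_system, nd_closed_form


def kkt_certificate(A, c, z, eps, tol=1e-5):
    """Independent global-optimality check for min ||z||_1 s.t. ||Az-c|| <= eps.

    Duality/KKT: either z = 0 and the zero vector is feasible, or the
    constraint is active and A^T r is anti-aligned with sign(z) on the
    support with no off-support coordinate exceeding the common multiplier.
    """
    r = A @ z - c
    if not np.any(np.abs(z) > tol):
        return np.linalg.norm(c) <= eps + tol
    if abs(np.linalg.norm(r) - eps) > max(1e-6, tol * eps):
        return False
    v = A.T @ r
    supp = np.abs(z) > tol
    ratios = -np.sign(z[supp]) / v[supp]
    if np.any(~np.isfinite(ratios)) or np.any(ratios <= 0):
        return False
    mu = np.median(ratios)
    if np.max(np.abs(mu * v[supp] + np.sign(z[supp]))) > 1e-3:
        return False
    return np.all(mu * np.abs(v[~supp]) <= 1 + 1e-3)


class TestSolveRow:
    def test_soft_threshold_geometry(self):
        s, status = l1min.solve_row(np.eye(2), np.array([1.0, 0.0]), 0.5)
        assert status == "optimal"
        assert np.allclose(s, [0.5, 0.0], atol=1e-8)

    def test_zero_when_budget_covers_c(self):
        s, _ = l1min.solve_row(np.eye(2), np.array([1.0, 0.0]), 1.5)
        assert np.allclose(s, 0.0)

    def test_equality_case_unique_point(self):
        rng = np.random.default_rng(0)
        B = np.eye(5) + 0.1 * rng.standard_normal((5, 5))
        c = rng.standard_normal(5)
        s, _ = l1min.solve_row(B, c, 0.0)
        assert np.allclose(s, np.linalg.solve(B.T, c), atol=1e-7)

    def test_negative_eps_rejected(self):
        with pytest.raises(ValueError):
            l1min.solve_row(np.eye(2), np.ones(2), -0.1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), eps_scale=st.floats(0.05, 0.9))
    def test_feasibility_and_kkt_optimality(self, seed, eps_scale):
        """Every returned row is feasible and passes the duality certificate."""
        rng = np.random.default_rng(seed)
        n = 6
        B = np.eye(n) + 0.3 * rng.standard_normal((n, n))
        c = rng.standard_normal(n)
        eps = eps_scale * np.linalg.norm(c)
        s, status = l1min.solve_row(B, c, eps)
        assert status == "optimal"
        assert np.linalg.norm(B.T @ s - c) <= eps + 1e-6
        assert kkt_certificate(B.T, c, s, eps)

    def test_l1_norm_monotone_in_eps(self, noisy_instance):
        S0, _, G, _ = noisy_instance
        form = build_linear_system(G)
        c = form.C[4]
        norms = []
        for eps in [0.0, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0]:
            s, _ = l1min.solve_row(form.B, c, eps)
            norms.append(np.abs(s).sum())
        assert all(a >= b - 1e-7 for a, b in zip(norms, norms[1:]))


class TestSolveMatrix:
    def test_eps_zero_equals_closed_form(self, noisy_instance):
        _, _, G, _ = noisy_instance
        form = build_linear_system(G)
        res = l1min.solve_matrix(form, l1min.BoundEstimate(np.zeros(G.n)))
        S_nd = nd_closed_form(G)
        assert np.max(np.abs(res.S_hat.S - S_nd.S)) < 1e-6

    def test_noiseless_exact_recovery(self, small_instance):
        S0, G0 = small_instance
        form = build_linear_system(G0)
        res = l1min.solve_matrix(form, l1min.BoundEstimate(np.zeros(G0.n)))
        rho = np.linalg.norm(res.S_hat.S - S0.S) / np.linalg.norm(S0.S)
        assert rho < 1e-6

    def test_zero_diagonal_flag(self, noisy_instance):
        S0, _, G, dG = noisy_instance
        form = build_linear_system(G)
        res = l1min.solve_matrix(
            form, l1min.true_bound(S0, form), zero_diagonal=True
        )
        assert not np.diag(res.S_hat.S).any()

    def test_residuals_within_budget(self, noisy_instance):
        S0, _, G, dG = noisy_instance
        form = build_linear_system(G)
        bounds = l1min.true_bound(S0, form)
        res = l1min.solve_matrix(form, bounds)
        ok = np.array(res.status) == "optimal"
        assert ok.all()
        assert np.all(res.residual_norms <= bounds.eps + 1e-6)


class TestBounds:
    def test_true_bound_noiseless_is_zero(self, small_instance):
        S0, G0 = small_instance
        b = l1min.true_bound(S0, build_linear_system(G0))
        assert np.allclose(b.eps, 0.0, atol=1e-12)

    def test_true_bound_scalar_arithmetic(self):
        S0 = netsim.DirectInfluence([[0.5]])
        form = build_linear_system(netsim.TotalInfluence([[1.1]]))
        b = l1min.true_bound(S0, form)
        assert np.isclose(b.eps[0], abs(0.5 * 2.1 - 1.1))

    def test_approx_bound_zero_noise(self, small_instance):
        _, G0 = small_instance
        b = l1min.approx_bound(G0, np.zeros((G0.n, G0.n)))
        assert np.allclose(b.eps, 0.0)

    def test_approx_bound_scalar_arithmetic(self):
        # plug-in residual |s_ref*dg - dg| with the scalar reference 0.5
        G = netsim.TotalInfluence([[1.0]])
        b = l1min.approx_bound(G, [[0.1]], S_ref=netsim.DirectInfluence([[0.5]]))
        assert np.isclose(b.eps[0], abs(0.5 * 0.1 - 0.1))
        assert np.isclose(b.gamma, 0.1)

    def test_approx_bound_tracks_true_bound(self, small_instance):
        """With an accurate reference the plug-in budget nearly equals the
        oracle budget (second-order error in the noise)."""
        S0, G0 = small_instance
        G, dG = netsim.add_noise(G0, netsim.NoiseSpec("independent", 0.01, 5))
        form = build_linear_system(G)
        bt = l1min.true_bound(S0, form)
        ba = l1min.approx_bound(G, dG)
        assert 0.8 <= ba.eps.mean() / bt.eps.mean() <= 1.25

    def test_upper_dominates_approx(self, noisy_instance):
        _, _, G, dG = noisy_instance
        ba = l1min.approx_bound(G, dG)
        bu = l1min.upper_bound(G, dG)
        assert np.all(bu.eps >= ba.eps - 1e-12)
        assert bu.kind == "upper" and ba.kind == "approx"


class TestRicErrorBound:
    def test_zero_eps(self):
        assert l1min.ric_error_bound(0.2, 0.0) == 0.0

    def test_delta_zero_constant(self):
        assert np.isclose(l1min.ric_error_bound(0.0, 1.0), 4.0)

    def test_monotone_in_delta(self):
        grid = np.linspace(0, np.sqrt(2) - 1 - 1e-6, 30)
        vals = [l1min.ric_error_bound(d, 1.0) for d in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            l1min.ric_error_bound(0.5, 1.0)


class TestHoyer:
    def test_single_nonzero(self):
        M = np.zeros((3, 3))
        M[1, 2] = 7.0
        assert np.isclose(l1min.hoyer(M), 1.0)

    def test_flat_matrix(self):
        assert np.isclose(l1min.hoyer(np.full((4, 4), 0.3)), 0.0)

    def test_hand_computed_vector(self):
        v = np.array([[3.0, 4.0]])
        expected = (np.sqrt(2) - 7.0 / 5.0) / (np.sqrt(2) - 1.0)
        assert np.isclose(l1min.hoyer(v), expected)
        assert np.isclose(l1min.hoyer(v), 0.0343, atol=1e-3)

    def test_all_zero_convention(self):
        assert l1min.hoyer(np.zeros((5, 5))) == 1.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.standard_normal((6, 6))
        perm = rng.permutation(6)
        assert np.isclose(l1min.hoyer(M), l1min.hoyer(M[perm][:, perm]))
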