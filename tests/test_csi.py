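"""CSI cost functionals, updates, and convergence behavior.

The exact-pair oracle used throughout comes from
``simulate_contrast_sources``: solving the discrete state equation for
the total field makes (w, χ) satisfy both CSI equations identically, so
costs evaluated there must vanish to machine precision.
"""

import numpy as np
import pytest
import scipy.sparse as sp

from legtomo.csi import (
    CsiState,
    InversionConfig,
    MultiplicativeRegularizer,
    backpropagation_init,
    cost_FD,
    cost_FS,
    invert,
    set_inhomogeneous_background,
    simulate_contrast_sources,
    update_chi_analytic,
    update_w_cg,
)
from legtomo.forward import assemble_operators, collect_scatter_data

from conftest import EPS_B, FREQ


@pytest.fixture(scope="module")
def exact_pair(cylinder):
    """A contrast supported inside D plus its exact (w, data) pair."""
    ops = cylinder.ops_inv
    coords = ops.mesh.nodes[ops.domain.node_indices]
    chi = np.where(np.linalg.norm(coords, axis=1) < 0.02, 0.15 - 0.05j, 0.0)
    w, data = simulate_contrast_sources(ops, chi)
    return chi, w, data


class TestCostFS:
    def test_zero_sources_give_unit_cost(self, cylinder, exact_pair):
        _, w, data = exact_pair
        assert cost_FS(np.zeros_like(w), data, cylinder.ops_inv) == pytest.approx(1.0)

    def test_exact_sources_give_zero_cost(self, cylinder, exact_pair):
        _, w, data = exact_pair
        assert cost_FS(w, data, cylinder.ops_inv) < 1e-20

    def test_half_prediction_gives_quarter_cost(self, cylinder, exact_pair):
        # data whose truth is 2× the prediction: ‖u − u/2‖²/‖u‖² = 1/4
        from dataclasses import replace

        _, w, data = exact_pair
        doubled = replace(data, u=2.0 * data.u)
        assert cost_FS(w, doubled, cylinder.ops_inv) == pytest.approx(0.25)

    def test_zero_data_rejected(self, cylinder, exact_pair):
        from dataclasses import replace

        _, w, data = exact_pair
        with pytest.raises(ZeroDivisionError):
            cost_FS(w, replace(data, u=np.zeros_like(data.u)), cylinder.ops_inv)


class TestCostFD:
    def test_exact_state_pair_vanishes(self, cylinder, exact_pair):
        chi, w, _ = exact_pair
        E_inc = cylinder.ops_inv.E_inc[cylinder.ops_inv.domain.node_indices]
        assert cost_FD(w, chi, E_inc, cylinder.ops_inv) < 1e-6

    def test_zero_sources_give_unit_cost_for_any_chi(self, cylinder, exact_pair):
        chi, w, _ = exact_pair
        E_inc = cylinder.ops_inv.E_inc[cylinder.ops_inv.domain.node_indices]
        w0 = np.zeros_like(w)
        assert cost_FD(w0, chi, E_inc, cylinder.ops_inv) == pytest.approx(1.0)
        # scaling χ rescales numerator and denominator identically
        assert cost_FD(w0, 2.0 * chi, E_inc, cylinder.ops_inv) == pytest.approx(1.0)

    def test_zero_chi_rejected(self, cylinder, exact_pair):
        _, w, _ = exact_pair
        E_inc = cylinder.ops_inv.E_inc[cylinder.ops_inv.domain.node_indices]
        with pytest.raises(ZeroDivisionError):
            cost_FD(w, np.zeros(len(w), complex), E_inc, cylinder.ops_inv)


class TestBackpropagation:
    def test_formula_against_dense_operators(self, cylinder, exact_pair):
        """w⁰ = (‖G^H u‖²/‖G G^H u‖²) G^H u, rebuilt with dense algebra."""
        _, _, data = exact_pair
        ops = cylinder.ops_inv
        I = ops.domain.size
        # dense G: receivers × domain, columns from unit contrast sources
        G = np.asarray(ops.M_S @ ops.lu.solve(
            np.asarray(ops.S_D.todense(), dtype=complex)))
        w0 = backpropagation_init(data, ops)
        for t in range(data.n_transmitters):
            g_row = G.copy()
            g_row[t, :] = 0.0  # collocated receiver excluded
            back = g_row.conj().T @ data.u[t]
            fwd = g_row @ back
            expected = (np.linalg.norm(back) ** 2 / np.linalg.norm(fwd) ** 2) * back
            assert np.allclose(w0[:, t], expected, rtol=1e-10)

    def test_zero_transmitter_stays_zero(self, cylinder, exact_pair):
        from dataclasses import replace

        _, _, data = exact_pair
        u = data.u.copy()
        u[3, :] = 0.0
        w0 = backpropagation_init(replace(data, u=u), cylinder.ops_inv)
        assert np.all(w0[:, 3] == 0.0)
        assert np.any(w0[:, 0] != 0.0)

    def test_homogeneous_in_the_data(self, cylinder, exact_pair):
        from dataclasses import replace

        _, _, data = exact_pair
        w1 = backpropagation_init(data, cylinder.ops_inv)
        w2 = backpropagation_init(replace(data, u=2.0 * data.u), cylinder.ops_inv)
        assert np.allclose(w2, 2.0 * w1)


def _state_from(chi, w, ops):
    E_inc = ops.E_inc[ops.domain.node_indices]
    return CsiState(chi=chi.copy(), w=w.copy(), E_inc=E_inc)


class TestWUpdate:
    def test_step_matches_brute_force_quadratic_minimum(self, cylinder, exact_pair):
        """One CG step from w = 0 equals the independent quadratic fit.

        The cost along the search direction is an exact quadratic in
        (Re α, Im α); sampling it at six points and solving the normal
        equations gives a brute-force minimizer to compare against.
        """
        chi, _, data = exact_pair
        ops = cylinder.ops_inv
        state = _state_from(chi, np.zeros((ops.domain.size, data.n_transmitters),
                                          complex), ops)
        E_inc = state.E_inc

        def total_cost(w):
            return (cost_FS(w, data, ops) + cost_FD(w, chi, E_inc, ops))

        new = update_w_cg(state, data, ops)
        d = new.d_prev
        t = 0  # check the first transmitter's line search
        alphas = [0.0, 1e-3, -1e-3, 1e-3j, -1e-3j, 1e-3 + 1e-3j]

        def f(a):
            w = state.w.copy()
            w[:, t] = w[:, t] + a * d[:, t]
            return total_cost(w)

        # fit f(x, y) = c + gx x + gy y + .5(hxx x² + 2hxy xy + hyy y²)
        A = []
        b = []
        for a in alphas:
            x, y = a.real, a.imag
            A.append([1.0, x, y, 0.5 * x * x, x * y, 0.5 * y * y])
            b.append(f(a))
        coef = np.linalg.solve(np.array(A), np.array(b))
        H = np.array([[coef[3], coef[4]], [coef[4], coef[5]]])
        g = np.array([coef[1], coef[2]])
        xy = -np.linalg.solve(H, g)
        alpha_bf = xy[0] + 1j * xy[1]
        w_expected = state.w[:, t] + alpha_bf * d[:, t]
        scale = np.abs(w_expected).max()
        assert np.allclose(new.w[:, t], w_expected, atol=1e-10 * scale)

    def test_cost_never_increases(self, cylinder, exact_pair):
        chi, _, data = exact_pair
        ops = cylinder.ops_inv
        w0 = backpropagation_init(data, ops)
        state = _state_from(chi, w0, ops)
        E_inc = state.E_inc
        prev = cost_FS(state.w, data, ops) + cost_FD(state.w, chi, E_inc, ops)
        for _ in range(25):
            state = update_w_cg(state, data, ops)
            cur = cost_FS(state.w, data, ops) + cost_FD(state.w, chi, E_inc, ops)
            assert cur <= prev * (1.0 + 1e-12)
            prev = cur

    def test_no_op_at_the_exact_minimum(self, cylinder, exact_pair):
        chi, w, data = exact_pair
        ops = cylinder.ops_inv
        state = _state_from(chi, w, ops)
        new = update_w_cg(state, data, ops)
        assert np.linalg.norm(new.w - w) < 1e-8 * np.linalg.norm(w)


class _FakeOps:
    """Minimal operator stand-in: M_D = identity, L ≡ 0, so the total
    field in the χ update reduces to the prescribed incident field."""

    def __init__(self, I):
        self.M_D = sp.identity(I, format="csr")

    def L_apply(self, w):
        return np.zeros_like(w)


class TestChiUpdate:
    def test_single_transmitter_hand_value(self):
        # E = 2, w = 4 → χ = (4·2)/(2·2) = 2
        state = CsiState(chi=np.zeros(1, complex),
                         w=np.array([[4.0 + 0j]]),
                         E_inc=np.array([[2.0 + 0j]]))
        out = update_chi_analytic(state, _FakeOps(1))
        assert out.chi[0] == pytest.approx(2.0)

    def test_two_transmitter_hand_value(self):
        # E = (1, 2), w = (1, 4) → χ = (1·1 + 4·2)/(1 + 4) = 1.8
        state = CsiState(chi=np.zeros(1, complex),
                         w=np.array([[1.0 + 0j, 4.0 + 0j]]),
                         E_inc=np.array([[1.0 + 0j, 2.0 + 0j]]))
        out = update_chi_analytic(state, _FakeOps(1))
        assert out.chi[0] == pytest.approx(1.8)

    def test_zero_field_node_keeps_previous_value(self):
        state = CsiState(chi=np.array([0.0j, 0.7 + 0.1j]),
                         w=np.array([[1.0 + 0j], [0.0j]]),
                         E_inc=np.array([[2.0 + 0j], [0.0j]]))
        out = update_chi_analytic(state, _FakeOps(2))
        assert out.chi[0] == pytest.approx(0.5)  # (1·2)/|2|²
        assert out.chi[1] == 0.7 + 0.1j           # zero-field node kept
        assert out.chi_flags[1] and not out.chi_flags[0]

    def test_exact_pair_is_a_fixed_point(self, cylinder, exact_pair):
        chi, w, _ = exact_pair
        ops = cylinder.ops_inv
        state = _state_from(chi, w, ops)
        out = update_chi_analytic(state, ops)
        assert np.allclose(out.chi, chi, atol=1e-12)


class TestMultiplicativeRegularization:
    def test_uniform_contrast_not_penalized(self, cylinder):
        ops = cylinder.ops_inv
        reg = MultiplicativeRegularizer(ops.mesh, ops.domain)
        chi = np.full(ops.domain.size, 0.3 - 0.1j)
        b2 = reg.weights(chi, f_d=0.01)
        assert reg.factor(chi, b2) == pytest.approx(1.0)

    def test_steering_parameter_tracks_domain_cost(self, cylinder):
        ops = cylinder.ops_inv
        reg = MultiplicativeRegularizer(ops.mesh, ops.domain)
        chi = np.zeros(ops.domain.size, complex)
        reg.weights(chi, f_d=0.1)
        d1 = reg.delta2_prev
        reg.weights(chi, f_d=0.01)
        assert reg.delta2_prev < d1

    def test_mr_reduces_total_variation_on_noisy_data(self, cylinder):
        from legtomo.forward import add_noise

        noisy = add_noise(cylinder.data, 25.0, seed=3)
        ops = cylinder.ops_inv
        tv = {}
        for mr in (False, True):
            rec = invert(noisy, ops, config=InversionConfig(
                max_iterations=192, mr=mr, tolerance=1e-12))
            reg = MultiplicativeRegularizer(ops.mesh, ops.domain)
            tv[mr] = reg.total_variation(rec.chi)
        assert tv[True] < tv[False]


class TestInvert:
    def test_exact_pair_drives_total_cost_below_1e6(self, cylinder, exact_pair):
        chi, w, data = exact_pair
        ops = cylinder.ops_inv
        E_inc = ops.E_inc[ops.domain.node_indices]
        f_csi = cost_FS(w, data, ops) + cost_FD(w, chi, E_inc, ops)
        assert f_csi < 1e-6

    def test_background_data_reconstructs_nothing(self, cylinder):
        from legtomo.forward import ScatterData

        ops = cylinder.ops_inv
        eps_bg = np.full(cylinder.mesh_fwd.num_triangles, EPS_B)
        data = collect_scatter_data(cylinder.ops_fwd, eps_bg)
        # guard: add the tiniest of numerical data so F_S is defined
        assert np.abs(data.u).max() < 1e-12
        u = data.u + 1e-14 * (1 + 1j)
        np.fill_diagonal(u, 0.0)
        from dataclasses import replace

        rec = invert(replace(data, u=u), ops,
                     config=InversionConfig(max_iterations=64, mr=False))
        assert np.abs(rec.chi).max() < 0.05

    def test_near_monotone_descent(self, cylinder, exact_pair):
        _, _, data = exact_pair
        rec = invert(data, cylinder.ops_inv,
                     config=InversionConfig(max_iterations=128, tolerance=1e-12))
        f = rec.cost_history[:, 0]
        assert np.all(f[1:] <= 1.05 * f[:-1])

    def test_requires_imaging_domain(self, cylinder, exact_pair):
        _, _, data = exact_pair
        with pytest.raises(ValueError):
            invert(data, cylinder.ops_fwd)

    def test_deterministic(self, cylinder, exact_pair):
        _, _, data = exact_pair
        cfg = InversionConfig(max_iterations=24)
        r1 = invert(data, cylinder.ops_inv, config=cfg)
        r2 = invert(data, cylinder.ops_inv, config=cfg)
        assert np.array_equal(r1.eps, r2.eps)


class TestInhomogeneousBackground:
    def test_homogeneous_prior_reproduces_original(self, cylinder):
        ops = cylinder.ops_inv
        ops2 = set_inhomogeneous_background(ops, EPS_B)
        assert abs(ops2.A_b - ops.A_b).max() == 0
        assert np.array_equal(ops2.E_inc, ops.E_inc)

    def test_perfect_prior_leaves_no_scattered_data(self, cylinder):
        # background = the true scene → measurements equal incident field
        ops = assemble_operators(cylinder.mesh_fwd, cylinder.eps_scene_fwd,
                                 FREQ, cylinder.antennas)
        data = collect_scatter_data(ops, cylinder.eps_scene_fwd)
        assert np.abs(data.u).max() < 1e-12 * np.abs(ops.E_inc).max()
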