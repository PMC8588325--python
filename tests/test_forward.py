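"""FEM forward solver: element matrices, analytic oracles, reciprocity, noise.

The two analytic oracles are the 2D line-source Green's function
−(j/4)H₀⁽²⁾(k|r−r′|) for the incident field in a homogeneous lossy
medium, and the Mie (cylindrical-harmonic) series for scattering from a
homogeneous dielectric cylinder under line-source illumination.  Both
are implemented here from scratch, independently of the solver, and
compared in relative L2 norm.
"""

import numpy as np
import pytest
from scipy.special import h2vp, hankel2, jv, jvp

from legtomo.forward import (
    add_noise,
    assemble_matrices,
    assemble_operators,
    collect_scatter_data,
    element_mass,
    element_stiffness,
    make_antenna_array,
    scene_permittivity,
    solve_fields,
)
from legtomo.meshing import MESH_SIZE_FACTOR, characteristic_length
from legtomo.phantoms import make_leg_phantom

from conftest import CYL_RADIUS, EPS_B, EPS_CYL, FREQ, LAM_B, circle, disc_mesh, ring_antennas

K0 = 2 * np.pi * FREQ / 3e8
KB = K0 * np.sqrt(EPS_B)


# ---------------------------------------------------------------------------
# independent analytic oracles

def greens_line_source(points, src):
    """−(j/4) H₀⁽²⁾(k|r − r′|), the outgoing 2D line-source field."""
    r = np.linalg.norm(points - np.asarray(src), axis=-1)
    return -0.25j * hankel2(0, KB * r)


def mie_cylinder_scatter(src, rcv, a, eps_cyl, nmax=25):
    """Scattered field at ``rcv`` from a line source at ``src`` with a
    dielectric cylinder (radius a, permittivity eps_cyl) at the origin.

    Expansion of the incident Hankel field in cylindrical harmonics and
    2×2 continuity solve (E and dE/dr) per harmonic at r = a.
    """
    kc = K0 * np.sqrt(eps_cyl)
    rs, ps = np.hypot(*src), np.arctan2(src[1], src[0])
    rr, pr = np.hypot(*rcv), np.arctan2(rcv[1], rcv[0])
    total = 0.0j
    for n in range(-nmax, nmax + 1):
        alpha = -0.25j * hankel2(n, KB * rs)
        M = np.array([[hankel2(n, KB * a), -jv(n, kc * a)],
                      [KB * h2vp(n, KB * a), -kc * jvp(n, kc * a)]])
        rhs = -alpha * np.array([jv(n, KB * a), KB * jvp(n, KB * a)])
        A_scat, _ = np.linalg.solve(M, rhs)
        total += A_scat * hankel2(n, KB * rr) * np.exp(1j * n * (pr - ps))
    return total


# ---------------------------------------------------------------------------

class TestElementMatrices:
    def test_reference_right_triangle_stiffness(self):
        # unit right triangle: closed-form P1 stiffness
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        expected = 0.5 * np.array([[2.0, -1.0, -1.0],
                                   [-1.0, 1.0, 0.0],
                                   [-1.0, 0.0, 1.0]])
        assert np.allclose(element_stiffness(xy), expected)

    def test_reference_right_triangle_mass(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        area = 0.5
        expected = area / 12.0 * np.array([[2.0, 1.0, 1.0],
                                           [1.0, 2.0, 1.0],
                                           [1.0, 1.0, 2.0]])
        assert np.allclose(element_mass(xy), expected)
        # fully lumped variant: area/3 on the diagonal
        assert np.allclose(element_mass(xy, lumping=1.0), area / 3.0 * np.eye(3))

    def test_stiffness_invariant_to_translation_and_rotation(self):
        rng = np.random.default_rng(7)
        xy = rng.random((3, 2))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert np.allclose(element_stiffness(xy),
                           element_stiffness(xy @ R.T + np.array([3.0, -2.0])))


class TestAssembly:
    def test_system_matrix_symmetric(self, cylinder):
        A = cylinder.ops_fwd.A_b
        asym = abs(A - A.T).max() / abs(A).max()
        assert asym < 1e-12

    def test_doubling_eps_changes_only_mass_term(self, cylinder):
        mesh = cylinder.mesh_fwd
        eps = np.full(mesh.num_triangles, EPS_B)
        K1, M1, B1 = assemble_matrices(mesh, eps)
        K2, M2, B2 = assemble_matrices(mesh, 2.0 * eps)
        assert abs(K1 - K2).max() == 0
        assert abs(B1 - B2).max() == 0
        assert abs(M2 - 2.0 * M1).max() < 1e-12 * abs(M1).max()

    def test_receiver_rows_sum_to_one(self, cylinder):
        rows = np.asarray(cylinder.ops_fwd.M_S.sum(axis=1)).ravel()
        assert np.allclose(rows, 1.0)


class TestIncidentField:
    def test_matches_hankel_solution_within_2_percent(self, cylinder):
        """Homogeneous-background FEM field vs the analytic line source."""
        ops = cylinder.ops_fwd
        mesh = cylinder.mesh_fwd
        src = ops.antennas.positions[0]
        E = ops.E_inc[:, 0]
        r = np.linalg.norm(mesh.nodes - src, axis=1)
        R_dom = np.linalg.norm(mesh.nodes, axis=1).max()
        sel = (r > LAM_B / 4) & (np.linalg.norm(mesh.nodes, axis=1) < R_dom - LAM_B / 2)
        exact = greens_line_source(mesh.nodes[sel], src)
        err = np.linalg.norm(E[sel] - exact) / np.linalg.norm(exact)
        assert err < 0.02

    def test_error_decreases_on_refinement(self):
        errs = []
        for h_fac in (1.0, 0.5):
            h = h_fac * MESH_SIZE_FACTOR * characteristic_length(FREQ, EPS_B.real)
            mesh = disc_mesh(LAM_B, h)
            ants = ring_antennas(0.5 * LAM_B, 2, phase=0.3)
            ops = assemble_operators(mesh, EPS_B, FREQ, ants)
            src = ants.positions[0]
            r = np.linalg.norm(mesh.nodes - src, axis=1)
            sel = (r > LAM_B / 4) & (np.linalg.norm(mesh.nodes, axis=1) < LAM_B / 2)
            exact = greens_line_source(mesh.nodes[sel], src)
            errs.append(np.linalg.norm(ops.E_inc[sel, 0] - exact)
                        / np.linalg.norm(exact))
        assert errs[1] < errs[0]

    def test_lossy_medium_decays_faster_than_lossless(self):
        h = MESH_SIZE_FACTOR * characteristic_length(FREQ, EPS_B.real)
        mesh = disc_mesh(LAM_B, h)
        ants = ring_antennas(0.0, 1)  # a single source at the origin
        ants.positions[0][:] = 0.0
        radii = np.array([0.3, 0.5, 0.7]) * LAM_B
        mags = {}
        for eps in (EPS_B, EPS_B.real + 0.0j):
            ops = assemble_operators(mesh, eps, FREQ, ants)
            E = ops.E_inc[:, 0]
            r = np.linalg.norm(mesh.nodes, axis=1)
            mags[eps] = [np.abs(E[np.argmin(np.abs(r - rad))]) for rad in radii]
        ratio = np.array(mags[EPS_B]) / np.array(mags[EPS_B.real + 0.0j])
        assert np.all(np.diff(ratio) < 0)  # lossy/lossless ratio shrinks with r


class TestScatteredData:
    def test_background_scene_gives_zero_scattered_field(self, cylinder):
        ops = cylinder.ops_fwd
        eps_bg = np.full(cylinder.mesh_fwd.num_triangles, EPS_B)
        sol = solve_fields(ops, eps_bg, 0)
        assert (np.linalg.norm(sol.E_scat) / np.linalg.norm(sol.E_inc)) < 1e-10
        data = collect_scatter_data(ops, eps_bg)
        assert np.abs(data.u).max() < 1e-10 * np.abs(ops.E_inc).max()

    def test_mie_series_agreement_within_5_percent(self, cylinder):
        """Cylinder scattering at the receivers vs the analytic series."""
        pos = cylinder.antennas.positions
        T = len(pos)
        U = np.zeros((T, T), complex)
        for t in range(T):
            for r in range(T):
                if r != t:
                    U[t, r] = mie_cylinder_scatter(pos[t], pos[r], CYL_RADIUS, EPS_CYL)
        err = np.linalg.norm(cylinder.data.u - U) / np.linalg.norm(U)
        assert err < 0.05

    def test_reciprocity_of_measurement_matrix(self, cylinder):
        u = cylinder.data.u
        assert np.linalg.norm(u - u.T) / np.linalg.norm(u) < 0.01

    def test_media_change_alters_data(self, thin_phantom):
        """Glycerin/water vs gel backgrounds give distinct measurements."""
        h = MESH_SIZE_FACTOR * characteristic_length(FREQ, 71.4)
        us = {}
        for medium in ("glycerin_water", "gel"):
            model = make_leg_phantom("thin_fat", matching_medium=medium)
            ants = make_antenna_array(model, count=8)
            from legtomo.meshing import generate_mesh

            mesh = generate_mesh(model, 1.3 * h, ants.max_radius + 0.02)
            ops = assemble_operators(mesh, model.matching_medium, FREQ, ants)
            us[medium] = collect_scatter_data(ops, scene_permittivity(mesh, model)).u
        diff = np.linalg.norm(us["gel"] - us["glycerin_water"])
        assert diff / np.linalg.norm(us["glycerin_water"]) > 0.01

    def test_transmitter_index_validated(self, cylinder):
        with pytest.raises(IndexError):
            solve_fields(cylinder.ops_fwd, cylinder.eps_scene_fwd, 99)


class TestAntennaArray:
    def test_contour_offset_placement(self, thin_phantom):
        ants = make_antenna_array(thin_phantom, count=24, offset=0.010)
        assert ants.count == 24
        from shapely.geometry import Point, Polygon

        skin = Polygon(thin_phantom.skin_contour)
        for p in ants.positions:
            assert not skin.contains(Point(p))
            # roughly the offset away from the skin
            assert 0.5 * 0.010 < skin.exterior.distance(Point(p)) < 2.0 * 0.010
        ang = np.mod(np.arctan2(ants.positions[:, 1], ants.positions[:, 0]), 2 * np.pi)
        gaps = np.diff(np.sort(ang))
        assert np.allclose(gaps, 2 * np.pi / 24, rtol=0.01)

    def test_minimum_count_enforced(self, thin_phantom):
        with pytest.raises(ValueError):
            make_antenna_array(thin_phantom, count=3)


class TestNoise:
    def test_infinite_snr_is_identity(self, cylinder):
        out = add_noise(cylinder.data, np.inf, seed=1)
        assert np.array_equal(out.u, cylinder.data.u)

    def test_snr_power_accounting(self, cylinder):
        # 20 dB: pooled signal/noise power ratio within 5% of 100
        # (pool ≥ 576 noise samples, as the band assumes)
        mask = np.abs(cylinder.data.u) > 0
        p_sig = np.mean(np.abs(cylinder.data.u[mask]) ** 2)
        noise_sq = []
        for seed in range(40):
            noisy = add_noise(cylinder.data, 20.0, seed=seed)
            noise_sq.append(np.abs((noisy.u - cylinder.data.u)[mask]) ** 2)
        noise_sq = np.concatenate(noise_sq)
        assert noise_sq.size >= 576
        assert p_sig / noise_sq.mean() == pytest.approx(100.0, rel=0.05)

    def test_deterministic_per_seed(self, cylinder):
        a = add_noise(cylinder.data, 10.0, seed=42)
        b = add_noise(cylinder.data, 10.0, seed=42)
        c = add_noise(cylinder.data, 10.0, seed=43)
        assert np.array_equal(a.u, b.u)
        assert not np.array_equal(a.u, c.u)

    def test_collocated_entries_stay_zero(self, cylinder):
        noisy = add_noise(cylinder.data, 5.0, seed=0)
        assert np.all(np.diag(noisy.u) == 0)


class TestPersistence:
    def test_h5_round_trip(self, tmp_path, cylinder):
        from legtomo.forward import load_scatter_h5, save_scatter_h5

        p = tmp_path / "scatter.h5"
        save_scatter_h5(cylinder.data, p)
        back = load_scatter_h5(p)
        assert np.array_equal(back.u, cylinder.data.u)
        assert back.frequency == cylinder.data.frequency
        assert back.collocated_excluded == cylinder.data.collocated_excluded

    def test_field_solution_h5_round_trip(self, tmp_path, cylinder):
        from legtomo.forward import load_fields_h5, save_fields_h5

        sol = solve_fields(cylinder.ops_fwd, cylinder.eps_scene_fwd, 2)
        save_fields_h5(sol, tmp_path / "fields.h5", FREQ)
        back, freq = load_fields_h5(tmp_path / "fields.h5")
        assert back.transmitter == 2
        assert np.array_equal(back.E_total, sol.E_total)
        assert np.array_equal(back.E_scat, sol.E_scat)
        assert freq == FREQ
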