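"""Periodic FE engine: meshing, embedding, constraints, solves, averaging."""

import math

import numpy as np
import pytest

import axonrve as ax
from axonrve.fem import SolverSettings, write_vtk


class TestMesh:
    def test_element_and_node_counts(self):
        mesh = ax.build_mesh(5.0, 1.25)
        assert mesh.n_elems == 64 and mesh.n_nodes == 125
        mesh = ax.build_mesh(25.0, 1.25)
        assert mesh.n_elems == 8000

    def test_node_coordinates_are_grid_multiples(self):
        mesh = ax.build_mesh(5.0, 1.25)
        assert np.allclose(mesh.nodes / 1.25, np.round(mesh.nodes / 1.25))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            ax.build_mesh(5.0, 7.0)  # h > La
        with pytest.raises(ValueError):
            ax.build_mesh(5.0, 1.3)  # non-divisible


class TestEmbedding:
    def test_axis_aligned_fiber_splits_per_element(self, small_mesh, single_fiber_network):
        truss = ax.embed_fibers(single_fiber_network, small_mesh)
        assert truss.n_segments == 4
        assert truss.L.sum() == pytest.approx(5.0, rel=1e-12)

    def test_diagonal_fiber_crossing_count(self, small_mesh):
        # cube diagonal crosses 3 interior planes per axis → 9 crossings, but
        # triples coincide at the shared diagonal points → 3 unique cuts
        net = ax.FiberNetwork(
            La=5.0, anchor=np.zeros((1, 3)), N=np.full((1, 3), 1 / math.sqrt(3)),
            L0=np.array([5 * math.sqrt(3)]), d=np.array([0.3]), Ps=np.array([1.0]),
        )
        truss = ax.embed_fibers(net, small_mesh)
        assert truss.n_segments == 4
        assert truss.L.sum() == pytest.approx(5 * math.sqrt(3), rel=1e-10)

    def test_generic_fiber_preserves_length_and_local_coords(self, small_mesh):
        rng = np.random.default_rng(0)
        N = rng.standard_normal(3)
        N /= np.linalg.norm(N)
        anchor = np.array([[2.0, 2.6, 1.3]])
        from axonrve.network import _clip_chords

        start, L0 = _clip_chords(anchor, N[None], 5.0)
        net = ax.FiberNetwork(
            La=5.0, anchor=start, N=N[None], L0=L0, d=np.array([0.3]), Ps=np.array([0.9]),
        )
        truss = ax.embed_fibers(net, small_mesh)
        assert truss.L.sum() == pytest.approx(L0[0], rel=1e-10)
        # endpoints interpolate back to their reference coordinates
        for s in range(truss.n_segments):
            nodes = small_mesh.nodes[small_mesh.elems[truss.elem[s]]]
            for e in range(2):
                x = truss.shape_w[s, e] @ nodes
                assert np.allclose(x, truss.X_end[s, e], atol=1e-9)

    def test_fiber_outside_cube_rejected(self, small_mesh):
        net = ax.FiberNetwork(
            La=5.0, anchor=np.array([[0.0, 6.0, 1.0]]), N=np.array([[1.0, 0, 0]]),
            L0=np.array([5.0]), d=np.array([0.3]), Ps=np.array([1.0]),
        )
        with pytest.raises(ValueError):
            ax.embed_fibers(net, small_mesh)


class TestPeriodicConstraints:
    def test_every_dependent_boundary_node_has_one_relation(self, small_mesh):
        con = ax.periodic_constraints(small_mesh)
        n = small_mesh.n
        n_dependent = small_mesh.n_nodes - n**3
        assert con.n_constraints == 3 * n_dependent
        # slaves map to masters with all indices interior-or-zero
        masters = np.unique(con.master_of)
        assert masters.size == n**3

    def test_affine_field_has_zero_fluctuation_residual(self, small_mesh):
        con = ax.periodic_constraints(small_mesh)
        F = np.array([[1.1, 0.05, 0.0], [0.0, 0.95, 0.02], [0.01, 0.0, 1.0]])
        u = small_mesh.nodes @ (F - np.eye(3)).T
        jump = u - (u[con.master_of] + con.offset @ (F - np.eye(3)).T)
        assert np.abs(jump).max() < 1e-12

    def test_identity_forces_equal_boundary_displacements(self, small_mesh):
        con = ax.periodic_constraints(small_mesh)
        rng = np.random.default_rng(0)
        u_red = rng.standard_normal(3 * con.n_red_nodes)
        u = con.full_displacement(u_red, np.eye(3))
        # opposite faces carry identical displacements under F = I
        n = small_mesh.n
        left = np.isclose(small_mesh.nodes[:, 0], 0.0)
        right = np.isclose(small_mesh.nodes[:, 0], small_mesh.La)
        order_l = np.lexsort(small_mesh.nodes[left, 1:].T)
        order_r = np.lexsort(small_mesh.nodes[right, 1:].T)
        assert np.allclose(u[left][order_l], u[right][order_r])


class TestSolve:
    def test_fiber_free_rve_recovers_homogeneous_solution(
        self, small_mesh, cc_matrix_penalty
    ):
        con = ax.periodic_constraints(small_mesh)
        for mode, amount in (("tension_FF", 1.2), ("compression_TT", 0.8), ("shear_TF", 0.2)):
            F = ax.macro_F(ax.LoadingMode(mode, amount))
            res = ax.solve_rve(small_mesh, None, con, cc_matrix_penalty, None, F)
            assert res.converged
            P_exact = ax.matrix_pk1(F, cc_matrix_penalty)
            assert np.abs(res.P_total - P_exact).max() < 1e-6 * np.abs(P_exact).max()

    def test_zero_load_gives_zero_displacement_and_stress(self, small_mesh, cc_matrix_penalty):
        con = ax.periodic_constraints(small_mesh)
        res = ax.solve_rve(small_mesh, None, con, cc_matrix_penalty, None, np.eye(3))
        assert res.converged
        assert np.abs(res.u).max() < 1e-12
        assert np.abs(res.P_total).max() < 1e-9

    def test_single_aligned_fiber_matches_affine_rule_of_mixtures(
        self, small_mesh, single_fiber_network, cc_matrix_penalty, cc_fibers
    ):
        truss = ax.embed_fibers(single_fiber_network, small_mesh)
        con = ax.periodic_constraints(small_mesh)
        F = ax.macro_F(ax.LoadingMode("tension_FF", 1.2))
        res = ax.solve_rve(small_mesh, truss, con, cc_matrix_penalty, cc_fibers, F)
        assert res.converged
        P_aff, _, _, _ = ax.homogenize(single_fiber_network, F, cc_matrix_penalty, cc_fibers)
        assert abs(res.P_total[0, 0] - P_aff[0, 0]) < 0.01 * abs(P_aff[0, 0])

    def test_newton_converges_quadratically_near_solution(self, small_mesh, cc_matrix_penalty):
        # perturb the homogeneous state and watch the residual contraction
        con = ax.periodic_constraints(small_mesh)
        F = ax.macro_F(ax.LoadingMode("tension_FF", 1.2))
        mask = con.red_of_node >= 0
        Xm = small_mesh.nodes[mask]
        rng = np.random.default_rng(0)
        u0 = ((F - np.eye(3)) @ Xm.T).T.ravel()
        u0 += 0.05 * rng.standard_normal(u0.size)
        res = ax.solve_rve(
            small_mesh, None, con, cc_matrix_penalty, None, F,
            SolverSettings(n_increments=1, max_iter=30), u0=u0, F0=F,
        )
        assert res.converged
        tr = [r for r in res.residual_trace[0] if r > 0]
        # contraction order estimated from the last three residuals
        order = math.log(tr[-1] / tr[-2]) / math.log(tr[-2] / tr[-3])
        assert order >= 1.8

    def test_dispersed_network_fe_close_to_affine_at_moderate_stretch(
        self, cc_matrix_penalty, cc_fibers, cc_structural
    ):
        # small aligned RVE: FE within 5% of the affine engine up to 10%
        net = ax.generate_rve(cc_structural, 5.0, seed=9, min_chord=0.625)
        amounts = np.linspace(1.0, 1.1, 5)
        c_fe = ax.fe_response_curve(net, "tension_FF", cc_matrix_penalty, cc_fibers,
                                    h=1.25, amounts=amounts)
        c_af = ax.response_curve(net, "tension_FF", cc_matrix_penalty, cc_fibers,
                                 amounts=amounts)
        rel = np.abs(c_fe.P_total[1:] - c_af.P_total[1:]) / np.abs(c_af.P_total[1:])
        assert rel.max() < 0.05

    def test_hill_mandel_macro_work_equals_energy(self, cc_matrix_penalty, cc_fibers):
        # one oblique fiber forces a fluctuation field; the external work of
        # the macro stress along the path must equal the stored energy
        net = ax.FiberNetwork(
            La=5.0, anchor=np.array([[0.0, 0.5, 2.1]]),
            N=np.array([[0.8, 0.6, 0.0]]),
            L0=np.array([5.0 / 0.8]), d=np.array([0.4]), Ps=np.array([0.95]),
        )
        mesh = ax.build_mesh(5.0, 1.25)
        truss = ax.embed_fibers(net, mesh)
        con = ax.periodic_constraints(mesh)
        amounts = np.linspace(1.0, 1.2, 41)
        work = 0.0
        prev_F, prev_P = np.eye(3), np.zeros((3, 3))
        u0, F_prev = None, np.eye(3)
        mask = con.red_of_node >= 0
        final = None
        for a in amounts[1:]:
            F = ax.macro_F(ax.LoadingMode("tension_FF", float(a)))
            res = ax.solve_rve(mesh, truss, con, cc_matrix_penalty, cc_fibers, F,
                               SolverSettings(n_increments=1), u0=u0, F0=F_prev)
            assert res.converged
            work += 0.5 * float(np.sum((prev_P + res.P_total) * (F - prev_F)))
            prev_F, prev_P = F, res.P_total
            u0, F_prev = res.u[mask].ravel(), F
            final = res
        assert work == pytest.approx(final.energy_density, rel=1e-3)

    def test_nonconvergence_returns_failure_diagnostics(
        self, small_mesh, cc_matrix_penalty, cc_fibers
    ):
        # an oblique fiber makes the affine predictor inexact, so a crippled
        # iteration budget cannot reach the tolerance
        net = ax.FiberNetwork(
            La=5.0, anchor=np.array([[0.0, 0.5, 2.1]]), N=np.array([[0.8, 0.6, 0.0]]),
            L0=np.array([5.0 / 0.8]), d=np.array([0.4]), Ps=np.array([0.95]),
        )
        truss = ax.embed_fibers(net, small_mesh)
        con = ax.periodic_constraints(small_mesh)
        F = ax.macro_F(ax.LoadingMode("tension_FF", 1.2))
        bad = SolverSettings(n_increments=1, max_iter=1, max_cuts=0)
        res = ax.solve_rve(small_mesh, truss, con, cc_matrix_penalty, cc_fibers, F, bad)
        assert not res.converged
        assert "reason" in res.diagnostics


class TestMeshConvergence:
    def test_fiber_free_is_mesh_independent(self, cc_matrix_penalty, cc_fibers):
        empty = ax.FiberNetwork(
            La=5.0, anchor=np.zeros((0, 3)), N=np.zeros((0, 3)),
            L0=np.zeros(0), d=np.zeros(0), Ps=np.zeros(0),
        )
        df = ax.mesh_convergence(empty, [2.5, 1.25], "tension_FF", cc_matrix_penalty,
                                 cc_fibers, amount=1.1)
        assert df.attrs["relative_spread"] < 1e-8

    def test_fibered_rve_spread_below_two_percent(
        self, single_fiber_network, cc_matrix_penalty, cc_fibers
    ):
        df = ax.mesh_convergence(single_fiber_network, [2.5, 1.25], "tension_FF",
                                 cc_matrix_penalty, cc_fibers, amount=1.1)
        assert df["converged"].all()
        assert df.attrs["relative_spread"] < 0.02

    def test_empty_size_list_rejected(self, single_fiber_network, cc_matrix_penalty, cc_fibers):
        with pytest.raises(ValueError):
            ax.mesh_convergence(single_fiber_network, [], "tension_FF",
                                cc_matrix_penalty, cc_fibers)


def test_vtk_export_writes_legacy_header(tmp_path, small_mesh):
    u = np.zeros((small_mesh.n_nodes, 3))
    out = tmp_path / "rve.vtk"
    write_vtk(small_mesh, u, out)
    text = out.read_text().splitlines()
    assert text[0].startswith("# vtk DataFile")
    assert f"POINTS {small_mesh.n_nodes} double" in text
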