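"""Matrix and fiber hyperelastic laws: energies, stresses, tangents."""

import math

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

import axonrve as ax
from axonrve.constitutive import (
    fiber_stress_derivative,
    matrix_pk1_tangent,
    true_stretch,
)


def _random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestRecruitment:
    def test_reference_state(self):
        s = ax.recruitment_split(1.0, 0.9)
        assert (s.lam_r, s.lam_t) == (1.0, 1.0)

    def test_threshold_is_exact(self):
        Ps = 0.878
        s = ax.recruitment_split(1.0 / Ps, Ps)
        assert s.lam_r == pytest.approx(1.0 / Ps, rel=1e-15)
        assert s.lam_t == pytest.approx(1.0, rel=1e-15)

    def test_recruited_true_stretch(self):
        s = ax.recruitment_split(1.2, 0.9)
        assert s.lam_t == pytest.approx(1.08, rel=1e-12)

    def test_invalid_straightness(self):
        with pytest.raises(ValueError):
            ax.recruitment_split(1.1, 1.5)
        with pytest.raises(ValueError):
            ax.recruitment_split(1.1, 0.0)

    @given(
        lam=st.floats(0.0, 3.0),
        Ps=st.floats(0.05, 1.0, exclude_min=True),
    )
    @settings(max_examples=200, deadline=None)
    def test_multiplicative_split_invariant(self, lam, Ps):
        s = ax.recruitment_split(lam, Ps)
        assert s.lam_r * s.lam_t == pytest.approx(lam, rel=1e-12, abs=1e-12)
        if lam < 1.0 / Ps:
            assert s.lam_t == 1.0


class TestFiberLaw:
    def test_zero_energy_and_stress_below_recruitment(self, cc_fibers):
        lam = np.linspace(0.0, 1.0 / 0.878 - 1e-9, 20)
        assert np.all(ax.fiber_energy(lam, 0.878, cc_fibers) == 0.0)
        assert np.all(ax.fiber_nominal_stress(lam, 0.878, cc_fibers) == 0.0)

    def test_continuity_at_recruitment(self, cc_fibers):
        Ps = 0.878
        thr = 1.0 / Ps
        eps = 1e-12
        e_lo = ax.fiber_energy(thr - eps, Ps, cc_fibers)
        e_hi = ax.fiber_energy(thr + eps, Ps, cc_fibers)
        assert abs(e_hi - e_lo) < 1e-12
        p_hi = ax.fiber_nominal_stress(thr + eps, Ps, cc_fibers)
        assert abs(p_hi) < 1e-6  # stress is C0: starts from zero

    def test_energy_matches_symbolic_evaluation(self, cc_fibers):
        # independent symbolic route at λ = 1.15, Ps = 0.878
        lam_t = sp.Float("1.15", 30) * sp.Float("0.878", 30)
        mu, a = sp.Float("80.8", 30), sp.Float("62.3", 30)
        expected = 2 * mu / a**2 * (lam_t**a + 2 * lam_t ** (-a / 2) - 3)
        got = ax.fiber_energy(1.15, 0.878, cc_fibers)
        assert got > 0
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_stress_is_energy_derivative(self, cc_fibers):
        h = 1e-7
        for lam in (1.15, 1.2, 1.3):
            fd = (
                ax.fiber_energy(lam + h, 0.878, cc_fibers)
                - ax.fiber_energy(lam - h, 0.878, cc_fibers)
            ) / (2 * h)
            assert ax.fiber_nominal_stress(lam, 0.878, cc_fibers) == pytest.approx(
                fd, rel=1e-6
            )

    def test_stress_positive_and_increasing_when_recruited(self, cc_fibers):
        lam = np.linspace(1.0 / 0.878 + 1e-6, 1.3, 50)
        p = ax.fiber_nominal_stress(lam, 0.878, cc_fibers)
        assert np.all(p > 0)
        assert np.all(np.diff(p) > 0)

    def test_tangent_matches_stress_derivative(self, cc_fibers):
        h = 1e-7
        for lam in (1.2, 1.25):
            fd = (
                ax.fiber_nominal_stress(lam + h, 0.878, cc_fibers)
                - ax.fiber_nominal_stress(lam - h, 0.878, cc_fibers)
            ) / (2 * h)
            assert fiber_stress_derivative(lam, 0.878, cc_fibers) == pytest.approx(
                fd, rel=1e-5
            )

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            ax.FiberParams(80.0, 0.0)


class TestMatrixLaw:
    def test_zero_energy_and_stress_at_identity(self, cc_matrix_penalty):
        assert ax.matrix_energy(np.eye(3), cc_matrix_penalty) == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(ax.matrix_pk1(np.eye(3), cc_matrix_penalty), 0.0)

    def test_isochoric_uniaxial_energy_matches_symbolic(self, cc_matrix_incompressible):
        lam = 1.1
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        l, mu, a = sp.Float("1.1", 40), sp.Float("353.5", 40), sp.Float("-21.5", 40)
        expected = 2 * mu / a**2 * (l**a + 2 * (1 / sp.sqrt(l)) ** a - 3)
        assert ax.matrix_energy(F, cc_matrix_incompressible) == pytest.approx(
            float(expected), rel=1e-10
        )

    def test_objectivity_under_rotations(self, cc_matrix_penalty):
        rng = np.random.default_rng(0)
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        for _ in range(5):
            R = _random_rotation(rng)
            assert ax.matrix_energy(R @ F, cc_matrix_penalty) == pytest.approx(
                ax.matrix_energy(F, cc_matrix_penalty), rel=1e-10
            )
            # isotropy: right rotations too
            assert ax.matrix_energy(F @ R, cc_matrix_penalty) == pytest.approx(
                ax.matrix_energy(F, cc_matrix_penalty), rel=1e-10
            )

    def test_negative_jacobian_rejected(self, cc_matrix_penalty):
        F = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            ax.matrix_energy(F, cc_matrix_penalty)
        with pytest.raises(ValueError):
            ax.matrix_pk1(F, cc_matrix_penalty)

    def test_stress_matches_finite_difference_gradient(self, cc_matrix_penalty):
        rng = np.random.default_rng(1)
        h = 1e-6
        worst = 0.0
        for _ in range(30):
            F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
            if np.linalg.det(F) < 0.3:
                continue
            P = ax.matrix_pk1(F, cc_matrix_penalty)
            scale = np.abs(P).max()
            for i in range(3):
                for J in range(3):
                    dF = np.zeros((3, 3))
                    dF[i, J] = h
                    fd = (
                        ax.matrix_energy(F + dF, cc_matrix_penalty)
                        - ax.matrix_energy(F - dF, cc_matrix_penalty)
                    ) / (2 * h)
                    worst = max(worst, abs(fd - P[i, J]) / scale)
        assert worst < 1e-6

    def test_equal_biaxial_stress_and_tangent_are_finite_and_consistent(
        self, cc_matrix_penalty
    ):
        # repeated principal stretches exercise the divided-difference limit
        for F in (np.diag([1.1, 1.1, 0.9]), 1.05 * np.eye(3)):
            P = ax.matrix_pk1(F, cc_matrix_penalty)
            A = matrix_pk1_tangent(F, cc_matrix_penalty)
            assert np.all(np.isfinite(P)) and np.all(np.isfinite(A))
            h = 1e-6
            for i in range(3):
                for J in range(3):
                    dF = np.zeros((3, 3))
                    dF[i, J] = h
                    fd = (
                        ax.matrix_pk1(F + dF, cc_matrix_penalty)
                        - ax.matrix_pk1(F - dF, cc_matrix_penalty)
                    ) / (2 * h)
                    assert np.abs(fd - A[:, :, i, J]).max() < 1e-5 * np.abs(A).max()

    def test_incompressible_params_refuse_full_stress(self, cc_matrix_incompressible):
        with pytest.raises(ValueError):
            ax.matrix_pk1(np.eye(3), cc_matrix_incompressible)


class TestPoissonAndUniaxial:
    def test_default_compliance_gives_049(self):
        mp = ax.MatrixParams.nearly_incompressible(353.5, -21.5)
        assert round(ax.initial_poisson(mp), 2) == 0.49
        assert ax.initial_poisson(mp) == pytest.approx(0.4901, abs=5e-5)

    def test_incompressible_limit(self):
        assert ax.initial_poisson(ax.MatrixParams(100.0, 2.0, None)) == 0.5
        tiny = ax.MatrixParams(100.0, 2.0, 1e-12)
        assert ax.initial_poisson(tiny) == pytest.approx(0.5, abs=1e-9)

    def test_equal_bulk_and_shear_moduli(self):
        # K = µ ⇒ ν = 1/8
        mu = 200.0
        mp = ax.MatrixParams(mu, 2.0, 2.0 / mu)
        assert ax.initial_poisson(mp) == pytest.approx(0.125, rel=1e-12)

    def test_uniaxial_curve_reference_and_slope(self):
        mu, alpha = 353.5, -21.5
        assert ax.uniaxial_incompressible_nominal(1.0, mu, alpha) == 0.0
        h = 1e-7
        slope = (
            ax.uniaxial_incompressible_nominal(1 + h, mu, alpha)
            - ax.uniaxial_incompressible_nominal(1 - h, mu, alpha)
        ) / (2 * h)
        assert slope == pytest.approx(3 * mu, rel=1e-6)

    def test_compression_gives_negative_stress(self):
        assert ax.uniaxial_incompressible_nominal(0.95, 353.5, -21.5) < 0
        assert ax.uniaxial_incompressible_nominal(0.95, 100.0, 8.0) < 0

    def test_true_stretch_vectorized_matches_scalar(self):
        lam = np.array([0.9, 1.0, 1.1, 1.2])
        lt = true_stretch(lam, 0.9)
        expected = [ax.recruitment_split(x, 0.9).lam_t for x in lam]
        assert np.allclose(lt, expected)
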