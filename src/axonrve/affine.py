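"""Affine (Taylor) homogenization of a fiber network.

Every micro constituent deforms with the macroscopic deformation gradient:
the matrix stress is the Ogden stress at F, each fiber stretches by
λ_i = ‖F·N_i‖ and contributes its nominal stress along the deformed
direction.  The homogenized nominal stress follows the rule of mixtures

    P = P̄_m + v_f · P̄̃_f,      P̄̃_f = Σ_i w_i p_f(λ_i) m_i ⊗ N_i,

with reference-volume weights w_i (chord-length bookkeeping, Σw_i = 1),
m_i = F·N_i/λ_i, and v_f the achieved fiber volume fraction of the network.
The affine assumption is an upper bound on the periodic-BC finite-element
response; both engines share this module's curve interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .constitutive import (
    FiberParams,
    MatrixParams,
    fiber_energy,
    fiber_nominal_stress,
    matrix_energy,
    matrix_pk1,
    uniaxial_incompressible_nominal,
)
from .loading import LoadingMode, conjugate_index, default_amounts, macro_F
from .network import FiberNetwork

__all__ = [
    "HomogenizedCurve",
    "fiber_stretch",
    "homogenize",
    "response_curve",
]


@dataclass
class HomogenizedCurve:
    """Conjugate nominal stress vs deformation amount for one loading mode,
    with the matrix/fiber partition and the recruited fiber fraction."""

    mode: str
    amounts: np.ndarray
    P_total: np.ndarray
    P_matrix: np.ndarray
    P_fiber: np.ndarray  # volume-averaged fiber stress (before the v_f factor)
    recruited_fraction: np.ndarray
    engine: str = "affine"
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "amount": self.amounts,
                "P_total": self.P_total,
                "P_matrix": self.P_matrix,
                "P_fiber": self.P_fiber,
                "recruited_fraction": self.recruited_fraction,
            }
        ).to_csv(path, index=False)
        meta = {"mode": self.mode, "engine": self.engine, **self.metadata}
        Path(path).with_suffix(Path(path).suffix + ".json").write_text(
            json.dumps(meta, indent=1, default=str)
        )


def fiber_stretch(F: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Affine stretch of 1-D segments: λ = ‖F·N‖ (N unit, batched)."""
    FN = np.einsum("ij,...j->...i", np.asarray(F, float), np.asarray(N, float))
    out = np.linalg.norm(FN, axis=-1)
    return out if out.shape else float(out)


def homogenize(
    net: FiberNetwork, F: np.ndarray, mp: MatrixParams, fp: FiberParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Rule-of-mixtures nominal stress of the network at macro gradient F.

    Returns ``(P_total, P_matrix, P_fiber, recruited_fraction)`` where
    ``P_total = P_matrix + v_f · P_fiber`` and ``recruited_fraction`` is the
    fiber-volume-weighted share of fibers stretched past 1/Ps.
    """
    P_m = matrix_pk1(F, mp)
    if net.n_fibers == 0 or net.achieved_vf == 0.0:
        return P_m.copy(), P_m, np.zeros((3, 3)), 0.0
    w = net.fiber_volumes
    w = w / w.sum()
    FN = np.einsum("ij,fj->fi", np.asarray(F, float), net.N)
    lam = np.linalg.norm(FN, axis=1)
    m = FN / lam[:, None]
    p = fiber_nominal_stress(lam, net.Ps, fp)
    P_f = np.einsum("f,fi,fj->ij", w * p, m, net.N)
    recruited = float(w[lam * net.Ps >= 1.0].sum())
    P_total = P_m + net.achieved_vf * P_f
    return P_total, P_m, P_f, recruited


def _relaxed_uniaxial_F(lam: float, axis: int, net, mp, fp) -> np.ndarray:
    """Uniaxial macro gradient with lateral stretches solved for zero lateral
    macro stress (equal-lateral ansatz), for dispersed orientations."""

    def lateral_stress(q: float) -> float:
        d = np.full(3, q)
        d[axis] = lam
        P, _, _, _ = homogenize(net, np.diag(d), mp, fp)
        others = [k for k in range(3) if k != axis]
        return 0.5 * (P[others[0], others[0]] + P[others[1], others[1]])

    q0 = lam**-0.5
    bracket = (0.5 * q0, 2.0 * q0)
    sol = optimize.brentq(lateral_stress, *bracket, xtol=1e-12)
    d = np.full(3, sol)
    d[axis] = lam
    return np.diag(d)


def response_curve(
    net: FiberNetwork,
    mode_label: str,
    mp: MatrixParams,
    fp: FiberParams,
    n_steps: int = 21,
    amounts: np.ndarray | None = None,
    lateral: str = "isochoric",
) -> HomogenizedCurve:
    """Sweep one loading mode and report the work-conjugate nominal stress.

    ``lateral='relaxed'`` replaces the isochoric uniaxial ansatz by a nested
    zero-lateral-macro-stress solve (useful for dispersed orientations).
    """
    if amounts is None:
        amounts = default_amounts(mode_label, n_steps)
    amounts = np.asarray(amounts, dtype=float)
    if amounts.size < 2:
        raise ValueError("need at least 2 amounts")
    i, j = conjugate_index(mode_label)
    uniaxial = mode_label.split("_")[0] in ("tension", "compression")
    # Incompressible matrix: the uniaxial conjugate stress is the analytic
    # incompressible Ogden curve (the isochoric ansatz is exact in this
    # limit); shear conjugate components are pressure-independent at J = 1,
    # so a dummy compliance evaluates them without ambiguity.
    mp_eval = MatrixParams(mp.mu, mp.alpha, 1.0 / mp.mu) if mp.incompressible else mp
    tot, mat, fib, rec = [], [], [], []
    for a in amounts:
        mode = LoadingMode(mode_label, float(a))
        if lateral == "relaxed" and uniaxial:
            from .loading import _STRETCH_AXIS  # axis of the stretch direction

            F = _relaxed_uniaxial_F(float(a), _STRETCH_AXIS[mode_label], net, mp_eval, fp)
        else:
            F = macro_F(mode)
        P_t, P_m, P_f, r = homogenize(net, F, mp_eval, fp)
        if mp.incompressible and uniaxial and lateral != "relaxed":
            pm = uniaxial_incompressible_nominal(float(a), mp.mu, mp.alpha)
            mat.append(pm)
            tot.append(pm + net.achieved_vf * P_f[i, j])
        else:
            mat.append(P_m[i, j])
            tot.append(P_t[i, j])
        fib.append(P_f[i, j])
        rec.append(r)
    return HomogenizedCurve(
        mode=mode_label,
        amounts=amounts,
        P_total=np.array(tot),
        P_matrix=np.array(mat),
        P_fiber=np.array(fib),
        recruited_fraction=np.array(rec),
        engine="affine",
        metadata={
            "La": net.La,
            "seed": net.seed,
            "v_f": net.achieved_vf,
            "lateral": lateral,
            "shear_convention": "first letter = displacement direction, second = face normal",
        },
    )


def path_energy_density(
    net: FiberNetwork, F_path: np.ndarray, mp: MatrixParams, fp: FiberParams
) -> np.ndarray:
    """Total energy density Ψ_m(F) + v_f·Σ w_i Ψ̃_f(λ_i) along a path of macro
    gradients (used by the stress-power consistency checks)."""
    out = np.empty(len(F_path))
    w = net.fiber_volumes
    w = w / w.sum()
    for k, F in enumerate(F_path):
        lam = fiber_stretch(F, net.N)
        out[k] = matrix_energy(F, mp) + net.achieved_vf * float(
            (w * fiber_energy(lam, net.Ps, fp)).sum()
        )
    return out
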