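"""Hyperelastic laws of the two white-matter constituents.

Ground matrix — isotropic one-term Ogden law in the *deviatoric* principal
stretches λ̄_a = J^{-1/3} λ_a with a quadratic volumetric penalty:

    Ψ_m = (2 µ_m / α_m²) (λ̄1^α + λ̄2^α + λ̄3^α − 3) + (1/D_m) (J − 1)²,

with J = λ1 λ2 λ3.  The deviatoric/volumetric split keeps the reference state
stress-free for every exponent; on isochoric deformations (J = 1, i.e. all
seven loading modes of this study) it coincides with the same Ogden form
written in the raw stretches.  The default volumetric compliance
D_m = 0.04/µ_m gives an initial Poisson's ratio of 0.49 (nearly
incompressible); ``D=None`` marks the incompressible limit (energy evaluated
without the penalty term, valid on isochoric states only).

Embedded axon fiber — a 1-D incompressible Ogden law in the *true* stretch λ_t,
combined with the recruitment-stretch concept: a tortuous fiber with
straightness Ps = L0/Lf first unbends (λ < 1/Ps: recruitment only, no load),
then bears load with λ_t = λ·Ps:

    Ψ̃_f = (2 µ_f / α_f²) (λ_t^α + 2 λ_t^{−α/2} − 3).

Ψ̃_f is the *modified* (embedded) fiber energy: in the embedded-element rule of
mixtures the matrix fills the whole cube and the fiber carries Ψ̃_f = Ψ_f − Ψ_m,
so the total energy W = ∫Ψ_m dV + Σ∫Ψ̃_f dV never double-counts the matrix
volume occupied by the fibers.  The parameters (µ_f, α_f) are parameters *of
the embedded fibers*, not of isolated axons.

All stresses are nominal (first Piola–Kirchhoff); units are Pa and µm
throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MatrixParams",
    "FiberParams",
    "RecruitmentState",
    "corpus_callosum_materials",
    "recruitment_split",
    "fiber_energy",
    "fiber_nominal_stress",
    "fiber_stress_derivative",
    "matrix_energy",
    "matrix_pk1",
    "matrix_pk1_tangent",
    "initial_poisson",
    "uniaxial_incompressible_nominal",
]

# relative eigenvalue gap below which the divided difference of the spectral
# stress switches to its analytic limit (guards catastrophic cancellation)
_EIG_GAP = 1e-8


@dataclass(frozen=True)
class MatrixParams:
    """Ground-matrix Ogden constants: shear modulus ``mu`` (Pa), exponent
    ``alpha`` (nonzero), volumetric compliance ``D`` (1/Pa; ``None`` =
    incompressible)."""

    mu: float
    alpha: float
    D: float | None = None

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise ValueError(f"matrix shear modulus must be > 0, got {self.mu}")
        if self.alpha == 0:
            raise ValueError("matrix Ogden exponent must be nonzero")
        if self.D is not None and not (self.D > 0):
            raise ValueError(f"volumetric compliance must be > 0, got {self.D}")

    @property
    def incompressible(self) -> bool:
        return self.D is None

    @classmethod
    def nearly_incompressible(cls, mu: float, alpha: float) -> "MatrixParams":
        """Standard near-incompressibility D = 0.04/µ (initial ν = 0.49)."""
        return cls(mu, alpha, 0.04 / mu)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"mu_Pa": self.mu, "alpha": self.alpha,
                 "D_per_Pa": self.D, "incompressible": self.incompressible},
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "MatrixParams":
        d = json.loads(Path(path).read_text())
        D = None if d.get("incompressible") else d["D_per_Pa"]
        return cls(d["mu_Pa"], d["alpha"], D)


@dataclass(frozen=True)
class FiberParams:
    """Embedded-fiber Ogden constants: shear modulus ``mu`` (Pa), exponent
    ``alpha`` (nonzero)."""

    mu: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise ValueError(f"fiber shear modulus must be > 0, got {self.mu}")
        if self.alpha == 0:
            raise ValueError("fiber Ogden exponent must be nonzero")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({"mu_Pa": self.mu, "alpha": self.alpha}, indent=1))

    @classmethod
    def from_json(cls, path) -> "FiberParams":
        d = json.loads(Path(path).read_text())
        return cls(d["mu_Pa"], d["alpha"])


def corpus_callosum_materials() -> tuple[MatrixParams, FiberParams]:
    """Identified corpus-callosum constants: matrix (353.5 Pa, −21.5, ν=0.49)
    and embedded fibers (80.8 Pa, 62.3)."""
    return MatrixParams.nearly_incompressible(353.5, -21.5), FiberParams(80.8, 62.3)


# ---------------------------------------------------------------------------
# recruitment + fiber law
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecruitmentState:
    """Multiplicative split λ = λ_r · λ_t of the total fiber stretch into
    recruitment (unbending) and true (load-bearing) parts."""

    lam: float
    lam_r: float
    lam_t: float


def _check_ps(Ps) -> None:
    Ps = np.asarray(Ps)
    if np.any((Ps <= 0) | (Ps > 1)):
        raise ValueError("straightness Ps must lie in (0, 1]")


def true_stretch(lam, Ps):
    """Vectorized load-bearing stretch: λ_t = λ·Ps once λ ≥ 1/Ps, else 1."""
    _check_ps(Ps)
    lam = np.asarray(lam, dtype=float)
    Ps = np.asarray(Ps, dtype=float)
    return np.where(lam * Ps >= 1.0, lam * Ps, 1.0)


def recruitment_split(lam: float, Ps: float) -> RecruitmentState:
    """Split a fiber stretch at straightness ``Ps``: below the recruitment
    threshold 1/Ps the fiber only unbends (λ_t = 1); above, λ_r = 1/Ps and
    λ_t = λ·Ps.  Stretches below 1 are treated as unrecruited."""
    _check_ps(Ps)
    if lam < 0:
        raise ValueError(f"stretch must be >= 0, got {lam}")
    if lam * Ps >= 1.0:
        return RecruitmentState(lam, 1.0 / Ps, lam * Ps)
    return RecruitmentState(lam, lam, 1.0)


def fiber_energy(lam, Ps, fp: FiberParams):
    """Embedded-fiber energy density Ψ̃_f (Pa) at total stretch ``lam``.

    Zero up to recruitment (λ_t = 1) and C0-continuous across it.
    """
    lt = true_stretch(lam, Ps)
    a = fp.alpha
    out = 2.0 * fp.mu / a**2 * (lt**a + 2.0 * lt ** (-a / 2.0) - 3.0)
    return out if out.shape else float(out)


def fiber_nominal_stress(lam, Ps, fp: FiberParams):
    """Nominal fiber stress dΨ̃_f/dλ (Pa), per unit reference (chord, L0-based)
    configuration: (2µ/α)(λ_t^{α−1} − λ_t^{−α/2−1})·Ps above recruitment, zero
    below (tortuous fibers bear no compressive load)."""
    lam = np.asarray(lam, dtype=float)
    lt = true_stretch(lam, Ps)
    a = fp.alpha
    p = 2.0 * fp.mu / a * (lt ** (a - 1.0) - lt ** (-a / 2.0 - 1.0)) * np.asarray(Ps, float)
    p = np.where(lam * np.asarray(Ps, float) >= 1.0, p, 0.0)
    return p if p.shape else float(p)


def fiber_stress_derivative(lam, Ps, fp: FiberParams):
    """dP_f/dλ (Pa), the 1-D material tangent of the recruited fiber."""
    lam = np.asarray(lam, dtype=float)
    Ps_ = np.asarray(Ps, dtype=float)
    lt = true_stretch(lam, Ps)
    a = fp.alpha
    k = 2.0 * fp.mu / a * (
        (a - 1.0) * lt ** (a - 2.0) + (a / 2.0 + 1.0) * lt ** (-a / 2.0 - 2.0)
    ) * Ps_**2
    k = np.where(lam * Ps_ >= 1.0, k, 0.0)
    return k if k.shape else float(k)


# ---------------------------------------------------------------------------
# matrix law
# ---------------------------------------------------------------------------


def _principal(F: np.ndarray):
    """Batched spectral data of the right Cauchy–Green tensor C = FᵀF.

    Returns (λ² eigenvalues ascending, eigenvectors, principal stretches, J).
    """
    F = np.asarray(F, dtype=float)
    C = np.einsum("...ki,...kj->...ij", F, F)
    lam2, V = np.linalg.eigh(C)
    lam2 = np.maximum(lam2, 1e-300)
    lam = np.sqrt(lam2)
    J = np.linalg.det(F)
    return lam2, V, lam, J


def matrix_energy(F, mp: MatrixParams):
    """Ogden (deviatoric stretches) + volumetric-penalty energy density (Pa)
    at deformation gradient ``F`` (3×3 or batched ...×3×3).  Requires
    det F > 0."""
    F = np.asarray(F, dtype=float)
    _, _, lam, J = _principal(F)
    if np.any(J <= 0):
        raise ValueError("deformation gradient must have positive determinant")
    a = mp.alpha
    lam_bar = lam * J[..., None] ** (-1.0 / 3.0)
    W = 2.0 * mp.mu / a**2 * ((lam_bar**a).sum(axis=-1) - 3.0)
    if not mp.incompressible:
        W = W + (J - 1.0) ** 2 / mp.D
    return W if np.ndim(W) else float(W)


def _spectral_stress_coeffs(lam, J, mp: MatrixParams):
    """Principal second Piola–Kirchhoff coefficients S_a = (1/λ_a) ∂Ψ/∂λ_a.

    With λ̄_a = J^{-1/3} λ_a:  S_a = (2µ/α)(λ̄_a^α − s̄/3)/λ_a² + 2k(J² − J)/λ_a²,
    s̄ = Σ_b λ̄_b^α (the deviatoric projection removes the hydrostatic part at
    the reference state).
    """
    a = mp.alpha
    lam_bar = lam * J[..., None] ** (-1.0 / 3.0)
    sbar = (lam_bar**a).sum(axis=-1)[..., None]
    S = 2.0 * mp.mu / a * (lam_bar**a - sbar / 3.0) / lam**2
    if not mp.incompressible:
        k = 1.0 / mp.D
        S = S + 2.0 * k * ((J**2 - J)[..., None]) / lam**2
    return S


def matrix_pk1(F, mp: MatrixParams):
    """Nominal (first Piola–Kirchhoff) matrix stress ∂Ψ_m/∂F (Pa).

    Computed through the spectral decomposition of C; repeated principal
    stretches are harmless here because equal eigenvalues share the same
    stress coefficient.  Incompressible parameters are rejected — without the
    penalty term the hydrostatic pressure is indeterminate.
    """
    if mp.incompressible:
        raise ValueError(
            "matrix_pk1 requires a finite volumetric compliance; "
            "use uniaxial_incompressible_nominal for incompressible-limit curves"
        )
    F = np.asarray(F, dtype=float)
    lam2, V, lam, J = _principal(F)
    if np.any(J <= 0):
        raise ValueError("deformation gradient must have positive determinant")
    S_coef = _spectral_stress_coeffs(lam, J, mp)
    S = np.einsum("...a,...ia,...ja->...ij", S_coef, V, V)
    P = np.einsum("...ik,...kj->...ij", F, S)
    return P


def matrix_pk1_tangent(F, mp: MatrixParams):
    """First elasticity tensor A_iJkL = ∂P_iJ/∂F_kL (batched).

    Spectral form of the material tangent ℂ = 2 ∂S/∂C with the analytic limit
    of the divided difference (S_a − S_b)/(λ_a² − λ_b²) when principal
    stretches are nearly equal, then push-forward
    A = δ_ik S_JL + F_iM F_kN ℂ_{MJNL}.
    """
    if mp.incompressible:
        raise ValueError("tangent requires a finite volumetric compliance")
    F = np.asarray(F, dtype=float)
    squeeze = F.ndim == 2
    if squeeze:
        F = F[None]
    lam2, V, lam, J = _principal(F)
    a = mp.alpha
    k = 1.0 / mp.D
    S = _spectral_stress_coeffs(lam, J, mp)

    # split S_a = (2µ/α) J^{-α/3} λ_a^{α-2} + q/λ_a² with the index-free part
    # q = −(2µ/3α) s̄ + 2k(J² − J); derivatives follow in closed form
    n = F.shape[0]
    eye3 = np.eye(3)
    Jc = J[:, None, None]
    la = lam[:, :, None]  # index a
    lb = lam[:, None, :]  # index b
    lam_bar = lam * J[:, None] ** (-1.0 / 3.0)
    sbar = (lam_bar**a).sum(axis=-1)[:, None, None]
    Jma3 = J[:, None, None] ** (-a / 3.0)
    q = -2.0 * mp.mu / (3.0 * a) * sbar + 2.0 * k * (Jc**2 - Jc)
    dq_db = (
        -2.0 * mp.mu / 3.0 * (lam_bar[:, None, :] ** a - sbar / 3.0) / lb
        + 2.0 * k * (2.0 * Jc**2 - Jc) / lb
    )
    dS = 2.0 * mp.mu / a * Jma3 * (
        (a - 2.0) * la ** (a - 3.0) * eye3 - a / (3.0 * lb) * la ** (a - 2.0)
    )
    dS += dq_db / la**2 - 2.0 * q / la**3 * eye3
    C_ab = dS / lb

    # divided difference g_ab = (S_a − S_b)/(λ_a² − λ_b²)
    x = lam2[:, :, None]
    y = lam2[:, None, :]
    p = (a - 2.0) / 2.0
    diff = x - y
    near = np.abs(diff) < _EIG_GAP * np.maximum(np.abs(x), np.abs(y))
    safe = np.where(near, 1.0, diff)
    g_iso = 2.0 * mp.mu / a * Jma3 * np.where(
        near, p * ((x + y) / 2.0) ** (p - 1.0), (x**p - y**p) / safe
    )
    g_vol = -q / (x * y)
    g = g_iso + g_vol

    # ℂ in the principal frame
    CC = np.einsum("nab,nia,nja,nkb,nlb->nijkl", C_ab, V, V, V, V)
    off = np.zeros((n, 3, 3))
    offdiag = ~np.eye(3, dtype=bool)
    off[:, offdiag] = g[:, offdiag]
    CC += np.einsum("nab,nia,njb,nka,nlb->nijkl", off, V, V, V, V)
    CC += np.einsum("nab,nia,njb,nkb,nla->nijkl", off, V, V, V, V)

    Smat = np.einsum("na,nia,nja->nij", S, V, V)
    A = np.einsum("ik,nJL->niJkL", np.eye(3), Smat) + np.einsum(
        "niM,nkN,nMJNL->niJkL", F, F, CC
    )
    return A[0] if squeeze else A


def initial_poisson(mp: MatrixParams) -> float:
    """Small-strain Poisson's ratio implied by the volumetric compliance.

    The penalty (1/D)(J−1)² linearizes to an initial bulk modulus K = 2/D, so
    ν = (3K − 2µ)/(2(3K + µ)); the incompressible limit returns exactly 0.5.
    """
    if mp.incompressible:
        return 0.5
    K = 2.0 / mp.D
    return (3.0 * K - 2.0 * mp.mu) / (2.0 * (3.0 * K + mp.mu))


def uniaxial_incompressible_nominal(lam, mu: float, alpha: float):
    """Analytic uniaxial nominal stress of the incompressible one-term Ogden
    solid: P(λ) = (2µ/α)(λ^{α−1} − λ^{−α/2−1}).

    The lateral stretches follow λ_lat = λ^{−1/2}; the hydrostatic pressure is
    eliminated by the traction-free lateral condition.  The initial slope is
    3µ (incompressible Young's modulus).
    """
    if alpha == 0:
        raise ValueError("Ogden exponent must be nonzero")
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    P = 2.0 * mu / alpha * (lam ** (alpha - 1.0) - lam ** (-alpha / 2.0 - 1.0))
    return P if P.shape else float(P)
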