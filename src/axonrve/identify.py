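"""Two-step inverse identification of the matrix and fiber Ogden constants.

Step 1 fits the ground-matrix pair (µ_m, α_m) to the compression-FF and
tension-TT curves up to 10% deformation — both are pure-matrix responses for
aligned fiber networks (tortuous fibers bear no compressive load, and fibers
stretched transversely shorten), so the analytic incompressible uniaxial
Ogden curve is the forward model, fitted jointly over both modes in a single
objective.

Step 2 fixes the matrix and fits the embedded-fiber pair (µ_f, α_f) to the
tension-FF curve up to 10% stretch, with forward evaluations of the
homogenized RVE response (affine engine by default; the periodic FE engine is
available and the affine surrogate is validated against it on small RVEs).

The objective is the unweighted sum of squared nominal-stress residuals
χ² = Σ (P_exp − P_sim)² over all points and modes, minimized by bounded
trust-region-reflective least squares from several interior starting points.
Default bounds: µ_m ∈ [50, 5000] Pa, α_m ∈ [−50, 50], µ_f ∈ [20, 5000] Pa,
α_f unbounded (internally soft-clamped at ±500 to avoid overflow in λ^α).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .affine import response_curve
from .constitutive import FiberParams, MatrixParams, uniaxial_incompressible_nominal
from .loading import ALL_MODES
from .network import FiberNetwork

__all__ = [
    "ExperimentCurves",
    "IdentResult",
    "chi2",
    "fit_matrix",
    "fit_fibers",
    "identify_two_step",
]

logger = logging.getLogger(__name__)

MATRIX_BOUNDS = ((50.0, 5000.0), (-50.0, 50.0))
FIBER_BOUNDS = ((20.0, 5000.0), (-np.inf, np.inf))
_ALPHA_CLAMP = 500.0  # soft clamp of the unbounded fiber exponent
_FIT_STRETCH_LIMIT = 0.10  # both steps use data up to 10% deformation


class IdentificationError(RuntimeError):
    pass


@dataclass
class ExperimentCurves:
    """Per-mode (amount, nominal stress Pa) arrays for any subset of the seven
    loading modes.  Amounts must be strictly monotone per mode and the stress
    at the identity amount (stretch 1 / shear 0) must vanish."""

    curves: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for mode, (x, y) in self.curves.items():
            if mode not in ALL_MODES:
                raise ValueError(f"unknown mode {mode!r}")
            x, y = np.asarray(x, float), np.asarray(y, float)
            if x.size != y.size or x.size < 2:
                raise ValueError(f"{mode}: malformed curve")
            dx = np.diff(x)
            if not (np.all(dx > 0) or np.all(dx < 0)):
                raise ValueError(f"{mode}: amounts must be strictly monotone")
            self.curves[mode] = (x, y)

    def modes(self):
        return set(self.curves)

    def __getitem__(self, mode: str):
        return self.curves[mode]

    def restrict(self, mode: str, max_deformation: float = _FIT_STRETCH_LIMIT):
        """Points within ``max_deformation`` of the identity amount."""
        x, y = self.curves[mode]
        ref = 0.0 if mode.startswith("shear") else 1.0
        keep = np.abs(x - ref) <= max_deformation + 1e-12
        return x[keep], y[keep]

    def write(self, directory) -> None:
        """Per-mode CSV files plus a JSON manifest naming the modes."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for mode, (x, y) in self.curves.items():
            pd.DataFrame({"amount": x, "stress_Pa": y}).to_csv(
                directory / f"{mode}.csv", index=False
            )
        (directory / "manifest.json").write_text(
            json.dumps({"modes": sorted(self.curves)}, indent=1)
        )

    @classmethod
    def read(cls, directory) -> "ExperimentCurves":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        curves = {}
        for mode in manifest["modes"]:
            df = pd.read_csv(directory / f"{mode}.csv")
            curves[mode] = (df["amount"].to_numpy(float), df["stress_Pa"].to_numpy(float))
        return cls(curves)


@dataclass
class IdentResult:
    """Outcome of the two-step identification."""

    matrix: MatrixParams
    fibers: FiberParams | None
    chi2_matrix: float
    chi2_fibers: float | None
    iterations: dict
    bounds_active: dict
    seeds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mu_m_Pa": self.matrix.mu, "alpha_m": self.matrix.alpha,
                    "mu_f_Pa": self.fibers.mu if self.fibers else None,
                    "alpha_f": self.fibers.alpha if self.fibers else None,
                    "chi2_matrix": self.chi2_matrix, "chi2_fibers": self.chi2_fibers,
                    "iterations": self.iterations, "bounds_active": self.bounds_active,
                    "seeds": self.seeds,
                },
                indent=1,
            )
        )


def chi2(sim: ExperimentCurves, exp: ExperimentCurves) -> float:
    """Unweighted χ² = Σ (P_exp − P_sim)² over all shared modes and the
    experimental amount grids (simulation curves are interpolated)."""
    shared = sim.modes() & exp.modes()
    if not shared:
        raise ValueError("simulated and experimental curve sets share no modes")
    total = 0.0
    for mode in shared:
        xe, ye = exp[mode]
        xs, ys = sim[mode]
        order = np.argsort(xs)
        ysim = np.interp(xe, xs[order], ys[order])
        total += float(((ye - ysim) ** 2).sum())
    return total


def _multistart_least_squares(resid, starts, bounds, tie_rel=0.01):
    """Bounded trust-region-reflective least squares from several starts.

    The one-term Ogden fiber law has two χ²-branches (large positive and
    large negative exponents) that can be statistically indistinguishable on
    truncated noisy data.  Among solutions whose cost is within ``tie_rel``
    of the best, the one with the smallest parameter norm is returned
    (Occam tie-break, matching the convention of the distribution fits).
    """
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    solutions = []
    n_iter = 0
    for x0 in starts:
        sol = optimize.least_squares(
            resid, x0=np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        n_iter += sol.nfev
        if sol.success:
            solutions.append(sol)
    if not solutions:
        raise IdentificationError("trust-region least squares did not converge")
    best_cost = min(s.cost for s in solutions)
    ties = [s for s in solutions if s.cost <= best_cost * (1.0 + tie_rel) + 1e-300]
    ties.sort(key=lambda s: float(np.linalg.norm(s.x)))
    return ties[0], n_iter


def _bound_activity(x, bounds, rel=1e-3):
    flags = []
    for v, (lo, hi) in zip(x, bounds):
        span = hi - lo if np.isfinite(hi - lo) else max(abs(v), 1.0)
        at = (np.isfinite(lo) and abs(v - lo) < rel * span) or (
            np.isfinite(hi) and abs(v - hi) < rel * span
        )
        flags.append(bool(at))
        if at:
            warnings.warn(
                f"identified parameter {v:g} sits on a bound [{lo:g}, {hi:g}]; "
                "the optimum may not be interior",
                stacklevel=3,
            )
    return flags


def fit_matrix(
    exp: ExperimentCurves,
    bounds=MATRIX_BOUNDS,
    n_starts: int = 5,
    seed: int = 0,
):
    """Step 1: joint fit of (µ_m, α_m) to compression-FF + tension-TT data up
    to 10% deformation against the analytic incompressible uniaxial curves.

    Returns ``(MatrixParams (incompressible flag), chi2, info dict)``.
    """
    for mode in ("compression_FF", "tension_TT"):
        if mode not in exp.modes():
            raise IdentificationError(f"step 1 requires mode {mode!r}")
    xc, yc = exp.restrict("compression_FF")
    xt, yt = exp.restrict("tension_TT")
    lam = np.concatenate([xc, xt])
    y = np.concatenate([yc, yt])

    def resid(theta):
        return uniaxial_incompressible_nominal(lam, theta[0], theta[1]) - y

    rng = np.random.default_rng(seed)
    (lo_mu, hi_mu), (lo_a, hi_a) = bounds
    starts = [
        np.array([
            np.exp(rng.uniform(np.log(lo_mu), np.log(hi_mu))),
            rng.uniform(lo_a + 0.05 * (hi_a - lo_a), hi_a - 0.05 * (hi_a - lo_a)),
        ])
        for _ in range(n_starts)
    ]
    sol, n_iter = _multistart_least_squares(resid, starts, bounds)
    mp = MatrixParams(float(sol.x[0]), float(sol.x[1]), None)
    info = {
        "iterations": n_iter,
        "bounds_active": _bound_activity(sol.x, bounds),
        "n_points": int(lam.size),
    }
    return mp, 2.0 * float(sol.cost), info


def fit_fibers(
    exp: ExperimentCurves,
    mp: MatrixParams,
    net: FiberNetwork,
    engine: str = "affine",
    bounds=FIBER_BOUNDS,
    n_starts: int = 4,
    seed: int = 0,
    fe_h: float | None = None,
):
    """Step 2: fit (µ_f, α_f) to the tension-FF curve up to 10% stretch with
    forward homogenization on ``net`` (matrix parameters fixed).

    Raises :class:`IdentificationError` when no fiber is recruited anywhere on
    the data grid (flat objective: the fiber parameters are not identifiable).
    Returns ``(FiberParams, chi2, info dict)``.
    """
    if "tension_FF" not in exp.modes():
        raise IdentificationError("step 2 requires a tension_FF curve")
    lam, y = exp.restrict("tension_FF")
    if np.max(lam * net.Ps.max()) < 1.0:
        raise IdentificationError(
            "no fiber is recruited on the tension_FF grid; "
            "fiber parameters are not identifiable from these data"
        )

    def forward(theta):
        fp = FiberParams(float(theta[0]), float(np.clip(theta[1], -_ALPHA_CLAMP, _ALPHA_CLAMP)))
        if engine == "affine":
            c = response_curve(net, "tension_FF", mp, fp, amounts=lam)
        elif engine == "fe":
            from .fem import fe_response_curve

            c = fe_response_curve(net, "tension_FF", mp, fp, h=fe_h, amounts=lam)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        return c.P_total

    def resid(theta):
        return forward(theta) - y

    rng = np.random.default_rng(seed)
    (lo_mu, hi_mu), _ = bounds
    alpha_starts = rng.uniform(1.0, 100.0, size=n_starts)
    starts = [
        np.array([np.exp(rng.uniform(np.log(lo_mu), np.log(hi_mu))), a])
        for a in alpha_starts
    ]
    sol, n_iter = _multistart_least_squares(resid, starts, bounds)
    fp = FiberParams(float(sol.x[0]), float(sol.x[1]))
    info = {
        "iterations": n_iter,
        "bounds_active": _bound_activity(sol.x, bounds),
        "n_points": int(lam.size),
        "engine": engine,
    }
    return fp, 2.0 * float(sol.cost), info


def identify_two_step(
    exp: ExperimentCurves,
    net: FiberNetwork,
    engine: str = "affine",
    matrix_bounds=MATRIX_BOUNDS,
    fiber_bounds=FIBER_BOUNDS,
    seed: int = 0,
    fe_h: float | None = None,
) -> IdentResult:
    """Run step 1 (matrix) then step 2 (fibers) and record everything needed
    to reproduce the result (seeds, engine, bound activity)."""
    mp, chi2_m, info_m = fit_matrix(exp, bounds=matrix_bounds, seed=seed)
    fp, chi2_f, info_f = fit_fibers(
        exp, mp, net, engine=engine, bounds=fiber_bounds, seed=seed, fe_h=fe_h
    )
    return IdentResult(
        matrix=mp,
        fibers=fp,
        chi2_matrix=chi2_m,
        chi2_fibers=chi2_f,
        iterations={"matrix": info_m["iterations"], "fibers": info_f["iterations"]},
        bounds_active={"matrix": info_m["bounds_active"], "fibers": info_f["bounds_active"]},
        seeds={"optimizer": seed, "network": net.seed},
    )
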