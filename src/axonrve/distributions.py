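"""Probability densities of axon-fiber microstructure.

Three fiber properties are described statistically, following histological
observations of corpus callosum white matter:

* **diameter** ``d`` (µm) — generalized extreme value (GEV) law with location
  ``mu``, scale ``sigma`` and shape ``xi``;
* **straightness** ``Ps = L0/Lf ∈ (0, 1]`` (end-to-end over arc length; the
  complement of tortuosity) — beta law with shapes ``a, b``;
* **orientation** — bivariate von Mises density over azimuth Φ and elevation Θ
  with in-plane / out-of-plane concentrations ``alpha, beta``; infinite
  concentration denotes perfect alignment with the fiber axis e1.

The orientation density is the product of an in-plane factor
``exp(α cos 2Φ)/I0(α)`` and an out-of-plane factor
``2 sqrt(2β/π) exp[β(cos 2Θ − 1)]/erf(sqrt(2β))``.  As printed, the product is
normalized against the *spherical area measure* ``cosΘ dΘ dΦ`` with a 1/(4π)
reference: the analytic integral of the product over the sphere equals 4π for
every finite (α, β).  Sampling therefore includes the cosΘ area factor, so
``alpha = beta = 0`` yields directions uniform on the unit sphere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats

__all__ = [
    "GEVParams",
    "BetaParams",
    "OrientationParams",
    "gev_pdf",
    "gev_mean",
    "gev_sample",
    "gev_fit",
    "beta_pdf",
    "beta_mean",
    "beta_sample",
    "beta_fit",
    "orientation_pdf",
    "orientation_normalization",
    "orientation_sample",
    "load_sample_csv",
]

logger = logging.getLogger(__name__)


class InvalidParameterError(ValueError):
    """A distribution parameter violates its support constraints."""


class FitError(RuntimeError):
    """Maximum-likelihood fitting failed (degenerate or insufficient data)."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GEVParams:
    """GEV diameter distribution: location ``mu`` (µm), scale ``sigma`` (µm, > 0),
    shape ``xi`` (negative shape gives an upper-bounded support)."""

    mu: float
    sigma: float
    xi: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise InvalidParameterError(f"GEV scale must be > 0, got {self.sigma}")

    def frozen(self):
        # scipy's genextreme shape convention is c = -xi
        return stats.genextreme(c=-self.xi, loc=self.mu, scale=self.sigma)


@dataclass(frozen=True)
class BetaParams:
    """Beta straightness distribution on (0, 1): shapes ``a, b > 0``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise InvalidParameterError(f"beta shapes must be > 0, got ({self.a}, {self.b})")

    def frozen(self):
        return stats.beta(self.a, self.b)

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class OrientationParams:
    """Bivariate von Mises orientation: in-plane concentration ``alpha`` and
    out-of-plane concentration ``beta`` (both ≥ 0; ``math.inf`` = aligned)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise InvalidParameterError("concentration parameters must be >= 0")

    @property
    def aligned_in_plane(self) -> bool:
        return math.isinf(self.alpha)

    @property
    def aligned_out_of_plane(self) -> bool:
        return math.isinf(self.beta)

    @property
    def fully_aligned(self) -> bool:
        return self.aligned_in_plane and self.aligned_out_of_plane


ISOTROPIC = OrientationParams(0.0, 0.0)
ALIGNED = OrientationParams(math.inf, math.inf)


# ---------------------------------------------------------------------------
# GEV diameter law
# ---------------------------------------------------------------------------


def gev_pdf(d, p: GEVParams):
    """GEV probability density of fiber diameter ``d`` (1/µm).

    Out-of-support diameters return zero density.
    """
    d = np.asarray(d, dtype=float)
    out = p.frozen().pdf(d)
    return out if out.shape else float(out)


def gev_mean(p: GEVParams) -> float:
    """Closed-form mean ``mu + sigma (Γ(1 − xi) − 1)/xi`` (requires xi < 1)."""
    if p.xi >= 1:
        raise InvalidParameterError("GEV mean undefined for xi >= 1")
    if p.xi == 0:
        return p.mu + p.sigma * np.euler_gamma
    return p.mu + p.sigma * (special.gamma(1.0 - p.xi) - 1.0) / p.xi


def gev_sample(p: GEVParams, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` strictly positive diameters; non-positive draws (possible for
    left-unbounded shapes) are rejected and redrawn."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    dist = p.frozen()
    out = np.empty(n)
    filled = 0
    rejected = 0
    while filled < n:
        draw = dist.rvs(size=n - filled, random_state=rng)
        draw = np.atleast_1d(draw)
        good = draw[draw > 0]
        rejected += draw.size - good.size
        out[filled : filled + good.size] = good
        filled += good.size
    if rejected:
        logger.info("gev_sample: rejected %d non-positive draws", rejected)
    return out


def _mle_restarts(neg_loglik, x0, bounds, seed=0, n_restarts=3):
    """Bounded quasi-Newton MLE with random restarts.

    Ties are broken by highest log-likelihood, then lowest parameter norm.
    """
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = [np.asarray(x0, dtype=float)]
    for _ in range(n_restarts):
        jitter = 1.0 + 0.2 * rng.standard_normal(len(x0))
        starts.append(np.clip(np.asarray(x0) * jitter, lo + 1e-10, hi - 1e-10))
    best = None  # (neg loglik, parameter norm, x): ties by loglik then lowest norm
    for s in starts:
        with np.errstate(invalid="ignore"):  # finite-difference probes may leave support
            res = optimize.minimize(neg_loglik, s, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            continue
        key = (float(res.fun), float(np.linalg.norm(res.x)))
        if best is None or key < best[:2]:
            best = (*key, res.x)
    if best is None:
        raise FitError("all MLE restarts diverged")
    return best[2]


def gev_fit(samples, method: str = "mle") -> GEVParams:
    """Fit a GEV law to raw diameter samples.

    ``method='mle'`` (default) maximizes the log-likelihood with an L-BFGS-B
    search refined from scipy's internal MLE; ``method='lsq'`` least-squares
    fits the density to a histogram of the sample.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 50:
        raise FitError(f"need at least 50 samples to fit a GEV, got {x.size}")
    if np.ptp(x) == 0:
        raise FitError("degenerate (constant) sample")
    with np.errstate(invalid="ignore"):  # scipy's fit probes out-of-support points
        c0, loc0, scale0 = stats.genextreme.fit(x)
    if method == "lsq":
        counts, edges = np.histogram(x, bins=64, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])

        def resid(theta):
            mu, sigma, xi = theta
            if sigma <= 0:
                return np.full_like(centers, 1e6)
            return stats.genextreme.pdf(centers, c=-xi, loc=mu, scale=sigma) - counts

        sol = optimize.least_squares(resid, x0=[loc0, scale0, -c0], method="trf")
        mu, sigma, xi = sol.x
        return GEVParams(float(mu), float(sigma), float(xi))
    if method != "mle":
        raise ValueError(f"unknown fit method {method!r}")

    def nll(theta):
        mu, sigma, xi = theta
        if sigma <= 0:
            return np.inf
        ll = stats.genextreme.logpdf(x, c=-xi, loc=mu, scale=sigma)
        if not np.all(np.isfinite(ll)):
            return np.inf
        return -float(ll.sum())

    span = np.ptp(x)
    bounds = [(x.min() - span, x.max() + span), (1e-8 * span, 10 * span), (-5.0, 0.99)]
    mu, sigma, xi = _mle_restarts(nll, [loc0, scale0, -c0], bounds)
    return GEVParams(float(mu), float(sigma), float(xi))


# ---------------------------------------------------------------------------
# beta straightness law
# ---------------------------------------------------------------------------


def beta_pdf(ps, p: BetaParams):
    """Beta density of the straightness parameter on (0, 1); zero outside."""
    ps = np.asarray(ps, dtype=float)
    out = p.frozen().pdf(ps)
    return out if out.shape else float(out)


def beta_mean(p: BetaParams) -> float:
    return p.mean


def beta_sample(p: BetaParams, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` straightness values in (0, 1); endpoint draws are rejected so
    1/Ps stays finite."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = np.atleast_1d(p.frozen().rvs(size=n - filled, random_state=rng))
        good = draw[(draw > 0) & (draw < 1)]
        out[filled : filled + good.size] = good
        filled += good.size
    return out


def beta_fit(samples, method: str = "mle") -> BetaParams:
    """Fit a beta law to straightness samples in (0, 1) (MLE by default)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 50:
        raise FitError(f"need at least 50 samples to fit a beta law, got {x.size}")
    if np.ptp(x) == 0:
        raise FitError("degenerate (constant) sample")
    if np.any((x <= 0) | (x >= 1)):
        raise InvalidParameterError("straightness samples must lie in (0, 1)")
    a0, b0, _, _ = stats.beta.fit(x, floc=0, fscale=1)
    if method == "lsq":
        counts, edges = np.histogram(x, bins=64, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])

        def resid(theta):
            return stats.beta.pdf(centers, *np.maximum(theta, 1e-8)) - counts

        sol = optimize.least_squares(resid, x0=[a0, b0], method="trf")
        return BetaParams(float(max(sol.x[0], 1e-8)), float(max(sol.x[1], 1e-8)))
    if method != "mle":
        raise ValueError(f"unknown fit method {method!r}")

    def nll(theta):
        a, b = theta
        if a <= 0 or b <= 0:
            return np.inf
        return -float(stats.beta.logpdf(x, a, b).sum())

    a, b = _mle_restarts(nll, [a0, b0], [(1e-6, 1e4), (1e-6, 1e4)])
    return BetaParams(float(a), float(b))


# ---------------------------------------------------------------------------
# bivariate von Mises orientation law
# ---------------------------------------------------------------------------


def _in_plane_factor(phi, alpha):
    # exp(alpha cos 2Φ)/I0(alpha), computed via the scaled Bessel function to
    # stay finite for large concentrations
    return np.exp(alpha * (np.cos(2.0 * phi) - 1.0)) / special.i0e(alpha)


def _out_of_plane_factor(theta, beta):
    if beta == 0:
        return np.ones_like(np.asarray(theta, dtype=float))
    # 2 sqrt(2β/π) exp[β(cos2Θ − 1)]/erf(sqrt(2β))
    norm = 2.0 * math.sqrt(2.0 * beta / math.pi) / special.erf(math.sqrt(2.0 * beta))
    return norm * np.exp(beta * (np.cos(2.0 * theta) - 1.0))


def orientation_pdf(phi, theta, p: OrientationParams, normalized: bool = False):
    """Bivariate von Mises orientation density ρ_ip(Φ)·ρ_op(Θ).

    As printed the product integrates to 4π against the spherical area measure
    cosΘ dΘ dΦ.  With ``normalized=True`` the value is divided by the
    numerically computed constant so that ∬ ρ cosΘ dΘ dΦ = 1.

    Degenerate (infinite) concentrations have no density; use
    :func:`orientation_sample` for aligned populations.
    """
    if p.aligned_in_plane or p.aligned_out_of_plane:
        raise InvalidParameterError(
            "orientation density undefined for infinite concentration; "
            "use orientation_sample for aligned fibers"
        )
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    val = _in_plane_factor(phi, p.alpha) * _out_of_plane_factor(theta, p.beta)
    if normalized:
        val = val / orientation_normalization(p.alpha, p.beta)
    return val if val.shape else float(val)


@lru_cache(maxsize=128)
def orientation_normalization(alpha: float, beta: float) -> float:
    """Numerical normalization constant ∬ ρ_ip ρ_op cosΘ dΘ dΦ (→ 4π analytically)."""
    p = OrientationParams(alpha, beta)

    def integrand(theta, phi):
        return float(
            _in_plane_factor(np.float64(phi), p.alpha)
            * _out_of_plane_factor(np.float64(theta), p.beta)
            * math.cos(theta)
        )

    val, _ = integrate.dblquad(
        integrand, 0.0, 2.0 * math.pi, -math.pi / 2.0, math.pi / 2.0,
        epsabs=1e-10, epsrel=1e-10,
    )
    return val


def _sample_in_plane(alpha: float, n: int, rng) -> np.ndarray:
    if alpha == 0:
        return rng.uniform(0.0, 2.0 * math.pi, size=n)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(n - filled, 256)
        phi = rng.uniform(0.0, 2.0 * math.pi, size=m)
        u = rng.uniform(size=m)
        keep = phi[u < np.exp(alpha * (np.cos(2.0 * phi) - 1.0))]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _sample_out_of_plane(beta: float, n: int, rng) -> np.ndarray:
    # proposal: elevation of a sphere-uniform direction (density cosΘ/2)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(n - filled, 256)
        theta = np.arcsin(rng.uniform(-1.0, 1.0, size=m))
        if beta == 0:
            keep = theta
        else:
            u = rng.uniform(size=m)
            keep = theta[u < np.exp(beta * (np.cos(2.0 * theta) - 1.0))]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def orientation_sample(p: OrientationParams, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` unit direction vectors N(Φ, Θ) = (cosΦ cosΘ, sinΦ cosΘ, sinΘ).

    Angles are drawn by rejection against the von Mises factors with the
    spherical area factor cosΘ in the elevation proposal, so zero
    concentrations yield directions uniform on the sphere.  Infinite
    concentrations pin the corresponding angle to zero; fully aligned
    parameters return N = e1 for every fiber.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    if p.fully_aligned:
        out = np.zeros((n, 3))
        out[:, 0] = 1.0
        return out
    phi = np.zeros(n) if p.aligned_in_plane else _sample_in_plane(p.alpha, n, rng)
    theta = np.zeros(n) if p.aligned_out_of_plane else _sample_out_of_plane(p.beta, n, rng)
    ct = np.cos(theta)
    return np.column_stack((np.cos(phi) * ct, np.sin(phi) * ct, np.sin(theta)))


# ---------------------------------------------------------------------------
# CSV helpers for fitting user-supplied data
# ---------------------------------------------------------------------------


def load_sample_csv(path, histogram: bool = False):
    """Read fitting input.

    Raw mode (default): one-column CSV of samples → 1-D array.
    ``histogram=True``: two-column CSV ``bin_center,value`` → (centers, values).
    """
    df = pd.read_csv(path)
    if histogram:
        if df.shape[1] != 2:
            raise ValueError(f"histogram CSV must have 2 columns, got {df.shape[1]}")
        return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
    if df.shape[1] != 1:
        raise ValueError(f"raw sample CSV must have 1 column, got {df.shape[1]}")
    return df.iloc[:, 0].to_numpy(float)
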