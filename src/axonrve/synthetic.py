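"""Pseudo-experimental data generation.

Emulates uniaxial and simple-shear nominal-stress curves of human corpus
callosum (deformations up to 20%) by running the package's own forward model
(affine homogenization on a generated fiber network) and perturbing the
stresses with multiplicative Gaussian noise, stress × (1 + σ·ε).  The
zero-stress identity point is never perturbed — it is a physical anchor.
The default noise level is σ = 5% (multiplicative, because soft-tissue
stress magnitudes span decades across modes); additive noise is available.

Also writes sample-file fixtures for the distribution-fitting pipeline,
standing in for digitized histology histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .affine import response_curve
from .constitutive import FiberParams, MatrixParams
from .distributions import beta_sample, gev_sample
from .identify import ExperimentCurves
from .loading import ALL_MODES, default_amounts
from .network import FiberNetwork, StructuralParams, corpus_callosum_params, generate_rve

__all__ = ["SyntheticConfig", "make_experiment", "make_histogram_fixture"]


@dataclass
class SyntheticConfig:
    """Ground truth and sampling plan for one pseudo-experiment.

    Defaults reproduce the study conditions: the corpus-callosum structural
    parameters on a 25 µm RVE, the identified material constants with an
    incompressible matrix, all seven loading modes on 21-point grids
    (stretch 0.8–1.2, shear 0–0.2), 5% multiplicative noise.
    """

    matrix: MatrixParams = field(
        default_factory=lambda: MatrixParams(353.5, -21.5, None)
    )
    fibers: FiberParams = field(default_factory=lambda: FiberParams(80.8, 62.3))
    structural: StructuralParams = field(default_factory=corpus_callosum_params)
    La: float = 25.0
    modes: tuple = ALL_MODES
    n_steps: int = 21
    noise_sigma: float = 0.05
    noise_model: str = "multiplicative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise level must be >= 0")
        if self.noise_model not in ("multiplicative", "additive"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        unknown = set(self.modes) - set(ALL_MODES)
        if unknown:
            raise ValueError(f"unknown modes {sorted(unknown)}")


def make_experiment(cfg: SyntheticConfig) -> tuple[ExperimentCurves, FiberNetwork]:
    """Forward-model curves for every configured mode, with noise.

    The network is generated from ``cfg.seed``; the noise stream is a separate
    seeded generator so the same network can carry different noise
    realizations.  Returns the curves and the network they were computed on.
    """
    net = generate_rve(cfg.structural, cfg.La, seed=cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    curves = {}
    for mode in cfg.modes:
        c = response_curve(net, mode, cfg.matrix, cfg.fibers, n_steps=cfg.n_steps)
        y = c.P_total.copy()
        if cfg.noise_sigma > 0:
            eps = rng.standard_normal(y.size)
            if cfg.noise_model == "multiplicative":
                y = y * (1.0 + cfg.noise_sigma * eps)
            else:
                scale = np.abs(c.P_total).max()
                y = y + cfg.noise_sigma * scale * eps
        ref = 0.0 if mode.startswith("shear") else 1.0
        y[np.isclose(c.amounts, ref)] = 0.0  # identity point is exact
        curves[mode] = (c.amounts, y)
    return ExperimentCurves(curves), net


def make_histogram_fixture(family: str, params, n: int, seed: int, path) -> None:
    """Write an ``n``-sample one-column CSV fixture for ``family`` ('gev'
    diameters or 'beta' straightness); byte-identical for a fixed seed."""
    if family == "gev":
        x = gev_sample(params, n, seed)
        name = "diameter_um"
    elif family == "beta":
        x = beta_sample(params, n, seed)
        name = "straightness"
    else:
        raise ValueError(f"unknown distribution family {family!r}")
    pd.DataFrame({name: x}).to_csv(path, index=False, float_format="%.17g")
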