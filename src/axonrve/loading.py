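"""The seven canonical macroscopic loading modes of the white-matter RVE.

The mean fiber axis is the global x-axis (e1 = F direction, e2/e3 = T).
Uniaxial modes prescribe the isochoric ansatz diag(λ, λ^{-1/2}, λ^{-1/2})
(stretch axis e1 for FF, e2 for TT) — exact in the incompressible-matrix limit,
and aligned fibers add no lateral stress.  Simple-shear modes prescribe
F = I + γ e_i ⊗ e_j with the convention *first letter = displacement
direction, second = face-normal direction*:

    shear_FT → I + γ e1⊗e2,  shear_TF → I + γ e2⊗e1,  shear_TT → I + γ e2⊗e3.

Each mode's work-conjugate nominal-stress component is the (i, j) pair
returned by :func:`conjugate_index`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UNIAXIAL_MODES",
    "SHEAR_MODES",
    "ALL_MODES",
    "LoadingMode",
    "macro_F",
    "conjugate_index",
    "default_amounts",
]

UNIAXIAL_MODES = ("compression_FF", "tension_FF", "compression_TT", "tension_TT")
SHEAR_MODES = ("shear_FT", "shear_TF", "shear_TT")
ALL_MODES = UNIAXIAL_MODES + SHEAR_MODES

_SHEAR_AXES = {"shear_FT": (0, 1), "shear_TF": (1, 0), "shear_TT": (1, 2)}
_STRETCH_AXIS = {"compression_FF": 0, "tension_FF": 0, "compression_TT": 1, "tension_TT": 1}


@dataclass(frozen=True)
class LoadingMode:
    """One macroscopic loading state: a mode label and its amount (stretch λ
    for uniaxial modes, amount of shear γ for shear modes)."""

    label: str
    amount: float

    def __post_init__(self) -> None:
        if self.label not in ALL_MODES:
            raise ValueError(f"unknown loading mode {self.label!r}; valid: {ALL_MODES}")
        if self.label in UNIAXIAL_MODES:
            if not (0.0 < self.amount):
                raise ValueError(f"stretch must be positive, got {self.amount}")
            if "compression" in self.label and self.amount > 1.0:
                raise ValueError(f"{self.label} expects stretch <= 1, got {self.amount}")
            if "tension" in self.label and self.amount < 1.0:
                raise ValueError(f"{self.label} expects stretch >= 1, got {self.amount}")
        elif self.amount < 0.0:
            raise ValueError(f"amount of shear must be >= 0, got {self.amount}")


def macro_F(mode: LoadingMode) -> np.ndarray:
    """Macroscopic deformation gradient of a loading mode (det = 1 for the
    uniaxial isochoric modes; identity at zero shear)."""
    F = np.eye(3)
    if mode.label in UNIAXIAL_MODES:
        lam = mode.amount
        axis = _STRETCH_AXIS[mode.label]
        F *= lam**-0.5
        F[axis, axis] = lam
    else:
        i, j = _SHEAR_AXES[mode.label]
        F[i, j] += mode.amount
    return F


def conjugate_index(label: str) -> tuple[int, int]:
    """(i, j) of the nominal-stress component work-conjugate to the mode's
    amount: P11 for FF uniaxial, P22 for TT uniaxial, P_ij for shear."""
    if label in _STRETCH_AXIS:
        a = _STRETCH_AXIS[label]
        return a, a
    if label in _SHEAR_AXES:
        return _SHEAR_AXES[label]
    raise ValueError(f"unknown loading mode {label!r}")


def default_amounts(label: str, n_steps: int = 21, limit: float | None = None) -> np.ndarray:
    """Monotone amount grid from the reference state to the study limit
    (stretch 0.8/1.2 for compression/tension, shear 0.2)."""
    if n_steps < 2:
        raise ValueError("need at least 2 steps")
    if label not in ALL_MODES:
        raise ValueError(f"unknown loading mode {label!r}")
    if label in SHEAR_MODES:
        return np.linspace(0.0, 0.2 if limit is None else limit, n_steps)
    if "compression" in label:
        return np.linspace(1.0, 0.8 if limit is None else limit, n_steps)
    return np.linspace(1.0, 1.2 if limit is None else limit, n_steps)
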