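"""Random axon-fiber networks inside a cubic representative volume element.

Fibers are straight 1-D chords: a direction drawn from the orientation law,
an anchor point uniform in the open cube, and the segment extended to the cube
boundary in both directions.  Diameter and straightness are attached from
their respective laws.  Fibers are added until the cumulative reference
volume Σ π d²/4 · L0 reaches the target fraction of the cube volume, so the
achieved fraction overshoots the target by at most one fiber's volume.

Conventions (recorded in the JSON sidecar of every written network):

* chords are clipped to the cube — no periodic wrapping across faces;
* volume bookkeeping uses the end-to-end (chord) length L0, not the arc
  length L0/Ps: tortuosity enters only the constitutive law through the
  recruitment stretch (``arc_length_volume=True`` switches the bookkeeping);
* fibers are 1-D entities, so fiber–fiber overlap is not checked;
* chords shorter than ``min_chord`` are rejected to keep finite-element
  embedding well-posed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import (
    ALIGNED,
    BetaParams,
    GEVParams,
    OrientationParams,
    beta_sample,
    gev_sample,
    orientation_sample,
)

__all__ = [
    "StructuralParams",
    "FiberNetwork",
    "corpus_callosum_params",
    "generate_rve",
    "network_volume_fraction",
    "write_network",
    "read_network",
]


class NetworkGenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class StructuralParams:
    """Histology statistics defining an RVE population: target fiber volume
    fraction plus the three property distributions."""

    v_f: float
    diameter: GEVParams
    straightness: BetaParams
    orientation: OrientationParams

    def __post_init__(self) -> None:
        if not (0.0 < self.v_f < 1.0):
            raise ValueError(f"volume fraction must be in (0, 1), got {self.v_f}")

    def to_dict(self) -> dict:
        return {
            "v_f": self.v_f,
            "diameter": dataclasses.asdict(self.diameter),
            "straightness": dataclasses.asdict(self.straightness),
            "orientation": {
                "alpha": "inf" if math.isinf(self.orientation.alpha) else self.orientation.alpha,
                "beta": "inf" if math.isinf(self.orientation.beta) else self.orientation.beta,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StructuralParams":
        ori = d["orientation"]
        conv = lambda v: math.inf if v in ("inf", "Infinity", None) else float(v)
        return cls(
            v_f=float(d["v_f"]),
            diameter=GEVParams(**d["diameter"]),
            straightness=BetaParams(**d["straightness"]),
            orientation=OrientationParams(conv(ori["alpha"]), conv(ori["beta"])),
        )


def corpus_callosum_params() -> StructuralParams:
    """Default corpus-callosum histology: 40% axon volume fraction, GEV
    diameters (0.426 µm location, 0.200 µm scale, −0.305 shape), beta
    straightness (9.155, 1.275), perfectly aligned orientation."""
    return StructuralParams(
        v_f=0.400,
        diameter=GEVParams(0.426, 0.200, -0.305),
        straightness=BetaParams(9.155, 1.275),
        orientation=ALIGNED,
    )


@dataclass
class FiberNetwork:
    """A realized fiber population in the cube [0, La]³.

    Per-fiber arrays: ``anchor`` (chord start point on the cube boundary, µm),
    ``N`` (unit direction), ``L0`` (end-to-end chord length, µm), ``d``
    (diameter, µm), ``Ps`` (straightness in (0, 1]).
    """

    La: float
    anchor: np.ndarray  # (Nf, 3)
    N: np.ndarray  # (Nf, 3)
    L0: np.ndarray  # (Nf,)
    d: np.ndarray  # (Nf,)
    Ps: np.ndarray  # (Nf,)
    seed: int | None = None
    structural: StructuralParams | None = None
    achieved_vf: float = field(default=0.0)

    @property
    def n_fibers(self) -> int:
        return int(self.L0.size)

    @property
    def fiber_volumes(self) -> np.ndarray:
        """Reference chord volumes π d²/4 · L0 (µm³)."""
        return math.pi * self.d**2 / 4.0 * self.L0

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.anchor, self.anchor + self.L0[:, None] * self.N


def network_volume_fraction(net: FiberNetwork) -> float:
    """Total fiber reference volume Σ π d²/4 · L0 over the cube volume La³."""
    if net.n_fibers == 0:
        return 0.0
    return float(net.fiber_volumes.sum() / net.La**3)


def _clip_chords(anchor: np.ndarray, N: np.ndarray, La: float):
    """Extend lines anchor + t·N to the cube [0, La]³ (slab intersection).

    Returns chord start points, lengths.  Anchors are interior, so every line
    intersects the cube in a nonempty chord.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = (0.0 - anchor) / N
        t1 = (La - anchor) / N
    lo = np.where(np.isfinite(t0), np.minimum(t0, t1), -np.inf)
    hi = np.where(np.isfinite(t0), np.maximum(t0, t1), np.inf)
    t_min = lo.max(axis=1)
    t_max = hi.min(axis=1)
    start = anchor + t_min[:, None] * N
    return start, t_max - t_min


def generate_rve(
    sp: StructuralParams,
    La: float,
    seed: int,
    min_chord: float | None = None,
    arc_length_volume: bool = False,
    max_fibers: int = 2_000_000,
) -> FiberNetwork:
    """Generate a random fiber network matching ``sp`` inside a cube of edge
    ``La`` (µm).

    Fibers are accumulated until the cumulative fiber volume reaches
    ``sp.v_f · La³``; the achieved fraction overshoots the target by at most
    one fiber volume.  Fully reproducible for a fixed ``seed``.

    Parameters
    ----------
    min_chord : float, optional
        Chords shorter than this are rejected (default La/20, roughly one
        matrix element of the default FE discretization).
    arc_length_volume : bool
        Book-keep fiber volume with the arc length L0/Ps instead of the chord
        length L0.
    """
    if not (La > 0):
        raise ValueError(f"edge length must be positive, got {La}")
    if min_chord is None:
        min_chord = La / 20.0
    target = sp.v_f * La**3
    batch = 1024
    anchors, dirs, lens, dias, straights = [], [], [], [], []
    cum = 0.0
    n_total = 0
    rng_streams = np.random.SeedSequence(seed).spawn(4)
    s_ori, s_anchor, s_d, s_ps = (int(s.generate_state(1)[0] % 2**31) for s in rng_streams)
    anchor_rng = np.random.default_rng(s_anchor)
    batch_idx = 0
    while cum < target:
        if n_total > max_fibers:
            raise NetworkGenerationError(
                f"failed to reach v_f={sp.v_f} after {n_total} fibers "
                f"(cumulative fraction {cum / La**3:.4f}); check parameters"
            )
        N = orientation_sample(sp.orientation, batch, s_ori + batch_idx)
        X = anchor_rng.uniform(0.0, La, size=(batch, 3))
        start, L0 = _clip_chords(X, N, La)
        d = gev_sample(sp.diameter, batch, s_d + batch_idx)
        Ps = beta_sample(sp.straightness, batch, s_ps + batch_idx)
        keep = L0 >= min_chord
        start, N, L0, d, Ps = start[keep], N[keep], L0[keep], d[keep], Ps[keep]
        length = L0 / Ps if arc_length_volume else L0
        vol = math.pi * d**2 / 4.0 * length
        cumvol = cum + np.cumsum(vol)
        if cumvol.size and cumvol[-1] >= target:
            stop = int(np.searchsorted(cumvol, target) + 1)
        else:
            stop = vol.size
        anchors.append(start[:stop])
        dirs.append(N[:stop])
        lens.append(L0[:stop])
        dias.append(d[:stop])
        straights.append(Ps[:stop])
        cum = cumvol[stop - 1] if stop else cum
        n_total += stop
        batch_idx += 1
    net = FiberNetwork(
        La=float(La),
        anchor=np.concatenate(anchors),
        N=np.concatenate(dirs),
        L0=np.concatenate(lens),
        d=np.concatenate(dias),
        Ps=np.concatenate(straights),
        seed=seed,
        structural=sp,
    )
    net.achieved_vf = network_volume_fraction(net)
    return net


# ---------------------------------------------------------------------------
# file round-trip: CSV table + JSON sidecar
# ---------------------------------------------------------------------------

_COLUMNS = ["anchor_x", "anchor_y", "anchor_z", "Nx", "Ny", "Nz", "L0", "d", "Ps"]


def write_network(net: FiberNetwork, path) -> None:
    """Write the fiber table as CSV plus a ``<path>.json`` sidecar holding the
    edge length, seed, structural parameters and achieved volume fraction."""
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([net.anchor, net.N, net.L0, net.d, net.Ps]), columns=_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "La": net.La,
        "seed": net.seed,
        "achieved_vf": net.achieved_vf,
        "structural": net.structural.to_dict() if net.structural else None,
        "conventions": {"chords": "clipped", "volume": "chord_length"},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_network(path) -> FiberNetwork:
    """Read a network written by :func:`write_network` (lossless round-trip)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"cannot parse network file {path}: {exc}") from exc
    if list(df.columns) != _COLUMNS:
        raise ValueError(f"{path}: expected columns {_COLUMNS}, got {list(df.columns)}")
    if df.empty:
        raise ValueError(f"{path}: network file contains no fibers")
    bad = df.index[(df["d"] <= 0) | (df["L0"] <= 0) | (df["Ps"] <= 0) | (df["Ps"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: invalid fiber fields at data line {bad[0] + 2}")
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise ValueError(f"missing network sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    structural = (
        StructuralParams.from_dict(meta["structural"]) if meta.get("structural") else None
    )
    net = FiberNetwork(
        La=float(meta["La"]),
        anchor=df[["anchor_x", "anchor_y", "anchor_z"]].to_numpy(float),
        N=df[["Nx", "Ny", "Nz"]].to_numpy(float),
        L0=df["L0"].to_numpy(float),
        d=df["d"].to_numpy(float),
        Ps=df["Ps"].to_numpy(float),
        seed=meta.get("seed"),
        structural=structural,
        achieved_vf=float(meta["achieved_vf"]),
    )
    return net
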