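"""Helical-lattice geometry for filamentous enzyme assemblies.

A helical filament is generated from one asymmetric unit by repeated
application of a screw operation: a rotation Δφ (the helical twist, in
degrees per subunit, negative = left-handed) about the helix axis combined
with an axial translation (the rise, in Å per subunit). All filament
descriptors — subunits per turn, pitch, the half-pitch translation relating
the two diad axes, the expected monomer count inside a boxed segment —
derive from (Δφ, rise).

The module also quantifies how a point at fixed radius moves in the helical
plane when the inter-subunit twist changes (the lid-loop displacement
argument: at constant filament diameter, a smaller twist magnitude swings
loop anchors further, producing steric clashes unless the loop opens), and
counts steric clashes between coordinate sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from .io import CoordinateModel

__all__ = [
    "HelicalParams",
    "ScrewOperation",
    "SegmentSpec",
    "subunits_per_turn",
    "twist_from_subunits_per_turn",
    "pitch",
    "half_pitch",
    "screw_operation",
    "monomers_per_segment",
    "generate_filament",
    "loop_displacement",
    "count_clashes",
]

#: Conventional heavy-atom contact threshold, Å.
DEFAULT_CLASH_CUTOFF = 3.0


@dataclass(frozen=True)
class HelicalParams:
    """Signed twist (degrees per subunit; negative = left-handed) and rise (Å)."""

    twist: float
    rise: float

    def __post_init__(self) -> None:
        if not 0.0 < abs(self.twist) <= 180.0:
            raise ValueError("twist magnitude must be in (0, 180] degrees")
        if self.rise <= 0.0:
            raise ValueError("rise must be positive")

    @property
    def handedness(self) -> str:
        return "left" if self.twist < 0 else "right"


@dataclass(frozen=True)
class ScrewOperation:
    """Rotation (degrees, reduced to (−180, 180]) and axial translation (Å)."""

    rotation: float
    translation: float


@dataclass(frozen=True)
class SegmentSpec:
    """A boxed filament segment: box size (px), pixel size (Å/px), monomers
    per helical subunit (2 for dimeric nitrilase subunits)."""

    box_px: int
    pixel_size: float
    monomers_per_subunit: int = 2

    def __post_init__(self) -> None:
        if self.box_px <= 0 or self.pixel_size <= 0 or self.monomers_per_subunit <= 0:
            raise ValueError("segment parameters must be strictly positive")


def subunits_per_turn(p: HelicalParams) -> float:
    """Number of subunits in one full 360° helical turn."""
    return 360.0 / abs(p.twist)


def twist_from_subunits_per_turn(u: float, handedness: Literal["left", "right"]) -> float:
    """Signed twist from subunits/turn; inverse of :func:`subunits_per_turn`."""
    if u <= 1.0:
        raise ValueError("subunits per turn must exceed 1")
    if handedness not in ("left", "right"):
        raise ValueError("handedness must be 'left' or 'right'")
    mag = 360.0 / u
    return -mag if handedness == "left" else mag


def pitch(p: HelicalParams) -> float:
    """Axial distance (Å) covered by one full turn: rise × subunits/turn."""
    return p.rise * subunits_per_turn(p)


def half_pitch(p: HelicalParams) -> float:
    """Half the pitch (Å): the axial translation relating the two diad axes."""
    return pitch(p) / 2.0


def _reduce_angle(deg: float) -> float:
    """Reduce an angle to (−180, 180]."""
    r = math.fmod(deg, 360.0)
    if r <= -180.0:
        r += 360.0
    elif r > 180.0:
        r -= 360.0
    return r


def screw_operation(k: int, p: HelicalParams) -> ScrewOperation:
    """The k-step screw: rotation k·Δφ (reduced) and translation k·rise.

    Satisfies the composition law screw(a)∘screw(b) = screw(a+b).
    """
    return ScrewOperation(
        rotation=_reduce_angle(k * p.twist), translation=k * p.rise
    )


def monomers_per_segment(s: SegmentSpec, p: HelicalParams) -> float:
    """Expected monomer count in a boxed segment of the filament."""
    return (s.box_px * s.pixel_size / p.rise) * s.monomers_per_subunit


def _rotation_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generate_filament(
    asu: CoordinateModel, p: HelicalParams, copies: int
) -> CoordinateModel:
    """Symmetry-expand a single-subunit asymmetric unit into a filament.

    Copy j is the asu rotated by j·Δφ about z (counter-clockwise positive,
    viewed from +z) and translated by j·rise along z. The asu must be
    pre-oriented with the helix axis along z.
    """
    if asu.n_subunits != 1:
        raise ValueError("asymmetric unit must contain exactly one subunit")
    if copies < 1:
        raise ValueError("need at least one copy")
    coords = []
    sub_ids = []
    atom_ids: list[str] = []
    for j in range(copies):
        xyz = asu.coords @ _rotation_z(j * p.twist).T
        xyz = xyz + np.array([0.0, 0.0, j * p.rise])
        coords.append(xyz)
        sub_ids.append(np.full(len(xyz), j))
        atom_ids.extend(asu.atom_ids)
    return CoordinateModel(
        subunit_ids=np.concatenate(sub_ids),
        atom_ids=atom_ids,
        coords=np.vstack(coords),
    )


def loop_displacement(
    radius: float,
    twist_a: float,
    twist_b: float,
    mode: Literal["chord", "arc"] = "chord",
) -> float:
    """In-plane movement (Å) of a point at the given radius when the
    inter-subunit twist changes from twist_a to twist_b degrees.

    "chord" is the straight-line point-to-point distance 2r·sin(Δ/2);
    "arc" is the path length r·Δ (radians) along the lattice circle.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    delta = abs(twist_a - twist_b)
    if mode == "chord":
        return 2.0 * radius * math.sin(math.radians(delta) / 2.0)
    if mode == "arc":
        return radius * math.radians(delta)
    raise ValueError(f"unknown displacement mode {mode!r}")


def count_clashes(
    a: CoordinateModel | np.ndarray,
    b: CoordinateModel | np.ndarray,
    cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> int:
    """Number of inter-set atom pairs closer than ``cutoff`` Å."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    xa = a.coords if isinstance(a, CoordinateModel) else np.asarray(a, dtype=float)
    xb = b.coords if isinstance(b, CoordinateModel) else np.asarray(b, dtype=float)
    return int(np.count_nonzero(cdist(xa, xb) < cutoff))
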