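"""Seeded generators for synthetic inputs with known ground truth.

Each generator is a pure function of its scenario (seed included) and
emulates the statistical structure one pipeline stage assumes: grouped
alignments with planted determinant columns for the specificity scan,
uniform codon sampling for the library coverage statistics, pseudo-atom
helical asymmetric units (optionally with a protruding "closed-lid" arm)
for the lattice geometry, and linear-plus-noise kinetics for the activity
reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import helix
from .activity import ActivitySeries
from .io import AlignedSeqSet, CoordinateModel, GroupRow, GroupTable, SequenceRecord
from .library import VariantSpace

__all__ = [
    "ScanScenario",
    "KineticsScenario",
    "make_specificity_alignment",
    "sample_library",
    "make_helical_asu",
    "make_kinetics",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ScanScenario:
    """A grouped alignment with planted specificity-determinant columns.

    Planted columns carry one residue per substrate profile (perfect
    residue/substrate correlation); background columns are either fully
    conserved or label-independent uniform random.
    """

    n_groups: int = 4
    seqs_per_group: int = 3
    width: int = 40
    planted_columns: tuple[int, ...] = (5, 17, 29)  # 1-based
    background: str = "conserved"  # "conserved" | "random"
    substrate_profiles: Optional[tuple[str, ...]] = None  # one per group
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2 or self.seqs_per_group < 1:
            raise ValueError("need at least 2 groups with at least 1 sequence each")
        if len(set(self.planted_columns)) != len(self.planted_columns):
            raise ValueError("planted columns must be distinct")
        if self.width < len(self.planted_columns):
            raise ValueError("width smaller than number of planted columns")
        if any(not 1 <= c <= self.width for c in self.planted_columns):
            raise ValueError("planted columns must lie within the alignment width")
        if self.background not in ("conserved", "random"):
            raise ValueError("background must be 'conserved' or 'random'")
        if self.substrate_profiles is not None and len(self.substrate_profiles) != self.n_groups:
            raise ValueError("need one substrate profile per group")

    @property
    def profiles(self) -> tuple[str, ...]:
        if self.substrate_profiles is not None:
            return self.substrate_profiles
        return tuple(f"S{i}" for i in range(self.n_groups))


def make_specificity_alignment(sc: ScanScenario) -> tuple[AlignedSeqSet, dict]:
    """Generate the alignment plus a truth record of the planted columns."""
    rng = np.random.default_rng(sc.seed)
    profiles = sc.profiles
    distinct = sorted(set(profiles))
    n_seq = sc.n_groups * sc.seqs_per_group
    planted0 = [c - 1 for c in sc.planted_columns]

    # residue per substrate profile, per planted column (distinct within column)
    planted_residues: dict[int, dict[str, str]] = {}
    for col in planted0:
        chosen = rng.choice(list(_AA20), size=len(distinct), replace=False)
        planted_residues[col] = dict(zip(distinct, chosen))

    mat = np.empty((n_seq, sc.width), dtype="<U1")
    for col in range(sc.width):
        if col in planted_residues:
            continue
        if sc.background == "conserved":
            mat[:, col] = rng.choice(list(_AA20))
        else:
            mat[:, col] = rng.choice(list(_AA20), size=n_seq)
    seq_profiles = [profiles[g] for g in range(sc.n_groups) for _ in range(sc.seqs_per_group)]
    for col in planted0:
        mat[:, col] = [planted_residues[col][p] for p in seq_profiles]

    records, rows = [], []
    i = 0
    for g in range(sc.n_groups):
        for s in range(sc.seqs_per_group):
            seq_id = f"G{g}_s{s}"
            records.append(SequenceRecord(id=seq_id, residues="".join(mat[i])))
            rows.append(GroupRow(seq_id=seq_id, group=f"G{g}", substrate=profiles[g]))
            i += 1
    aln = AlignedSeqSet(records=records).with_groups(GroupTable(rows=rows))
    truth = {
        "planted_columns": tuple(sorted(sc.planted_columns)),
        "residue_by_profile": {c + 1: planted_residues[c] for c in planted0},
    }
    return aln, truth


def sample_library(
    space: VariantSpace, L: int, trials: int, seed: int
) -> list[frozenset[str]]:
    """Monte-Carlo library draws: each of L clones picks a codon combination
    uniformly, so protein outcomes appear with their codon degeneracies.

    Returns one frozenset of drawn outcomes per trial.
    """
    if L < 0:
        raise ValueError("library size must be non-negative")
    if trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    names = sorted(space.outcomes)
    cum = np.cumsum([space.outcomes[o] for o in names])
    if L == 0:
        return [frozenset() for _ in range(trials)]
    draws = rng.integers(0, space.codon_combinations, size=(trials, L))
    idx = np.searchsorted(cum, draws, side="right")
    names_arr = np.array(names)
    return [frozenset(names_arr[np.unique(row)]) for row in idx]


def make_helical_asu(
    n_atoms: int = 20,
    radial_band: tuple[float, float] = (8.0, 15.0),
    axial_band: tuple[float, float] = (-2.0, 2.0),
    arm: bool = False,
    seed: int = 0,
    rise: float = 17.48,
    twist_clear: float = -73.0,
    twist_clash: float = -60.0,
    cutoff: float = helix.DEFAULT_CLASH_CUTOFF,
) -> CoordinateModel:
    """Random pseudo-atom asymmetric unit, helix axis on z.

    With ``arm=True`` a tangential pseudo-atom arm mimicking a closed lid
    loop is added at a radius outside the body band: its anchor sits at
    (r_arm, 0, 0) and its tip is placed exactly where the next subunit's
    anchor lands under the reduced twist, so symmetry mates clash under
    ``twist_clash`` but clear each other under ``twist_clear``. The
    construction is re-checked geometrically before returning.
    """
    if n_atoms < 1:
        raise ValueError("need at least one atom")
    r0, r1 = radial_band
    if not 0 < r0 < r1:
        raise ValueError("radial band must satisfy 0 < inner < outer")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_atoms)
    r = rng.uniform(r0, r1, size=n_atoms)
    z = rng.uniform(axial_band[0], axial_band[1], size=n_atoms)
    coords = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    atom_ids = [f"C{i+1}" for i in range(n_atoms)]

    if arm:
        r_arm = r1 + 2.0 * cutoff  # radial clearance from the body band
        anchor = np.array([r_arm, 0.0, 0.0])
        phi = np.radians(twist_clash)
        rot = np.array(
            [[np.cos(phi), -np.sin(phi), 0.0], [np.sin(phi), np.cos(phi), 0.0], [0.0, 0.0, 1.0]]
        )
        tip = rot @ anchor + np.array([0.0, 0.0, rise])
        # intermediate beads stay well below the neighbour's axial plane
        beads = [anchor + t * (tip - anchor) for t in (0.2, 0.4, 0.6)]
        arm_coords = np.vstack([anchor, *beads, tip])
        coords = np.vstack([coords, arm_coords])
        atom_ids += [f"ARM{i+1}" for i in range(len(arm_coords))]

    model = CoordinateModel(
        subunit_ids=np.zeros(len(coords), dtype=int),
        atom_ids=atom_ids,
        coords=coords,
    )
    if arm:
        clear = helix.generate_filament(model, helix.HelicalParams(twist_clear, rise), 2)
        clash = helix.generate_filament(model, helix.HelicalParams(twist_clash, rise), 2)
        n_clear = helix.count_clashes(clear.subunit(0), clear.subunit(1), cutoff)
        n_clash = helix.count_clashes(clash.subunit(0), clash.subunit(1), cutoff)
        if n_clear != 0 or n_clash == 0:
            raise RuntimeError(
                "armed-asu construction failed its geometric check "
                f"(clashes: {n_clear} at {twist_clear}°, {n_clash} at {twist_clash}°)"
            )
    return model


@dataclass(frozen=True)
class KineticsScenario:
    """Linear-plus-noise colorimetric kinetics with a known true activity.

    Defaults mirror a bench assay: ~300 nKat·mg⁻¹ enzyme at 2 µg in the
    cuvette, readings every 5 min, an ammonia calibration of 0.001
    absorbance per nmol, and small Gaussian read noise.
    """

    activity: float = 300.0  # nKat per mg, the ground truth
    cal_slope: float = 0.001  # absorbance per nmol ammonia
    noise_sd: float = 0.01  # absorbance units
    n_points: int = 8
    interval_s: float = 300.0
    enzyme_mg: float = 0.002
    blank: float = 0.05
    plateau_onset: Optional[int] = None  # 0-based point index
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.activity, self.cal_slope, self.interval_s, self.enzyme_mg) <= 0:
            raise ValueError("activity, calibration slope, interval and mass must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.n_points < 2:
            raise ValueError("need at least 2 points")
        if self.plateau_onset is not None and self.plateau_onset <= 4:
            raise ValueError("plateau onset must leave more than 4 linear points")


def make_kinetics(
    sc: KineticsScenario,
) -> tuple[ActivitySeries, list[tuple[float, float]], dict]:
    """Generate one assay series, exact calibration standards, and the truth."""
    rng = np.random.default_rng(sc.seed)
    times = sc.interval_s * np.arange(1, sc.n_points + 1)
    rate_abs = sc.cal_slope * sc.activity * sc.enzyme_mg  # absorbance per second
    clean = sc.blank + rate_abs * times
    if sc.plateau_onset is not None:
        clean[sc.plateau_onset :] = clean[sc.plateau_onset]
    noisy = clean + rng.normal(0.0, sc.noise_sd, size=sc.n_points)
    series = ActivitySeries(
        times_s=times, absorbances=noisy, enzyme_mg=sc.enzyme_mg
    )
    standards = [(float(nmol), float(sc.cal_slope * nmol)) for nmol in np.linspace(0, 250, 6)]
    truth = {"activity": sc.activity}
    return series, standards, truth
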