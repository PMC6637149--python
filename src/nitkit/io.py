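"""Readers and writers for the standard formats the pipeline touches.

Sequence alignments are plain FASTA (gapped, equal-width records), group
assignments are three-column TSV, and pseudo-atom coordinate models are
written as fixed-width PDB with one chain per helical subunit.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("nitkit")

#: The 20 amino-acid one-letter codes plus ambiguity 'X' and the gap '-'.
RESIDUE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX-")

#: PDB chain identifiers, in assignment order (62 available).
CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned protein sequence: an identifier and its residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues) - RESIDUE_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residue symbols: "
                f"{sorted(bad)}"
            )


@dataclass(frozen=True)
class GroupRow:
    seq_id: str
    group: str
    substrate: str

    def __post_init__(self) -> None:
        if not (self.seq_id and self.group and self.substrate):
            raise ValueError("group-table fields must be non-empty")


@dataclass
class GroupTable:
    """Per-sequence group and substrate-profile labels.

    Groups are discrete families (e.g. NIT4 vs NIT1 vs specialist NIT1);
    substrate profiles are the categorical specificity classes the scan
    correlates residues against.
    """

    rows: list[GroupRow]

    def __post_init__(self) -> None:
        ids = [r.seq_id for r in self.rows]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sequence ids in group table: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def by_id(self) -> dict[str, GroupRow]:
        return {r.seq_id: r for r in self.rows}


@dataclass
class AlignedSeqSet:
    """A gapped alignment plus (optionally) the joined group table.

    All records have equal width; the specificity scan additionally requires
    every record to carry a group and substrate-profile label.
    """

    records: list[SequenceRecord]
    groups: Optional[GroupTable] = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment is empty")
        width = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != width:
                raise ValueError(
                    f"not an alignment: sequence {rec.id!r} has width "
                    f"{len(rec.residues)}, expected {width}"
                )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")

    @property
    def width(self) -> int:
        return len(self.records[0].residues)

    def __len__(self) -> int:
        return len(self.records)

    def record(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(f"sequence id {seq_id!r} not in alignment")

    def with_groups(self, table: GroupTable) -> "AlignedSeqSet":
        """Attach labels; warn about table rows absent from the alignment."""
        known = {r.id for r in self.records}
        for row in table.rows:
            if row.seq_id not in known:
                logger.warning(
                    "group table id %r not present in alignment (row retained)",
                    row.seq_id,
                )
        missing = known - set(table.by_id)
        if missing:
            raise ValueError(f"alignment ids missing from group table: {sorted(missing)}")
        return AlignedSeqSet(records=self.records, groups=table)

    def substrate_labels(self) -> list[str]:
        if self.groups is None:
            raise ValueError("alignment has no group table attached")
        by_id = self.groups.by_id
        return [by_id[r.id].substrate for r in self.records]


@dataclass
class CoordinateModel:
    """Pseudo-atom coordinates grouped into helical subunits.

    ``subunit_ids`` are contiguous integers starting at 0; coordinates are
    in Å with the helix axis along z.
    """

    subunit_ids: np.ndarray  # (n_atoms,) int
    atom_ids: list[str]
    coords: np.ndarray  # (n_atoms, 3) float, Å

    def __post_init__(self) -> None:
        self.subunit_ids = np.asarray(self.subunit_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(self.atom_ids) != len(self.coords) or len(self.subunit_ids) != len(self.coords):
            raise ValueError("subunit_ids, atom_ids and coords must have equal length")
        uniq = np.unique(self.subunit_ids)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("subunit ids must be contiguous integers starting at 0")

    @property
    def n_subunits(self) -> int:
        return int(self.subunit_ids.max()) + 1 if len(self.subunit_ids) else 0

    def subunit(self, j: int) -> np.ndarray:
        """Coordinates of subunit ``j`` as an (m, 3) array."""
        mask = self.subunit_ids == j
        if not mask.any():
            raise KeyError(f"no subunit {j}")
        return self.coords[mask]


# ---------------------------------------------------------------------------
# FASTA


def read_alignment(path: str | Path) -> AlignedSeqSet:
    """Read a gapped FASTA alignment.

    '.' gap characters are normalised to '-'; residues are upper-cased.
    Raises ``ValueError`` if the file is empty or records differ in width.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace(".", "-")
        records.append(SequenceRecord(id=rec.id, residues=residues))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return AlignedSeqSet(records=records)


def write_alignment(aln: AlignedSeqSet, path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in aln.records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Group table


def read_group_table(path: str | Path, header: bool = False) -> GroupTable:
    """Read a three-column TSV of (sequence id, group, substrate profile)."""
    rows: list[GroupRow] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if header:
        lines = lines[1:]
    for i, line in enumerate(lines, start=1):
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(
                f"group table line {i}: expected 3 tab-separated columns, got {len(parts)}"
            )
        rows.append(GroupRow(*[p.strip() for p in parts]))
    if not rows:
        raise ValueError(f"no rows in group table {path}")
    return GroupTable(rows=rows)


def write_group_table(table: GroupTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in table.rows:
            fh.write(f"{r.seq_id}\t{r.group}\t{r.substrate}\n")


# ---------------------------------------------------------------------------
# PDB coordinates


def write_coordinates(
    model: CoordinateModel, path: str | Path, multi_model: bool = False
) -> None:
    """Write a coordinate model as PDB, one chain per subunit.

    Pseudo-atoms are emitted as carbon atoms, one residue per atom, with
    coordinates at 3-decimal precision (the PDB fixed-column limit). With
    more than 62 subunits the chain-id alphabet is exhausted; pass
    ``multi_model=True`` to emit one MODEL per subunit (chain A) instead.
    """
    n_sub = model.n_subunits
    if n_sub > len(CHAIN_IDS) and not multi_model:
        raise ValueError(
            f"{n_sub} subunits exceed the {len(CHAIN_IDS)}-chain PDB alphabet; "
            "request multi-model output"
        )
    st = gemmi.Structure()
    st.name = "nitkit"

    def build_chain(chain_id: str, sub: int) -> gemmi.Chain:
        chain = gemmi.Chain(chain_id)
        mask = model.subunit_ids == sub
        for serial, (atom_id, xyz) in enumerate(
            zip(np.asarray(model.atom_ids, dtype=object)[mask], model.coords[mask]),
            start=1,
        ):
            res = gemmi.Residue()
            res.name = "PSD"
            res.het_flag = "A"  # emit ATOM records for pseudo-atoms
            res.seqid = gemmi.SeqId(serial, " ")
            atom = gemmi.Atom()
            atom.name = str(atom_id)[:4] or "C"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        return chain

    if multi_model and n_sub > len(CHAIN_IDS):
        for sub in range(n_sub):
            mdl = gemmi.Model(str(sub + 1))
            mdl.add_chain(build_chain("A", sub))
            st.add_model(mdl)
    else:
        mdl = gemmi.Model("1")
        for sub in range(n_sub):
            mdl.add_chain(build_chain(CHAIN_IDS[sub], sub))
        st.add_model(mdl)
    st.write_pdb(str(path))


def read_coordinates(path: str | Path) -> CoordinateModel:
    """Read a PDB file written by :func:`write_coordinates`.

    Chains (or models, for multi-model files) are mapped back to subunit
    ids 0..n−1 in file order.
    """
    st = gemmi.read_structure(str(path))
    subunit_ids: list[int] = []
    atom_ids: list[str] = []
    coords: list[tuple[float, float, float]] = []
    sub = 0
    multi = len(st) > 1
    for mdl in st:
        for chain in mdl:
            for res in chain:
                for atom in res:
                    subunit_ids.append(sub)
                    atom_ids.append(atom.name)
                    coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
            if not multi:
                sub += 1
        if multi:
            sub += 1
    if not coords:
        raise ValueError(f"no atoms in {path}")
    return CoordinateModel(
        subunit_ids=np.array(subunit_ids),
        atom_ids=atom_ids,
        coords=np.array(coords),
    )
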