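"""Residue–substrate correlation scan for specificity-determining positions.

Each alignment column is scored over all unordered sequence pairs: a pair
contributes +1 when residue identity co-varies with the substrate-profile
label (both equal, or both different) and −1 otherwise. Columns where
residue identity tracks the specificity classes — candidate determinants
of substrate specificity — therefore accumulate the maximal score of
C(n, 2). Scores are reported against the residue numbering of a designated
reference sequence.

The gap character '-' is treated as a 21st residue symbol: a gap against a
residue counts as "residue differed". Columns where the reference itself is
gapped are scored but carry no reference position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import AlignedSeqSet

__all__ = [
    "AlignedSeqSet",
    "PositionScore",
    "map_columns_to_reference",
    "score_position",
    "rank_positions",
    "select_determinants",
]


@dataclass(frozen=True)
class PositionScore:
    """Score of one alignment column.

    ``column`` is 1-based; ``reference_position`` is the 1-based residue
    number in the reference sequence, or None where the reference is gapped.
    """

    column: int
    reference_position: Optional[int]
    score: int


def map_columns_to_reference(
    aln: AlignedSeqSet, reference_id: str
) -> list[Optional[int]]:
    """Map alignment columns to reference residue numbers.

    Entry c (0-based) is the count of non-gap reference residues in columns
    1..c+1, or None where the reference has a gap.
    """
    ref = aln.record(reference_id).residues
    mapping: list[Optional[int]] = []
    pos = 0
    for ch in ref:
        if ch == "-":
            mapping.append(None)
        else:
            pos += 1
            mapping.append(pos)
    return mapping


def score_position(residues: Sequence[str], labels: Sequence[str]) -> int:
    """Score one column over all unordered sequence pairs.

    +1 when the pair's substrate labels and residues are both equal or both
    different; −1 otherwise.
    """
    if len(residues) != len(labels):
        raise ValueError("residues and labels must have equal length")
    if len(residues) < 2:
        raise ValueError("no pairs: need at least 2 sequences")
    score = 0
    n = len(residues)
    for i in range(n):
        for j in range(i + 1, n):
            same_res = residues[i] == residues[j]
            same_lab = labels[i] == labels[j]
            score += 1 if same_res == same_lab else -1
    return score


def _column_scores(aln: AlignedSeqSet) -> np.ndarray:
    """Vectorised per-column scores (equals score_position column-wise)."""
    labels = aln.substrate_labels()
    n = len(aln)
    if n < 2:
        raise ValueError("no pairs: need at least 2 sequences")
    mat = np.array([list(r.residues) for r in aln.records])  # (n, width) of chars
    lab = np.array(labels)
    same_lab = lab[:, None] == lab[None, :]  # (n, n)
    iu, ju = np.triu_indices(n, k=1)
    same_res = mat[iu] == mat[ju]  # (n_pairs, width)
    agree = same_res == same_lab[iu, ju][:, None]
    return np.where(agree, 1, -1).sum(axis=0)


def rank_positions(aln: AlignedSeqSet, reference_id: str) -> list[PositionScore]:
    """Score every column and rank by score (descending, ties by column)."""
    scores = _column_scores(aln)
    ref_map = map_columns_to_reference(aln, reference_id)
    out = [
        PositionScore(column=c + 1, reference_position=ref_map[c], score=int(s))
        for c, s in enumerate(scores)
    ]
    out.sort(key=lambda p: (-p.score, p.column))
    return out


def select_determinants(ranked: list[PositionScore], k: int) -> list[PositionScore]:
    """Top-k candidate determinant positions from a ranked list."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds number of columns {len(ranked)}")
    return ranked[:k]
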