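"""Insertion of trimmed query tags into the fixed master reference alignment.

The master alignment's columns are a frozen coordinate system: queries are
aligned one at a time to the column profile (global in columns with free end
gaps, affine penalties, deletion costs scaled by column occupancy), and any
query residues that would require opening a new column are dropped and
logged instead. Reference rows are never modified, so tree topology over the
references cannot drift as queries are added, and each query's row depends
only on its own sequence — there is no progressive coupling between queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .detection import Profile, build_profile
from .reference_db import ReferenceAlignment
from .trimming import TrimmedDomain

#: affine gap penalties in bits (profile scores are log2 odds). 5.5/0.5 are
#: the BLOSUM62 11/1 half-bit penalties expressed in bits.
GAP_OPEN_BITS = 5.5
GAP_EXTEND_BITS = 0.5

#: minimum fraction of tag residues that must land in reference columns
MIN_PLACED_FRACTION = 0.3


class ProfileAlignError(ValueError):
    pass


class UnalignableTagError(ProfileAlignError):
    """Raised when fewer than MIN_PLACED_FRACTION of a tag's residues can be
    placed; such tags are excluded from the tree and reported separately."""


@dataclass(frozen=True)
class InsertionLogEntry:
    tag_id: str
    n_dropped: int
    dropped_positions: tuple[int, ...]  # 0-based positions in the tag
    placed_fraction: float


@dataclass
class ExtendedAlignment:
    base: ReferenceAlignment
    query_rows: dict[str, str] = field(default_factory=dict)
    insertion_log: dict[str, InsertionLogEntry] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return self.base.n_columns

    def all_rows(self) -> dict[str, str]:
        """References first (database order), then queries (insertion order)."""
        out = dict(self.base.rows)
        out.update(self.query_rows)
        return out

    def write_fasta(self, path) -> None:
        from .sequence_io import write_fasta

        write_fasta(self.all_rows().items(), path)


def _alignment_profile(reference_alignment: ReferenceAlignment) -> Profile:
    # all columns retained: the row must have exactly n_columns characters
    return build_profile(reference_alignment, drop_gap_majority=False)


def align_to_profile(
    tag: TrimmedDomain | str,
    reference_alignment: ReferenceAlignment,
    profile: Optional[Profile] = None,
    gap_open: float = GAP_OPEN_BITS,
    gap_extend: float = GAP_EXTEND_BITS,
) -> tuple[str, InsertionLogEntry]:
    """Align one tag to the reference columns; return its gapped row (length
    n_columns) and the insertion log entry.

    Dynamic program over (residue i, column j) with three states: residue
    placed in column (M), column deleted (D, cost scaled by the column's
    occupancy so sparse columns are cheap to skip), residue dropped as an
    insertion (I). Leading and trailing column deletions are free.
    """
    if isinstance(tag, TrimmedDomain):
        tag_id, seq = tag.tag_id, tag.aa_sequence
    else:
        tag_id, seq = "tag", tag
    if not seq:
        raise ProfileAlignError("cannot align an empty tag")
    if profile is None:
        profile = _alignment_profile(reference_alignment)
    C = profile.n_columns
    if C != reference_alignment.n_columns:
        raise ProfileAlignError("profile must retain every master-alignment column")
    m = len(seq)
    enc = profile.encode(seq)
    table = profile.score_table()  # (C, 22)
    occ = profile.occupancy
    dgo = gap_open * occ  # per-column deletion open
    dge = gap_extend * occ
    G = np.concatenate(([0.0], np.cumsum(dge)))  # G[j] = sum dge[:j]

    NEG = -1.0e18
    # rows over residues 0..m, columns 0..C
    M = np.full((m + 1, C + 1), NEG)
    D = np.full((m + 1, C + 1), NEG)
    I = np.full((m + 1, C + 1), NEG)
    M[0, 0] = 0.0
    D[0, :] = 0.0  # free leading deletions
    I[1:, 0] = -(gap_open + gap_extend * np.arange(m))
    ptrM = np.zeros((m + 1, C + 1), dtype=np.uint8)  # prev state of M: 0=M,1=D,2=I
    ptrI = np.zeros((m + 1, C + 1), dtype=np.uint8)
    # D pointers resolved during traceback from values

    col_scores = table[np.arange(C)[None, :], enc[:, None]]  # (m, C)
    for i in range(1, m + 1):
        prevM, prevD, prevI = M[i - 1], D[i - 1], I[i - 1]
        # M: place residue i at column j (consumes one residue + one column)
        cand = np.stack((prevM[:-1], prevD[:-1], prevI[:-1]))
        choice = np.argmax(cand, axis=0)
        M[i, 1:] = cand[choice, np.arange(C)] + col_scores[i - 1]
        ptrM[i, 1:] = choice
        # I: drop residue i (consumes one residue)
        candI = np.stack((prevM - gap_open, prevD - gap_open, prevI - gap_extend))
        choiceI = np.argmax(candI, axis=0)
        I[i] = candI[choiceI, np.arange(C + 1)]
        ptrI[i] = choiceI
        # D: delete column j (consumes one column); within-row running max
        base = np.maximum(M[i, :-1], I[i, :-1]) - dgo + G[:-1]
        run = np.maximum.accumulate(base)
        D[i, 1:] = run - G[1:]
    # best end: all residues consumed, trailing deletions free
    endM = M[m]
    endI = I[m]
    ends = np.maximum(endM, endI)
    j = int(np.argmax(ends))
    state = 0 if endM[j] >= endI[j] else 2
    i = m
    placed_cols: dict[int, str] = {}
    dropped: list[int] = []
    while i > 0:
        if state == 0:  # M at (i, j): residue i-1 placed at column j-1
            placed_cols[j - 1] = seq[i - 1]
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 2:  # I at (i, j): residue i-1 dropped
            dropped.append(i - 1)
            state = int(ptrI[i, j])
            i -= 1
        else:  # D at (i, j): columns (k, j] deleted; find the run start k
            target = D[i, j] + G[j]
            base_j = np.maximum(M[i, :j], I[i, :j]) - dgo[:j] + G[:j]
            k = int(np.flatnonzero(np.isclose(base_j, target, atol=1e-9))[0])
            state = 0 if M[i, k] >= I[i, k] else 2
            j = k
    dropped.reverse()
    n_placed = len(placed_cols)
    placed_fraction = n_placed / m
    entry = InsertionLogEntry(
        tag_id=tag_id,
        n_dropped=len(dropped),
        dropped_positions=tuple(dropped),
        placed_fraction=placed_fraction,
    )
    if placed_fraction < MIN_PLACED_FRACTION:
        raise UnalignableTagError(
            f"tag {tag_id!r}: only {placed_fraction:.0%} of residues aligned to "
            f"reference columns"
        )
    row = "".join(placed_cols.get(c, "-") for c in range(C))
    return row, entry


def build_extended_alignment(
    tags: list[TrimmedDomain],
    reference_alignment: ReferenceAlignment,
    profile: Optional[Profile] = None,
) -> tuple[ExtendedAlignment, list[InsertionLogEntry]]:
    """Insert every tag into the reference alignment; unalignable tags are
    returned in the second element instead of being added."""
    if profile is None:
        profile = _alignment_profile(reference_alignment)
    ext = ExtendedAlignment(base=reference_alignment)
    unalignable: list[InsertionLogEntry] = []
    for tag in tags:
        try:
            row, entry = align_to_profile(tag, reference_alignment, profile=profile)
        except UnalignableTagError:
            unalignable.append(
                InsertionLogEntry(tag.tag_id, n_dropped=len(tag.aa_sequence), dropped_positions=(), placed_fraction=0.0)
            )
            continue
        ext.query_rows[tag.tag_id] = row
        ext.insertion_log[tag.tag_id] = entry
    return ext, unalignable
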