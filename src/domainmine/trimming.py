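"""Extraction of domain sequence tags from queries by best-hit coordinates.

A tag is the query subsequence spanned by its best reference alignment,
carrying full provenance: parent query, reading frame/strand, amino-acid
interval on the frame, and the forward-strand nucleotide interval, so a tag
from a metagenomic contig can always be traced back to its codons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .search import HitRecord
from .sequence_io import QuerySequence, TranslatedFrame


class TrimmingError(ValueError):
    pass


@dataclass(frozen=True)
class TrimmedDomain:
    tag_id: str
    aa_sequence: str
    parent_query_id: str
    frame: Optional[int]  # None for direct amino-acid queries
    strand: Optional[str]
    aa_start: int
    aa_end: int
    nt_start: Optional[int]
    nt_end: Optional[int]
    best_hit: HitRecord


def trim_query(
    query_or_frame: Union[QuerySequence, TranslatedFrame],
    hit: HitRecord,
    pad: int = 0,
    tag_id: Optional[str] = None,
) -> TrimmedDomain:
    """Cut the tag [q_start - pad, q_end + pad) (clipped) out of the query or
    translated frame the hit was found on."""
    if pad < 0:
        raise TrimmingError("pad must be >= 0")
    if isinstance(query_or_frame, TranslatedFrame):
        residues = query_or_frame.aa_residues
        parent = query_or_frame.parent_query_id
    else:
        if query_or_frame.alphabet != "aa":
            raise TrimmingError("direct trimming requires an amino-acid query")
        residues = query_or_frame.residues
        parent = query_or_frame.query_id
    if not (0 <= hit.q_start < hit.q_end <= len(residues)):
        raise TrimmingError(
            f"hit interval [{hit.q_start},{hit.q_end}) outside query "
            f"{parent!r} of length {len(residues)}"
        )
    aa_start = max(0, hit.q_start - pad)
    aa_end = min(len(residues), hit.q_end + pad)
    if isinstance(query_or_frame, TranslatedFrame):
        nt_start, nt_end = query_or_frame.aa_to_nt(aa_start, aa_end)
        frame = query_or_frame.frame
        strand = query_or_frame.strand
    else:
        nt_start = nt_end = None
        frame = strand = None
    return TrimmedDomain(
        tag_id=tag_id if tag_id is not None else f"{parent}_1",
        aa_sequence=residues[aa_start:aa_end],
        parent_query_id=parent,
        frame=frame,
        strand=strand,
        aa_start=aa_start,
        aa_end=aa_end,
        nt_start=nt_start,
        nt_end=nt_end,
        best_hit=hit,
    )


def _overlap_fraction(a: TrimmedDomain, b: TrimmedDomain) -> float:
    lo = max(a.aa_start, b.aa_start)
    hi = min(a.aa_end, b.aa_end)
    if hi <= lo:
        return 0.0
    shorter = min(a.aa_end - a.aa_start, b.aa_end - b.aa_start)
    return (hi - lo) / shorter


def resolve_overlaps(tags: list[TrimmedDomain], max_overlap: float = 0.5) -> list[TrimmedDomain]:
    """Collapse tags on the same query frame overlapping by more than
    ``max_overlap`` (of the shorter tag) to the one with the better E-value.

    Output preserves coordinate order within each (query, frame) group.
    """
    by_group: dict[tuple, list[TrimmedDomain]] = {}
    for t in tags:
        by_group.setdefault((t.parent_query_id, t.frame), []).append(t)
    kept: list[TrimmedDomain] = []
    for group in by_group.values():
        # greedy by E-value: best hits claim their interval first
        accepted: list[TrimmedDomain] = []
        for t in sorted(group, key=lambda t: (t.best_hit.e_value, t.aa_start)):
            if all(_overlap_fraction(t, a) <= max_overlap for a in accepted):
                accepted.append(t)
        kept.extend(accepted)
    kept.sort(key=lambda t: (t.parent_query_id, t.frame if t.frame is not None else 0, t.aa_start))
    return kept


def assign_serials(tags: list[TrimmedDomain]) -> list[TrimmedDomain]:
    """Re-id tags as ``<query>_<serial>`` in coordinate order per query, the
    per-domain row convention for multimodular genes."""
    from dataclasses import replace

    counters: dict[str, int] = {}
    out = []
    for t in sorted(
        tags,
        key=lambda t: (t.parent_query_id, t.nt_start if t.nt_start is not None else t.aa_start),
    ):
        counters[t.parent_query_id] = counters.get(t.parent_query_id, 0) + 1
        out.append(replace(t, tag_id=f"{t.parent_query_id}_{counters[t.parent_query_id]}"))
    return out


def tags_to_fasta(tags: list[TrimmedDomain], path) -> None:
    from .sequence_io import write_fasta

    write_fasta([(t.tag_id, t.aa_sequence) for t in tags], path)
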