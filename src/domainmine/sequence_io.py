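"""FASTA input/output, alphabet detection, input-size limits, and six-frame
translation with invertible coordinate bookkeeping.

Coordinates are 0-based, half-open throughout. Nucleotide intervals are always
reported on the forward strand, with the strand carried separately, so that
downstream interval arithmetic (BED-style) never needs to know about frames.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
AA_EXTENDED = AA_ALPHABET | set("X*")
NT_CANONICAL = set("ACGTUN")
# IUPAC nucleotide ambiguity codes
NT_EXTENDED = NT_CANONICAL | set("RYSWKMBDHV")

#: web-service defaults for input caps (residue bytes / record count)
DEFAULT_MAX_BYTES = 30_000_000
DEFAULT_MAX_COUNT = 50_000


class SequenceError(ValueError):
    pass


class LimitExceededError(SequenceError):
    pass


@dataclass(frozen=True)
class QuerySequence:
    """One input record; ``alphabet`` is 'nt' or 'aa'."""

    query_id: str
    alphabet: str
    residues: str
    source_index: int

    def __post_init__(self):
        if not self.residues:
            raise SequenceError(f"empty sequence for query {self.query_id!r}")
        allowed = NT_EXTENDED if self.alphabet == "nt" else AA_EXTENDED
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise SequenceError(
                f"query {self.query_id!r}: residues {sorted(bad)} not in "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TranslatedFrame:
    """One reading frame of a nucleotide query.

    ``frame`` is +1/+2/+3 (forward) or -1/-2/-3 (reverse complement).
    ``nt_offset`` is the forward-strand index of the first base of the frame's
    first codon; ``parent_length`` lets the frame map amino-acid intervals back
    to forward-strand nucleotide intervals without the parent record in hand.
    """

    parent_query_id: str
    frame: int
    aa_residues: str
    nt_offset: int
    parent_length: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    def aa_to_nt(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Forward-strand nucleotide interval [start, end) covered by the
        amino-acid interval [aa_start, aa_end) of this frame."""
        if not (0 <= aa_start <= aa_end <= len(self.aa_residues)):
            raise SequenceError(
                f"aa interval [{aa_start},{aa_end}) outside frame of length "
                f"{len(self.aa_residues)}"
            )
        k = abs(self.frame) - 1
        if self.frame > 0:
            return k + 3 * aa_start, k + 3 * aa_end
        # on the reverse complement the frame starts at RC index k;
        # RC index r maps to forward index L-1-r
        L = self.parent_length
        return L - k - 3 * aa_end, L - k - 3 * aa_start

    def nt_to_aa(self, nt_start: int, nt_end: int) -> tuple[int, int]:
        """Inverse of :meth:`aa_to_nt` (interval must be a codon image)."""
        k = abs(self.frame) - 1
        if self.frame > 0:
            aa_start, r0 = divmod(nt_start - k, 3)
            aa_end, r1 = divmod(nt_end - k, 3)
        else:
            L = self.parent_length
            aa_start, r0 = divmod(L - k - nt_end, 3)
            aa_end, r1 = divmod(L - k - nt_start, 3)
        if r0 or r1:
            raise SequenceError("nucleotide interval is not a codon image on this frame")
        return aa_start, aa_end


def detect_alphabet(residues: str) -> str:
    """'nt' when >=90% of residues are canonical nucleotide letters."""
    up = residues.upper()
    if not up:
        raise SequenceError("cannot detect alphabet of an empty sequence")
    frac_nt = sum(c in NT_CANONICAL for c in up) / len(up)
    return "nt" if frac_nt >= 0.9 else "aa"


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path, expected_alphabet: Optional[str] = None) -> list[QuerySequence]:
    """Read a (possibly gzipped) FASTA file into :class:`QuerySequence` records.

    The alphabet is auto-detected per file (majority over all residues) unless
    ``expected_alphabet`` is given, in which case a mismatch is an error.
    """
    with _open_maybe_gzip(path) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
    pooled = "".join(str(rec.seq) for rec in records)
    alphabet = detect_alphabet(pooled)
    if expected_alphabet is not None and alphabet != expected_alphabet:
        raise SequenceError(
            f"input looks like {alphabet} but {expected_alphabet} was requested"
        )
    return [
        QuerySequence(rec.id, alphabet, str(rec.seq).upper(), i)
        for i, rec in enumerate(records)
    ]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write (id, residues) pairs as FASTA (60-column wrap)."""
    seqs = [SeqRecord(Seq(res), id=name, description="") for name, res in records]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta")


def enforce_limits(
    sequences: list[QuerySequence],
    max_bytes: int = DEFAULT_MAX_BYTES,
    max_count: int = DEFAULT_MAX_COUNT,
) -> None:
    """Raise :class:`LimitExceededError` when the input exceeds the configured
    caps (compared inclusively: exactly at the cap passes)."""
    if not sequences:
        raise SequenceError("no input sequences")
    n = len(sequences)
    if n > max_count:
        raise LimitExceededError(
            f"{n} sequences exceeds the {max_count}-sequence limit by {n - max_count}"
        )
    total = sum(len(s) for s in sequences)
    if total > max_bytes:
        raise LimitExceededError(
            f"{total} residue bytes exceeds the {max_bytes}-byte limit "
            f"by {total - max_bytes}"
        )


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def translate_six_frames(query: QuerySequence, codon_table: int = 1) -> list[TranslatedFrame]:
    """Translate all six reading frames of a nucleotide query.

    Ambiguous codons translate to X (or to their unambiguous residue when all
    resolutions agree); stop codons are kept as '*' — splitting at stops is the
    detection stage's job. Frames shorter than one codon yield empty frames.
    """
    if query.alphabet != "nt":
        raise SequenceError(f"query {query.query_id!r} is not nucleotide")
    fwd = query.residues.upper().replace("U", "T")
    rev = reverse_complement(fwd)
    L = len(fwd)
    frames = []
    for strand_seq, sign in ((fwd, 1), (rev, -1)):
        for k in range(3):
            sub = strand_seq[k : k + 3 * ((L - k) // 3)]
            aa = str(Seq(sub).translate(table=codon_table)) if sub else ""
            frames.append(
                TranslatedFrame(
                    parent_query_id=query.query_id,
                    frame=sign * (k + 1),
                    aa_residues=aa,
                    nt_offset=k if sign > 0 else max(L - k - 3, 0),
                    parent_length=L,
                )
            )
    return frames
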