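"""Seeded generators for class-structured domain families, divergent query
tags, and genomes/metagenomes with embedded domains plus truth tables.

These generators are the package's offline test surface: every stage of the
pipeline is benchmarked against data whose ground truth is known by
construction. Families are generated as star-of-stars phylogenies (a root
sequence, one ancestor per class, members radiating from each ancestor), so
class structure is real but simpler than biological domain families: no
rate heterogeneity, no indel history in the master alignment (rows are
gap-free and equal length), substitutions biased by BLOSUM62 exchangeability.
Everything is a pure function of its seed and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .reference_db import (
    DomainClass,
    ReferenceAlignment,
    ReferenceDatabase,
    ReferenceDomain,
    taxonomy,
)
from .sequence_io import reverse_complement

AA = "ACDEFGHIKLMNPQRSTVWY"

#: standard-code codons per amino acid (DNA alphabet)
_CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
_CODE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_CODE):
    codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    _CODONS.setdefault(_aa, []).append(codon)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class TruthRecord:
    planted_tag_id: str
    class_label: str
    parent_reference_id: str
    target_identity: float
    replicon_id: str
    strand: str
    frame: int
    nt_start: int
    nt_end: int
    aa_start: int
    aa_end: int


TRUTH_COLUMNS = list(TruthRecord.__dataclass_fields__)


def _substitution_kernel(temperature: float = 0.5) -> np.ndarray:
    """P(b | a) for b != a, proportional to 2**(temperature * BLOSUM62[a,b]),
    so substitutions favor biochemically exchangeable residues."""
    mat = substitution_matrices.load("BLOSUM62")
    idx = [str(mat.alphabet).index(c) for c in AA]
    S = np.asarray(mat)[np.ix_(idx, idx)]
    W = np.power(2.0, temperature * S)
    np.fill_diagonal(W, 0.0)
    return W / W.sum(axis=1, keepdims=True)


_KERNEL = _substitution_kernel()
_AA_IDX = {c: i for i, c in enumerate(AA)}


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA), size=length))


def mutate_to_identity(
    sequence: str,
    target_identity: float,
    indel_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Mutate a protein to a controlled identity with its parent.

    Exactly round((1 - target) * L) positions receive a BLOSUM62-biased
    substitution, so without indels the realized identity is within half a
    residue of the target. Indels (single-residue, Poisson at ``indel_rate``
    per site, balanced insert/delete) additionally shift the alignment;
    combinations that could not realize the target within 3 points raise.
    """
    if not 0.0 < target_identity <= 1.0:
        raise SyntheticError("target identity must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(sequence)
    n_sub = round((1.0 - target_identity) * L)
    expected_indels = indel_rate * L
    if expected_indels / max(L, 1) > 0.03:
        raise SyntheticError(
            f"indel_rate {indel_rate} cannot keep realized identity within 3 "
            f"points of target {target_identity}"
        )
    out = list(sequence)
    positions = rng.choice(L, size=n_sub, replace=False)
    for p in positions:
        a = _AA_IDX.get(out[p])
        if a is None:
            continue
        out[p] = AA[rng.choice(20, p=_KERNEL[a])]
    n_indels = rng.poisson(expected_indels)
    for _ in range(n_indels):
        p = int(rng.integers(0, len(out)))
        if rng.random() < 0.5 and len(out) > 1:
            del out[p]
        else:
            out.insert(p, AA[int(rng.integers(0, 20))])
    return "".join(out)


_PATHWAY_TYPE = {
    "KS": {"Hybrid": "hybrid", "FAS": "FAS"},
    "C": {"Hybrid C": "hybrid"},
}


def _safe_id(class_name: str) -> str:
    return "".join(c for c in class_name if c.isalnum())


def simulate_reference_family(
    n_classes: int | None = None,
    members_per_class: int = 3,
    domain_length: int = 400,
    between_class_divergence: float = 0.7,
    within_class_divergence: float = 0.08,
    seed: int = 0,
    domain_type: str = "KS",
) -> tuple[ReferenceDatabase, str]:
    """Generate a class-structured reference database with a gap-free master
    alignment; returns (database, generating tree newick).

    Classes are clades: each class ancestor is the root mutated to identity
    1 - between/2 (so two ancestors differ by roughly ``between``), and each
    member is its ancestor mutated to identity 1 - within.
    """
    if between_class_divergence <= within_class_divergence:
        raise SyntheticError("between-class divergence must exceed within-class")
    if not 0 < between_class_divergence < 2 * (1 - 1 / len(AA)):
        raise SyntheticError("infeasible between-class divergence")
    classes = taxonomy(domain_type)
    if n_classes is None:
        n_classes = len(classes)
    if n_classes > len(classes):
        raise SyntheticError(
            f"at most {len(classes)} {domain_type} classes are defined"
        )
    rng = np.random.default_rng(seed)
    root = random_protein(domain_length, rng)
    domains: list[ReferenceDomain] = []
    rows: dict[str, str] = {}
    clades = []
    type_default = "PKS" if domain_type == "KS" else "NRPS"
    for ci, cls in enumerate(classes[:n_classes]):
        ancestor = mutate_to_identity(root, 1 - between_class_divergence / 2, seed=rng)
        member_ids = []
        for k in range(members_per_class):
            seq = mutate_to_identity(ancestor, 1 - within_class_divergence, seed=rng)
            domain_id = f"{_safe_id(cls.class_name)}_{k + 1}"
            domains.append(
                ReferenceDomain(
                    domain_id=domain_id,
                    domain_type=domain_type,
                    class_label=cls.class_name,
                    pathway_name=f"{cls.class_name} synthetic pathway {k + 1}",
                    pathway_type=_PATHWAY_TYPE[domain_type].get(cls.class_name, type_default),
                    product=cls.example_product,
                    gene_accession=f"SYN{domain_type}{ci:02d}{k:02d}",
                    literature_ref="synthetic",
                    sequence=seq,
                )
            )
            rows[domain_id] = seq
            member_ids.append(domain_id)
        w = within_class_divergence
        clades.append(
            "(" + ",".join(f"{m}:{w:.4f}" for m in member_ids) + f"):{between_class_divergence / 2:.4f}"
        )
    newick = "(" + ",".join(clades) + ");"
    db = ReferenceDatabase(domains, ReferenceAlignment(domain_type, rows))
    return db, newick


def simulate_query_tags(
    db: ReferenceDatabase,
    n_tags: int,
    target_identity: float = 0.7,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str, str, str]]:
    """Divergent query tags drawn round-robin across classes; returns
    (tag_id, sequence, true_class, parent_reference_id) tuples."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[ReferenceDomain]] = {}
    for d in db:
        by_class.setdefault(d.class_label, []).append(d)
    class_cycle = sorted(by_class)
    out = []
    for t in range(n_tags):
        cls = class_cycle[t % len(class_cycle)]
        parent = by_class[cls][int(rng.integers(0, len(by_class[cls])))]
        seq = mutate_to_identity(parent.sequence, target_identity, indel_rate, seed=rng)
        out.append((f"tag{t:04d}", seq, cls, parent.domain_id))
    return out


def reverse_translate(protein: str, rng: np.random.Generator, gc: float = 0.5) -> str:
    """Encode a protein as DNA with codon usage biased toward the requested
    GC content (codon weight = product of its base probabilities)."""
    p_base = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    codons = []
    for aa in protein:
        options = _CODONS.get(aa)
        if not options:  # X etc.: unknown codon
            codons.append("NNN")
            continue
        w = np.array([math.prod(p_base[b] for b in c) for c in options])
        codons.append(options[rng.choice(len(options), p=w / w.sum())])
    return "".join(codons)


def random_genome(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return "".join(rng.choice(list("ATGC"), size=length, p=p))


def embed_in_genome(
    domains: list[tuple[str, str, str, str]],
    genome_length: int,
    n_replicons: int = 1,
    seed: int = 0,
    gc: float = 0.5,
    target_identity: float = 1.0,
    max_tries: int = 1000,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Plant reverse-translated domains at random non-overlapping positions
    and strands in i.i.d. background nucleotide sequence.

    ``domains`` holds (tag_id, aa_sequence, class_label, parent_reference_id)
    tuples (the output of :func:`simulate_query_tags`). Returns the replicon
    FASTA records and a BED-compatible truth table (0-based half-open).
    """
    rng = np.random.default_rng(seed)
    total_embedded = sum(3 * len(d[1]) for d in domains)
    if total_embedded >= genome_length:
        raise SyntheticError("total embedded length must be below genome length")
    per_replicon = genome_length // n_replicons
    replicons = [list(random_genome(per_replicon, rng, gc)) for _ in range(n_replicons)]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n_replicons)]
    truth: list[TruthRecord] = []
    for tag_id, aa_seq, class_label, parent_id in domains:
        nt = reverse_translate(aa_seq, rng, gc)
        m = len(nt)
        placed = False
        for _ in range(max_tries):
            r = int(rng.integers(0, n_replicons))
            if per_replicon <= m:
                continue
            p = int(rng.integers(0, per_replicon - m))
            if any(p < e and s < p + m for s, e in occupied[r]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            insert = nt if strand == "+" else reverse_complement(nt)
            replicons[r][p : p + m] = list(insert)
            occupied[r].append((p, p + m))
            L = per_replicon
            if strand == "+":
                k = p % 3
                frame = k + 1
                aa_start = (p - k) // 3
            else:
                start_rc = L - (p + m)
                k = start_rc % 3
                frame = -(k + 1)
                aa_start = (start_rc - k) // 3
            truth.append(
                TruthRecord(
                    planted_tag_id=tag_id,
                    class_label=class_label,
                    parent_reference_id=parent_id,
                    target_identity=target_identity,
                    replicon_id=f"replicon{r + 1}",
                    strand=strand,
                    frame=frame,
                    nt_start=p,
                    nt_end=p + m,
                    aa_start=aa_start,
                    aa_end=aa_start + len(aa_seq),
                )
            )
            placed = True
            break
        if not placed:
            raise SyntheticError(
                f"could not place {tag_id!r} after {max_tries} tries"
            )
    records = [(f"replicon{r + 1}", "".join(replicons[r])) for r in range(n_replicons)]
    table = pd.DataFrame([[getattr(t, c) for c in TRUTH_COLUMNS] for t in truth], columns=TRUTH_COLUMNS)
    return records, table


def fragment_genome(
    records: list[tuple[str, str]],
    mean_length: int = 244,
    seed: int = 0,
    min_length: int = 50,
) -> list[tuple[str, str]]:
    """Cut replicons into consecutive reads with normally distributed lengths
    around ``mean_length``, emulating short-read draft-assembly input."""
    rng = np.random.default_rng(seed)
    reads = []
    for name, seq in records:
        pos = 0
        i = 1
        while pos < len(seq):
            ln = max(min_length, int(rng.normal(mean_length, mean_length / 4)))
            reads.append((f"{name}_read{i}", seq[pos : pos + ln]))
            pos += ln
            i += 1
    return [r for r in reads if len(r[1]) >= min_length]
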