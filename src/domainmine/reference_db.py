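"""Curated reference database: class-labelled KS and C domains, their master
alignments, and the fixed domain-class taxonomy.

The taxonomy is a controlled, case-sensitive vocabulary. Ketosynthase (KS)
domains carry nine classes spanning type I PKS architectures (enediyne,
trans-AT, cis-AT, hybrid PKS/NRPS, iterative, PUFA, KS1/starter), type II
PKSs, and fatty-acid synthases (FAS, the one class not associated with
secondary metabolism). Condensation (C) domains carry eight classes defined by
substrate stereochemistry and tailoring chemistry (LCL, DCL, starter,
cyclization, epimerization, dual E/C, modified-AA, hybrid C).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from importlib import resources

import pandas as pd

from .sequence_io import AA_ALPHABET

METADATA_COLUMNS = [
    "domain_id",
    "domain_type",
    "class_label",
    "pathway_name",
    "pathway_type",
    "product",
    "gene_accession",
    "literature_ref",
]

_REF_ALPHABET = AA_ALPHABET | {"X"}


class ReferenceDBError(ValueError):
    pass


@dataclass(frozen=True)
class DomainClass:
    domain_type: str  # KS | C
    class_name: str
    description: str
    example_product: str
    secondary_metabolism: bool = True


KS_CLASSES: tuple[DomainClass, ...] = (
    DomainClass("KS", "Enediyne", "iteratively acting KS building 9- or 10-membered enediyne cores", "calicheamicin"),
    DomainClass("KS", "Trans-AT", "module lacks a cognate AT domain; AT activity supplied by a discrete protein in trans", "leinamycin"),
    DomainClass("KS", "Cis-AT", "multi-domain type I module including its own AT domain", "erythromycin"),
    DomainClass("KS", "Hybrid", "condenses an amino acid with an acyl extender unit in a hybrid NRPS/PKS pathway", "microcystin"),
    DomainClass("KS", "Iterative", "domain reused multiple times in a cyclic fashion", "aflatoxin"),
    DomainClass("KS", "PUFA", "produces long-chain polyunsaturated fatty acids", "omega-3 fatty acid"),
    DomainClass("KS", "KS1", "first-module KS, including starter KSQ domains and loaders of unusual precursors", "salinosporamide"),
    DomainClass("KS", "Type II", "each domain on a discrete protein (aromatic polyketides)", "actinorhodin"),
    DomainClass("KS", "FAS", "fatty-acid biosynthesis (e.g. FabB/FabF)", "palmitic acid", secondary_metabolism=False),
)

C_CLASSES: tuple[DomainClass, ...] = (
    DomainClass("C", "LCL", "peptide bond between two L-amino acids", "surfactin"),
    DomainClass("C", "DCL", "links an L-amino acid to a peptide ending in a D-amino acid", "tyrocidine"),
    DomainClass("C", "Starter", "acylates the first amino acid with a beta-hydroxy carboxylic acid", "surfactin lipoinitiation"),
    DomainClass("C", "Cyclization", "peptide bond formation plus cyclization of Cys/Ser/Thr", "bacitracin"),
    DomainClass("C", "Epimerization", "switches chirality of the terminal amino acid", "gramicidin"),
    DomainClass("C", "Dual E/C", "catalyzes both epimerization and condensation", "arthrofactin"),
    DomainClass("C", "Modified AA", "apparent modification of the incorporated amino acid (e.g. Ser dehydration)", "bleomycin"),
    DomainClass("C", "Hybrid C", "condensation of an amino acid onto an aminated polyketide", "mycosubtilin"),
)


def taxonomy(domain_type: str) -> tuple[DomainClass, ...]:
    if domain_type == "KS":
        return KS_CLASSES
    if domain_type == "C":
        return C_CLASSES
    raise ReferenceDBError(f"unknown domain type {domain_type!r}")


def class_names(domain_type: str) -> list[str]:
    return [c.class_name for c in taxonomy(domain_type)]


@dataclass(frozen=True)
class ReferenceDomain:
    domain_id: str
    domain_type: str
    class_label: str
    pathway_name: str
    pathway_type: str  # PKS | NRPS | hybrid | FAS
    product: str
    gene_accession: str
    literature_ref: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ReferenceDBError(f"reference {self.domain_id!r}: empty sequence")
        bad = set(self.sequence) - _REF_ALPHABET
        if bad:
            raise ReferenceDBError(
                f"reference {self.domain_id!r}: invalid residues {sorted(bad)}"
            )
        if self.class_label not in class_names(self.domain_type):
            raise ReferenceDBError(
                f"reference {self.domain_id!r}: unknown class label "
                f"{self.class_label!r} for domain type {self.domain_type}"
            )


@dataclass
class ReferenceAlignment:
    """Master alignment over the reference domains; the fixed coordinate
    system every downstream stage (profile, query insertion, tree) works in."""

    domain_type: str
    rows: dict[str, str]  # ordered: domain_id -> gapped sequence
    n_columns: int = field(init=False)

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ReferenceDBError(f"ragged master alignment: row lengths {sorted(lengths)}")
        self.n_columns = lengths.pop()

    def ungapped(self, domain_id: str) -> str:
        return self.rows[domain_id].replace("-", "")


@dataclass
class ValidationReport:
    domain_type: str
    class_counts: dict[str, int]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.warnings


class ReferenceDatabase:
    """Validated bundle of reference domains, taxonomy, and master alignment."""

    def __init__(self, domains: list[ReferenceDomain], alignment: ReferenceAlignment):
        types = {d.domain_type for d in domains}
        if len(types) != 1:
            raise ReferenceDBError(f"mixed domain types in one database: {sorted(types)}")
        self.domain_type = types.pop()
        if alignment.domain_type != self.domain_type:
            raise ReferenceDBError("alignment domain type differs from domains")
        self.domains: dict[str, ReferenceDomain] = {}
        for d in domains:
            if d.domain_id in self.domains:
                raise ReferenceDBError(f"duplicate domain id {d.domain_id!r}")
            self.domains[d.domain_id] = d
        self.alignment = alignment
        for domain_id in alignment.rows:
            if domain_id not in self.domains:
                raise ReferenceDBError(
                    f"alignment row {domain_id!r} has no database entry"
                )
        for d in self.domains.values():
            if d.domain_id not in alignment.rows:
                raise ReferenceDBError(
                    f"reference {d.domain_id!r} missing from the master alignment"
                )
            if alignment.ungapped(d.domain_id) != d.sequence:
                raise ReferenceDBError(
                    f"reference {d.domain_id!r}: ungapped alignment row does not "
                    f"match its FASTA sequence"
                )
        self.taxonomy = taxonomy(self.domain_type)

    def __len__(self) -> int:
        return len(self.domains)

    def __iter__(self):
        return iter(self.domains.values())

    def get(self, domain_id: str) -> ReferenceDomain:
        return self.domains[domain_id]

    @property
    def ids(self) -> list[str]:
        return list(self.domains)

    def total_residues(self) -> int:
        return sum(len(d.sequence) for d in self.domains.values())

    def class_of(self, domain_id: str) -> str:
        return self.domains[domain_id].class_label

    def class_map(self) -> dict[str, str]:
        return {i: d.class_label for i, d in self.domains.items()}


def _read_fasta_rows(path) -> dict[str, str]:
    from Bio import SeqIO

    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ReferenceDBError(f"duplicate id {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq).upper()
    if not rows:
        raise ReferenceDBError(f"no records in {path}")
    return rows


def load_reference_db(domain_fasta_path, metadata_table_path, alignment_path) -> ReferenceDatabase:
    """Load and cross-validate the reference FASTA, TSV metadata, and master
    alignment. Every mismatch error names the offending domain id."""
    seqs = _read_fasta_rows(domain_fasta_path)
    meta = pd.read_csv(metadata_table_path, sep="\t", dtype=str).fillna("")
    if list(meta.columns) != METADATA_COLUMNS:
        raise ReferenceDBError(
            f"metadata header must be {METADATA_COLUMNS}, got {list(meta.columns)}"
        )
    meta_ids = list(meta["domain_id"])
    for domain_id in seqs:
        if domain_id not in meta_ids:
            raise ReferenceDBError(f"no metadata row for FASTA id {domain_id!r}")
    for domain_id in meta_ids:
        if domain_id not in seqs:
            raise ReferenceDBError(f"metadata row {domain_id!r} has no FASTA sequence")
    domains = [
        ReferenceDomain(sequence=seqs[row.domain_id], **{c: getattr(row, c) for c in METADATA_COLUMNS})
        for row in meta.itertuples(index=False)
    ]
    aln_rows = _read_fasta_rows(alignment_path)
    alignment = ReferenceAlignment(domains[0].domain_type, aln_rows)
    return ReferenceDatabase(domains, alignment)


def write_reference_db(db: ReferenceDatabase, domain_fasta_path, metadata_table_path, alignment_path) -> None:
    """Inverse of :func:`load_reference_db` (byte-stable round trip)."""
    from .sequence_io import write_fasta

    write_fasta([(d.domain_id, d.sequence) for d in db], domain_fasta_path)
    meta = pd.DataFrame(
        [[getattr(d, c) for c in METADATA_COLUMNS] for d in db],
        columns=METADATA_COLUMNS,
    )
    meta.to_csv(metadata_table_path, sep="\t", index=False)
    write_fasta(db.alignment.rows.items(), alignment_path)


def validate_taxonomy(db: ReferenceDatabase) -> ValidationReport:
    """Per-class member counts; warns (does not fail) on empty classes."""
    counts = {c.class_name: 0 for c in db.taxonomy}
    for d in db:
        counts[d.class_label] += 1
    warnings = [
        f"class {name!r} has no reference members"
        for name, n in counts.items()
        if n == 0
    ]
    return ValidationReport(db.domain_type, counts, warnings)


_PACKAGED = {
    "KS": ("ks_reference.synthetic.faa", "ks_reference.synthetic.tsv", "ks_reference.synthetic.afa"),
    "C": ("c_reference.synthetic.faa", "c_reference.synthetic.tsv", "c_reference.synthetic.afa"),
}


def packaged_db_paths(domain_type: str) -> tuple[Path, Path, Path]:
    base = resources.files("domainmine") / "data"
    names = _PACKAGED[domain_type]
    return tuple(Path(str(base / n)) for n in names)  # type: ignore[return-value]


def load_packaged_db(domain_type: str) -> ReferenceDatabase:
    """Load the miniature reference set shipped with the package.

    The shipped set is synthetic: class-structured families produced by
    :mod:`domainmine.synthetic` under a fixed seed, carrying the real KS/C
    class taxonomy and example-product metadata. It stands in for a curated
    database of experimentally characterized pathway domains, which cannot be
    redistributed here, and is sized for offline testing (tens of domains per
    type rather than hundreds).
    """
    return load_reference_db(*packaged_db_paths(domain_type))
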