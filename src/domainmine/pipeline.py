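"""End-to-end orchestration: routing, detection, search, trimming, dedup,
alignment insertion, tree building, classification, and report writing.

Input routing mirrors how a domain-mining service treats different data:
amino-acid input is searched directly; short nucleotide input (PCR amplicons,
CDS — median < 5,000 nt) is six-frame translated and searched directly with
the best frame kept; long nucleotide input (contigs, genomes, metagenomes)
is first prescreened with the domain profile to get rough coordinates, which
are then confirmed by a loose local-alignment search (E <= 1) against the
reference database.
"""

from __future__ import annotations

import dataclasses
import logging
import statistics
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import classify as classify_mod
from . import detection, profile_align, search, sequence_io, trimming
from .reference_db import ReferenceDatabase, load_packaged_db
from .sequence_io import QuerySequence

GENOMIC_MEDIAN_NT = 5000
MIN_CANDIDATE_LENGTH = {"KS": 150, "C": 100}
#: padding (aa) around prescreen regions when cutting candidate subsequences
CANDIDATE_PAD = 30

REPORT_COLUMNS = [
    "tag_id",
    "parent_query_id",
    "best_match_id",
    "percent_identity",
    "alignment_length",
    "e_value",
    "product",
    "pathway_classification",
    "provisional_class",
    "final_class",
    "support",
    "novel_flag",
    "reclassified",
    "frame",
    "strand",
    "aa_start",
    "aa_end",
    "nt_start",
    "nt_end",
]

DIAGNOSTIC_COLUMNS = [
    "query_id",
    "frame",
    "aa_start",
    "aa_end",
    "nt_start",
    "nt_end",
    "strand",
    "raw_score",
    "e_value",
    "confirmed",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    domain_type: str = "KS"  # KS | C | both
    input_type: str = "auto"  # auto | aa | nt | genomic
    hmm_e_cutoff: float = detection.DEFAULT_E_CUTOFF
    confirm_e_cutoff: Optional[float] = None  # default: 1 genomic, 1e-8 direct
    min_candidate_length: Optional[int] = None
    dedup: str = "auto"  # auto (exact on the genomic path, off otherwise) | off | exact | cluster
    dedup_identity: float = 0.95
    build_tree: bool = True
    support_threshold: float = classify_mod.DEFAULT_SUPPORT_THRESHOLD
    seed: int = 0
    output_dir: str = "domainmine_out"
    max_bytes: int = sequence_io.DEFAULT_MAX_BYTES
    max_count: int = sequence_io.DEFAULT_MAX_COUNT

    def __post_init__(self):
        if self.domain_type not in ("KS", "C", "both"):
            raise PipelineError(f"unknown domain type {self.domain_type!r}")
        if self.input_type not in ("auto", "aa", "nt", "genomic"):
            raise PipelineError(f"unknown input type {self.input_type!r}")
        if self.hmm_e_cutoff <= 0:
            raise PipelineError("prescreen E cutoff must be > 0")
        if not 0 <= self.dedup_identity <= 1:
            raise PipelineError("dedup identity must be in [0, 1]")
        if self.dedup not in ("auto", "off", "exact", "cluster"):
            raise PipelineError(f"unknown dedup mode {self.dedup!r}")


@dataclass
class RunResult:
    report: pd.DataFrame
    diagnostics: pd.DataFrame
    tags: list[trimming.TrimmedDomain]
    newick: dict[str, str]  # domain_type -> newick text (empty if no tree)
    class_counts: dict[str, dict[str, int]]
    output_dir: Path
    unalignable: list[str] = field(default_factory=list)


def route(sequences: list[QuerySequence], config: RunConfig) -> str:
    """Return the execution plan: 'direct_aa', 'direct_nt', or 'genomic'."""
    alphabets = {s.alphabet for s in sequences}
    if config.input_type == "auto" and len(alphabets) > 1:
        raise PipelineError(
            "mixed nucleotide/amino-acid input; set input_type explicitly"
        )
    alphabet = sequences[0].alphabet
    if config.input_type == "aa":
        if alphabet != "aa":
            raise PipelineError("input_type=aa but sequences look like nucleotide")
        return "direct_aa"
    if config.input_type in ("nt", "genomic"):
        if alphabet != "nt":
            raise PipelineError(f"input_type={config.input_type} but sequences look like amino acid")
        if config.input_type == "genomic":
            return "genomic"
        return "direct_nt" if statistics.median(len(s) for s in sequences) < GENOMIC_MEDIAN_NT else "genomic"
    # auto
    if alphabet == "aa":
        return "direct_aa"
    median_len = statistics.median(len(s) for s in sequences)
    return "direct_nt" if median_len < GENOMIC_MEDIAN_NT else "genomic"


def dedup(
    tags: list[trimming.TrimmedDomain],
    mode: str = "exact",
    identity_threshold: float = 0.95,
) -> tuple[list[trimming.TrimmedDomain], dict[str, list[str]]]:
    """Remove redundant tags; returns (representatives, redundancy map).

    'exact' collapses byte-identical amino-acid tags; 'cluster' greedily
    clusters longest-first at >= ``identity_threshold`` alignment identity.
    The redundancy map (representative -> member tag ids, self included)
    preserves pre-dedup counts.
    """
    if mode == "off":
        return list(tags), {t.tag_id: [t.tag_id] for t in tags}
    if mode == "exact":
        reps: dict[str, trimming.TrimmedDomain] = {}
        mapping: dict[str, list[str]] = {}
        for t in tags:
            if t.aa_sequence in reps:
                mapping[reps[t.aa_sequence].tag_id].append(t.tag_id)
            else:
                reps[t.aa_sequence] = t
                mapping[t.tag_id] = [t.tag_id]
        return list(reps.values()), mapping
    if mode == "cluster":
        order = sorted(tags, key=lambda t: (-len(t.aa_sequence), t.tag_id))
        reps_list: list[trimming.TrimmedDomain] = []
        mapping = {}
        for t in order:
            home = None
            for rep in reps_list:
                aln = search.local_align(t.aa_sequence, rep.aa_sequence)
                if aln.percent_identity / 100.0 >= identity_threshold and (
                    aln.alignment_length >= 0.8 * min(len(t.aa_sequence), len(rep.aa_sequence))
                ):
                    home = rep
                    break
            if home is None:
                reps_list.append(t)
                mapping[t.tag_id] = [t.tag_id]
            else:
                mapping[home.tag_id].append(t.tag_id)
        kept_ids = {r.tag_id for r in reps_list}
        out = [t for t in tags if t.tag_id in kept_ids]
        return out, mapping
    raise PipelineError(f"unknown dedup mode {mode!r}")


def _setup_logger(output_dir: Path) -> logging.Logger:
    logger = logging.getLogger(f"domainmine.{output_dir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(output_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.propagate = False
    return logger


def _direct_hits(
    sequences, frames_by_query, db, cutoff, stats
) -> tuple[list[trimming.TrimmedDomain], pd.DataFrame]:
    """Direct path: best hit per query (aa) or per best frame (nt)."""
    tags = []
    for qs in sequences:
        if frames_by_query is None:
            hits = search.search_db(qs.residues, db, cutoff, query_id=qs.query_id, stats=stats)
            if hits:
                tags.append(trimming.trim_query(qs, hits[0]))
        else:
            best = None
            for frame in frames_by_query[qs.query_id]:
                if not frame.aa_residues:
                    continue
                hits = search.search_db(
                    frame.aa_residues, db, cutoff, query_id=qs.query_id, stats=stats
                )
                if hits and (best is None or hits[0].e_value < best[1].e_value):
                    best = (frame, hits[0])
            if best is not None:
                tags.append(trimming.trim_query(best[0], best[1]))
    return tags, pd.DataFrame(columns=DIAGNOSTIC_COLUMNS)


def _genomic_hits(
    sequences, db, config: RunConfig, min_len: int, stats, logger
) -> tuple[list[trimming.TrimmedDomain], pd.DataFrame]:
    """Genomic path: profile prescreen, then loose confirmation search."""
    profile = detection.build_profile(db.alignment)
    profile = detection.calibrate_profile(profile, seed=config.seed)
    all_frames = []
    frames_by_query = {}
    for qs in sequences:
        frames = sequence_io.translate_six_frames(qs)
        frames_by_query[qs.query_id] = {f.frame: f for f in frames}
        all_frames.extend(frames)
    regions = detection.scan_frames(
        profile, all_frames, e_cutoff=config.hmm_e_cutoff, min_candidate_length=min_len
    )
    logger.info("prescreen: %d candidate regions", len(regions))
    confirm_cutoff = (
        config.confirm_e_cutoff
        if config.confirm_e_cutoff is not None
        else search.CONFIRM_E_CUTOFF
    )
    tags = []
    diag_rows = []
    for region in regions:
        frame = frames_by_query[region.parent_query_id][region.frame]
        lo = max(0, region.aa_start - CANDIDATE_PAD)
        hi = min(len(frame.aa_residues), region.aa_end + CANDIDATE_PAD)
        candidate = frame.aa_residues[lo:hi]
        hits = search.search_db(
            candidate, db, confirm_cutoff, query_id=region.parent_query_id, stats=stats
        )
        confirmed = bool(hits)
        if confirmed:
            hit = hits[0]
            # hit coordinates are on the candidate slice; shift to the frame
            shifted = dataclasses.replace(
                hit, q_start=hit.q_start + lo, q_end=hit.q_end + lo
            )
            tags.append(trimming.trim_query(frame, shifted))
        diag_rows.append(
            [
                region.parent_query_id,
                region.frame,
                region.aa_start,
                region.aa_end,
                region.nt_start,
                region.nt_end,
                region.strand,
                round(region.raw_score, 3),
                f"{region.e_value:.3g}",
                confirmed,
            ]
        )
    diagnostics = pd.DataFrame(diag_rows, columns=DIAGNOSTIC_COLUMNS)
    return tags, diagnostics


def _format_report(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return df


def _run_single(
    config: RunConfig,
    sequences: list[QuerySequence],
    domain_type: str,
    db: Optional[ReferenceDatabase],
    logger,
) -> tuple[pd.DataFrame, pd.DataFrame, list, dict, Optional[str], list[str]]:
    db = db if db is not None else load_packaged_db(domain_type)
    master_before = dict(db.alignment.rows)
    stats = search.default_score_stats()
    plan = route(sequences, config)
    logger.info("domain_type=%s plan=%s n_queries=%d", domain_type, plan, len(sequences))
    min_len = (
        config.min_candidate_length
        if config.min_candidate_length is not None
        else MIN_CANDIDATE_LENGTH[domain_type]
    )
    direct_cutoff = (
        config.confirm_e_cutoff
        if config.confirm_e_cutoff is not None
        else search.DIRECT_E_CUTOFF
    )
    if plan == "direct_aa":
        tags, diagnostics = _direct_hits(sequences, None, db, direct_cutoff, stats)
    elif plan == "direct_nt":
        frames_by_query = {
            qs.query_id: sequence_io.translate_six_frames(qs) for qs in sequences
        }
        tags, diagnostics = _direct_hits(sequences, frames_by_query, db, direct_cutoff, stats)
    else:
        tags, diagnostics = _genomic_hits(sequences, db, config, min_len, stats, logger)
    tags = trimming.resolve_overlaps(tags)
    tags = trimming.assign_serials(tags)
    logger.info("%d domain tags after trimming/overlap resolution", len(tags))
    dedup_mode = config.dedup
    if dedup_mode == "auto":
        dedup_mode = "exact" if plan == "genomic" else "off"
    tags, redundancy = dedup(tags, dedup_mode, config.dedup_identity)
    logger.info("%d tags after dedup (%s)", len(tags), dedup_mode)

    results: dict[str, classify_mod.ClassificationResult] = {}
    newick_text = None
    ext = None
    unalignable_ids: list[str] = []
    if config.build_tree and tags:
        from . import phylogeny

        ext, unalignable = profile_align.build_extended_alignment(tags, db.alignment)
        unalignable_ids = [e.tag_id for e in unalignable]
        if unalignable_ids:
            logger.info("unalignable tags excluded from tree: %s", unalignable_ids)
        dm = phylogeny.compute_distances(ext)
        tree = phylogeny.neighbor_joining(dm)
        rooted = phylogeny.midpoint_root(tree)
        newick_text = phylogeny.write_newick(rooted)
        clf = classify_mod.TreeClassifier(
            rooted, db.class_map(), domain_type, config.support_threshold
        )
        for t in tags:
            if t.tag_id in ext.query_rows:
                provisional = classify_mod.classify_by_hit(t.best_hit, domain_type)
                results[t.tag_id] = classify_mod.reconcile(
                    provisional, clf.classify(t.tag_id), domain_type
                )
        # fixed-reference contract: master alignment never mutates
        if dict(db.alignment.rows) != master_before:
            raise PipelineError("reference alignment was modified during the run")
    rows = []
    class_counts: dict[str, int] = {}
    for t in tags:
        hit = t.best_hit
        res = results.get(t.tag_id)
        provisional = classify_mod.classify_by_hit(hit, domain_type)
        final = res.final_class if res is not None else provisional
        class_counts[final] = class_counts.get(final, 0) + 1
        rows.append(
            {
                "tag_id": t.tag_id,
                "parent_query_id": t.parent_query_id,
                "best_match_id": hit.subject_id,
                "percent_identity": f"{hit.percent_identity:.1f}",
                "alignment_length": hit.alignment_length,
                "e_value": f"{hit.e_value:.3g}",
                "product": hit.subject_product,
                "pathway_classification": hit.subject_pathway_type,
                "provisional_class": provisional,
                "final_class": final,
                "support": f"{res.support:.3f}" if res is not None else "",
                "novel_flag": res.novel_flag if res is not None else "",
                "reclassified": res.reclassified if res is not None else "",
                "frame": t.frame if t.frame is not None else "",
                "strand": t.strand if t.strand is not None else "",
                "aa_start": t.aa_start,
                "aa_end": t.aa_end,
                "nt_start": t.nt_start if t.nt_start is not None else "",
                "nt_end": t.nt_end if t.nt_end is not None else "",
            }
        )
    report = _format_report(rows)
    return report, diagnostics, tags, class_counts, newick_text, unalignable_ids, ext


def run(config: RunConfig, input_path) -> RunResult:
    """Execute the full pipeline and write all artifacts to the output dir:
    report.tsv, tags.faa, extended_alignment.afa, tree.nwk, diagnostics.tsv,
    run.log. Deterministic for a fixed config (including seed)."""
    output_dir = Path(config.output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    logger = _setup_logger(output_dir)
    t0 = time.time()
    logger.info("seed=%d input=%s", config.seed, input_path)
    written: list[Path] = []
    try:
        sequences = sequence_io.read_fasta(input_path)
        sequence_io.enforce_limits(sequences, config.max_bytes, config.max_count)
        domain_types = ["KS", "C"] if config.domain_type == "both" else [config.domain_type]
        reports, diags, all_tags, newicks, counts = [], [], [], {}, {}
        exts: dict[str, object] = {}
        unalignable: list[str] = []
        for dt in domain_types:
            rep, diag, tags, cc, nwk, unal, ext = _run_single(config, sequences, dt, None, logger)
            rep.insert(0, "domain_type", dt)
            diag.insert(0, "domain_type", dt)
            reports.append(rep)
            diags.append(diag)
            all_tags.extend(tags)
            counts[dt] = cc
            unalignable.extend(unal)
            if nwk is not None:
                newicks[dt] = nwk
            if ext is not None:
                exts[dt] = ext

        report = pd.concat(reports, ignore_index=True)
        diagnostics = pd.concat(diags, ignore_index=True)
        report_path = output_dir / "report.tsv"
        report.to_csv(report_path, sep="\t", index=False)
        written.append(report_path)
        tags_path = output_dir / "tags.faa"
        trimming.tags_to_fasta(all_tags, tags_path)
        written.append(tags_path)
        diag_path = output_dir / "diagnostics.tsv"
        diagnostics.to_csv(diag_path, sep="\t", index=False)
        written.append(diag_path)
        for dt, nwk in newicks.items():
            suffix = "" if len(domain_types) == 1 else f"_{dt}"
            tree_path = output_dir / f"tree{suffix}.nwk"
            tree_path.write_text(nwk)
            written.append(tree_path)
        for dt, ext in exts.items():
            suffix = "" if len(domain_types) == 1 else f"_{dt}"
            ext_path = output_dir / f"extended_alignment{suffix}.afa"
            ext.write_fasta(ext_path)
            written.append(ext_path)
        # summary: per-class counts and secondary-vs-FAS breakdown
        for dt, cc in counts.items():
            n_fas = cc.get("FAS", 0)
            n_secondary = sum(v for k, v in cc.items() if k not in ("FAS", "unclassified"))
            logger.info(
                "%s summary: %s | secondary-metabolism domains: %d | FAS: %d",
                dt,
                dict(sorted(cc.items())),
                n_secondary,
                n_fas,
            )
        logger.info("done in %.1fs", time.time() - t0)
        return RunResult(
            report=report,
            diagnostics=diagnostics,
            tags=all_tags,
            newick=newicks,
            class_counts=counts,
            output_dir=output_dir,
            unalignable=unalignable,
        )
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        stage = type(exc).__name__
        logger.error("aborted: %s: %s", stage, exc)
        raise PipelineError(f"pipeline aborted ({stage}): {exc}") from exc
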