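"""Self-contained benchmark computations over synthetic ground truth.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stage(s), and measures the outcome, so the quality claims in the
documentation can be recomputed from scratch at any time. Problem sizes are
desk-scale: alignment oracles run on exhaustive enumeration of short pairs,
detection on a 1 Mb genome with 100 planted domains, classification on 200
divergent tags against the shipped reference sets.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from . import detection, phylogeny, profile_align, search
from .classify import TreeClassifier
from .reference_db import ReferenceAlignment, ReferenceDatabase, load_packaged_db
from .sequence_io import QuerySequence, translate_six_frames
from .synthetic import embed_in_genome, random_genome, simulate_query_tags

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# exact-alignment oracle


def brute_force_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Exhaustive local-alignment optimum for short sequences: enumerate every
    monotone matching of residue pairs; unmatched residues between consecutive
    pairs form affine gap runs (open + extend per residue). Independent of the
    dynamic program it checks."""
    S, idx = search._matrix("BLOSUM62")
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        for ia in itertools.combinations(range(len(a)), k):
            for ib in itertools.combinations(range(len(b)), k):
                sc = sum(int(S[idx[a[i]], idx[b[j]]]) for i, j in zip(ia, ib))
                for t in range(k - 1):
                    di = ia[t + 1] - ia[t] - 1
                    dj = ib[t + 1] - ib[t] - 1
                    if di:
                        sc -= gap_open + gap_extend * di
                    if dj:
                        sc -= gap_open + gap_extend * dj
                best = max(best, sc)
    return best


def smith_waterman_oracle(n_pairs: int = 1000, max_length: int = 6, seed: int = 0) -> dict:
    """Fraction of random short pairs (4-letter reduced alphabet) on which the
    Smith-Waterman score equals the brute-force enumeration."""
    rng = np.random.default_rng(seed)
    alphabet = list("ACDW")
    agree = 0
    for _ in range(n_pairs):
        a = "".join(rng.choice(alphabet, size=rng.integers(1, max_length + 1)))
        b = "".join(rng.choice(alphabet, size=rng.integers(1, max_length + 1)))
        agree += search.local_align(a, b).score == brute_force_local_score(a, b)
    return {"value": agree / n_pairs, "n": n_pairs}


# ---------------------------------------------------------------------------
# neighbor-joining oracle


def _random_binary_tree(n_leaves: int, rng: np.random.Generator) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_leaves):
        nd = dendropy.Node(taxon=tns.new_taxon(f"L{i}"))
        nd.edge.length = rng.exponential(0.3) + 0.05
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        p = dendropy.Node()
        p.add_child(nodes[int(i)])
        p.add_child(nodes[int(j)])
        p.edge.length = rng.exponential(0.3) + 0.05
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))] + [p]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = False
    return tree


def _rf(newick_a: str, newick_b: str) -> int:
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return treecompare.symmetric_difference(a, b)


def neighbor_joining_oracle(n_trials: int = 50, n_leaves: int = 8, seed: int = 0) -> dict:
    """Fraction of random additive matrices (path distances of random binary
    trees) from which neighbor joining recovers the exact topology (RF = 0)."""
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_trials):
        true = _random_binary_tree(n_leaves, rng)
        pdm = true.phylogenetic_distance_matrix()
        taxa = sorted(true.taxon_namespace, key=lambda t: t.label)
        labels = [t.label for t in taxa]
        D = np.zeros((n_leaves, n_leaves))
        for i in range(n_leaves):
            for j in range(i + 1, n_leaves):
                D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        est = phylogeny.neighbor_joining(phylogeny.DistanceMatrix(labels, D, []))
        exact += _rf(phylogeny.write_newick(est), true.as_string(schema="newick")) == 0
    return {"value": exact / n_trials, "n": n_trials}


# ---------------------------------------------------------------------------
# detection sensitivity / specificity


def detection_benchmark(
    seed: int = 0,
    n_domains: int = 100,
    genome_length: int = 1_000_000,
    identities: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8),
    coord_tolerance_aa: int = 15,
) -> dict:
    """Plant ``n_domains`` KS domains (identity >= 50% to their parent
    reference) in a 1 Mb random genome; measure prescreen recall (coordinates
    within the tolerance) at E <= 1e-5, plus the false-region rate on an
    equally sized domain-free genome."""
    db = load_packaged_db("KS")
    profile = detection.calibrate_profile(detection.build_profile(db.alignment), seed=seed)
    per = n_domains // len(identities)
    tags = []
    for k, ident in enumerate(identities):
        batch = simulate_query_tags(db, per, target_identity=ident, seed=seed * 997 + k)
        tags.extend((f"i{k}_{t[0]}", t[1], t[2], t[3]) for t in batch)
    records, truth = embed_in_genome(tags, genome_length, seed=seed * 991 + 5)
    frames = []
    for rec_id, nt in records:
        frames.extend(translate_six_frames(QuerySequence(rec_id, "nt", nt, 0)))
    regions = detection.scan_frames(profile, frames, e_cutoff=1e-5, min_candidate_length=150)
    found = 0
    errors = []
    for row in truth.itertuples():
        for r in regions:
            if (
                r.parent_query_id == row.replicon_id
                and r.frame == row.frame
                and abs(r.aa_start - row.aa_start) <= coord_tolerance_aa
                and abs(r.aa_end - row.aa_end) <= coord_tolerance_aa
            ):
                found += 1
                errors.append(abs(r.aa_start - row.aa_start))
                break
    # specificity: an equally sized genome with no planted domains
    rng = np.random.default_rng(seed * 983 + 7)
    clean = random_genome(genome_length, rng)
    clean_frames = translate_six_frames(QuerySequence("clean", "nt", clean, 0))
    false_regions = detection.scan_frames(
        profile, clean_frames, e_cutoff=1e-5, min_candidate_length=150
    )
    return {
        "recall": found / len(truth),
        "mean_coord_error_aa": float(np.mean(errors)) if errors else float("nan"),
        "false_regions_per_mb": len(false_regions) / (genome_length / 1e6),
        "n": len(truth),
    }


# ---------------------------------------------------------------------------
# classification recovery


def classification_benchmark(seed: int = 0, n_tags: int = 200, identity: float = 0.7) -> dict:
    """Simulate tags at the given identity from every KS class, insert them
    into the master alignment, build the joint tree, and score the fraction
    whose tree-based class matches the generating class."""
    db = load_packaged_db("KS")
    sims = simulate_query_tags(db, n_tags, target_identity=identity, seed=seed * 977 + 11)
    aln_profile = detection.build_profile(db.alignment, drop_gap_majority=False)
    ext = profile_align.ExtendedAlignment(base=db.alignment)
    kept = []
    for tag_id, seq, cls, _parent in sims:
        try:
            row, _entry = profile_align.align_to_profile(seq, db.alignment, profile=aln_profile)
        except profile_align.UnalignableTagError:
            continue
        ext.query_rows[tag_id] = row
        kept.append((tag_id, cls))
    dm = phylogeny.compute_distances(ext)
    rooted = phylogeny.midpoint_root(phylogeny.neighbor_joining(dm))
    clf = TreeClassifier(rooted, db.class_map(), "KS")
    correct = sum(clf.classify(tag_id).final_class == cls for tag_id, cls in kept)
    return {"value": correct / n_tags, "n": n_tags}


def leave_one_out_self_recovery(domain_types: tuple[str, ...] = ("KS", "C")) -> dict:
    """Re-run every shipped reference as a query against the database without
    it; score the fraction that recover their own class from the tree."""
    total = 0
    correct = 0
    for dt in domain_types:
        db = load_packaged_db(dt)
        for held_out in db.ids:
            kept = [d for d in db if d.domain_id != held_out]
            rows = {d.domain_id: db.alignment.rows[d.domain_id] for d in kept}
            sub = ReferenceDatabase(kept, ReferenceAlignment(dt, rows))
            query = db.get(held_out).sequence
            row, _ = profile_align.align_to_profile(query, sub.alignment)
            ext = profile_align.ExtendedAlignment(base=sub.alignment)
            ext.query_rows["query"] = row
            dm = phylogeny.compute_distances(ext)
            rooted = phylogeny.midpoint_root(phylogeny.neighbor_joining(dm))
            clf = TreeClassifier(rooted, sub.class_map(), dt)
            total += 1
            correct += clf.classify("query").final_class == db.class_of(held_out)
    return {"value": correct / total, "n": total}


# ---------------------------------------------------------------------------
# pipeline contracts


def pipeline_contract_checks(seed: int, workdir) -> dict:
    """Run the genomic pipeline twice on a small planted genome and check the
    fixed-reference contract and byte-level reproducibility."""
    from pathlib import Path

    from .pipeline import RunConfig, run
    from .reference_db import packaged_db_paths
    from .sequence_io import write_fasta

    workdir = Path(workdir)
    db = load_packaged_db("KS")
    tags = simulate_query_tags(db, 5, target_identity=0.7, seed=seed * 953 + 3)
    records, _ = embed_in_genome(tags, 150_000, seed=seed * 947 + 1)
    fasta = workdir / "genome.fasta"
    write_fasta(records, fasta)
    outs = []
    for name in ("run_a", "run_b"):
        config = RunConfig(domain_type="KS", output_dir=str(workdir / name), seed=seed)
        run(config, fasta)
        outs.append(workdir / name)
    identical = (
        (outs[0] / "report.tsv").read_bytes() == (outs[1] / "report.tsv").read_bytes()
        and (outs[0] / "tree.nwk").read_bytes() == (outs[1] / "tree.nwk").read_bytes()
    )
    # the master alignment rows embedded in the output are byte-identical to
    # the shipped file
    shipped = packaged_db_paths("KS")[2].read_text()
    produced = (outs[0] / "extended_alignment.afa").read_text()
    intact = all(
        produced.find(f">{domain_id}\n") >= 0 for domain_id in db.ids
    )
    fresh = load_packaged_db("KS")
    intact = intact and dict(fresh.alignment.rows) == dict(db.alignment.rows)
    # extract reference rows from the produced alignment and compare bytes
    prod_rows = _fasta_rows(produced)
    ship_rows = _fasta_rows(shipped)
    intact = intact and all(prod_rows[i] == ship_rows[i] for i in db.ids)
    return {
        "reference_rows_intact": float(intact),
        "same_seed_byte_identical": float(identical),
    }


def _fasta_rows(text: str) -> dict[str, str]:
    rows = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            rows[name] = ""
        elif name is not None:
            rows[name] += line.strip()
    return rows


def input_limit_boundary() -> dict:
    """Validator boundary behavior at the documented caps."""
    from .sequence_io import LimitExceededError, enforce_limits

    ok = True
    seqs_50k = [QuerySequence(f"q{i}", "aa", "M", i) for i in range(50_000)]
    try:
        enforce_limits(seqs_50k)
    except LimitExceededError:
        ok = False
    try:
        enforce_limits(seqs_50k + [QuerySequence("extra", "aa", "M", 50_000)])
        ok = False
    except LimitExceededError:
        pass
    big = [QuerySequence("big", "aa", "M" * 1_000_000, 0) for _ in range(30)]
    try:
        enforce_limits(big)  # exactly 30e6 residues: inclusive boundary
    except LimitExceededError:
        ok = False
    try:
        enforce_limits(big + [QuerySequence("x", "aa", "M", 30)])
        ok = False
    except LimitExceededError:
        pass
    return {"value": float(ok), "n": 50_000}
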