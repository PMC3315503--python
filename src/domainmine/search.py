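"""Local alignment of queries against the reference domains.

The aligner is a full Smith-Waterman dynamic program with affine gaps
(a gap of length g costs open + g*extend), scored with BLOSUM62 by default.
It fills the role a heuristic BLASTP/BLASTX search plays in a web pipeline;
at reference-database scale (tens of domains) the exact algorithm is fast
enough and bit-reproducible.

E-values follow the extreme-value form E = K*m*n*exp(-lambda*S). The gapped
(lambda, K) pair for a scoring scheme is fitted once by seeded Monte-Carlo
(moment-matched Gumbel over optimal local scores of random sequence pairs)
and cached — shipped as package data for the default BLOSUM62/11/1 scheme.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

NEG = np.int64(-(2**40))

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_MATRIX = "BLOSUM62"

#: default E-value cutoffs: strict for direct amino-acid/CDS queries, loose
#: for confirming prescreened genomic candidates
DIRECT_E_CUTOFF = 1e-8
CONFIRM_E_CUTOFF = 1.0


class AlignmentError(ValueError):
    pass


@lru_cache(maxsize=None)
def _matrix(name: str):
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    index = {c: i for i, c in enumerate(alphabet)}
    return np.asarray(mat, dtype=np.int64), index


def encode(seq: str, matrix_name: str = DEFAULT_MATRIX) -> np.ndarray:
    _, index = _matrix(matrix_name)
    x = index.get("X", 0)
    return np.fromiter((index.get(c, x) for c in seq.upper()), dtype=np.int64, count=len(seq))


@dataclass(frozen=True)
class Alignment:
    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aligned_query: str
    aligned_subject: str
    n_identical: int
    alignment_length: int

    @property
    def percent_identity(self) -> float:
        if self.alignment_length == 0:
            return 0.0
        return 100.0 * self.n_identical / self.alignment_length


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    percent_identity: float
    alignment_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    subject_product: str
    subject_class: str
    subject_pathway_type: str


def local_align(
    query_aa: str,
    subject_aa: str,
    substitution_matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Optimal Smith-Waterman local alignment with affine gap costs.

    Traceback ties are broken diagonal > up > left, and the start cell of the
    optimum is the row-major argmax, so output is deterministic.
    """
    if not query_aa or not subject_aa:
        raise AlignmentError("cannot align an empty sequence")
    S, _ = _matrix(substitution_matrix)
    q = encode(query_aa, substitution_matrix)
    s = encode(subject_aa, substitution_matrix)
    m, n = len(q), len(s)
    oe = np.int64(gap_open + gap_extend)
    e = np.int64(gap_extend)

    # M: q[i-1] aligned to s[j-1]; Ix: gap in subject (consumes query);
    # Iy: gap in query (consumes subject). Row-wise vectorized; the same-row
    # Iy recursion is solved by a running-max identity.
    M = np.full((m + 1, n + 1), 0, dtype=np.int64)
    Ix = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    Iy = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    sub = S[q][:, s]  # (m, n) substitution scores

    jj = np.arange(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        prevM, prevIx, prevIy = M[i - 1], Ix[i - 1], Iy[i - 1]
        best_prev = np.maximum(np.maximum(prevM, prevIx), prevIy)
        M[i, 1:] = np.maximum(0, np.maximum(best_prev[:-1] + sub[i - 1], 0))
        Ix[i] = np.maximum(np.maximum(prevM, prevIy) - oe, prevIx - e)
        # Iy[i, j] = max over k<j of (max(M[i,k], Ix[i,k]) - oe - e*(j-1-k))
        base = np.maximum(M[i], Ix[i]) - oe + e * jj
        run = np.maximum.accumulate(base)
        Iy[i, 1:] = run[:-1] - e * jj[1:] + e
    i, j = np.unravel_index(int(np.argmax(M)), M.shape)
    score = int(M[i, j])
    if score <= 0:
        return Alignment(0, 0, 0, 0, 0, "", "", 0, 0)

    # traceback (diag > up > left at every choice point)
    aq, asub = [], []
    q_end, s_end = i, j
    state = "M"
    while True:
        if state == "M":
            aq.append(query_aa[i - 1])
            asub.append(subject_aa[j - 1])
            base = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            if base == 0:
                break
            if M[i, j] == base:
                state = "M"
            elif Ix[i, j] == base:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            aq.append(query_aa[i - 1])
            asub.append("-")
            v = Ix[i, j]
            i -= 1
            if M[i, j] - oe == v:
                state = "M"
            elif Ix[i, j] - e == v:
                state = "Ix"
            else:
                state = "Iy"
        else:  # Iy
            aq.append("-")
            asub.append(subject_aa[j - 1])
            v = Iy[i, j]
            j -= 1
            if M[i, j] - oe == v:
                state = "M"
            elif Ix[i, j] - oe == v:
                state = "Ix"
            else:
                state = "Iy"
    aq.reverse()
    asub.reverse()
    aligned_q = "".join(aq)
    aligned_s = "".join(asub)
    n_id = sum(a == b for a, b in zip(aligned_q, aligned_s) if a != "-" and b != "-")
    return Alignment(
        score=score,
        q_start=i,
        q_end=q_end,
        s_start=j,
        s_end=s_end,
        aligned_query=aligned_q,
        aligned_subject=aligned_s,
        n_identical=n_id,
        alignment_length=len(aligned_q),
    )


# ---------------------------------------------------------------------------
# E-value statistics


@dataclass(frozen=True)
class ScoreStats:
    """Gumbel parameters of the gapped local-score null for one scheme."""

    matrix: str
    gap_open: int
    gap_extend: int
    lam: float
    K: float

    def e_value(self, score: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * score)

    def bit_score(self, score: float) -> float:
        return (self.lam * score - math.log(self.K)) / math.log(2)


def fit_score_stats(
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    n_pairs: int = 400,
    length: int = 200,
    seed: int = 271828,
    background: np.ndarray | None = None,
) -> ScoreStats:
    """Fit (lambda, K) by moment-matching a Gumbel to optimal local scores of
    random amino-acid sequence pairs: mu = ln(K*m*n)/lambda, beta = 1/lambda."""
    rng = np.random.default_rng(seed)
    letters = "ACDEFGHIKLMNPQRSTVWY"
    p = background if background is not None else np.full(20, 0.05)
    scores = np.empty(n_pairs)
    for t in range(n_pairs):
        a = "".join(rng.choice(list(letters), size=length, p=p))
        b = "".join(rng.choice(list(letters), size=length, p=p))
        scores[t] = local_align(a, b, matrix, gap_open, gap_extend).score
    beta = scores.std(ddof=1) * math.sqrt(6) / math.pi
    mu = scores.mean() - 0.5772156649015329 * beta
    lam = 1.0 / beta
    K = math.exp(lam * mu) / (length * length)
    return ScoreStats(matrix, gap_open, gap_extend, lam, K)


@lru_cache(maxsize=None)
def default_score_stats(
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> ScoreStats:
    """Cached stats: packaged JSON for the default scheme, fresh fit otherwise."""
    try:
        path = resources.files("domainmine") / "data" / "score_stats.json"
        entries = json.loads(path.read_text())
    except (FileNotFoundError, OSError):
        entries = []
    for entry in entries:
        if (entry["matrix"], entry["gap_open"], entry["gap_extend"]) == (
            matrix,
            gap_open,
            gap_extend,
        ):
            return ScoreStats(matrix, gap_open, gap_extend, entry["lambda"], entry["K"])
    return fit_score_stats(matrix, gap_open, gap_extend)


def search_db(
    query_aa: str,
    database,
    e_cutoff: float = DIRECT_E_CUTOFF,
    query_id: str = "query",
    substitution_matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    stats: ScoreStats | None = None,
) -> list[HitRecord]:
    """Align a query against every reference domain; return hits with
    E-value <= ``e_cutoff`` sorted by (E-value, -bit score, subject id)."""
    if stats is None:
        stats = default_score_stats(substitution_matrix, gap_open, gap_extend)
    n_total = database.total_residues()
    m = len(query_aa)
    hits = []
    for ref in database:
        aln = local_align(query_aa, ref.sequence, substitution_matrix, gap_open, gap_extend)
        if aln.score <= 0:
            continue
        ev = stats.e_value(aln.score, m, n_total)
        if ev > e_cutoff:
            continue
        hits.append(
            HitRecord(
                query_id=query_id,
                subject_id=ref.domain_id,
                raw_score=aln.score,
                bit_score=stats.bit_score(aln.score),
                e_value=ev,
                percent_identity=aln.percent_identity,
                alignment_length=aln.alignment_length,
                q_start=aln.q_start,
                q_end=aln.q_end,
                s_start=aln.s_start,
                s_end=aln.s_end,
                subject_product=ref.product,
                subject_class=ref.class_label,
                subject_pathway_type=ref.pathway_type,
            )
        )
    hits.sort(key=lambda h: (h.e_value, -h.bit_score, h.subject_id))
    return hits
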