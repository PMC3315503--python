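"""Profile-based prescreen of translated genomic/metagenomic frames.

A position-specific scoring profile (per-column log-odds in bits, built from
the master reference alignment) replaces third-party domain HMMs so the
package is self-contained; it plays the identical role in the pipeline:
cheap, low-stringency localization of candidate KS/C domain regions, whose
precise coordinates are recovered later by local alignment against the
reference database.

Window scores are calibrated empirically: a Gumbel is moment-matched to the
maximum window score of random background sequences, and region E-values are
the Gumbel tail probability scaled by dataset size (total translated residues
over calibration length), mirroring database-size E-value semantics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .reference_db import ReferenceAlignment
from .sequence_io import TranslatedFrame

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {c: i for i, c in enumerate(AA_ORDER)}

#: score assigned to stop codons: guarantees any window containing a stop is
#: rejected, truncating candidate windows at frame breaks
STOP_SCORE = -1.0e4

DEFAULT_E_CUTOFF = 1e-5
#: scan stride in residues. A position-specific profile has no shift
#: tolerance (a window off-register with the domain scores like background),
#: so candidate windows are evaluated at every position.
DEFAULT_SCAN_STEP = 1


class DetectionError(ValueError):
    pass


@dataclass(frozen=True)
class Calibration:
    mu: float
    beta: float
    length: int
    n_random: int
    seed: int

    def tail_probability(self, score: float) -> float:
        """P(max window score over one calibration-length sequence >= score)."""
        z = (score - self.mu) / self.beta
        if z > 30:
            return math.exp(-z)
        return -math.expm1(-math.exp(-z))

    def score_at_tail(self, p: float) -> float:
        """Inverse of :meth:`tail_probability`."""
        if p >= 1.0:
            return -math.inf
        return self.mu - self.beta * math.log(-math.log1p(-p))


@dataclass(frozen=True)
class Profile:
    """Per-column log-odds model over the 20 amino acids (bits)."""

    domain_type: str
    scores: np.ndarray  # (n_columns, 20) float64
    occupancy: np.ndarray  # (n_columns,) non-gap fraction per column
    background: np.ndarray  # (20,)
    column_index: np.ndarray  # original master-alignment column of each profile column
    calibration: Optional[Calibration] = None

    @property
    def n_columns(self) -> int:
        return self.scores.shape[0]

    def encode(self, aa: str) -> np.ndarray:
        """Residues -> alphabet indices; 20 = X/unknown (scores 0), 21 = stop."""
        return np.fromiter(
            (21 if c == "*" else _AA_INDEX.get(c, 20) for c in aa.upper()),
            dtype=np.int64,
            count=len(aa),
        )

    def score_table(self) -> np.ndarray:
        """(n_columns, 22) score matrix including X (0) and stop columns."""
        ext = np.zeros((self.n_columns, 22))
        ext[:, :20] = self.scores
        ext[:, 21] = STOP_SCORE
        return ext

    def window_scores(self, encoded: np.ndarray, step: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Total profile score of every length-``n_columns`` window at the
        given stride. Returns (start_positions, scores)."""
        L = self.n_columns
        n_pos = len(encoded) - L + 1
        if n_pos <= 0:
            return np.empty(0, dtype=np.int64), np.empty(0)
        starts = np.arange(0, n_pos, step, dtype=np.int64)
        table = self.score_table()
        out = np.zeros(len(starts))
        for c in range(L):
            out += table[c, encoded[starts + c]]
        return starts, out

    def to_json(self) -> str:
        doc = {
            "format_version": 1,
            "domain_type": self.domain_type,
            "alphabet": AA_ORDER,
            "scores": self.scores.tolist(),
            "occupancy": self.occupancy.tolist(),
            "background": self.background.tolist(),
            "column_index": self.column_index.tolist(),
            "calibration": None
            if self.calibration is None
            else {
                "mu": self.calibration.mu,
                "beta": self.calibration.beta,
                "length": self.calibration.length,
                "n_random": self.calibration.n_random,
                "seed": self.calibration.seed,
            },
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Profile":
        doc = json.loads(text)
        cal = doc.get("calibration")
        return cls(
            domain_type=doc["domain_type"],
            scores=np.asarray(doc["scores"]),
            occupancy=np.asarray(doc["occupancy"]),
            background=np.asarray(doc["background"]),
            column_index=np.asarray(doc["column_index"], dtype=np.int64),
            calibration=None if cal is None else Calibration(**cal),
        )


@dataclass(frozen=True)
class CandidateRegion:
    parent_query_id: str
    frame: int
    aa_start: int
    aa_end: int
    nt_start: int
    nt_end: int
    strand: str
    raw_score: float
    e_value: float


def build_profile(
    reference_alignment: ReferenceAlignment,
    pseudocount_weight: float = 1.0,
    background: Optional[np.ndarray] = None,
    drop_gap_majority: bool = True,
) -> Profile:
    """Column log-odds profile from the master alignment.

    Column frequencies are (observed counts + w * background) normalized;
    scores are log2(freq / background). Columns with more than 50% gaps are
    excluded when ``drop_gap_majority`` (the detection profile); the
    query-insertion stage keeps all columns to preserve coordinates.
    """
    rows = list(reference_alignment.rows.values())
    if len(rows) < 2:
        raise DetectionError("profile needs an alignment with at least 2 rows")
    bg = np.full(20, 0.05) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (20,) or not math.isclose(bg.sum(), 1.0, rel_tol=1e-6):
        raise DetectionError("background must be a 20-vector summing to 1")
    n_cols = reference_alignment.n_columns
    counts = np.zeros((n_cols, 20))
    nongap = np.zeros(n_cols)
    for row in rows:
        for j, c in enumerate(row):
            if c == "-":
                continue
            nongap[j] += 1
            k = _AA_INDEX.get(c)
            if k is not None:
                counts[j, k] += 1
    occupancy = nongap / len(rows)
    keep = occupancy > 0.5 if drop_gap_majority else np.ones(n_cols, dtype=bool)
    counts = counts[keep]
    denom = counts.sum(axis=1, keepdims=True) + pseudocount_weight
    freqs = (counts + pseudocount_weight * bg) / denom
    scores = np.log2(freqs / bg)
    return Profile(
        domain_type=reference_alignment.domain_type,
        scores=scores,
        occupancy=occupancy[keep],
        background=bg,
        column_index=np.flatnonzero(keep).astype(np.int64),
    )


def calibrate_profile(
    profile: Profile,
    n_random: int = 300,
    random_length: int = 2000,
    seed: int = 0,
) -> Profile:
    """Moment-match a Gumbel to max window scores of i.i.d. background
    sequences of ``random_length`` residues; stores (mu, beta) and the seed."""
    if n_random < 200:
        raise DetectionError("calibration needs n_random >= 200")
    if random_length < profile.n_columns + 1:
        raise DetectionError("calibration length must exceed the profile width")
    rng = np.random.default_rng(seed)
    draws = rng.choice(20, size=(n_random, random_length), p=profile.background).astype(np.int64)
    L = profile.n_columns
    n_pos = random_length - L + 1
    table = profile.score_table()
    totals = np.zeros((n_random, n_pos))
    for c in range(L):
        totals += table[c, draws[:, c : c + n_pos]]
    maxima = totals.max(axis=1)
    sd = maxima.std(ddof=1)
    if sd <= 0:
        raise DetectionError("degenerate calibration score distribution (beta <= 0)")
    beta = sd * math.sqrt(6) / math.pi
    mu = maxima.mean() - 0.5772156649015329 * beta
    cal = Calibration(mu=mu, beta=beta, length=random_length, n_random=n_random, seed=seed)
    return replace(profile, calibration=cal)


def _merge_and_refine(
    starts: np.ndarray,
    scores: np.ndarray,
    encoded: np.ndarray,
    profile: Profile,
    threshold: float,
    step: int,
) -> list[tuple[int, float]]:
    """Group above-threshold windows that overlap; keep each group's best
    window, refined to single-residue resolution around the stride optimum."""
    above = scores >= threshold
    if not above.any():
        return []
    sel_starts = starts[above]
    sel_scores = scores[above]
    L = profile.n_columns
    groups: list[list[int]] = [[0]]
    for idx in range(1, len(sel_starts)):
        if sel_starts[idx] - sel_starts[groups[-1][-1]] < L:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    table = profile.score_table()
    out = []
    for g in groups:
        best_local = g[int(np.argmax(sel_scores[g]))]
        coarse = int(sel_starts[best_local])
        if step == 1:
            out.append((coarse, float(sel_scores[best_local])))
            continue
        lo = max(0, coarse - step + 1)
        hi = min(len(encoded) - L, coarse + step - 1)
        cand = np.arange(lo, hi + 1, dtype=np.int64)
        fine = np.zeros(len(cand))
        for c in range(L):
            fine += table[c, encoded[cand + c]]
        k = int(np.argmax(fine))
        out.append((int(cand[k]), float(fine[k])))
    return out


def scan_frames(
    profile: Profile,
    frames: Sequence[TranslatedFrame],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    min_candidate_length: int = 0,
    step: int = DEFAULT_SCAN_STEP,
) -> list[CandidateRegion]:
    """Slide the profile along every frame and report maximal above-cutoff
    regions as rough candidate coordinates.

    E-values are normalized to the whole dataset: E = p_tail * (total
    translated residues / calibration length).
    """
    if profile.calibration is None:
        raise DetectionError("profile must be calibrated before scanning")
    cal = profile.calibration
    total_residues = sum(len(f.aa_residues) for f in frames)
    if total_residues == 0:
        return []
    norm = total_residues / cal.length
    # convert the E cutoff to a raw-score threshold once
    p_min = min(1.0, e_cutoff / norm)
    threshold = cal.score_at_tail(p_min)
    L = profile.n_columns
    regions = []
    for frame in frames:
        if len(frame.aa_residues) < max(L, min_candidate_length):
            continue
        enc = profile.encode(frame.aa_residues)
        starts, scores = profile.window_scores(enc, step=step)
        for aa_start, score in _merge_and_refine(starts, scores, enc, profile, threshold, step):
            aa_end = aa_start + L
            if aa_end - aa_start < min_candidate_length:
                continue
            ev = cal.tail_probability(score) * norm
            if ev > e_cutoff:
                continue
            nt_start, nt_end = frame.aa_to_nt(aa_start, aa_end)
            regions.append(
                CandidateRegion(
                    parent_query_id=frame.parent_query_id,
                    frame=frame.frame,
                    aa_start=aa_start,
                    aa_end=aa_end,
                    nt_start=nt_start,
                    nt_end=nt_end,
                    strand=frame.strand,
                    raw_score=score,
                    e_value=ev,
                )
            )
    regions.sort(key=lambda r: (r.parent_query_id, r.nt_start, r.frame))
    return regions
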