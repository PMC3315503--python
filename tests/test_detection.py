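import numpy as np
import pytest

from domainmine.detection import (
    DetectionError,
    Profile,
    build_profile,
    calibrate_profile,
    scan_frames,
)
from domainmine.reference_db import ReferenceAlignment
from domainmine.sequence_io import QuerySequence, reverse_complement, translate_six_frames
from domainmine.synthetic import embed_in_genome, random_protein, simulate_query_tags

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="module")
def calibrated(small_family):
    profile = build_profile(small_family.alignment)
    return calibrate_profile(profile, n_random=250, random_length=1200, seed=3)


class TestBuildProfile:
    def test_conserved_column_scores_its_residue_highest(self):
        aln = ReferenceAlignment("KS", {"r1": "AK", "r2": "AR", "r3": "AW"})
        profile = build_profile(aln, pseudocount_weight=1e-9)
        col = profile.scores[0]
        assert np.argmax(col) == AA.index("A")

    def test_uniform_usage_scores_near_zero(self):
        # 20 rows, each a different residue in column 0: matches uniform background
        rows = {f"r{i}": c for i, c in enumerate(AA)}
        aln = ReferenceAlignment("KS", rows)
        profile = build_profile(aln, pseudocount_weight=1e-9)
        assert np.allclose(profile.scores[0], 0.0, atol=1e-6)

    def test_consensus_outscores_every_reference_row(self, small_family):
        profile = build_profile(small_family.alignment)
        consensus = "".join(AA[k] for k in np.argmax(profile.scores, axis=1))
        enc_cons = profile.encode(consensus)
        table = profile.score_table()
        cons_score = sum(table[c, enc_cons[c]] for c in range(profile.n_columns))
        for row in small_family.alignment.rows.values():
            enc = profile.encode(row.replace("-", ""))
            row_score = sum(table[c, enc[c]] for c in range(profile.n_columns))
            assert cons_score >= row_score

    def test_gap_majority_columns_dropped(self):
        aln = ReferenceAlignment("KS", {"r1": "A-K", "r2": "A-R", "r3": "AW-"})
        profile = build_profile(aln)
        assert profile.n_columns == 2  # middle column is 2/3 gaps
        assert list(profile.column_index) == [0, 2]

    def test_requires_two_rows(self):
        with pytest.raises(DetectionError):
            build_profile(ReferenceAlignment("KS", {"r1": "AK"}))


class TestCalibration:
    def test_same_seed_same_parameters(self, small_family):
        p = build_profile(small_family.alignment)
        c1 = calibrate_profile(p, n_random=250, random_length=1200, seed=9).calibration
        c2 = calibrate_profile(p, n_random=250, random_length=1200, seed=9).calibration
        assert (c1.mu, c1.beta) == (c2.mu, c2.beta)

    def test_e_value_monotone_decreasing_in_score(self, calibrated):
        cal = calibrated.calibration
        scores = np.linspace(cal.mu, cal.mu + 200, 40)
        tails = [cal.tail_probability(s) for s in scores]
        assert all(a > b for a, b in zip(tails, tails[1:]))

    def test_median_random_max_score_has_tail_near_half(self, calibrated):
        """Monte-Carlo oracle: fresh random sequences of calibration length
        should exceed the fitted p=0.5 score about half the time."""
        cal = calibrated.calibration
        s_half = cal.score_at_tail(0.5)
        rng = np.random.default_rng(77)
        n, hits = 200, 0
        for _ in range(n):
            seq = "".join(rng.choice(list(AA), size=cal.length, p=calibrated.background))
            _, scores = calibrated.window_scores(calibrated.encode(seq))
            hits += scores.max() >= s_half
        assert abs(hits / n - 0.5) < 0.125  # within 25% of one half

    def test_minimum_sample_size_enforced(self, small_family):
        with pytest.raises(DetectionError):
            calibrate_profile(build_profile(small_family.alignment), n_random=100)

    def test_json_round_trip(self, calibrated):
        again = Profile.from_json(calibrated.to_json())
        assert np.allclose(again.scores, calibrated.scores)
        assert again.calibration == calibrated.calibration


def _frames_for(nt, name="contig"):
    return translate_six_frames(QuerySequence(name, "nt", nt, 0))


class TestScanFrames:
    def test_exact_domain_copy_is_found_significantly(self, small_family, calibrated):
        ref = next(iter(small_family))
        tags = [("t1", ref.sequence, ref.class_label, ref.domain_id)]
        records, truth = embed_in_genome(tags, 20_000, seed=5)
        regions = scan_frames(calibrated, _frames_for(records[0][1]), min_candidate_length=50)
        assert len(regions) == 1
        region = regions[0]
        row = truth.iloc[0]
        assert region.e_value <= 1e-5
        assert abs(region.aa_start - row.aa_start) <= 15
        assert region.frame == row.frame

    def test_random_background_yields_no_regions(self, calibrated, rng):
        from domainmine.sequence_io import TranslatedFrame

        for trial in range(10):
            frame_seq = random_protein(10_000, rng)
            frame = TranslatedFrame("bg", 1, frame_seq, 0, 30_000)
            regions = scan_frames(calibrated, [frame], min_candidate_length=50)
            assert regions == []

    def test_two_distant_domains_give_two_disjoint_regions(self, small_family, calibrated):
        refs = list(small_family)
        aa_gap = random_protein(1000, np.random.default_rng(8))
        frame_seq = (
            random_protein(200, np.random.default_rng(9))
            + refs[0].sequence
            + aa_gap
            + refs[3].sequence
            + random_protein(200, np.random.default_rng(10))
        )
        from domainmine.sequence_io import TranslatedFrame

        frame = TranslatedFrame("q", 1, frame_seq, 0, 3 * len(frame_seq))
        regions = scan_frames(calibrated, [frame], min_candidate_length=50)
        assert len(regions) == 2
        starts = sorted((r.aa_start, r.aa_end) for r in regions)
        assert abs(starts[0][0] - 200) <= 15
        assert abs(starts[1][0] - (200 + len(refs[0].sequence) + 1000)) <= 15
        assert starts[0][1] <= starts[1][0]

    def test_detection_is_strand_symmetric(self, small_family, calibrated):
        ref = next(iter(small_family))
        tags = [("t1", ref.sequence, ref.class_label, ref.domain_id)]
        records, _ = embed_in_genome(tags, 12_000, seed=21)
        nt = records[0][1]
        fwd = scan_frames(calibrated, _frames_for(nt), min_candidate_length=50)
        rev = scan_frames(calibrated, _frames_for(reverse_complement(nt)), min_candidate_length=50)
        L = len(nt)
        fwd_set = {(r.nt_start, r.nt_end, r.strand) for r in fwd}
        rev_mapped = {(L - r.nt_end, L - r.nt_start, "+" if r.strand == "-" else "-") for r in rev}
        assert fwd_set == rev_mapped

    def test_uncalibrated_profile_rejected(self, small_family):
        profile = build_profile(small_family.alignment)
        with pytest.raises(DetectionError):
            scan_frames(profile, [])
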