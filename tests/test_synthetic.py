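import numpy as np
import pytest
from Bio.Seq import Seq

from domainmine.search import local_align
from domainmine.sequence_io import QuerySequence, translate_six_frames
from domainmine.synthetic import (
    SyntheticError,
    embed_in_genome,
    fragment_genome,
    mutate_to_identity,
    random_protein,
    reverse_translate,
    simulate_query_tags,
    simulate_reference_family,
)


class TestReferenceFamily:
    def test_family_size_and_taxonomy(self):
        db, newick = simulate_reference_family(
            n_classes=9, members_per_class=4, domain_length=120, seed=2
        )
        assert len(db) == 36
        assert len({d.class_label for d in db}) == 9
        assert db.alignment.n_columns == 120

    def test_within_class_identity_exceeds_between_class(self, small_family):
        domains = list(small_family)
        within, between = [], []
        for i in range(len(domains)):
            for j in range(i + 1, len(domains)):
                a, b = domains[i], domains[j]
                ident = np.mean([x == y for x, y in zip(a.sequence, b.sequence)])
                (within if a.class_label == b.class_label else between).append(ident)
        assert np.mean(within) > np.mean(between) + 0.2

    def test_same_seed_reproduces_identical_sequences(self):
        a, _ = simulate_reference_family(n_classes=3, members_per_class=2, domain_length=80, seed=5)
        b, _ = simulate_reference_family(n_classes=3, members_per_class=2, domain_length=80, seed=5)
        assert [d.sequence for d in a] == [d.sequence for d in b]

    def test_divergence_ordering_enforced(self):
        with pytest.raises(SyntheticError):
            simulate_reference_family(
                between_class_divergence=0.05, within_class_divergence=0.1, seed=1
            )


class TestMutate:
    def test_target_one_returns_sequence_unchanged(self, rng):
        seq = random_protein(100, rng)
        assert mutate_to_identity(seq, 1.0, seed=3) == seq

    @pytest.mark.parametrize("target", [0.5, 0.7, 0.9])
    def test_realized_identity_within_three_points(self, target):
        rng = np.random.default_rng(0)
        seq = random_protein(450, rng)
        for trial in range(30):
            mutated = mutate_to_identity(seq, target, seed=trial)
            realized = np.mean([a == b for a, b in zip(seq, mutated)])
            assert abs(realized - target) <= 0.03

    def test_alignment_identity_agrees_with_bookkeeping(self):
        """Cross-check: the aligner's measured identity matches the
        generator's target within 3 points."""
        rng = np.random.default_rng(1)
        seq = random_protein(300, rng)
        for trial in range(10):
            mutated = mutate_to_identity(seq, 0.7, seed=50 + trial)
            aln = local_align(seq, mutated)
            assert abs(aln.percent_identity / 100 - 0.7) <= 0.03

    def test_invalid_target_rejected(self):
        with pytest.raises(SyntheticError):
            mutate_to_identity("MKLV", 0.0)


class TestEmbedding:
    def test_truth_rows_and_non_overlap(self, small_family):
        tags = simulate_query_tags(small_family, 5, 1.0, seed=3)
        records, truth = embed_in_genome(tags, 50_000, seed=4)
        assert len(truth) == 5
        intervals = sorted(zip(truth.nt_start, truth.nt_end))
        assert all(b0 >= a1 for (_, a1), (b0, _) in zip(intervals, intervals[1:]))

    def test_planted_frames_translate_back_to_the_domain(self, small_family):
        tags = simulate_query_tags(small_family, 6, 1.0, seed=7)
        by_id = {t[0]: t[1] for t in tags}
        records, truth = embed_in_genome(tags, 40_000, seed=8)
        frames = {
            (rec_id, f.frame): f
            for rec_id, seq in records
            for f in translate_six_frames(QuerySequence(rec_id, "nt", seq, 0))
        }
        for row in truth.itertuples():
            frame = frames[(row.replicon_id, row.frame)]
            assert frame.aa_residues[row.aa_start : row.aa_end] == by_id[row.planted_tag_id]

    def test_strand_balance(self, small_family):
        tags = simulate_query_tags(small_family, 40, 1.0, seed=11)
        small = [(t[0], t[1][:30], t[2], t[3]) for t in tags]
        all_strands = []
        for s in range(5):
            _, truth = embed_in_genome(small, 30_000, seed=s)
            all_strands.extend(truth.strand)
        n_plus = sum(s == "+" for s in all_strands)
        # binomial(200, 0.5) 99% band
        assert 77 <= n_plus <= 123

    def test_overfull_genome_rejected(self, small_family):
        tags = simulate_query_tags(small_family, 5, 1.0, seed=3)
        with pytest.raises(SyntheticError):
            embed_in_genome(tags, 1000, seed=1)

    def test_deterministic_for_fixed_seed(self, small_family):
        tags = simulate_query_tags(small_family, 3, 1.0, seed=5)
        a, _ = embed_in_genome(tags, 20_000, seed=6)
        b, _ = embed_in_genome(tags, 20_000, seed=6)
        assert a == b


class TestHelpers:
    def test_reverse_translation_round_trips(self, rng):
        protein = random_protein(80, rng)
        nt = reverse_translate(protein, rng)
        assert str(Seq(nt).translate()) == protein

    def test_gc_bias_shifts_composition(self, rng):
        protein = random_protein(500, rng)
        low = reverse_translate(protein, np.random.default_rng(1), gc=0.3)
        high = reverse_translate(protein, np.random.default_rng(1), gc=0.7)
        gc = lambda s: (s.count("G") + s.count("C")) / len(s)
        assert gc(high) > gc(low)

    def test_fragmentation_covers_the_genome(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        reads = fragment_genome([("g", seq)], mean_length=244, seed=2)
        assert sum(len(r[1]) for r in reads) == pytest.approx(5000, abs=300)
        assert np.mean([len(r[1]) for r in reads]) == pytest.approx(244, rel=0.35)
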