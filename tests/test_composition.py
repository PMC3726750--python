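import numpy as np
import pytest
from conftest import rand_dna
from oracles import brute_simple_repeats

from estqc.composition import (RepeatInterval, find_interspersed,
                               find_low_complexity, find_simple_repeats,
                               gc_profile, merge_intervals, repeat_profile)
from estqc.seqio import AssemblySet, SequenceRecord


class TestSimpleRepeats:
    def test_planted_dinucleotide_array(self):
        rng = np.random.default_rng(0)
        seq = rand_dna(rng, 1_000) + "AT" * 20 + rand_dna(rng, 1_000)
        hits = find_simple_repeats(SequenceRecord(id="c", residues=seq))
        # the reported maximal array contains the planted one and may extend
        # a few bases into chance continuations in the flanks
        assert any(h.motif == "AT" and h.start <= 1_000 and h.end >= 1_040
                   and h.end - h.start <= 60 for h in hits)

    def test_mononucleotide_run(self):
        rec = SequenceRecord(id="c", residues="GC" * 20 + "A" * 30 + "GC" * 20)
        hits = find_simple_repeats(rec)
        assert any(h.motif == "A" and h.end - h.start == 30 for h in hits)

    def test_rotated_motif_reported_canonically(self):
        # array starting mid-unit: TATATA... has canonical motif AT
        rec = SequenceRecord(id="c", residues="CCGCCG" + "TA" * 15 + "CGGCGG")
        hits = find_simple_repeats(rec)
        assert any(h.motif == "AT" for h in hits)

    def test_n_breaks_arrays(self):
        rec = SequenceRecord(id="c", residues="A" * 15 + "N" + "A" * 15)
        assert find_simple_repeats(rec) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_brute_force_on_seeded_sequences(self, seed):
        rng = np.random.default_rng(seed)
        parts = [rand_dna(rng, 400)]
        for _ in range(4):
            u = int(rng.integers(1, 7))
            motif = rand_dna(rng, u)
            parts.append(motif * int(rng.integers(3, 30)))
            parts.append(rand_dna(rng, int(rng.integers(50, 400))))
        seq = "".join(parts)[:2_000]
        rec = SequenceRecord(id="c", residues=seq)
        got = [(h.start, h.end, h.motif) for h in find_simple_repeats(rec)]
        assert got == brute_simple_repeats(seq)


class TestLowComplexity:
    def test_periodic_high_entropy_sequence_not_flagged(self):
        rec = SequenceRecord(id="c", residues="ACGT" * 100)
        assert find_low_complexity(rec, entropy_max=1.0) == []

    def test_biased_tract_flagged(self):
        rng = np.random.default_rng(1)
        tract = "".join("A" if rng.random() < 0.9 else "CGT"[int(rng.integers(3))]
                        for _ in range(300))
        seq = rand_dna(rng, 500) + tract + rand_dna(rng, 500)
        hits = find_low_complexity(SequenceRecord(id="c", residues=seq))
        assert hits
        covered = sum(min(h.end, 800) - max(h.start, 500) for h in hits
                      if h.end > 500 and h.start < 800)
        assert covered >= 0.8 * 300

    def test_uniform_random_rarely_flagged(self):
        rng = np.random.default_rng(2)
        rec = SequenceRecord(id="c", residues=rand_dna(rng, 100_000))
        hits = find_low_complexity(rec, window=64, entropy_max=1.0)
        assert sum(h.length for h in hits) <= 1_000

    def test_window_validation(self):
        rec = SequenceRecord(id="c", residues="ACGT" * 10)
        with pytest.raises(ValueError):
            find_low_complexity(rec, window=4)


class TestInterspersed:
    def test_planted_family_recovered(self):
        rng = np.random.default_rng(3)
        unit = rand_dna(rng, 500)
        loci = []
        chunks = []
        pos = 0
        for _ in range(20):
            gap = rand_dna(rng, int(rng.integers(2_000, 6_000)))
            chunks.append(gap)
            pos += len(gap)
            loci.append(pos)
            chunks.append(unit)
            pos += 500
        asm = AssemblySet(kind="chromosome", records=[
            SequenceRecord(id="c", residues="".join(chunks))])
        hits = find_interspersed(asm, k=13, copy_min=10)
        well_covered = 0
        for locus in loci:
            cov = sum(min(h.end, locus + 500) - max(h.start, locus)
                      for h in hits if h.end > locus and h.start < locus + 500)
            if cov >= 0.8 * 500:
                well_covered += 1
        assert well_covered >= 18

    def test_unique_sequence_is_clean(self):
        rng = np.random.default_rng(4)
        asm = AssemblySet(kind="chromosome", records=[
            SequenceRecord(id="c", residues=rand_dna(rng, 200_000))])
        assert find_interspersed(asm, k=13, copy_min=10) == []

    def test_duplicated_chromosome_fully_flagged(self):
        rng = np.random.default_rng(5)
        seq = rand_dna(rng, 30_000)
        asm = AssemblySet(kind="chromosome", records=[
            SequenceRecord(id="c1", residues=seq),
            SequenceRecord(id="c2", residues=seq),
        ])
        hits = find_interspersed(asm, k=13, copy_min=2)
        for rec_id in ("c1", "c2"):
            cov = sum(h.length for h in hits if h.target_id == rec_id)
            assert cov >= 0.99 * 30_000


class TestRepeatProfile:
    def test_boundary_spanning_interval_counts_twice(self):
        rec = SequenceRecord(id="c", residues="A" * 200)
        iv = RepeatInterval("c", 50, 150, "simple", "A")
        prof = repeat_profile(rec, [iv], width=100)
        assert prof == [(0, 1, 50), (1, 1, 50)]

    def test_no_intervals_all_zero(self):
        rec = SequenceRecord(id="c", residues="A" * 250)
        assert repeat_profile(rec, [], width=100) == \
            [(0, 0, 0), (1, 0, 0), (2, 0, 0)]

    def test_exact_tiling_fills_segment(self):
        rec = SequenceRecord(id="c", residues="A" * 200)
        ivs = [RepeatInterval("c", 0, 40, "simple", "A"),
               RepeatInterval("c", 40, 100, "low_complexity")]
        prof = repeat_profile(rec, ivs, width=100)
        assert prof[0] == (0, 2, 100)

    def test_total_length_is_conserved(self, tiny_sim):
        genome, truth = tiny_sim
        rec = genome.records[0]
        intervals = [RepeatInterval(c, s, e, k, m if k == "simple" else None)
                     for c, s, e, k, m in truth.repeat_intervals
                     if c == rec.id]
        merged = [RepeatInterval(c, s, e, "simple")
                  for c, s, e in merge_intervals(intervals)]
        prof = repeat_profile(rec, merged, width=10_000)
        assert sum(length for _, _, length in prof) == \
            sum(iv.length for iv in merged)


class TestGcProfile:
    def test_whole_record_equals_weighted_segment_mean(self, tiny_sim):
        genome, _ = tiny_sim
        for rec in genome.records:
            segments, overall = gc_profile(rec, width=10_000)
            weighted = sum((e - s) * gc for _, s, e, gc in segments) / rec.length
            assert overall == pytest.approx(weighted, abs=1e-9)

    def test_pure_n_segment_scores_zero(self):
        rec = SequenceRecord(id="c", residues="N" * 100 + "G" * 100)
        segments, overall = gc_profile(rec, width=100)
        assert segments[0][3] == 0.0
        assert segments[1][3] == 1.0
        assert overall == 0.5

    def test_uniform_gc_segments_are_tight(self):
        rng = np.random.default_rng(6)
        rec = SequenceRecord(id="c", residues=rand_dna(rng, 300_000))
        segments, _ = gc_profile(rec, width=100_000)
        for _, _, _, gc in segments:
            assert 0.47 <= gc <= 0.53


class TestRepeatInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            RepeatInterval("c", 10, 10, "simple")
        with pytest.raises(ValueError):
            RepeatInterval("c", 0, 10, "weird")
        with pytest.raises(ValueError):
            RepeatInterval("c", 0, 10, "simple", motif="AAAAAAA")
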