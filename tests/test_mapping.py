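import numpy as np
import pytest
from conftest import rand_dna
from oracles import best_single_intron_score

from estqc.mapping import (AlignParams, CapacityError, KmerIndex, map_all,
                           map_est, seed_candidates,
                           spliced_align_exhaustive)
from estqc.seqio import AssemblySet, SequenceRecord, reverse_complement
from estqc.simulate import surviving_fraction


def _two_exon(rng, e1=150, e2=150, intron=100, flank=50):
    E1, E2 = rand_dna(rng, e1), rand_dna(rng, e2)
    inner = "GT" + rand_dna(rng, intron - 4) + "AG"
    target = rand_dna(rng, flank) + E1 + inner + E2 + rand_dna(rng, flank)
    return E1 + E2, target, flank, flank + e1 + intron


class TestExhaustiveAligner:
    def test_exact_substring_scores_match_times_length(self):
        rng = np.random.default_rng(0)
        target = rand_dna(rng, 1_000)
        est = target[300:600]
        hit = spliced_align_exhaustive(est, target)
        assert hit.score == 300
        assert hit.identity == 1.0
        assert hit.coverage == 1.0
        assert hit.exon_blocks == [(300, 600)]
        assert hit.strand == "+"

    def test_two_exon_construction_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        est, target, x1, x2 = _two_exon(rng)
        hit = spliced_align_exhaustive(est, target)
        assert hit.score == 300 - 20
        assert hit.exon_blocks == [(x1, x1 + 150), (x2, x2 + 150)]
        assert hit.score == best_single_intron_score(est, target)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_two_exon_instances_equal_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        e1 = int(rng.integers(100, 200))
        e2 = int(rng.integers(100, 200))
        intron = int(rng.integers(40, 300))
        est, target, _, _ = _two_exon(rng, e1, e2, intron)
        hit = spliced_align_exhaustive(est, target)
        assert hit.score == best_single_intron_score(est, target)
        assert hit.score == e1 + e2 - 20

    def test_splice_preference_is_exactly_the_penalty_difference(self):
        from oracles import controlled_two_exon

        rng = np.random.default_rng(2)
        est, target, broken = controlled_two_exon(rng, 150, 150)
        p = AlignParams()
        canonical = spliced_align_exhaustive(est, target, p)
        non_canon = spliced_align_exhaustive(est, broken, p)
        assert canonical.score == 300 - p.spliced_intron_open
        assert canonical.score - non_canon.score == \
            p.intron_open - p.spliced_intron_open

    def test_five_percent_substitutions_still_matched(self):
        rng = np.random.default_rng(3)
        target = rand_dna(rng, 2_000)
        est = list(target[500:900])
        for i in rng.choice(400, size=20, replace=False):
            est[i] = "ACGT"[(("ACGT".index(est[i])) + 1) % 4]
        hit = spliced_align_exhaustive("".join(est), target)
        assert 0.90 <= hit.identity <= 1.0
        assert hit.matched

    def test_strand_symmetry(self):
        rng = np.random.default_rng(4)
        est, target, _, _ = _two_exon(rng)
        fwd = spliced_align_exhaustive(est, target)
        rev = spliced_align_exhaustive(reverse_complement(est), target)
        assert fwd.strand == "+" and rev.strand == "-"
        assert fwd.score == rev.score
        assert fwd.exon_blocks == rev.exon_blocks

    def test_score_monotone_in_appended_matches(self):
        rng = np.random.default_rng(5)
        target = rand_dna(rng, 800)
        prev = 0
        for length in (50, 100, 200, 400):
            est = target[100:100 + length]
            hit = spliced_align_exhaustive(est, target)
            assert hit.score >= prev
            prev = hit.score

    def test_capacity_error_directs_to_map_est(self):
        with pytest.raises(CapacityError, match="map_est"):
            spliced_align_exhaustive(
                "ACGT" * 10, "A" * 250_000,
                AlignParams(exhaustive_target_max=200_000))

    def test_empty_sequences_rejected(self):
        with pytest.raises(ValueError):
            spliced_align_exhaustive("", "ACGT")


class TestSeedCandidates:
    @pytest.fixture(scope="class")
    def assembly(self):
        rng = np.random.default_rng(6)
        return AssemblySet(kind="chromosome", records=[
            SequenceRecord(id="chr1", residues=rand_dna(rng, 50_000)),
            SequenceRecord(id="chr2", residues=rand_dna(rng, 50_000)),
        ])

    def test_exact_source_window_found(self, assembly):
        est = assembly.records[1].residues[20_000:20_400]
        p = AlignParams(max_intron=2_000)
        windows = seed_candidates(est, assembly, p)
        covering = [w for w in windows
                    if w[0] == "chr2" and w[3] == "+"
                    and w[1] <= 20_000 and w[2] >= 20_400]
        assert covering

    def test_alien_est_yields_no_windows(self, assembly):
        # rejection-sample an EST sharing no k-mer with the assembly
        p = AlignParams(max_intron=2_000)
        index = KmerIndex(assembly, p.seed_k)
        rng = np.random.default_rng(7)
        for _ in range(50):
            est = rand_dna(rng, 100)
            if not seed_candidates(est, assembly, p, index=index):
                return
        pytest.fail("could not construct a seed-free EST in 50 draws")

    def test_tandem_copies_give_windows_containing_each_copy(self):
        rng = np.random.default_rng(8)
        unit = rand_dna(rng, 300)
        target = rand_dna(rng, 5_000) + unit + rand_dna(rng, 10_000) \
            + unit + rand_dna(rng, 5_000)
        asm = AssemblySet(kind="chromosome", records=[
            SequenceRecord(id="c", residues=target)])
        windows = seed_candidates(unit, asm, AlignParams(max_intron=2_000))
        plus = [w for w in windows if w[3] == "+"]
        assert 1 <= len(plus) <= 2
        for locus in (5_000, 15_300):
            assert any(ws <= locus and we >= locus + 300
                       for _, ws, we, _ in plus)


class TestMapEst:
    def test_all_n_est_maps_nowhere(self):
        rng = np.random.default_rng(9)
        asm = AssemblySet(kind="chromosome", records=[
            SequenceRecord(id="c", residues=rand_dna(rng, 10_000))])
        est = SequenceRecord(id="n", residues="N" * 200)
        assert map_est(est, asm) is None

    def test_empty_assembly(self):
        est = SequenceRecord(id="e", residues="ACGTACGT")
        hits, matched, selected = map_all(
            [est], AssemblySet(kind="chromosome", records=[]))
        assert (hits, matched, selected) == ([], 0, 1)

    def test_error_free_ests_all_match_at_planted_loci(self, clean_run):
        cfg, genome, truth, assembly, ests, params = clean_run
        hits, matched, selected = map_all(ests[:60], assembly, params)
        assert selected == 60
        assert matched == 60
        genes = truth.genes_by_id()
        by_est = {h.est_id: h for h in hits}
        exact_checked = 0
        for est in ests[:60]:
            hit = by_est[est.id]
            label = truth.est_labels[est.id]
            gene = genes[label.gene_id]
            assert hit.target_id == gene.chrom
            assert hit.strand == gene.strand
            source = [(s, e) for _, s, e in label.source_intervals]
            # exactness is asserted for + genes whose terminal exon pieces
            # outweigh the intron penalty; a sliver may legally stay
            # unaligned, and on - genes (splice sites read CT..AC on the
            # forward target, so the GT..AG discount does not apply) the
            # junction may shift a few bases toward a chance canonical site
            if (gene.strand == "+"
                    and source[0][1] - source[0][0] > 20
                    and source[-1][1] - source[-1][0] > 20):
                assert hit.identity == 1.0
                assert hit.exon_blocks == source
                exact_checked += 1
            else:
                assert hit.identity >= 0.95
                assert hit.coverage >= 0.85
                lo, hi = gene.span
                assert hit.exon_blocks[0][0] >= lo - 25
                assert hit.exon_blocks[-1][1] <= hi + 25
        assert exact_checked >= 15

    def test_est_from_dropped_region_fails(self, clean_run):
        from estqc.simulate import derive_assembly

        cfg, genome, truth, _, ests, params = clean_run
        import copy

        import dataclasses
        truth2 = copy.deepcopy(truth)
        cfg2 = dataclasses.replace(cfg, drop_fraction=0.3)
        assembly = derive_assembly(genome, truth2, cfg2)
        dropped = {}
        for chrom, s, e in truth2.dropped_regions:
            dropped.setdefault(chrom, []).append((s, e))
        lost = [e for e in ests
                if surviving_fraction(truth2.est_labels[e.id], dropped) == 0.0]
        assert lost, "expected at least one fully dropped EST"
        for est in lost[:5]:
            hit = map_est(est, assembly, params)
            assert hit is None or not hit.matched


class TestMapAllAgainstTruth:
    def test_matched_fraction_tracks_planted_survival(self, clean_run):
        from estqc.simulate import matchable_fraction

        cfg, genome, truth, _, ests, params = clean_run
        import copy
        import dataclasses

        truth2 = copy.deepcopy(truth)
        cfg2 = dataclasses.replace(cfg, drop_fraction=0.3)
        from estqc.simulate import derive_assembly

        assembly = derive_assembly(genome, truth2, cfg2)
        hits, matched, selected = map_all(ests, assembly, params)
        pred = matchable_fraction(truth2, params.coverage_min)
        se = np.sqrt(max(pred * (1 - pred), 0.01) / selected)
        assert abs(matched / selected - pred) <= 3 * se
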