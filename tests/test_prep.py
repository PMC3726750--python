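import numpy as np
import pytest

from estqc.prep import (CleaningOutcome, CleanParams, _draw,
                        clip_vector_adaptor, first_round_sample,
                        run_cleaning, screen_contaminants,
                        second_round_sample, second_round_size)
from estqc.seqio import SequenceRecord
from conftest import rand_dna


def _ids(n):
    return [f"acc{i:07d}" for i in range(n)]


class TestFirstRoundSample:
    def test_half_above_ten_thousand(self):
        ids = _ids(10_855)
        chosen = first_round_sample(ids, 10_855, seed=1)
        assert len(chosen) == 5_428          # round-half-up of 5427.5

    def test_all_below_ten_thousand(self):
        ids = _ids(8_146)
        assert first_round_sample(ids, 8_146, seed=1) == ids

    def test_boundary_exactly_ten_thousand_keeps_all(self):
        ids = _ids(10_000)
        assert first_round_sample(ids, 10_000, seed=1) == ids

    def test_preconditions(self):
        with pytest.raises(ValueError):
            first_round_sample([], 10, seed=1)
        with pytest.raises(ValueError):
            first_round_sample(_ids(20), 10, seed=1)


class TestSecondRoundSample:
    @pytest.mark.parametrize("total,expect", [
        (1_529_700, 15_297),   # 1% tier
        (10_855, 1_086),       # 10% tier, round half up
        (89_943, 8_994),       # 10% tier
        (8_146, 8_146),        # keep-all tier
        (100_000, 10_000),     # boundary falls to the 10% tier
        (10_000, 10_000),      # boundary falls to keep-all
    ])
    def test_tier_sizes(self, total, expect):
        assert second_round_size(total) == expect

    def test_selection_honours_size_rule(self):
        ids = _ids(12_000)
        chosen = second_round_sample(ids, 10_855, seed=7)
        assert len(chosen) == 1_086
        assert len(set(chosen)) == 1_086
        assert set(chosen) <= set(ids)

    def test_capped_at_clean_pool(self, caplog):
        ids = _ids(500)
        with caplog.at_level("WARNING"):
            chosen = second_round_sample(ids, 10_855, seed=7)
        assert len(chosen) == 500
        assert "capped" in caplog.text

    def test_determinism_and_seed_sensitivity(self):
        ids = _ids(20_000)
        a = second_round_sample(ids, 20_000, seed=3)
        b = second_round_sample(ids, 20_000, seed=3)
        c = second_round_sample(ids, 20_000, seed=4)
        assert a == b
        assert a != c


class TestSamplingUniformity:
    def test_each_id_selected_near_ten_percent(self):
        ids = _ids(1_000)
        counts = np.zeros(1_000)
        reps = 200
        for seed in range(reps):
            for chosen in _draw(ids, 100, seed):
                counts[int(chosen[3:])] += 1
        freq = counts / reps
        sd = np.sqrt(0.1 * 0.9 / reps)
        assert (np.abs(freq - 0.1) <= 4 * sd).all()


class TestClipVectorAdaptor:
    @pytest.fixture()
    def vectors(self, tiny_refs):
        return [r for r in tiny_refs if "class=vector" in r.description]

    def test_planted_prefix_is_trimmed(self, vectors):
        rng = np.random.default_rng(0)
        insert = rand_dna(rng, 400)
        est = SequenceRecord(id="e1",
                             residues=vectors[0].residues[:40] + insert)
        outcome, trimmed = clip_vector_adaptor(est, vectors)
        assert outcome.action == "trimmed_kept"
        assert outcome.trimmed_prefix == 40
        assert outcome.final_length == 400
        assert trimmed.residues == insert

    def test_unrelated_est_kept_unchanged(self, vectors):
        rng = np.random.default_rng(1)
        est = SequenceRecord(id="e2", residues=rand_dna(rng, 300))
        outcome, kept = clip_vector_adaptor(est, vectors)
        assert outcome.action == "kept"
        assert kept.residues == est.residues

    def test_pure_vector_removed_as_too_short(self, vectors):
        est = SequenceRecord(id="e3", residues=vectors[1].residues[100:600])
        outcome, kept = clip_vector_adaptor(est, vectors)
        assert kept is None
        assert outcome.removal_reason == "too_short_after_trim"

    def test_internal_vector_marks_chimera(self, vectors):
        rng = np.random.default_rng(2)
        est = SequenceRecord(
            id="e4",
            residues=rand_dna(rng, 200) + vectors[0].residues[:60]
            + rand_dna(rng, 200))
        outcome, kept = clip_vector_adaptor(est, vectors)
        assert kept is None
        assert outcome.removal_reason == "internal_vector"


class TestScreenContaminants:
    @pytest.fixture()
    def screens(self, tiny_refs):
        return [r for r in tiny_refs if "class=vector" not in r.description]

    def test_exact_chloroplast_substring_removed(self, screens):
        chloro = next(r for r in screens if "chloroplast" in r.description)
        est = SequenceRecord(id="e1", residues=chloro.residues[500:800])
        outcome = screen_contaminants(est, screens)
        assert outcome.action == "removed"
        assert outcome.removal_reason == "chloroplast"

    def test_unrelated_est_kept(self, screens):
        rng = np.random.default_rng(3)
        est = SequenceRecord(id="e2", residues=rand_dna(rng, 300))
        assert screen_contaminants(est, screens).action == "kept"

    def test_half_contaminant_below_coverage_kept(self, screens):
        rng = np.random.default_rng(4)
        rrna = next(r for r in screens if "rRNA" in r.description)
        est = SequenceRecord(id="e3",
                             residues=rrna.residues[:150] + rand_dna(rng, 150))
        outcome = screen_contaminants(
            est, screens, CleanParams(screen_coverage_min=0.8))
        assert outcome.action == "kept"


class TestRunCleaning:
    def test_accounts_for_every_input(self, tiny_config, tiny_refs, tiny_sim):
        from estqc import simulate_ests

        genome, truth = tiny_sim
        import copy

        truth = copy.deepcopy(truth)
        ests, truth = simulate_ests(genome, truth, tiny_refs, tiny_config)
        vectors = [r for r in tiny_refs if "class=vector" in r.description]
        screens = [r for r in tiny_refs if "class=vector" not in r.description]
        clean, outcomes = run_cleaning(ests, vectors, screens)
        assert len(outcomes) == len(ests)
        removed = [o for o in outcomes if o.action == "removed"]
        assert len(clean) + len(removed) == len(ests)
        # trimming is terminal-only: every kept record is a substring
        by_id = {e.id: e for e in ests}
        for rec in clean:
            assert rec.residues in by_id[rec.id].residues
        # every removal agrees with the planted label
        for o in removed:
            label = truth.est_labels[o.est_id].label
            if o.removal_reason in ("rRNA", "bacterial", "chloroplast",
                                    "mitochondrial"):
                assert label == o.removal_reason

    def test_planted_contaminant_share_recovered(self):
        from estqc import (SimConfig, simulate_ests, simulate_genome,
                           simulate_references)
        from estqc.simulate import ContaminantMix

        cfg = SimConfig(n_chromosomes=2, chrom_length=100_000, n_genes=20,
                        est_count=1_000, est_error_rate=0.0, seed=9,
                        contaminant_mix=ContaminantMix(0, 0, 0, 0.2, 0))
        genome, truth = simulate_genome(cfg)
        refs = simulate_references(cfg)
        ests, truth = simulate_ests(genome, truth, refs, cfg)
        vectors = [r for r in refs if "class=vector" in r.description]
        screens = [r for r in refs if "class=vector" not in r.description]
        _, outcomes = run_cleaning(ests, vectors, screens)
        n_removed = sum(o.removal_reason == "chloroplast" for o in outcomes)
        sd = np.sqrt(1_000 * 0.2 * 0.8)
        assert abs(n_removed - 200) <= 3 * sd

    def test_empty_input(self, tiny_refs):
        vectors = [r for r in tiny_refs if "class=vector" in r.description]
        screens = [r for r in tiny_refs if "class=vector" not in r.description]
        clean, outcomes = run_cleaning([], vectors, screens)
        assert clean == [] and outcomes == []

    def test_all_genic_error_free_nothing_removed(self, clean_run, tiny_refs):
        _, _, _, _, ests, _ = clean_run
        vectors = [r for r in tiny_refs if "class=vector" in r.description]
        screens = [r for r in tiny_refs if "class=vector" not in r.description]
        clean, outcomes = run_cleaning(ests[:60], vectors, screens)
        assert len(clean) == 60
        assert all(o.action == "kept" for o in outcomes)


class TestCleaningOutcomeInvariants:
    def test_removed_iff_reason(self):
        with pytest.raises(ValueError):
            CleaningOutcome(est_id="x", action="removed")
        with pytest.raises(ValueError):
            CleaningOutcome(est_id="x", action="kept", removal_reason="rRNA")
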