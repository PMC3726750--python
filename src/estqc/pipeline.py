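"""End-to-end synthetic study: simulate -> clean -> map -> profile -> report.

This is the glue the CLI, the examples and the acceptance checks share: one
call generates a genome with planted truth, derives an imperfect assembly,
builds and cleans the EST library, maps the clean ESTs, profiles segments
and composition, and assembles the quality report.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from . import composition, prep, report
from .mapping import AlignParams, SplicedHit, map_all
from .prep import CleaningOutcome, CleanParams
from .report import QualityReport, SegmentProfile
from .seqio import AssemblySet, SequenceRecord, write_fasta
from .simulate import (SimConfig, SimTruth, derive_assembly, simulate_ests,
                       simulate_genome, simulate_references)


def synthetic_align_params(config: SimConfig, **overrides) -> AlignParams:
    """Alignment parameters scaled to a simulated genome.

    The intron-length search bound follows the simulated intron range (a few
    hundred bases) rather than the 100 kb plant-genome default, which keeps
    the candidate windows — and hence the DP — proportionate to the genome
    being analysed.  Seeding likewise demands more shared k-mers than the
    two-hit floor, since a true placement of a 150+ base EST shares
    hundreds; this suppresses windows arising from background k-mer
    collisions.  Scoring is unchanged.
    """
    max_intron = max(2_000, 5 * config.intron_length[1])
    kwargs = {"max_intron": max_intron, "min_seed_hits": 8}
    kwargs.update(overrides)
    return AlignParams(**kwargs)


@dataclass
class PipelineResult:
    """Everything one synthetic run produced, truth included."""

    config: SimConfig
    genome: AssemblySet
    truth: SimTruth
    assembly: AssemblySet
    references: list[SequenceRecord]
    ests: list[SequenceRecord]
    clean_ests: list[SequenceRecord]
    cleaning_outcomes: list[CleaningOutcome]
    hits: list[SplicedHit]
    matched_count: int
    selected_count: int
    segment_profiles: list[SegmentProfile]
    pct_segments_matched: float
    quality: QualityReport
    align_params: AlignParams = field(default_factory=AlignParams)


def run_synthetic(
    config: SimConfig | None = None,
    align_params: AlignParams | None = None,
    clean_params: CleanParams | None = None,
    assembly_kind: str = "chromosome",
    out_dir: str | None = None,
) -> PipelineResult:
    """Run the whole study on one synthetic genome; optionally write all
    artifacts (FASTA, truth ledger, hit tables, report) under ``out_dir``."""
    config = config or SimConfig()
    p = align_params or synthetic_align_params(config)
    cp = clean_params or CleanParams()

    genome, truth = simulate_genome(config)
    assembly = derive_assembly(genome, truth, config, kind=assembly_kind)
    refs = simulate_references(config)
    ests, truth = simulate_ests(genome, truth, refs, config)

    vectors = [r for r in refs if "class=vector" in r.description]
    screens = [r for r in refs if "class=vector" not in r.description]
    clean_ests, outcomes = prep.run_cleaning(ests, vectors, screens, cp)

    selected = prep.second_round_sample(
        [e.id for e in clean_ests], len(ests), seed=config.seed)
    selected_set = set(selected)
    mapped_input = [e for e in clean_ests if e.id in selected_set]

    hits, matched, selected_count = map_all(mapped_input, assembly, p)
    profiles, pct_matched = report.segment_match_profile(hits, assembly)

    gc_values = []
    for rec in assembly.records:
        _, overall = composition.gc_profile(rec)
        gc_values.append((rec.length, overall))
    total = sum(n for n, _ in gc_values)
    gc_avg_pct = round(100 * sum(n * g for n, g in gc_values) / total, 2)

    quality = report.summarize(
        assembly,
        matched_count=matched,
        selected_count=selected_count,
        pct_segments_matched=pct_matched if assembly.kind == "chromosome" else None,
        gc_avg_pct=gc_avg_pct,
    )
    result = PipelineResult(
        config=config, genome=genome, truth=truth, assembly=assembly,
        references=refs, ests=ests, clean_ests=clean_ests,
        cleaning_outcomes=outcomes, hits=hits, matched_count=matched,
        selected_count=selected_count, segment_profiles=profiles,
        pct_segments_matched=pct_matched, quality=quality, align_params=p,
    )
    if out_dir is not None:
        _write_artifacts(result, out_dir)
    return result


def _write_artifacts(res: PipelineResult, out_dir: str) -> None:
    from .mapping import write_bed12, write_hits_tsv
    from .prep import write_outcomes_tsv
    from .report import write_segment_tsv

    os.makedirs(out_dir, exist_ok=True)
    write_fasta(res.genome.records, f"{out_dir}/genome.fasta")
    write_fasta(res.assembly.records, f"{out_dir}/assembly.fasta")
    write_fasta(res.references, f"{out_dir}/references.fasta")
    write_fasta(res.ests, f"{out_dir}/ests.fasta")
    write_fasta(res.clean_ests, f"{out_dir}/clean_ests.fasta")
    res.truth.write_tsv(f"{out_dir}/truth")
    write_outcomes_tsv(res.cleaning_outcomes, f"{out_dir}/cleaning.tsv")
    write_bed12(res.hits, f"{out_dir}/hits.bed",
                {e.id: e.length for e in res.ests})
    write_hits_tsv(res.hits, f"{out_dir}/hits.tsv")
    write_segment_tsv(res.segment_profiles, f"{out_dir}/segments.tsv")
    res.quality.write_json(f"{out_dir}/quality.json")
    res.config.to_yaml(f"{out_dir}/config.yaml")
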