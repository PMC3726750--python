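"""Synthetic genomes, derived assemblies with planted defects, and EST
libraries with contamination — plus a full truth ledger.

The generator emulates the data regime the evaluation pipeline is built for:
multi-chromosome plant genomes whose spliced genes concentrate toward the
chromosome ends, three repeat classes (interspersed families, low-complexity
tracts, simple tandem arrays), regional GC variation with N-gap runs,
assemblies that have lost a fraction of the genome (or been fragmented into
scaffolds), and EST sets carrying sequencing error, vector/adaptor flanks
and organelle/rRNA/bacterial contaminants.

Everything is deterministic under a single root seed: each sub-generator
derives its own stream by a stable name, so adding one stage never perturbs
another stage's draws.

Design notes
------------
* Error model is per-base substitution only by default (an optional indel
  rate exists for aligner stress tests); this keeps the expected identity of
  a genic EST analytic (``1 - est_error_rate``).
* Repeats and N-gap runs are planted in intergenic sequence only, so the
  planted genic ESTs remain exact spliced substrings of the genome and the
  truth ledger stays analytic.  Transcribed repeats are out of scope.
* Gene midpoints are drawn from a mixture of two edge-concentrated
  triangular distributions and a uniform component, reproducing the
  empirical pattern that EST matches pile up at chromosome ends.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .seqio import AssemblySet, SequenceRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimulationError(RuntimeError):
    """Raised when a configuration cannot be realised (e.g. packing)."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RepeatConfig:
    """Planted-repeat layout: one knob set per repeat class."""

    interspersed_families: int = 3
    interspersed_unit_length: int = 500
    interspersed_copies: int = 20
    low_complexity_per_chrom: int = 4
    low_complexity_length: tuple[int, int] = (300, 800)
    low_complexity_bias: float = 0.9
    simple_per_chrom: int = 6
    simple_unit_range: tuple[int, int] = (1, 6)
    simple_copies: tuple[int, int] = (10, 40)


@dataclass
class ContaminantMix:
    """Fractions of the EST set drawn from each non-clean source."""

    vector_flanked: float = 0.05
    rrna: float = 0.02
    bacterial: float = 0.02
    chloroplast: float = 0.03
    mitochondrial: float = 0.02

    def total(self) -> float:
        return (self.vector_flanked + self.rrna + self.bacterial
                + self.chloroplast + self.mitochondrial)


@dataclass
class SimConfig:
    """All tunables of the synthetic study, with desk-scale defaults.

    Defaults describe a 5-chromosome, 2 Mb genome with 200 spliced genes
    biased toward chromosome ends, 2,000 ESTs at 1% substitution error and a
    modest contaminant load, and an assembly that has lost 20% of the genome
    — a regime in which integrity, accuracy and segment coverage all move
    away from 100% by known amounts.
    """

    n_chromosomes: int = 5
    chrom_length: int = 400_000
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (30, 300)
    gene_end_bias: float = 0.8
    gc_levels: tuple[float, ...] = (0.30, 0.38, 0.45)
    gc_region_length: int = 50_000
    n_gap_fraction: float = 0.02
    n_gap_mean_length: int = 5_000
    repeat_config: RepeatConfig = field(default_factory=RepeatConfig)
    drop_fraction: float = 0.20
    drop_segment_length: tuple[int, int] = (10_000, 30_000)
    fragmentation: int = 50_000
    unplaced_fraction: float = 0.05
    est_count: int = 2_000
    est_length: tuple[int, int] = (150, 500)
    est_error_rate: float = 0.01
    est_indel_rate: float = 0.0
    contaminant_mix: ContaminantMix = field(default_factory=ContaminantMix)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gene_end_bias", "n_gap_fraction", "drop_fraction",
                     "est_error_rate", "est_indel_rate", "unplaced_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.drop_fraction >= 1.0:
            raise ValueError("drop_fraction must be < 1")
        if self.contaminant_mix.total() > 1.0:
            raise ValueError("contaminant fractions must sum to <= 1")
        for name in ("exons_per_gene", "exon_length", "intron_length",
                     "est_length", "drop_segment_length"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range has min > max")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_asdict_plain(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        kwargs = dict(raw)
        if "repeat_config" in kwargs and isinstance(kwargs["repeat_config"], dict):
            kwargs["repeat_config"] = RepeatConfig(**_retuple(kwargs["repeat_config"]))
        if "contaminant_mix" in kwargs and isinstance(kwargs["contaminant_mix"], dict):
            kwargs["contaminant_mix"] = ContaminantMix(**kwargs["contaminant_mix"])
        return cls(**_retuple(kwargs))


def _asdict_plain(obj):
    d = dataclasses.asdict(obj)

    def conv(v):
        if isinstance(v, tuple):
            return list(v)
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        return v

    return {k: conv(v) for k, v in d.items()}


def _retuple(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


# ---------------------------------------------------------------------------
# truth ledger


@dataclass
class GenePlacement:
    gene_id: str
    chrom: str
    strand: str                      # '+' or '-'
    exons: list[tuple[int, int]]     # ascending, 0-based half-open, genome coords

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class ESTLabel:
    est_id: str
    label: str                       # genic / vector_flanked_genic / rRNA / ...
    gene_id: str | None = None
    source_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    flank_prefix: int = 0
    flank_suffix: int = 0


@dataclass
class SimTruth:
    """Planted facts for parameter-recovery tests: gene placements,
    repeat intervals by class, N-gap runs, dropped regions (original genome
    coordinates) and per-EST labels."""

    gene_placements: list[GenePlacement] = field(default_factory=list)
    repeat_intervals: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    gc_regions: list[tuple[str, int, int, float]] = field(default_factory=list)
    n_gap_regions: list[tuple[str, int, int]] = field(default_factory=list)
    dropped_regions: list[tuple[str, int, int]] = field(default_factory=list)
    est_labels: dict[str, ESTLabel] = field(default_factory=dict)

    def genes_by_id(self) -> dict[str, GenePlacement]:
        return {g.gene_id: g for g in self.gene_placements}

    def write_tsv(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        pd.DataFrame(
            [(g.gene_id, g.chrom, g.strand,
              ",".join(f"{s}-{e}" for s, e in g.exons))
             for g in self.gene_placements],
            columns=["gene_id", "chrom", "strand", "exons"],
        ).to_csv(f"{directory}/genes.tsv", sep="\t", index=False)
        pd.DataFrame(
            self.repeat_intervals,
            columns=["chrom", "start", "end", "class", "motif"],
        ).to_csv(f"{directory}/repeats.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(l.est_id, l.label, l.gene_id or "",
              ";".join(f"{c}:{s}-{e}" for c, s, e in l.source_intervals),
              l.flank_prefix, l.flank_suffix)
             for l in self.est_labels.values()],
            columns=["est_id", "label", "gene_id", "source",
                     "flank_prefix", "flank_suffix"],
        ).to_csv(f"{directory}/est_labels.tsv", sep="\t", index=False)
        pd.DataFrame(
            self.dropped_regions, columns=["chrom", "start", "end"]
        ).to_csv(f"{directory}/dropped_regions.tsv", sep="\t", index=False)
        with open(f"{directory}/summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def summary(self) -> dict:
        labels = pd.Series([l.label for l in self.est_labels.values()])
        return {
            "n_genes": len(self.gene_placements),
            "n_repeat_intervals": len(self.repeat_intervals),
            "n_dropped_regions": len(self.dropped_regions),
            "dropped_bases": int(sum(e - s for _, s, e in self.dropped_regions)),
            "est_label_counts": labels.value_counts().to_dict() if len(labels) else {},
        }


# ---------------------------------------------------------------------------
# RNG plumbing


def stream(seed: int, name: str) -> np.random.Generator:
    """A named RNG stream derived from the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    out = _BASES[np.clip(codes, 0, 3)].copy()
    out[codes == 4] = b"N"
    return out.tobytes().decode()


class _Occupancy:
    """Sorted non-overlapping reserved intervals on one chromosome."""

    def __init__(self, length: int):
        self.length = length
        self.intervals: list[tuple[int, int]] = []

    def is_free(self, start: int, end: int) -> bool:
        if start < 0 or end > self.length:
            return False
        import bisect

        i = bisect.bisect_left(self.intervals, (start, start))
        if i > 0 and self.intervals[i - 1][1] > start:
            return False
        if i < len(self.intervals) and self.intervals[i][0] < end:
            return False
        return True

    def reserve(self, start: int, end: int) -> None:
        import bisect

        bisect.insort(self.intervals, (start, end))

    def try_place(self, rng, length: int, pad: int = 100,
                  lo: int | None = None, hi: int | None = None,
                  attempts: int = 200) -> int | None:
        lo = 0 if lo is None else lo
        hi = self.length if hi is None else hi
        if hi - lo < length + 2 * pad:
            return None
        for _ in range(attempts):
            start = int(rng.integers(lo + pad, hi - length - pad + 1))
            if self.is_free(start - pad, start + length + pad):
                self.reserve(start - pad, start + length + pad)
                return start
        return None


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimConfig) -> tuple[AssemblySet, SimTruth]:
    """Generate a chromosome-level genome with planted genes, repeats,
    GC regions and N-gap runs; returns the genome and its truth ledger."""
    truth = SimTruth()
    chrom_codes: dict[str, np.ndarray] = {}
    occ: dict[str, _Occupancy] = {}

    rng_bg = stream(config.seed, "background")
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        codes = np.empty(config.chrom_length, dtype=np.uint8)
        for start in range(0, config.chrom_length, config.gc_region_length):
            end = min(start + config.gc_region_length, config.chrom_length)
            gc = float(rng_bg.choice(config.gc_levels))
            codes[start:end] = _random_dna(rng_bg, end - start, gc)
            truth.gc_regions.append((chrom, start, end, gc))
        chrom_codes[chrom] = codes
        occ[chrom] = _Occupancy(config.chrom_length)

    _place_genes(config, chrom_codes, occ, truth)
    _place_repeats(config, chrom_codes, occ, truth)
    _place_n_gaps(config, chrom_codes, occ, truth)

    records = [
        SequenceRecord(id=chrom, residues=_codes_to_str(codes),
                       description="synthetic chromosome")
        for chrom, codes in chrom_codes.items()
    ]
    genome = AssemblySet(kind="chromosome", records=records,
                         genome_size=sum(len(r) for r in records))
    return genome, truth


def _gene_midpoint(rng, length: int, end_bias: float) -> int:
    if rng.random() < end_bias:
        if rng.random() < 0.5:
            return int(rng.triangular(0, 0, length / 4))
        return int(rng.triangular(3 * length / 4, length, length))
    return int(rng.integers(0, length))


def _place_genes(config, chrom_codes, occ, truth) -> None:
    rng = stream(config.seed, "genes")
    chroms = list(chrom_codes)
    for g in range(config.n_genes):
        gene_id = f"gene_{g + 1:04d}"
        chrom = chroms[int(rng.integers(len(chroms)))]
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1,
                               size=n_ex)
        in_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1,
                               size=max(0, n_ex - 1))
        span = int(ex_lens.sum() + in_lens.sum())
        placed = None
        for _ in range(300):
            mid = _gene_midpoint(rng, config.chrom_length, config.gene_end_bias)
            start = min(max(0, mid - span // 2), config.chrom_length - span)
            if start < 0:
                continue
            if occ[chrom].is_free(start - 100, start + span + 100):
                occ[chrom].reserve(start - 100, start + span + 100)
                placed = start
                break
        if placed is None:
            raise SimulationError(
                f"could not place {gene_id}: requested genes exceed capacity"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        exons: list[tuple[int, int]] = []
        pos = placed
        codes = chrom_codes[chrom]
        for i, el in enumerate(ex_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < len(in_lens):
                ilen = int(in_lens[i])
                s, e = pos, pos + ilen
                # canonical splice dinucleotides on the transcribed strand
                if strand == "+":
                    codes[s], codes[s + 1] = 2, 3          # G T
                    codes[e - 2], codes[e - 1] = 0, 2      # A G
                else:
                    codes[s], codes[s + 1] = 1, 3          # C T  (rc of AG)
                    codes[e - 2], codes[e - 1] = 0, 1      # A C  (rc of GT)
                pos = e
        truth.gene_placements.append(
            GenePlacement(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons)
        )


def _place_repeats(config, chrom_codes, occ, truth) -> None:
    rng = stream(config.seed, "repeats")
    rc = config.repeat_config
    chroms = list(chrom_codes)

    for f in range(rc.interspersed_families):
        unit = _random_dna(rng, rc.interspersed_unit_length, gc=0.45)
        for _ in range(rc.interspersed_copies):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = occ[chrom].try_place(rng, len(unit))
            if start is None:
                raise SimulationError("could not place interspersed repeat copy")
            chrom_codes[chrom][start:start + len(unit)] = unit
            truth.repeat_intervals.append(
                (chrom, start, start + len(unit), "interspersed", f"family_{f + 1}")
            )

    for chrom in chroms:
        for _ in range(rc.low_complexity_per_chrom):
            length = int(rng.integers(rc.low_complexity_length[0],
                                      rc.low_complexity_length[1] + 1))
            start = occ[chrom].try_place(rng, length)
            if start is None:
                raise SimulationError("could not place low-complexity tract")
            major = int(rng.integers(4))
            p = np.full(4, (1 - rc.low_complexity_bias) / 3)
            p[major] = rc.low_complexity_bias
            chrom_codes[chrom][start:start + length] = rng.choice(
                4, size=length, p=p
            ).astype(np.uint8)
            truth.repeat_intervals.append(
                (chrom, start, start + length, "low_complexity", "ACGT"[major])
            )

    for chrom in chroms:
        for _ in range(rc.simple_per_chrom):
            u = int(rng.integers(rc.simple_unit_range[0], rc.simple_unit_range[1] + 1))
            motif = _primitive_motif(rng, u)
            copies = int(rng.integers(rc.simple_copies[0], rc.simple_copies[1] + 1))
            copies = max(copies, -(-24 // u))  # arrays at least 24 bases long
            length = u * copies
            start = occ[chrom].try_place(rng, length)
            if start is None:
                raise SimulationError("could not place simple repeat array")
            chrom_codes[chrom][start:start + length] = np.tile(motif, copies)
            truth.repeat_intervals.append(
                (chrom, start, start + length, "simple", _codes_to_str(motif))
            )


def _primitive_motif(rng, u: int) -> np.ndarray:
    while True:
        motif = rng.integers(0, 4, size=u).astype(np.uint8)
        s = motif.tobytes()
        if all(s != s[p:] + s[:p] for p in range(1, u)):
            return motif


def _place_n_gaps(config, chrom_codes, occ, truth) -> None:
    if config.n_gap_fraction <= 0:
        return
    rng = stream(config.seed, "ngaps")
    for chrom, codes in chrom_codes.items():
        target = int(config.n_gap_fraction * len(codes))
        total = 0
        while total < target:
            length = int(np.clip(rng.exponential(config.n_gap_mean_length),
                                 500, 4 * config.n_gap_mean_length))
            length = min(length, target - total) if target - total >= 500 else length
            start = occ[chrom].try_place(rng, length)
            if start is None:
                break
            codes[start:start + length] = 4
            truth.n_gap_regions.append((chrom, start, start + length))
            total += length


# ---------------------------------------------------------------------------
# derived assemblies


def derive_assembly(
    genome: AssemblySet,
    truth: SimTruth,
    config: SimConfig,
    kind: str = "chromosome",
) -> AssemblySet:
    """Derive an imperfect assembly from the simulated genome.

    ``chromosome`` kind removes ``drop_fraction`` of each chromosome as a few
    large deleted blocks (recorded in ``truth.dropped_regions`` in original
    coordinates).  ``scaffold`` kind additionally fragments each chromosome
    into scaffolds around the mean ``fragmentation`` length, renaming an
    ``unplaced_fraction`` share as unknown_random pieces.  ``genome_size`` is
    the original genome total, so the integrity ratio is computable.
    """
    if config.drop_fraction >= 1.0:
        raise ValueError("drop_fraction must be < 1")
    rng = stream(config.seed, "assembly")
    out_records: list[SequenceRecord] = []
    for rec in genome.records:
        n = rec.length
        target = round(config.drop_fraction * n)
        drops: list[tuple[int, int]] = []
        occ = _Occupancy(n)
        total = 0
        while total < target:
            lo, hi = config.drop_segment_length
            length = int(rng.integers(lo, hi + 1))
            length = min(length, target - total)
            start = occ.try_place(rng, length, pad=0)
            if start is None:
                break
            drops.append((start, start + length))
            total += length
        drops.sort()
        truth.dropped_regions.extend((rec.id, s, e) for s, e in drops)
        kept: list[str] = []
        pos = 0
        for s, e in drops:
            kept.append(rec.residues[pos:s])
            pos = e
        kept.append(rec.residues[pos:])
        out_records.append(
            SequenceRecord(id=rec.id, residues="".join(kept),
                           description=rec.description)
        )

    if kind == "scaffold":
        scaffolds: list[SequenceRecord] = []
        for rec in out_records:
            pos = 0
            i = 0
            while pos < rec.length:
                length = max(5_000, int(rng.exponential(config.fragmentation)))
                piece = rec.residues[pos:pos + length]
                i += 1
                scaffolds.append(
                    SequenceRecord(id=f"{rec.id}_scaf{i}", residues=piece,
                                   description=f"scaffold of {rec.id}")
                )
                pos += length
        n_unplaced = int(config.unplaced_fraction * len(scaffolds))
        if n_unplaced:
            idx = rng.choice(len(scaffolds), size=n_unplaced, replace=False)
            for j, k in enumerate(sorted(int(x) for x in idx)):
                old = scaffolds[k]
                scaffolds[k] = SequenceRecord(
                    id=f"scaffold_unknown_random_{j + 1}",
                    residues=old.residues,
                    description="unplaced scaffold",
                )
        out_records = scaffolds
    elif kind != "chromosome":
        raise ValueError(f"unknown assembly kind {kind!r}")

    return AssemblySet(kind=kind, records=out_records,
                       genome_size=sum(r.length for r in genome.records))


# ---------------------------------------------------------------------------
# references and ESTs


_REFERENCE_PLAN = (
    ("vector_1", "vector", 800),
    ("vector_2", "vector", 1_500),
    ("vector_3", "vector", 2_500),
    ("rRNA_ref", "rRNA", 1_500),
    ("bacterial_ref", "bacterial", 20_000),
    ("chloroplast_ref", "chloroplast", 20_000),
    ("mitochondrial_ref", "mitochondrial", 15_000),
)


def simulate_references(config: SimConfig) -> list[SequenceRecord]:
    """Synthetic contaminant references: a vector/adaptor library plus one
    reference per screening class, labelled ``class=<name>`` in the
    description.  Deterministic given the root seed."""
    rng = stream(config.seed, "references")
    return [
        SequenceRecord(
            id=name,
            residues=_codes_to_str(_random_dna(rng, length, gc=0.5)),
            description=f"class={cls} synthetic reference",
        )
        for name, cls, length in _REFERENCE_PLAN
    ]


def _transcript(genome: AssemblySet, gene: GenePlacement) -> str:
    chrom = genome.get(gene.chrom).residues
    spliced = "".join(chrom[s:e] for s, e in gene.exons)
    return spliced if gene.strand == "+" else reverse_complement(spliced)


def _source_intervals(gene: GenePlacement, start: int, length: int
                      ) -> list[tuple[str, int, int]]:
    """Genome-forward intervals covered by transcript slice [start, start+length)."""
    tlen = gene.transcript_length
    if gene.strand == "-":
        start = tlen - (start + length)
    intervals: list[tuple[str, int, int]] = []
    offset = 0
    for s, e in gene.exons:
        ex_len = e - s
        lo = max(start, offset)
        hi = min(start + length, offset + ex_len)
        if lo < hi:
            intervals.append((gene.chrom, s + (lo - offset), s + (hi - offset)))
        offset += ex_len
    return intervals


def _mutate(rng, seq: str, sub_rate: float, indel_rate: float) -> str:
    if sub_rate <= 0 and indel_rate <= 0:
        return seq
    out = []
    bases = "ACGT"
    for ch in seq:
        if indel_rate > 0 and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue                      # deletion
            out.append(bases[int(rng.integers(4))])  # insertion, keep base
        if sub_rate > 0 and rng.random() < sub_rate and ch in bases:
            choices = bases.replace(ch, "")
            out.append(choices[int(rng.integers(3))])
        else:
            out.append(ch)
    return "".join(out) or seq[:1]


def simulate_ests(
    genome: AssemblySet,
    truth: SimTruth,
    refs: Sequence[SequenceRecord],
    config: SimConfig,
) -> tuple[list[SequenceRecord], SimTruth]:
    """Generate the EST library and record per-EST labels in the truth.

    Genic ESTs are contiguous slices of a gene's spliced transcript read
    5'->3' on the gene strand, with substitution noise at
    ``est_error_rate``.  Vector-flanked ESTs carry a vector prefix (and
    sometimes suffix) of recorded length.  Contaminant ESTs are substrings of
    the matching class reference.
    """
    rng = stream(config.seed, "ests")
    mix = config.contaminant_mix
    classes = ["genic", "vector_flanked_genic", "rRNA", "bacterial",
               "chloroplast", "mitochondrial"]
    probs = np.array([1.0 - mix.total(), mix.vector_flanked, mix.rrna,
                      mix.bacterial, mix.chloroplast, mix.mitochondrial])
    by_class = {r.description.split()[0].split("=")[1]: r for r in refs
                if "class=" in r.description and "vector" not in r.description}
    vectors = [r for r in refs if "class=vector" in r.description]
    genes = truth.gene_placements
    if not genes:
        raise SimulationError("no genes available for EST generation")
    transcripts = {g.gene_id: _transcript(genome, g) for g in genes}
    lo, hi = config.est_length
    if all(len(t) < lo for t in transcripts.values()):
        raise SimulationError("est_length exceeds available exonic span "
                              "for all genes")

    ests: list[SequenceRecord] = []
    labels = rng.choice(len(classes), size=config.est_count, p=probs)
    for i in range(config.est_count):
        est_id = f"est_{i + 1:05d}"
        cls = classes[int(labels[i])]
        length = int(rng.integers(lo, hi + 1))
        if cls in ("genic", "vector_flanked_genic"):
            gene = genes[int(rng.integers(len(genes)))]
            t = transcripts[gene.gene_id]
            eff = min(length, len(t))
            start = int(rng.integers(0, len(t) - eff + 1))
            core = _mutate(rng, t[start:start + eff],
                           config.est_error_rate, config.est_indel_rate)
            source = _source_intervals(gene, start, eff)
            if cls == "vector_flanked_genic":
                vec = vectors[int(rng.integers(len(vectors)))]
                plen = int(rng.integers(25, 61))
                vstart = int(rng.integers(0, len(vec.residues) - plen + 1))
                prefix = vec.residues[vstart:vstart + plen]
                slen = 0
                suffix = ""
                if rng.random() < 0.5:
                    slen = int(rng.integers(25, 61))
                    vstart = int(rng.integers(0, len(vec.residues) - slen + 1))
                    suffix = vec.residues[vstart:vstart + slen]
                residues = prefix + core + suffix
                truth.est_labels[est_id] = ESTLabel(
                    est_id, cls, gene.gene_id, source, plen, slen)
            else:
                residues = core
                truth.est_labels[est_id] = ESTLabel(est_id, cls, gene.gene_id, source)
        else:
            ref = by_class[cls]
            eff = min(length, len(ref.residues))
            start = int(rng.integers(0, len(ref.residues) - eff + 1))
            residues = _mutate(rng, ref.residues[start:start + eff],
                               config.est_error_rate, config.est_indel_rate)
            truth.est_labels[est_id] = ESTLabel(
                est_id, cls, source_intervals=[(ref.id, start, start + eff)])
        ests.append(SequenceRecord(id=est_id, residues=residues,
                                   description=f"synthetic {cls} EST"))
    return ests, truth


# ---------------------------------------------------------------------------
# truth-based predictions


def surviving_fraction(label: ESTLabel, dropped: dict[str, list[tuple[int, int]]]
                       ) -> float:
    """Fraction of an EST's source bases not covered by dropped regions."""
    total = sum(e - s for _, s, e in label.source_intervals)
    if total == 0:
        return 0.0
    lost = 0
    for chrom, s, e in label.source_intervals:
        for ds, de in dropped.get(chrom, ()):
            lost += max(0, min(e, de) - max(s, ds))
    return (total - lost) / total


def matchable_fraction(
    truth: SimTruth,
    coverage_min: float = 0.50,
    est_ids: Sequence[str] | None = None,
) -> float:
    """Predicted matched fraction of genic ESTs: those whose surviving
    contiguous source span still covers at least ``coverage_min`` of the EST.

    Valid for substitution-free ESTs on an assembly whose dropped blocks are
    wider than any gene (each affected EST then keeps a single contiguous
    flank, which aligns with identity 1).
    """
    dropped: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in truth.dropped_regions:
        dropped.setdefault(chrom, []).append((s, e))
    ids = est_ids if est_ids is not None else [
        e for e, l in truth.est_labels.items() if l.label == "genic"
    ]
    if not ids:
        raise ValueError("no genic ESTs to predict for")
    ok = sum(
        surviving_fraction(truth.est_labels[e], dropped) >= coverage_min
        for e in ids
    )
    return ok / len(ids)
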