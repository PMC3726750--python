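"""Sequence records, FASTA I/O and base sequence utilities.

All coordinates in this package are 0-based half-open; 1-based inclusive
coordinates appear only in human-readable report text.  DNA is normalised at
read time to the five-letter alphabet {A, C, G, T, N}: lowercase is
uppercased, U becomes T, and every other IUPAC ambiguity code collapses to N
(none of the downstream metrics distinguish them).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ALPHABET = frozenset("ACGTN")

_NORMALISE = str.maketrans(
    {c: ("T" if c in "Uu" else c.upper() if c.upper() in "ACGTN" else "N")
     for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqIOError(ValueError):
    """Malformed sequence input (empty file, duplicate ids, empty record)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence: an assembly unit, an EST, or a contaminant reference.

    Parameters
    ----------
    id : str
        Unique identifier (first whitespace-delimited token of the header).
    residues : str
        Uppercase DNA over {A, C, G, T, N}; at least one base.
    description : str
        Free text after the id on the FASTA header line.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record requires a non-empty id")
        if not self.residues:
            raise SeqIOError(f"record {self.id!r} has zero residues")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise SeqIOError(
                f"record {self.id!r} contains symbols outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class AssemblySet:
    """A genome assembly: chromosome-level or scaffold-level records.

    ``genome_size`` is the externally estimated genome size in bases (flow
    cytometry / k-mer estimate); it is not derivable from the records and may
    be absent, in which case the integrity ratio is unavailable.
    """

    kind: Literal["chromosome", "scaffold"]
    records: list[SequenceRecord] = field(default_factory=list)
    genome_size: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("chromosome", "scaffold"):
            raise ValueError(f"unknown assembly kind {self.kind!r}")
        if self.genome_size is not None and self.genome_size <= 0:
            raise ValueError("genome_size must be positive when present")
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise SeqIOError("duplicate record ids in assembly")

    @property
    def assembled_size(self) -> int:
        return sum(r.length for r in self.records)

    @property
    def ratio_name(self) -> str:
        """CS/GS for chromosome assemblies, SS/GS for scaffold assemblies."""
        return "CS/GS" if self.kind == "chromosome" else "SS/GS"

    def get(self, record_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)


def normalize_residues(seq: str) -> str:
    """Uppercase, U->T, and collapse non-ACGT symbols to N."""
    return seq.translate(_NORMALISE)


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into normalised :class:`SequenceRecord` objects.

    Raises :class:`SeqIOError` on an empty file, duplicate ids, or a record
    with zero residues.  Record order follows file order.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = normalize_residues(str(rec.seq))
        if not residues:
            raise SeqIOError(f"record {rec.id!r} in {path} has zero residues")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if not records:
        raise SeqIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Sequence[SequenceRecord], path: str | os.PathLike, line_width: int = 60
) -> None:
    """Write records as wrapped FASTA; round-trips ids and residues exactly."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(bio)


def gc_fraction(seq: str, mode: str = "n_inclusive") -> float:
    """G+C fraction of ``seq``.

    ``n_inclusive`` (default) divides by the total length including N, so
    N-rich assembled sequence dilutes the value — this is the convention the
    whole-chromosome averages in reports use.  ``n_exclusive`` divides by the
    A+C+G+T count and is undefined on an all-N sequence.
    """
    if not seq:
        raise ValueError("gc_fraction of empty sequence is undefined")
    gc = seq.count("G") + seq.count("C")
    if mode == "n_inclusive":
        return gc / len(seq)
    if mode == "n_exclusive":
        acgt = gc + seq.count("A") + seq.count("T")
        if acgt == 0:
            raise ValueError("n_exclusive GC undefined on all-N sequence")
        return gc / acgt
    raise ValueError(f"unknown GC mode {mode!r}")


def window_iter(record: SequenceRecord, width: int) -> Iterator[tuple[int, int, int]]:
    """Tile ``[0, len(record))`` into segments of ``width`` bases.

    Yields ``(segment_index, start, end)`` with 0-based half-open
    coordinates; the final partial segment is its own segment.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    n = record.length
    for idx, start in enumerate(range(0, n, width)):
        yield idx, start, min(start + width, n)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}; an involution, N -> N."""
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"cannot complement symbols {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def write_bed3(
    segments: Sequence[tuple[str, int, int]], path: str | os.PathLike
) -> None:
    """Write (chrom, start, end) triples as BED3."""
    with open(path, "w") as fh:
        for chrom, start, end in segments:
            fh.write(f"{chrom}\t{start}\t{end}\n")
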