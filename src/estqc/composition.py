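"""GC content and repeat-landscape profiling at 0.1 Mb resolution.

Three self-contained detectors cover the three repeat classes reported in
assembly-quality summaries: dispersed multi-copy families (a library-free
k-mer-frequency detector), compositionally biased tracts (a DUST-style
windowed-entropy detector), and short-motif tandem arrays (an exact
microsatellite scan over unit lengths 1-6).  N runs are assembly artifacts,
never repeats: all three detectors skip them.

A boundary-spanning repeat interval contributes to *both* segments it
overlaps: its count increments each, and its length splits by overlap, so
summed per-segment lengths conserve the total masked length.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2

import numpy as np

from .seqio import AssemblySet, SequenceRecord, gc_fraction, window_iter
from .mapping import encode, _kmer_codes

SEGMENT_WIDTH = 100_000


@dataclass(frozen=True)
class RepeatInterval:
    """One detected repeat: 0-based half-open on the named target."""

    target_id: str
    start: int
    end: int
    klass: str                 # interspersed | low_complexity | simple
    motif: str | None = None   # unit string for simple repeats

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("repeat interval must have end > start")
        if self.klass not in ("interspersed", "low_complexity", "simple"):
            raise ValueError(f"unknown repeat class {self.klass!r}")
        if self.klass == "simple" and self.motif is not None:
            if not 1 <= len(self.motif) <= 6:
                raise ValueError("simple-repeat motif length must be 1..6")

    @property
    def length(self) -> int:
        return self.end - self.start


def _is_primitive(motif: str) -> bool:
    return all(motif != motif[p:] + motif[:p] for p in range(1, len(motif)))


def canonical_rotation(motif: str) -> str:
    return min(motif[p:] + motif[:p] for p in range(len(motif)))


def find_simple_repeats(
    record: SequenceRecord,
    min_unit: int = 1,
    max_unit: int = 6,
    min_length: int = 20,
    min_copies: int = 4,
) -> list[RepeatInterval]:
    """Maximal tandem arrays of primitive units of length 1-6.

    An array qualifies when it holds at least ``min_copies`` full copies and
    spans at least ``min_length`` bases.  Non-primitive motifs (e.g. "AA")
    are reported through their primitive unit; overlapping reports of
    rotated motifs collapse to one interval whose motif is the
    lexicographically smallest rotation.  Positions involving N never match.
    """
    seq = record.residues
    arr = encode(seq)
    n = arr.shape[0]
    found: list[tuple[int, int, str]] = []
    for u in range(min_unit, min(max_unit, n - 1) + 1):
        eq = (arr[u:] == arr[:-u]) & (arr[u:] != 4)
        if not eq.any():
            continue
        padded = np.concatenate([[False], eq, [False]])
        d = np.diff(padded.astype(np.int8))
        run_starts = np.nonzero(d == 1)[0]
        run_ends = np.nonzero(d == -1)[0]
        for rs, re in zip(run_starts, run_ends):
            total = (re - rs) + u          # array spans [rs, re + u)
            if total < min_length or total // u < min_copies:
                continue
            motif = seq[rs:rs + u]
            if not _is_primitive(motif):
                continue
            found.append((rs, rs + total, canonical_rotation(motif)))
    found.sort()
    merged: list[tuple[int, int, str]] = []
    for s, e, motif in found:
        if merged and merged[-1][2] == motif and s <= merged[-1][1]:
            prev = merged.pop()
            merged.append((prev[0], max(prev[1], e), motif))
        else:
            merged.append((s, e, motif))
    return [RepeatInterval(record.id, s, e, "simple", motif)
            for s, e, motif in merged]


def shannon_entropy(counts: np.ndarray) -> float:
    """Base-composition Shannon entropy in bits from ACGT counts."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def find_low_complexity(
    record: SequenceRecord,
    window: int = 64,
    entropy_max: float = 1.0,
    step: int | None = None,
) -> list[RepeatInterval]:
    """Windows whose ACGT-composition entropy is at most ``entropy_max``
    bits, merged where they overlap or touch.  Windows more than half N are
    skipped (gaps are not low-complexity sequence)."""
    if window < 8:
        raise ValueError("window must be >= 8")
    step = step or max(1, window // 4)
    arr = encode(record.residues)
    n = arr.shape[0]
    if n < window:
        return []
    onehot = np.zeros((5, n + 1), dtype=np.int64)
    for b in range(5):
        np.cumsum(arr == b, out=onehot[b, 1:])
    starts = np.arange(0, n - window + 1, step)
    counts = onehot[:4, starts + window] - onehot[:4, starts]   # (4, nwin)
    n_count = (onehot[4, starts + window] - onehot[4, starts])
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / np.where(totals == 0, 1, totals)
        ent = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1)), 0.0).sum(axis=0)
    flagged = (ent <= entropy_max) & (n_count <= window // 2) & (totals > 0)
    out: list[RepeatInterval] = []
    cur: list[int] | None = None
    for s, flag in zip(starts, flagged):
        if not flag:
            continue
        if cur is not None and s <= cur[1]:
            cur[1] = s + window
        else:
            if cur is not None:
                out.append(RepeatInterval(record.id, cur[0], cur[1],
                                          "low_complexity"))
            cur = [int(s), int(s) + window]
    if cur is not None:
        out.append(RepeatInterval(record.id, cur[0], cur[1], "low_complexity"))
    return out


def find_interspersed(
    assembly: AssemblySet,
    k: int = 13,
    copy_min: int = 10,
    merge_gap: int = 50,
) -> list[RepeatInterval]:
    """Positions covered by k-mers seen >= ``copy_min`` times genome-wide.

    Counting is strand-aware (canonical k-mers), runs closer than
    ``merge_gap`` merge, and intervals shorter than k are dropped.  This is a
    library-free stand-in for curated-library repeat masking: it reports
    where dispersed multi-copy families sit, not their taxonomy.
    """
    if not 11 <= k <= 17:
        raise ValueError("k must lie in [11, 17]")
    per_record: list[tuple[str, np.ndarray, np.ndarray]] = []
    all_codes = []
    for rec in assembly.records:
        arr = encode(rec.residues)
        if arr.shape[0] < k:
            per_record.append((rec.id, np.empty(0, np.uint64), np.empty(0, bool)))
            continue
        codes, valid = _kmer_codes(arr, k)
        canon = np.minimum(codes, _revcomp_codes(codes, k))
        per_record.append((rec.id, canon, valid))
        all_codes.append(canon[valid])
    if not all_codes:
        return []
    uniq, counts = np.unique(np.concatenate(all_codes), return_counts=True)
    frequent = uniq[counts >= copy_min]
    out: list[RepeatInterval] = []
    for rec_id, canon, valid in per_record:
        if canon.size == 0:
            continue
        hot = valid & np.isin(canon, frequent)
        if not hot.any():
            continue
        n = canon.shape[0] + k - 1
        cover = np.zeros(n + 1, dtype=np.int32)
        idx = np.nonzero(hot)[0]
        np.add.at(cover, idx, 1)
        np.add.at(cover, idx + k, -1)
        mask = np.cumsum(cover[:-1]) > 0
        runs: list[list[int]] = []
        for s, e in _mask_runs(mask):
            if runs and s - runs[-1][1] < merge_gap:
                runs[-1][1] = int(e)
            else:
                runs.append([int(s), int(e)])
        out.extend(RepeatInterval(rec_id, s, e, "interspersed")
                   for s, e in runs if e - s >= k)
    return out


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    rc = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        rc = rc * np.uint64(4) + (np.uint64(3) - (c & np.uint64(3)))
        c >>= np.uint64(2)
    return rc


def _mask_runs(mask: np.ndarray):
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    return zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0])


def merge_intervals(intervals: list[RepeatInterval]) -> list[tuple[str, int, int]]:
    """Union of intervals per target, as (target_id, start, end)."""
    by_target: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_target.setdefault(iv.target_id, []).append((iv.start, iv.end))
    out = []
    for tid, ivs in by_target.items():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((tid, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((tid, cur_s, cur_e))
    return sorted(out)


def repeat_profile(
    record: SequenceRecord,
    intervals: list[RepeatInterval],
    width: int = SEGMENT_WIDTH,
) -> list[tuple[int, int, int]]:
    """Per-segment (segment_index, repeat_count, repeat_total_length).

    count = intervals overlapping the segment (a boundary-spanning interval
    counts in every segment it touches); total_length = overlap bases, so
    lengths are conserved across segments.
    """
    segs = list(window_iter(record, width))
    counts = [0] * len(segs)
    lengths = [0] * len(segs)
    for iv in intervals:
        if iv.target_id != record.id:
            continue
        first = iv.start // width
        last = min((iv.end - 1) // width, len(segs) - 1)
        for si in range(first, last + 1):
            _, s, e = segs[si]
            ov = min(iv.end, e) - max(iv.start, s)
            if ov > 0:
                counts[si] += 1
                lengths[si] += ov
    return [(i, counts[i], lengths[i]) for i, _, _ in segs]


def gc_profile(
    record: SequenceRecord,
    width: int = SEGMENT_WIDTH,
    mode: str = "n_inclusive",
) -> tuple[list[tuple[int, int, int, float]], float]:
    """Per-segment GC fractions and the whole-record value.

    Returns ``([(segment_index, start, end, gc), ...], overall_gc)``.  In the
    default n_inclusive mode the overall value equals the length-weighted
    mean of the segment values exactly.
    """
    segments = []
    for idx, s, e in window_iter(record, width):
        segments.append((idx, s, e, gc_fraction(record.residues[s:e], mode)))
    return segments, gc_fraction(record.residues, mode)


def write_repeats_bed(intervals: list[RepeatInterval], path) -> None:
    """Repeat intervals as BED6 (name = class, score 0, strand '.')."""
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda r: (r.target_id, r.start, r.end)):
            fh.write(f"{iv.target_id}\t{iv.start}\t{iv.end}\t{iv.klass}\t0\t.\n")
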