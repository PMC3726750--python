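"""Spliced EST-to-genome alignment and the matched/unmatched decision.

The aligner follows the est2genome model: a local alignment in which the
genome side may open long gaps (introns) at a flat penalty, discounted when
the intron is flanked by the canonical GT..AG dinucleotides; ordinary
(small) gaps cost a linear per-base penalty on either sequence.  The dynamic
program is exact; chromosome-scale targets are handled by an exact k-mer
seeding stage that restricts the DP to candidate windows.

Scoring defaults (match +1, mismatch -1, gap -2/base, intron 40, GT..AG
intron 20, intron length 30..100,000 bp) follow est2genome's documented
defaults.  An EST is *matched* when its best hit reaches both the identity
and the EST-coverage thresholds; both are configurable and reported per hit.

Determinism: ties on score are broken by lowest target id, then smallest
target start, then the + strand; within one DP the earliest end cell in
row-major order wins and the traceback prefers diagonal, then the smallest
intron donor (spliced before plain), then target-gap, then EST-gap.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .seqio import AssemblySet, SequenceRecord, reverse_complement

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


class CapacityError(ValueError):
    """Sequence too long for the exhaustive DP; use map_est instead."""


@dataclass
class AlignParams:
    """Scoring and search parameters for spliced alignment."""

    match: int = 1
    mismatch: int = -1
    gap_per_base: int = -2
    intron_open: int = 40
    spliced_intron_open: int = 20
    min_intron: int = 30
    max_intron: int = 100_000
    seed_k: int = 12
    min_seed_hits: int = 2
    identity_min: float = 0.95
    coverage_min: float = 0.50
    # search plumbing: assemblies at or below full_scan_max total bases are
    # additionally scanned exhaustively (the seeded and exhaustive paths then
    # coincide); exhaustive_target_max caps the DP matrix.
    full_scan_max: int = 200_000
    exhaustive_target_max: int = 200_000
    max_hits_per_kmer: int = 64

    def __post_init__(self) -> None:
        if not (self.match > 0 >= self.mismatch):
            raise ValueError("need match > 0 >= mismatch")
        if self.gap_per_base > 0 or self.intron_open < 0 or self.spliced_intron_open < 0:
            raise ValueError("gap must be <= 0 and intron penalties >= 0")
        if not (0 < self.identity_min <= 1 and 0 < self.coverage_min <= 1):
            raise ValueError("identity_min/coverage_min must lie in (0, 1]")
        if self.min_intron >= self.max_intron:
            raise ValueError("min_intron must be < max_intron")


@dataclass
class SplicedHit:
    """One EST's best spliced placement: ordered exon blocks on the target
    (0-based half-open, ascending, disjoint), the aligned EST span, and the
    score/identity/coverage behind the matched decision."""

    est_id: str
    target_id: str
    strand: str
    exon_blocks: list[tuple[int, int]]
    est_span: tuple[int, int]
    score: int
    identity: float
    coverage: float
    matched: bool

    def __post_init__(self) -> None:
        for (s0, e0), (s1, e1) in zip(self.exon_blocks, self.exon_blocks[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ValueError("exon blocks must be ascending and disjoint")


def encode(seq: str) -> np.ndarray:
    """Encode DNA to uint8 codes A=0 C=1 G=2 T=3 N=4."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=False)
def _dp_fill(q, t, is_gt, is_ag, match, mismatch, gap, intron_open,
             spliced_open, min_intron, max_intron):  # pragma: no cover
    m = q.shape[0]
    n = t.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    dq_any_c = np.empty(n + 1, dtype=np.int64)
    dq_any_v = np.empty(n + 1, dtype=np.int64)
    dq_gt_c = np.empty(n + 1, dtype=np.int64)
    dq_gt_v = np.empty(n + 1, dtype=np.int64)
    best_score = 0
    best_i = 0
    best_j = 0
    NEG = -(1 << 30)
    for i in range(1, m + 1):
        ha = 0
        ta = 0
        hg = 0
        tg = 0
        qi = q[i - 1]
        Hp = H[i - 1]
        Hc = H[i]
        for j in range(1, n + 1):
            c = j - 1 - min_intron
            if c >= 0:
                v = Hp[c]
                while ta > ha and dq_any_v[ta - 1] <= v:
                    ta -= 1
                dq_any_c[ta] = c
                dq_any_v[ta] = v
                ta += 1
                if is_gt[c]:
                    while tg > hg and dq_gt_v[tg - 1] <= v:
                        tg -= 1
                    dq_gt_c[tg] = c
                    dq_gt_v[tg] = v
                    tg += 1
            cmin = j - 1 - max_intron
            while ta > ha and dq_any_c[ha] < cmin:
                ha += 1
            while tg > hg and dq_gt_c[hg] < cmin:
                hg += 1
            if qi == t[j - 1] and qi < 4:
                s = match
            else:
                s = mismatch
            best = 0
            v = Hp[j - 1] + s
            if v > best:
                best = v
            v = Hp[j] + gap
            if v > best:
                best = v
            v = Hc[j - 1] + gap
            if v > best:
                best = v
            A = NEG
            if ta > ha:
                A = dq_any_v[ha] - intron_open
            if (tg > hg) and is_ag[j]:
                a2 = dq_gt_v[hg] - spliced_open
                if a2 > A:
                    A = a2
            v = A + s
            if v > best:
                best = v
            Hc[j] = best
            if best > best_score:
                best_score = best
                best_i = i
                best_j = j
    return H, best_score, best_i, best_j


def _traceback(H, q, t, p: AlignParams, bi: int, bj: int):
    """Recover one optimal path from the filled matrix.

    Returns (blocks, est_lo, est_hi, matches, aligned_est_bases) with blocks
    as target 0-based half-open exon intervals.
    """
    i, j = bi, bj
    target_cols: list[int] = []      # target positions consumed, descending
    est_positions: list[int] = []
    matches = 0
    aligned_est = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        h = int(H[i, j])
        s = p.match if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else p.mismatch
        if h == int(H[i - 1, j - 1]) + s:
            target_cols.append(j - 1)
            est_positions.append(i - 1)
            aligned_est += 1
            if s == p.match:
                matches += 1
            i, j = i - 1, j - 1
            continue
        # intron arrival: est[i-1] aligned to t[j-1] right after an intron
        c_lo = max(0, j - 1 - p.max_intron)
        c_hi = j - 1 - p.min_intron
        found = False
        acceptor = j >= 3 and t[j - 3] == 0 and t[j - 2] == 2
        for c in range(c_lo, c_hi + 1):
            donor = c + 1 < len(t) and t[c] == 2 and t[c + 1] == 3
            cost = p.spliced_intron_open if (donor and acceptor) else p.intron_open
            if h == int(H[i - 1, c]) - cost + s:
                target_cols.append(j - 1)
                est_positions.append(i - 1)
                aligned_est += 1
                if s == p.match:
                    matches += 1
                i, j = i - 1, c              # intron occupied t[c .. j-2]
                found = True
                break
        if found:
            continue
        if h == int(H[i, j - 1]) + p.gap_per_base:
            target_cols.append(j - 1)
            j -= 1
            continue
        if h == int(H[i - 1, j]) + p.gap_per_base:
            est_positions.append(i - 1)
            aligned_est += 1
            i -= 1
            continue
        raise AssertionError("traceback found no consistent predecessor")
    if not target_cols:
        return [], 0, 0, 0, 0
    target_cols.reverse()
    blocks: list[tuple[int, int]] = []
    start = target_cols[0]
    prev = start
    for col in target_cols[1:]:
        if col != prev + 1:
            blocks.append((start, prev + 1))
            start = col
        prev = col
    blocks.append((start, prev + 1))
    est_lo = min(est_positions)
    est_hi = max(est_positions) + 1
    return blocks, est_lo, est_hi, matches, aligned_est


def _align_strand(est: str, target: str, p: AlignParams):
    """Single-strand DP on the given sequences; returns raw path facts or
    None when no positive-scoring local alignment exists."""
    q = encode(est)
    t = encode(target)
    if (len(q) + 1) * (len(t) + 1) > 200_000_000:
        raise CapacityError(
            "DP matrix would exceed the in-memory cap; use map_est with "
            "seeding or shorter sequences")
    n = t.shape[0]
    is_gt = np.zeros(n, dtype=np.uint8)
    is_ag = np.zeros(n + 1, dtype=np.uint8)
    if n >= 2:
        is_gt[:-1] = (t[:-1] == 2) & (t[1:] == 3)
        is_ag[3:] = (t[:-2] == 0) & (t[1:-1] == 2)
    H, score, bi, bj = _dp_fill(
        q, t, is_gt, is_ag, p.match, p.mismatch, p.gap_per_base,
        p.intron_open, p.spliced_intron_open, p.min_intron, p.max_intron,
    )
    if score <= 0:
        return None
    blocks, lo, hi, matches, aligned = _traceback(H, q, t, p, bi, bj)
    return int(score), blocks, (lo, hi), matches, aligned


def _make_hit(est_id, est_len, target_id, strand, raw, p: AlignParams,
              offset: int = 0) -> SplicedHit:
    score, blocks, (lo, hi), matches, aligned = raw
    if strand == "-":
        lo, hi = est_len - hi, est_len - lo
    identity = matches / aligned if aligned else 0.0
    coverage = aligned / est_len if est_len else 0.0
    return SplicedHit(
        est_id=est_id,
        target_id=target_id,
        strand=strand,
        exon_blocks=[(s + offset, e + offset) for s, e in blocks],
        est_span=(lo, hi),
        score=score,
        identity=identity,
        coverage=coverage,
        matched=(identity >= p.identity_min and coverage >= p.coverage_min),
    )


def _hit_order_key(hit: SplicedHit):
    start = hit.exon_blocks[0][0] if hit.exon_blocks else 0
    return (-hit.score, hit.target_id, start, 0 if hit.strand == "+" else 1)


def spliced_align_exhaustive(
    est: str, target: str, params: AlignParams | None = None,
    est_id: str = "est", target_id: str = "target",
) -> SplicedHit | None:
    """Best local spliced alignment of ``est`` to ``target`` by full DP.

    Both strands are evaluated (the EST is reverse-complemented; intron
    coordinates always live on the target) and the better score returned,
    ties going to +.  Returns None when no alignment scores above zero.
    Intended for targets up to ~200 kb; longer targets raise
    :class:`CapacityError` directing to :func:`map_est`.
    """
    p = params or AlignParams()
    if not est or not target:
        raise ValueError("both sequences must be non-empty")
    if len(target) > p.exhaustive_target_max:
        raise CapacityError(
            f"target of {len(target)} bases exceeds the exhaustive DP cap "
            f"({p.exhaustive_target_max}); use map_est with seeding"
        )
    hits = []
    fwd = _align_strand(est, target, p)
    if fwd is not None:
        hits.append(_make_hit(est_id, len(est), target_id, "+", fwd, p))
    rev = _align_strand(reverse_complement(est), target, p)
    if rev is not None:
        hits.append(_make_hit(est_id, len(est), target_id, "-", rev, p))
    if not hits:
        return None
    return min(hits, key=_hit_order_key)


# ---------------------------------------------------------------------------
# seeded search


class KmerIndex:
    """Sorted exact k-mer index over an assembly's forward strands."""

    def __init__(self, assembly: AssemblySet, k: int):
        self.k = k
        self.record_ids = [r.id for r in assembly.records]
        lengths = [r.length for r in assembly.records]
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])
        codes_all = []
        pos_all = []
        for ri, rec in enumerate(assembly.records):
            arr = encode(rec.residues)
            if arr.shape[0] < k:
                continue
            codes, valid = _kmer_codes(arr, k)
            idx = np.nonzero(valid)[0]
            codes_all.append(codes[idx])
            pos_all.append(idx + self.offsets[ri])
        if codes_all:
            allc = np.concatenate(codes_all)
            allp = np.concatenate(pos_all)
            order = np.argsort(allc, kind="stable")
            self.codes = allc[order]
            self.pos = allp[order]
        else:
            self.codes = np.empty(0, dtype=np.uint64)
            self.pos = np.empty(0, dtype=np.int64)

    def lookup(self, query_codes: np.ndarray, max_hits_per_kmer: int) -> np.ndarray:
        """Global target positions matching any query k-mer; over-represented
        k-mers (likely repeats) are skipped."""
        if query_codes.size == 0 or self.codes.size == 0:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self.codes, query_codes, side="left")
        hi = np.searchsorted(self.codes, query_codes, side="right")
        keep = (hi > lo) & (hi - lo <= max_hits_per_kmer)
        out = [self.pos[a:b] for a, b in zip(lo[keep], hi[keep])]
        return np.sort(np.concatenate(out)) if out else np.empty(0, dtype=np.int64)

    def to_record(self, global_pos: int) -> tuple[int, int]:
        ri = int(np.searchsorted(self.offsets, global_pos, side="right")) - 1
        return ri, int(global_pos - self.offsets[ri])


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = arr.shape[0]
    m = n - k + 1
    codes = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        codes = codes * np.uint64(4) + np.minimum(arr[j:m + j], 3).astype(np.uint64)
    is_n = np.concatenate([[0], np.cumsum(arr == 4)])
    valid = (is_n[k:] - is_n[:-k]) == 0
    return codes, valid


def seed_candidates(
    est: SequenceRecord | str,
    assembly: AssemblySet,
    params: AlignParams | None = None,
    index: KmerIndex | None = None,
) -> list[tuple[str, int, int, str]]:
    """Candidate (target_id, window_start, window_end, strand) windows.

    Positions sharing at least ``min_seed_hits`` exact k-mers, clustered at
    gaps <= max_intron, define windows extended by max_intron on both sides;
    overlapping windows merge.  Both strands of the EST are queried against
    the forward index.
    """
    p = params or AlignParams()
    seq = est.residues if isinstance(est, SequenceRecord) else est
    if index is None:
        index = KmerIndex(assembly, p.seed_k)
    windows: list[tuple[str, int, int, str]] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        arr = encode(s)
        if arr.shape[0] < p.seed_k:
            continue
        codes, valid = _kmer_codes(arr, p.seed_k)
        hits = index.lookup(codes[valid], p.max_hits_per_kmer)
        if hits.size == 0:
            continue
        # cluster sorted global positions
        brk = np.nonzero(np.diff(hits) > p.max_intron)[0] + 1
        for cluster in np.split(hits, brk):
            if cluster.size < p.min_seed_hits:
                continue
            ri_lo, lo = index.to_record(int(cluster[0]))
            ri_hi, hi = index.to_record(int(cluster[-1]))
            if ri_lo != ri_hi:       # cluster spans records: split crudely
                continue
            rec_len = int(index.offsets[ri_lo + 1] - index.offsets[ri_lo])
            ws = max(0, lo - p.max_intron)
            we = min(rec_len, hi + p.seed_k + p.max_intron)
            windows.append((index.record_ids[ri_lo], ws, we, strand))
    return _merge_windows(windows)


def _merge_windows(windows):
    merged: dict[tuple[str, str], list[list[int]]] = {}
    for tid, ws, we, strand in sorted(windows):
        key = (tid, strand)
        lst = merged.setdefault(key, [])
        if lst and ws <= lst[-1][1]:
            lst[-1][1] = max(lst[-1][1], we)
        else:
            lst.append([ws, we])
    out = []
    for (tid, strand), lst in merged.items():
        out.extend((tid, ws, we, strand) for ws, we in lst)
    out.sort()
    return out


def map_est(
    est: SequenceRecord,
    assembly: AssemblySet,
    params: AlignParams | None = None,
    index: KmerIndex | None = None,
) -> SplicedHit | None:
    """Best spliced placement of one EST on the assembly, or None.

    The exhaustive DP runs inside each seeded candidate window; on small
    assemblies (total <= ``full_scan_max`` bases) every full record is also
    scanned on both strands, so the seeded and exhaustive paths agree
    exactly.  Returns None when there is no window or no positive score.
    """
    p = params or AlignParams()
    if not assembly.records:
        return None
    windows = seed_candidates(est, assembly, p, index=index)
    if assembly.assembled_size <= p.full_scan_max:
        for rec in assembly.records:
            windows.append((rec.id, 0, rec.length, "+"))
            windows.append((rec.id, 0, rec.length, "-"))
        windows = _merge_windows(windows)
    best: SplicedHit | None = None
    by_id = {r.id: r for r in assembly.records}
    for tid, ws, we, strand in windows:
        target = by_id[tid].residues[ws:we]
        if not target:
            continue
        query = est.residues if strand == "+" else reverse_complement(est.residues)
        raw = _align_strand(query, target, p)
        if raw is None:
            continue
        hit = _make_hit(est.id, est.length, tid, strand, raw, p, offset=ws)
        if best is None or _hit_order_key(hit) < _hit_order_key(best):
            best = hit
    return best


def map_all(
    ests: Sequence[SequenceRecord],
    assembly: AssemblySet,
    params: AlignParams | None = None,
    include_unmatched: bool = False,
) -> tuple[list[SplicedHit], int, int]:
    """Map every EST, count matches: returns (hits, matched, selected).

    One decision per EST (best hit only); hits are emitted for matched ESTs,
    plus near-misses when ``include_unmatched`` is set.
    """
    p = params or AlignParams()
    index = KmerIndex(assembly, p.seed_k) if assembly.records else None
    hits: list[SplicedHit] = []
    matched = 0
    for est in ests:
        hit = map_est(est, assembly, p, index=index)
        if hit is None:
            continue
        if hit.matched:
            matched += 1
            hits.append(hit)
        elif include_unmatched:
            hits.append(hit)
    return hits, matched, len(ests)


# ---------------------------------------------------------------------------
# writers


def write_bed12(hits: Sequence[SplicedHit], path: str | os.PathLike,
                est_lengths: dict[str, int] | None = None) -> None:
    """Hits as BED12: exon blocks become blockSizes/blockStarts; the score
    column scales the alignment score to 0-1000 by EST length when known."""
    with open(path, "w") as fh:
        for h in hits:
            if not h.exon_blocks:
                continue
            start = h.exon_blocks[0][0]
            end = h.exon_blocks[-1][1]
            if est_lengths and h.est_id in est_lengths:
                score = min(1000, round(1000 * max(0, h.score)
                                        / est_lengths[h.est_id]))
            else:
                score = min(1000, max(0, h.score))
            sizes = ",".join(str(e - s) for s, e in h.exon_blocks)
            starts = ",".join(str(s - start) for s, e in h.exon_blocks)
            fh.write(
                f"{h.target_id}\t{start}\t{end}\t{h.est_id}\t{score}\t{h.strand}"
                f"\t{start}\t{end}\t0\t{len(h.exon_blocks)}\t{sizes}\t{starts}\n"
            )


def write_hits_tsv(hits: Sequence[SplicedHit], path: str | os.PathLike) -> None:
    import pandas as pd

    pd.DataFrame(
        [(h.est_id, h.target_id, h.strand,
          ",".join(f"{s}-{e}" for s, e in h.exon_blocks),
          h.est_span[0], h.est_span[1], h.score,
          round(h.identity, 4), round(h.coverage, 4), h.matched)
         for h in hits],
        columns=["est_id", "target_id", "strand", "blocks", "est_start",
                 "est_end", "score", "identity", "coverage", "matched"],
    ).to_csv(path, sep="\t", index=False)
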