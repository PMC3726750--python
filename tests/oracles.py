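"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the simple-repeat
oracle walks the sequence position by position with direct string
comparisons, and the spliced-alignment oracle enumerates every full-length
placement of an EST with zero or one intron on explicit diagonals.
"""

from __future__ import annotations

import numpy as np


def dna_without_splice_sites(rng, n: int, prev: str = "") -> str:
    """Random DNA containing no GT or AG dinucleotide (also across the
    junction with ``prev``'s last character)."""
    out = []
    last = prev[-1:] if prev else ""
    for _ in range(n):
        while True:
            ch = "ACGT"[int(rng.integers(4))]
            if not ((last == "G" and ch == "T") or (last == "A" and ch == "G")):
                break
        out.append(ch)
        last = ch
    return "".join(out)


def controlled_two_exon(rng, e1: int, e2: int, intron_interior: int = 96,
                        flank: int = 60):
    """A two-exon instance whose ONLY GT and AG dinucleotides are the
    planted splice sites, plus the same target with those sites broken
    (GT..AG -> CT..AC, leaving the target free of any splice site)."""
    left = dna_without_splice_sites(rng, flank)
    E1 = dna_without_splice_sites(rng, e1, prev=left)
    while E1.endswith("A"):      # would form AG against the donor
        E1 = dna_without_splice_sites(rng, e1, prev=left)
    interior = dna_without_splice_sites(rng, intron_interior, prev="T")
    E2 = dna_without_splice_sites(rng, e2, prev="G")
    right = dna_without_splice_sites(rng, flank, prev=E2)
    canonical = left + E1 + "GT" + interior + "AG" + E2 + right
    broken = left + E1 + "CT" + interior + "AC" + E2 + right
    assert canonical.count("GT") == 1 and canonical.count("AG") == 1
    assert broken.count("GT") == 0 and broken.count("AG") == 0
    return E1 + E2, canonical, broken


def brute_simple_repeats(seq: str, min_unit: int = 1, max_unit: int = 6,
                         min_length: int = 20, min_copies: int = 4):
    """Enumerate maximal tandem arrays by direct comparison.

    Returns sorted (start, end, canonical_motif) triples with the same
    qualification rules as the detector: primitive unit, >= min_copies full
    copies, total span >= min_length, N never matches, overlapping
    same-motif reports merged.
    """
    n = len(seq)
    found = []
    for u in range(min_unit, max_unit + 1):
        s = 0
        while s < n - u:
            # left-maximality: the self-match relation must fail just before s
            if s > 0 and seq[s - 1] != "N" and seq[s - 1] == seq[s - 1 + u]:
                s += 1
                continue
            t = s
            while t + u < n and seq[t] != "N" and seq[t] == seq[t + u]:
                t += 1
            if t == s:
                s += 1
                continue
            total = t - s + u
            motif = seq[s:s + u]
            if (total >= min_length and total // u >= min_copies
                    and "N" not in motif
                    and all(motif != motif[p:] + motif[:p]
                            for p in range(1, u))):
                canon = min(motif[p:] + motif[:p] for p in range(u))
                found.append((s, s + total, canon))
            s = t + 1
    found.sort()
    merged = []
    for s, e, m in found:
        if merged and merged[-1][2] == m and s <= merged[-1][1]:
            ps, pe, pm = merged.pop()
            merged.append((ps, max(pe, e), pm))
        else:
            merged.append((s, e, m))
    return merged


def _diag_cumscores(q: np.ndarray, t: np.ndarray, match: int, mismatch: int
                    ) -> np.ndarray:
    """C[d, i] = score of aligning q[:i] gaplessly at target offset d."""
    L = q.shape[0]
    n = t.shape[0]
    nd = n - L + 1
    C = np.zeros((nd, L + 1), dtype=np.int64)
    for d in range(nd):
        eq = (q == t[d:d + L]) & (q < 4)
        C[d, 1:] = np.cumsum(np.where(eq, match, mismatch))
    return C


def best_single_intron_score(est: str, target: str, match: int = 1,
                             mismatch: int = -1, intron_open: int = 40,
                             spliced_open: int = 20, min_intron: int = 30,
                             max_intron: int = 100_000) -> int:
    """Best score over all full-length placements of ``est`` on ``target``
    with zero or one intron and no small gaps (both segment offsets kept in
    [0, len(target) - len(est)]).  Enumerative; for constructed instances.
    """
    from estqc.mapping import encode

    q = encode(est)
    t = encode(target)
    L = q.shape[0]
    n = t.shape[0]
    if n < L:
        raise ValueError("oracle requires target at least as long as est")
    C = _diag_cumscores(q, t, match, mismatch)
    nd = C.shape[0]
    best = int(C[:, L].max())            # no intron
    d = np.arange(nd)
    for i in range(1, L):
        prefix = C[:, i]                             # by d1
        suffix = C[:, L] - C[:, i]                   # by d2
        # donor GT at t[d1+i], acceptor AG ending at t[d2+i-1]
        don = np.zeros(nd, dtype=bool)
        acc = np.zeros(nd, dtype=bool)
        pos = d + i
        ok = pos + 1 < n
        don[ok] = (t[pos[ok]] == 2) & (t[pos[ok] + 1] == 3)
        pos2 = d + i - 2
        ok2 = pos2 >= 0
        acc[ok2] = (t[pos2[ok2]] == 0) & (t[pos2[ok2] + 1] == 2)
        for is_spliced in (False, True):
            cost = spliced_open if is_spliced else intron_open
            suff = np.where(acc, suffix, -10**9) if is_spliced else suffix
            pref = np.where(don, prefix, -10**9) if is_spliced else prefix
            # cummax of suffix over d2 from the right
            cmax = np.maximum.accumulate(suff[::-1])[::-1]
            for d1 in range(nd):
                lo = d1 + min_intron
                hi = d1 + max_intron
                if lo >= nd:
                    continue
                s_best = cmax[lo] if hi >= nd - 1 else \
                    suff[lo:min(hi, nd - 1) + 1].max()
                total = int(pref[d1]) + int(s_best) - cost
                if total > best:
                    best = total
    return max(best, 0)
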