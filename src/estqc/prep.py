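"""Stratified random EST selection and the cleaning pipeline.

Selection follows the two-round rule used when sampling a species' public
EST library: round one keeps everything when the library holds at most
10,000 ESTs and draws 50% otherwise; round two (after cleaning) draws 1%
when the library exceeds 100,000, 10% when it exceeds 10,000, and keeps
everything otherwise.  Both percentages apply to the *library total* N (the
worked sizes 1,529,700 -> 15,297 and 10,855 -> 1,086 require this), with
sample sizes rounded half up and capped at the available pool.  Boundaries
are strict: N of exactly 10,000 or 100,000 falls to the lower tier.

Cleaning clips terminal vector/adaptor sequence, then removes ESTs whose
best local similarity to a labelled screening reference (rRNA, bacterial,
chloroplast, mitochondrial) passes the identity and coverage thresholds.
Similarity search is exact k-mer seeding plus edit-distance verification
(edlib); thresholds are conventional screening practice, all configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import edlib
import numpy as np

from .mapping import _kmer_codes, encode
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

#: tie-break precedence when two screening classes score equally
CLASS_PRECEDENCE = ("rRNA", "chloroplast", "mitochondrial", "bacterial")


def round_half_up(x: Decimal | float) -> int:
    return int(Decimal(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SamplingDecision:
    """Record of one sampling round: which tier applied and how many ids."""

    total_in_dbest: int
    round: int                # 1 or 2
    fraction: float           # 0.01, 0.10, 0.50 or 1.0
    n_selected: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "total_in_dbest": self.total_in_dbest,
            "round": self.round,
            "fraction_pct": self.fraction * 100,
            "n_selected": self.n_selected,
            "seed": self.seed,
        }


@dataclass
class CleanParams:
    """Thresholds for vector clipping and contaminant screening."""

    vector_identity_min: float = 0.95
    vector_hit_min: int = 20
    terminal_window: int = 50
    min_clean_length: int = 100
    screen_identity_min: float = 0.90
    screen_coverage_min: float = 0.80
    seed_k: int = 12


@dataclass(frozen=True)
class CleaningOutcome:
    """Per-EST cleaning record: kept, trimmed_kept, or removed (with reason)."""

    est_id: str
    action: str                       # kept | trimmed_kept | removed
    removal_reason: str | None = None
    trimmed_prefix: int = 0
    trimmed_suffix: int = 0
    final_length: int = 0

    def __post_init__(self) -> None:
        if (self.action == "removed") != (self.removal_reason is not None):
            raise ValueError("removed iff removal_reason present")


# ---------------------------------------------------------------------------
# sampling


def _draw(ids: Sequence[str], n: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in sorted(int(x) for x in idx)]


def _sample(ids: Sequence[str], total: int, fraction: Decimal, rnd: int,
            seed: int) -> tuple[list[str], SamplingDecision]:
    if fraction == 1:
        chosen = list(ids)
    else:
        want = round_half_up(Decimal(total) * fraction)
        if want > len(ids):
            logger.warning(
                "round-%d sample of %d exceeds the %d available ids; capped",
                rnd, want, len(ids))
            want = len(ids)
        chosen = _draw(ids, want, seed)
    return chosen, SamplingDecision(
        total_in_dbest=total, round=rnd, fraction=float(fraction),
        n_selected=len(chosen), seed=seed)


def first_round_sample(
    accessions: Sequence[str], total_in_dbest: int, seed: int = 0,
    with_decision: bool = False,
):
    """Round-one draw: 50% of N ids when the library total N exceeds 10,000,
    otherwise all of them; uniform without replacement, deterministic."""
    if not accessions:
        raise ValueError("accession list is empty")
    if total_in_dbest < len(accessions):
        raise ValueError("total_in_dbest smaller than the accession list")
    frac = Decimal("0.5") if total_in_dbest > 10_000 else Decimal(1)
    chosen, decision = _sample(accessions, total_in_dbest, frac, 1, seed)
    return (chosen, decision) if with_decision else chosen


def second_round_sample(
    clean_ids: Sequence[str], total_in_dbest: int, seed: int = 0,
    with_decision: bool = False,
):
    """Round-two draw from the clean pool: 1% of N above 100,000 ESTs,
    10% above 10,000, everything otherwise; capped at the clean-pool size."""
    if not clean_ids:
        raise ValueError("clean id list is empty")
    if total_in_dbest > 100_000:
        frac = Decimal("0.01")
    elif total_in_dbest > 10_000:
        frac = Decimal("0.10")
    else:
        frac = Decimal(1)
    chosen, decision = _sample(clean_ids, total_in_dbest, frac, 2, seed)
    return (chosen, decision) if with_decision else chosen


def second_round_size(total_in_dbest: int) -> int:
    """Selected count the round-two rule prescribes for a library of size N
    (before capping at the clean pool)."""
    if total_in_dbest > 100_000:
        return round_half_up(Decimal(total_in_dbest) * Decimal("0.01"))
    if total_in_dbest > 10_000:
        return round_half_up(Decimal(total_in_dbest) * Decimal("0.10"))
    return total_in_dbest


# ---------------------------------------------------------------------------
# local similarity search (seed + edit-distance verify)


class _RefIndex:
    """Exact k-mer index over a reference set, for candidate filtering."""

    def __init__(self, refs: Sequence[SequenceRecord], k: int):
        self.k = k
        self.refs = list(refs)
        self.ref_sets: list[set[int]] = []
        for ref in self.refs:
            arr = encode(ref.residues)
            if arr.shape[0] < k:
                self.ref_sets.append(set())
                continue
            codes, valid = _kmer_codes(arr, k)
            self.ref_sets.append(set(codes[valid].tolist()))


def _query_segments(est: str, ref_kmers: set[int], k: int,
                    max_join: int = 400) -> list[tuple[int, int]]:
    """EST intervals covered by k-mers shared with one reference, with
    nearby seeds joined; [] when nothing is shared."""
    arr = encode(est)
    if arr.shape[0] < k:
        return []
    codes, valid = _kmer_codes(arr, k)
    hits = [i for i in np.nonzero(valid)[0] if int(codes[i]) in ref_kmers]
    if not hits:
        return []
    segs: list[list[int]] = []
    for i in hits:
        if segs and i <= segs[-1][1] + max_join:
            segs[-1][1] = i + k
        else:
            segs.append([i, i + k])
    return [(s, e) for s, e in segs]


def _segment_identity(est_seg: str, ref: str) -> float:
    """Identity of the best placement of ``est_seg`` inside ``ref``."""
    res = edlib.align(est_seg, ref, mode="HW", task="distance")
    return 1.0 - res["editDistance"] / len(est_seg)


def ref_class(ref: SequenceRecord) -> str:
    """Screening class from a ``class=<name>`` token in the description."""
    for token in ref.description.split():
        if token.startswith("class="):
            return token.split("=", 1)[1]
    raise ValueError(f"reference {ref.id!r} carries no class=<name> label")


# ---------------------------------------------------------------------------
# cleaning stages


def clip_vector_adaptor(
    est: SequenceRecord,
    vector_refs: Sequence[SequenceRecord],
    params: CleanParams | None = None,
    index: _RefIndex | None = None,
) -> tuple[CleaningOutcome, SequenceRecord | None]:
    """Trim terminal vector/adaptor similarity from one EST.

    A hit (>= ``vector_hit_min`` bases at >= ``vector_identity_min``
    identity to any vector reference) starting within ``terminal_window`` of
    an end is clipped off that end; what remains must reach
    ``min_clean_length`` or the EST is removed.  A confident vector hit in
    the EST interior marks a chimera and removes the EST (reason
    ``internal_vector``).  No-hit ESTs are kept unchanged.
    """
    p = params or CleanParams()
    if index is None:
        index = _RefIndex(vector_refs, p.seed_k)
    n = est.length
    prefix_cut = 0
    suffix_cut = 0
    internal = False
    for ref, kmers in zip(index.refs, index.ref_sets):
        for s, e in _query_segments(est.residues, kmers, p.seed_k):
            if e - s < p.vector_hit_min:
                continue
            if _segment_identity(est.residues[s:e], ref.residues) \
                    < p.vector_identity_min:
                continue
            at_start = s < p.terminal_window
            at_end = e > n - p.terminal_window
            if at_start and at_end:
                prefix_cut = n            # pure vector
            elif at_start:
                prefix_cut = max(prefix_cut, e)
            elif at_end:
                suffix_cut = max(suffix_cut, n - s)
            else:
                internal = True
    if internal:
        logger.info("EST %s removed: internal vector similarity", est.id)
        return CleaningOutcome(est.id, "removed", "internal_vector",
                               final_length=0), None
    final = n - prefix_cut - suffix_cut
    if final < p.min_clean_length:
        return CleaningOutcome(est.id, "removed", "too_short_after_trim",
                               trimmed_prefix=prefix_cut,
                               trimmed_suffix=suffix_cut, final_length=0), None
    if prefix_cut or suffix_cut:
        trimmed = SequenceRecord(
            id=est.id, residues=est.residues[prefix_cut:n - suffix_cut],
            description=est.description)
        return CleaningOutcome(est.id, "trimmed_kept",
                               trimmed_prefix=prefix_cut,
                               trimmed_suffix=suffix_cut,
                               final_length=final), trimmed
    return CleaningOutcome(est.id, "kept", final_length=final), est


def screen_contaminants(
    est: SequenceRecord,
    screen_refs: Sequence[SequenceRecord],
    params: CleanParams | None = None,
    index: _RefIndex | None = None,
) -> CleaningOutcome:
    """Classify one EST against labelled screening references.

    The EST is removed with the class of its best hit when the best local
    similarity reaches ``screen_identity_min`` identity over at least
    ``screen_coverage_min`` of the EST; score ties between classes resolve
    by the fixed precedence rRNA > chloroplast > mitochondrial > bacterial.
    """
    p = params or CleanParams()
    if index is None:
        index = _RefIndex(screen_refs, p.seed_k)
    best: tuple[float, int] | None = None   # (identity*coverage, precedence)
    best_class = None
    for ref, kmers in zip(index.refs, index.ref_sets):
        cls = ref_class(ref)
        for s, e in _query_segments(est.residues, kmers, p.seed_k):
            coverage = (e - s) / est.length
            if coverage < p.screen_coverage_min:
                continue
            identity = _segment_identity(est.residues[s:e], ref.residues)
            if identity < p.screen_identity_min:
                continue
            prec = (CLASS_PRECEDENCE.index(cls)
                    if cls in CLASS_PRECEDENCE else len(CLASS_PRECEDENCE))
            key = (identity * coverage, -prec)
            if best is None or key > best:
                best = key
                best_class = cls
    if best_class is not None:
        return CleaningOutcome(est.id, "removed", best_class, final_length=0)
    return CleaningOutcome(est.id, "kept", final_length=est.length)


def run_cleaning(
    ests: Sequence[SequenceRecord],
    vector_refs: Sequence[SequenceRecord],
    screen_refs: Sequence[SequenceRecord],
    params: CleanParams | None = None,
) -> tuple[list[SequenceRecord], list[CleaningOutcome]]:
    """Full cleaning: clip first, then screen; one outcome per input EST.

    Residues are never altered except by terminal trimming; the kept list
    plus the removed outcomes account for every input.
    """
    p = params or CleanParams()
    vec_index = _RefIndex(vector_refs, p.seed_k)
    scr_index = _RefIndex(screen_refs, p.seed_k)
    clean: list[SequenceRecord] = []
    outcomes: list[CleaningOutcome] = []
    for est in ests:
        clip_out, trimmed = clip_vector_adaptor(est, vector_refs, p, vec_index)
        if trimmed is None:
            outcomes.append(clip_out)
            continue
        scr_out = screen_contaminants(trimmed, screen_refs, p, scr_index)
        if scr_out.action == "removed":
            outcomes.append(CleaningOutcome(
                est.id, "removed", scr_out.removal_reason,
                trimmed_prefix=clip_out.trimmed_prefix,
                trimmed_suffix=clip_out.trimmed_suffix, final_length=0))
            continue
        outcomes.append(clip_out)
        clean.append(trimmed)
    return clean, outcomes


def write_outcomes_tsv(outcomes: Sequence[CleaningOutcome], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(o.est_id, o.action, o.removal_reason or "", o.trimmed_prefix,
          o.trimmed_suffix, o.final_length) for o in outcomes],
        columns=["est_id", "action", "reason", "trimmed_prefix",
                 "trimmed_suffix", "final_length"],
    ).to_csv(path, sep="\t", index=False)


def read_accessions(path) -> list[str]:
    """Plain-text accession list, one id per line, blanks ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
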