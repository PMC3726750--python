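"""Headline assembly-quality metrics and the four-level classification.

* integrity: assembled size over the externally estimated genome size
  (CS/GS for chromosome assemblies, SS/GS for scaffold assemblies), as a
  percentage rounded half-up to 2 decimals.
* accuracy: matched ESTs over randomly selected clean ESTs (mEST/sEST).
* segment matching: the share of 0.1 Mb segments touched by at least one
  matched EST, pooled across chromosomes.
* classification: chromosome-level assemblies fall into four ordered
  levels; the published group definitions overlap and leave holes, so they
  are evaluated in order with first match winning and level 4 as the
  residual class — this reproduces all printed assignments while staying a
  total function.

All percentages round half-up to 2 decimals; aggregate rows over species
are unweighted means of the already-rounded per-species percentages (the
convention the published survey tables use).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

from .mapping import SplicedHit
from .seqio import AssemblySet, window_iter

SEGMENT_WIDTH = 100_000


def pct(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator, rounded half-up to 2 decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(q)


def mean_pct(values: Sequence[float]) -> float:
    """Unweighted mean of already-rounded percentages, rounded to 2 dp."""
    if not values:
        raise ValueError("cannot average an empty list")
    total = sum(Decimal(str(v)) for v in values)
    return float((total / len(values)).quantize(Decimal("0.01"),
                                                rounding=ROUND_HALF_UP))


def integrity_ratio(assembled_size: int, genome_size: int | None) -> float | None:
    """CS/GS (or SS/GS) as a percent; None when no genome size is available.

    Values above 100 are possible (an over-assembled or under-estimated
    genome) and are reported with a warning rather than clamped.
    """
    if genome_size is None:
        return None
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if assembled_size < 0:
        raise ValueError("assembled_size must be >= 0")
    value = pct(assembled_size, genome_size)
    if value > 100:
        import logging

        logging.getLogger(__name__).warning(
            "integrity %.2f%% exceeds 100%%: assembly larger than the "
            "genome-size estimate", value)
    return value


def accuracy_ratio(matched_count: int, selected_count: int) -> float:
    """mEST/sEST as a percent, rounded half-up to 2 decimals."""
    if selected_count <= 0:
        raise ValueError("selected_count must be positive")
    if matched_count > selected_count:
        raise ValueError("matched_count cannot exceed selected_count")
    return pct(matched_count, selected_count)


# ---------------------------------------------------------------------------
# segment profiles


@dataclass
class SegmentProfile:
    """One 0.1 Mb segment: EST-match count plus composition measures."""

    target_id: str
    segment_index: int
    start: int
    end: int
    est_match_count: int = 0
    gc: float | None = None
    repeat_count: int = 0
    repeat_length: int = 0
    abundance_bin: str | None = None


def segment_match_profile(
    hits: Sequence[SplicedHit],
    assembly: AssemblySet,
    width: int = SEGMENT_WIDTH,
) -> tuple[list[SegmentProfile], float]:
    """Count matched ESTs per segment and the % of segments matched.

    An EST increments every segment its exon blocks overlap, once per
    segment; the headline percentage pools segments across all records.
    """
    profiles: dict[str, list[SegmentProfile]] = {}
    for rec in assembly.records:
        profiles[rec.id] = [
            SegmentProfile(rec.id, idx, s, e)
            for idx, s, e in window_iter(rec, width)
        ]
    for hit in hits:
        segs = profiles.get(hit.target_id)
        if segs is None:
            continue
        touched: set[int] = set()
        for s, e in hit.exon_blocks:
            first = s // width
            last = min((e - 1) // width, len(segs) - 1)
            touched.update(range(first, last + 1))
        for si in touched:
            segs[si].est_match_count += 1
    flat = [p for rec in assembly.records for p in profiles[rec.id]]
    matched_segments = sum(1 for p in flat if p.est_match_count >= 1)
    return flat, pct(matched_segments, len(flat)) if flat else 0.0


def abundance_bins(
    profiles: Sequence[SegmentProfile],
    breakpoints: Sequence[int] = (10, 20, 30, 40),
) -> list[SegmentProfile]:
    """Label each segment with its EST-abundance bin.

    Six labels: "0", then four ranges between successive breakpoints, then
    ">b4"; zero is always its own bin.  Breakpoints are per-species
    configurable (dense transcriptomes need wider bins).
    """
    bps = list(breakpoints)
    if len(bps) != 4 or any(b <= a for a, b in zip(bps, bps[1:])) or bps[0] < 1:
        raise ValueError("need four strictly increasing positive breakpoints")
    for p in profiles:
        c = p.est_match_count
        if c == 0:
            p.abundance_bin = "0"
        elif c > bps[-1]:
            p.abundance_bin = f">{bps[-1]}"
        else:
            lo = 1
            for b in bps:
                if c <= b:
                    p.abundance_bin = f"{lo}-{b}"
                    break
                lo = b + 1
    return list(profiles)


# ---------------------------------------------------------------------------
# classification and correlation


def classify(integrity_pct: float, accuracy_pct: float,
             pct_segments_matched: float | None) -> int:
    """Quality level 1-4 for a chromosome-level assembly.

    Evaluated in order, first match wins:
      1: integrity > 85 and accuracy > 85 and segments > 70
      2: integrity > 85 and accuracy > 85 and segments > 30
      3: integrity > 80 and accuracy > 80
      4: otherwise (either core ratio at or below 80)
    """
    if pct_segments_matched is None:
        raise ValueError("segment-matching percentage required to classify")
    if integrity_pct > 85 and accuracy_pct > 85:
        if pct_segments_matched > 70:
            return 1
        if pct_segments_matched > 30:
            return 2
    if integrity_pct > 80 and accuracy_pct > 80:
        return 3
    return 4


@dataclass(frozen=True)
class CorrelationResult:
    name: str
    pearson_r: float | None
    spearman_rho: float | None
    n: int


def correlate(series_a: Sequence[float], series_b: Sequence[float],
              name: str = "correlation") -> CorrelationResult:
    """Pearson r and Spearman rho with n; zero-variance input yields None
    (unavailable), never a silent 0."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series lengths differ")
    if a.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("series must be finite")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(name, None, None, int(a.size))
    r = float(stats.pearsonr(a, b).statistic)
    rho = float(stats.spearmanr(a, b).statistic)
    return CorrelationResult(name, r, rho, int(a.size))


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class QualityReport:
    """One assembly's quality summary, in report units (percent, 2 dp)."""

    assembly_kind: str
    integrity_pct: float | None
    accuracy_pct: float
    selected_count: int
    matched_count: int
    pct_segments_matched: float | None
    level: int | str
    gc_avg_pct: float | None = None
    correlations: list[CorrelationResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "assembly_kind": self.assembly_kind,
            "integrity_pct": self.integrity_pct,
            "accuracy_pct": self.accuracy_pct,
            "selected_count": self.selected_count,
            "matched_count": self.matched_count,
            "pct_segments_matched": self.pct_segments_matched,
            "level": self.level,
            "gc_avg_pct": self.gc_avg_pct,
            "correlations": [
                {"name": c.name, "pearson_r": c.pearson_r,
                 "spearman_rho": c.spearman_rho, "n": c.n}
                for c in self.correlations
            ],
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def summarize(
    assembly: AssemblySet,
    matched_count: int,
    selected_count: int,
    pct_segments_matched: float | None = None,
    gc_avg_pct: float | None = None,
    correlations: Sequence[CorrelationResult] = (),
) -> QualityReport:
    """Assemble the quality report for one assembly from stage outputs.

    Scaffold assemblies are never assigned a level (the classification is
    defined on chromosome-level assemblies only).
    """
    integrity = integrity_ratio(assembly.assembled_size, assembly.genome_size)
    accuracy = accuracy_ratio(matched_count, selected_count)
    if assembly.kind == "chromosome":
        if pct_segments_matched is None:
            raise ValueError(
                "missing stage output: segment-matching percentage is "
                "required to classify a chromosome assembly")
        if integrity is None:
            raise ValueError(
                "missing stage output: genome size (integrity) is required "
                "to classify a chromosome assembly")
        level: int | str = classify(integrity, accuracy, pct_segments_matched)
    else:
        level = "unclassified (scaffold)"
    return QualityReport(
        assembly_kind=assembly.kind,
        integrity_pct=integrity,
        accuracy_pct=accuracy,
        selected_count=selected_count,
        matched_count=matched_count,
        pct_segments_matched=pct_segments_matched,
        level=level,
        gc_avg_pct=gc_avg_pct,
        correlations=list(correlations),
    )


def write_segment_tsv(profiles: Sequence[SegmentProfile], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(p.target_id, p.segment_index, p.start, p.end, p.est_match_count,
          "" if p.gc is None else round(p.gc, 6), p.repeat_count,
          p.repeat_length, p.abundance_bin or "")
         for p in profiles],
        columns=["target_id", "segment_index", "start", "end",
                 "est_match_count", "gc", "repeat_count", "repeat_length",
                 "abundance_bin"],
    ).to_csv(path, sep="\t", index=False)
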