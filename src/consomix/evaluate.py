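"""Scoring pipeline output against simulator truth tracks."""

from __future__ import annotations

from typing import Sequence

from .ancestry import UNDETERMINED, AncestryCall
from .backgroundqc import IslandSegment
from .simulate import TruthTrack


def window_truth_label(
    segments: Sequence[tuple[str, int, int, str]], chrom: str, start: int, end: int
) -> str | None:
    """Majority-overlap truth lineage for one window (None if no overlap)."""
    best, best_ov = None, 0
    for c, s, e, label in segments:
        if c != chrom:
            continue
        ov = min(e, end) - max(s, start)
        if ov > best_ov:
            best, best_ov = label, ov
    return best


def ancestry_recovery(calls: Sequence[AncestryCall], truth: TruthTrack) -> float:
    """Fraction of determinate windows whose label matches the truth lineage."""
    det = [c for c in calls if c.label != UNDETERMINED]
    if not det:
        return 0.0
    hits = sum(
        c.label == window_truth_label(truth.ancestry_segments, c.chromosome, c.start, c.end)
        for c in det
    )
    return hits / len(det)


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def island_jaccards(
    found: Sequence[IslandSegment], truth: TruthTrack
) -> list[float]:
    """Best per-truth-island Jaccard overlap with any recovered island."""
    out = []
    for chrom, start, end in truth.island_segments:
        best = 0.0
        for seg in found:
            if seg.chromosome == chrom:
                best = max(best, interval_jaccard((start, end), (seg.start, seg.end)))
        out.append(best)
    return out


def truth_contamination(truth: TruthTrack, chrom_lengths, donor_chrom: str) -> float:
    """Planted contamination fraction: island bp over background bp."""
    background = sum(v for k, v in chrom_lengths.items() if k != donor_chrom)
    planted = sum(e - s for _, s, e in truth.island_segments)
    return planted / background if background else 0.0
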