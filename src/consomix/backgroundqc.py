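"""Background contamination QC from sliding-window SNP density.

The genome is tiled into non-overlapping windows (default 100 kb) and the
SNP count per window is compared against a lower boundary derived from the
donor chromosome: mean − 2·SD of donor-window counts (clamped at 0).
Background windows *above* the boundary are residual wild-donor
contamination ("wild islands"); donor-chromosome runs at or *below* the
boundary are recipient-strain (reference-like) segments introduced by
recombination during backcrossing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ancestry import make_windows
from .variants import VariantRecord


@dataclass(frozen=True)
class DensityTrack:
    """Per-window SNP counts over an exhaustive genome tiling."""

    df: pd.DataFrame  # columns: chromosome, start, end, snp_count
    window_bp: int

    def windows(self, chromosome: str) -> pd.DataFrame:
        return self.df[self.df.chromosome == chromosome].reset_index(drop=True)

    @property
    def total_count(self) -> int:
        return int(self.df.snp_count.sum())


@dataclass(frozen=True)
class Boundary:
    """Donor-derived density boundary: lower = max(0, mean − 2·sd)."""

    mean: float
    sd: float

    @property
    def lower(self) -> float:
        return max(0.0, self.mean - 2.0 * self.sd)


@dataclass(frozen=True)
class IslandSegment:
    chromosome: str
    start: int
    end: int
    n_windows: int
    mean_density: float  # mean SNP count per window in the segment


@dataclass(frozen=True)
class RecipientSegment:
    start: int
    end: int
    n_windows: int
    location: str  # proximal | internal | distal


def density_track(
    records: Sequence[VariantRecord],
    chrom_lengths: Mapping[str, int],
    window_bp: int = 100_000,
) -> DensityTrack:
    """Count SNPs per window over an exhaustive tiling of every chromosome.

    The partial final window keeps its true length.  Records on chromosomes
    absent from ``chrom_lengths`` are an error.
    """
    positions: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    unknown = set()
    for r in records:
        if r.variant_class != "snp":
            continue
        if r.chromosome not in positions:
            unknown.add(r.chromosome)
        else:
            positions[r.chromosome].append(r.position)
    if unknown:
        raise ValueError(f"records on unknown chromosomes: {sorted(unknown)}")
    rows = []
    for chrom, length in chrom_lengths.items():
        pos = np.sort(np.array(positions[chrom], dtype=np.int64))
        for start, end in make_windows(length, window_bp):
            i = np.searchsorted(pos, start + 1, side="left")
            j = np.searchsorted(pos, end, side="right")
            rows.append((chrom, start, end, int(j - i)))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "snp_count"])
    return DensityTrack(df=df, window_bp=window_bp)


def donor_boundary(track: DensityTrack, donor_chrom: str) -> Boundary:
    """Mean and sample SD (n−1) of donor-chromosome window counts."""
    counts = track.windows(donor_chrom).snp_count.to_numpy(dtype=float)
    if len(counts) < 3:
        raise ValueError("need >= 3 donor windows to estimate the boundary")
    return Boundary(mean=float(counts.mean()), sd=float(counts.std(ddof=1)))


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first_index, last_index) pairs."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def find_islands(
    track: DensityTrack,
    boundary: Boundary,
    background_chroms: Sequence[str],
    max_gap_windows: int = 0,
) -> tuple[list[IslandSegment], float]:
    """Wild islands on background chromosomes, plus the contamination fraction.

    A background window is flagged iff its SNP count is strictly greater
    than the boundary's lower limit.  Consecutive flagged windows merge into
    one island (optionally bridging up to ``max_gap_windows`` unflagged
    windows).  The contamination fraction is flagged length over total
    background length.
    """
    if not background_chroms:
        raise ValueError("background chromosome set is empty")
    islands: list[IslandSegment] = []
    flagged_bp = 0
    total_bp = 0
    for chrom in background_chroms:
        win = track.windows(chrom)
        if win.empty:
            raise ValueError(f"no windows for background chromosome {chrom}")
        total_bp += int((win.end - win.start).sum())
        flags = (win.snp_count.to_numpy() > boundary.lower)
        if max_gap_windows > 0:
            runs = _runs(flags)
            for (s1, e1), (s2, _) in zip(runs, runs[1:]):
                if s2 - e1 - 1 <= max_gap_windows:
                    flags[e1 + 1 : s2] = True
        for s, e in _runs(flags):
            seg = win.iloc[s : e + 1]
            flagged_bp += int((seg.end - seg.start).sum())
            islands.append(
                IslandSegment(
                    chromosome=chrom,
                    start=int(seg.start.iloc[0]),
                    end=int(seg.end.iloc[-1]),
                    n_windows=len(seg),
                    mean_density=float(seg.snp_count.mean()),
                )
            )
    contamination = flagged_bp / total_bp if total_bp else 0.0
    return islands, contamination


def recipient_segments(
    track: DensityTrack,
    boundary: Boundary,
    donor_chrom: str,
    min_run_windows: int = 5,
) -> list[RecipientSegment]:
    """Recipient-like (low-density) segments on the donor chromosome.

    Runs of at least ``min_run_windows`` consecutive donor windows with SNP
    count <= the lower boundary, classified by position: proximal (touching
    the chromosome start), distal (touching the end), internal otherwise.
    A run covering the whole chromosome is reported as proximal.
    """
    if min_run_windows < 1:
        raise ValueError("min_run_windows must be >= 1")
    win = track.windows(donor_chrom)
    flags = win.snp_count.to_numpy() <= boundary.lower
    out: list[RecipientSegment] = []
    n = len(win)
    for s, e in _runs(flags):
        if e - s + 1 < min_run_windows:
            continue
        if s == 0:
            location = "proximal"
        elif e == n - 1:
            location = "distal"
        else:
            location = "internal"
        out.append(
            RecipientSegment(
                start=int(win.start.iloc[s]),
                end=int(win.end.iloc[e]),
                n_windows=e - s + 1,
                location=location,
            )
        )
    return out
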