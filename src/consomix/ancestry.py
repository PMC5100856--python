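"""Subspecies-origin painting of the donor chromosome in fixed windows.

Each line's donor chromosome is tiled into windows (default 10 kb) and each
window is compared against three wild-derived reference strains, one per
house-mouse lineage (by convention musculus→PWK, castaneus→CAST,
domesticus→WSB).  The per-window mismatch count between a line and a strain
is the size of the symmetric difference of their homozygous SNP key sets in
the window — for SNP-only consensus sequences over a shared reference this
equals the base-by-base consensus mismatch count.  The window's label is the
lineage with the highest percent similarity, except that windows unable to
discriminate (fewer than ``min_diff_snps`` differences to at least two
strains — the signature of intersubspecies introgression or missing signal —
or an exact tie for the maximum) are left undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .variants import VariantRecord

UNDETERMINED = "undetermined"

#: lineage -> conventional wild-derived reference strain
REFERENCE_STRAINS = {"musculus": "PWK", "castaneus": "CAST", "domesticus": "WSB"}


@dataclass(frozen=True)
class AncestryConfig:
    window_bp: int = 10_000
    min_diff_snps: int = 5
    lineages: tuple[str, str, str] = ("musculus", "castaneus", "domesticus")

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if self.min_diff_snps < 1:
            raise ValueError("min_diff_snps must be >= 1")
        if len(self.lineages) != 3:
            raise ValueError("exactly 3 lineages required")


@dataclass(frozen=True)
class AncestryCall:
    """One window's mismatch counts, similarities, and assigned label."""

    chromosome: str
    start: int
    end: int
    diffs: Mapping[str, int]
    similarity: Mapping[str, float]
    label: str
    reason: str = ""  # for undetermined windows: "introgressed" or "tie"


@dataclass(frozen=True)
class ContributionSummary:
    """Lineage fractions over determinate windows for one line."""

    line_id: str
    fractions: Mapping[str, float]
    determinate_fraction: float
    n_windows: int
    n_determinate: int


def make_windows(chrom_length: int, window_bp: int) -> list[tuple[int, int]]:
    """Tile [0, chrom_length) into half-open windows; last may be partial."""
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be > 0")
    return [
        (s, min(s + window_bp, chrom_length)) for s in range(0, chrom_length, window_bp)
    ]


def _hom_snp_index(records: Sequence[VariantRecord], chrom: str):
    """Sorted positions + parallel keys of homozygous-alt SNPs on one chromosome."""
    keyed = sorted(
        (r.position, (r.position, r.ref_allele, r.alt_allele))
        for r in records
        if r.chromosome == chrom and r.variant_class == "snp" and r.genotype == "hom_alt"
    )
    pos = np.array([p for p, _ in keyed], dtype=np.int64)
    keys = [k for _, k in keyed]
    return pos, keys


def _keys_in_window(pos: np.ndarray, keys: list, start: int, end: int) -> set:
    i = int(np.searchsorted(pos, start + 1, side="left"))
    j = int(np.searchsorted(pos, end, side="right"))
    return set(keys[i:j])


def window_diffs(
    line_records: Sequence[VariantRecord],
    strain_records: Sequence[VariantRecord],
    window: tuple[str, int, int],
) -> int:
    """Mismatch count between a line and one strain over one window.

    Counted as the symmetric difference of the homozygous SNP key sets;
    heterozygous and missing sites contribute nothing.
    """
    chrom, start, end = window
    if start < 0 or end <= start:
        raise ValueError(f"bad window ({chrom}, {start}, {end})")
    lp, lk = _hom_snp_index(line_records, chrom)
    sp, sk = _hom_snp_index(strain_records, chrom)
    return len(_keys_in_window(lp, lk, start, end) ^ _keys_in_window(sp, sk, start, end))


def assign_window(diffs: Mapping[str, int], config: AncestryConfig) -> tuple[str, str]:
    """Label one window from its per-lineage mismatch counts.

    Returns ``(label, reason)``; reason is empty for determinate labels,
    ``"introgressed"`` when at least two lineages fall below the
    ``min_diff_snps`` discrimination floor, ``"tie"`` on an exact tie for
    the minimum mismatch count.
    """
    missing = [lin for lin in config.lineages if lin not in diffs]
    if missing:
        raise ValueError(f"diffs missing lineages: {missing}")
    values = [diffs[lin] for lin in config.lineages]
    if sum(v < config.min_diff_snps for v in values) >= 2:
        return UNDETERMINED, "introgressed"
    best = min(values)
    if values.count(best) > 1:
        return UNDETERMINED, "tie"
    return config.lineages[int(np.argmin(values))], ""


def paint_chromosome(
    line_records: Sequence[VariantRecord],
    strains: Mapping[str, Sequence[VariantRecord]],
    chrom: str,
    chrom_length: int,
    config: AncestryConfig | None = None,
    line_id: str = "",
) -> tuple[list[AncestryCall], ContributionSummary]:
    """Paint every window of one chromosome and summarize contributions.

    ``strains`` maps each lineage name to its reference strain's (filtered,
    homozygous) records.  Similarity per lineage is
    ``(window_length - diffs) / window_length`` (the partial final window
    uses its true length), clipped at 0.
    """
    config = config or AncestryConfig()
    missing = [lin for lin in config.lineages if lin not in strains]
    if missing:
        raise ValueError(f"missing reference strains for lineages: {missing}")

    line_idx = _hom_snp_index(line_records, chrom)
    strain_idx = {lin: _hom_snp_index(strains[lin], chrom) for lin in config.lineages}

    calls: list[AncestryCall] = []
    for start, end in make_windows(chrom_length, config.window_bp):
        line_keys = _keys_in_window(*line_idx, start, end)
        diffs = {
            lin: len(line_keys ^ _keys_in_window(*strain_idx[lin], start, end))
            for lin in config.lineages
        }
        wlen = end - start
        similarity = {
            lin: max(0.0, (wlen - d) / wlen) for lin, d in diffs.items()
        }
        label, reason = assign_window(diffs, config)
        calls.append(AncestryCall(chrom, start, end, diffs, similarity, label, reason))

    determinate = [c for c in calls if c.label != UNDETERMINED]
    n_det = len(determinate)
    fractions = {
        lin: (sum(c.label == lin for c in determinate) / n_det if n_det else 0.0)
        for lin in config.lineages
    }
    summary = ContributionSummary(
        line_id=line_id,
        fractions=fractions,
        determinate_fraction=n_det / len(calls) if calls else 0.0,
        n_windows=len(calls),
        n_determinate=n_det,
    )
    return calls, summary


def merge_calls(calls: Sequence[AncestryCall]) -> list[tuple[str, int, int, str]]:
    """Merge adjacent same-label windows into BED-ready segments."""
    segments: list[tuple[str, int, int, str]] = []
    for c in calls:
        if (
            segments
            and segments[-1][3] == c.label
            and segments[-1][0] == c.chromosome
            and segments[-1][2] == c.start
        ):
            prev = segments[-1]
            segments[-1] = (prev[0], prev[1], c.end, prev[3])
        else:
            segments.append((c.chromosome, c.start, c.end, c.label))
    return segments
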