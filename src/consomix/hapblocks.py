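"""Four-gamete haplotype-block partitioning over a panel of inbred lines.

Each line contributes a single haplotype (lines are inbred; heterozygous
calls are treated as missing).  Two biallelic SNPs show evidence of
historical recombination iff all four two-locus gamete types are observed —
the four-gamete rule.  Blocks are maximal left-to-right runs of SNPs in
which every pair is compatible (no four-gamete violation), mirroring the
four-gamete (GAM) block definition of Haploview.  Block statistics and
mean+2SD "hotspot" regions follow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .variants import VariantPanel

COMPATIBLE = "compatible"
RECOMBINANT = "recombinant"

MISSING = -1  # allele code for missing / heterozygous calls


@dataclass(frozen=True)
class FourGameteConfig:
    """Gamete-frequency thresholds for calling a recombinant pair.

    With the Haploview GAM default ``freq_threshold = 0.01`` and a panel of
    ~18 haplotypes, any observed gamete exceeds the frequency bound, so
    ``min_minor_count = 1`` is the effective rule.
    """

    freq_threshold: float = 0.01
    min_minor_count: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq_threshold < 0.5:
            raise ValueError("freq_threshold must lie in [0, 0.5)")
        if self.min_minor_count < 1:
            raise ValueError("min_minor_count must be >= 1")


@dataclass(frozen=True)
class HapBlock:
    """A maximal run of mutually four-gamete-compatible SNPs."""

    start_idx: int
    end_idx: int  # inclusive SNP index
    start_bp: int
    end_bp: int
    n_snps: int
    region: int = 0

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


class HaplotypeMatrix:
    """Per-line haplotypes at panel SNP positions on one chromosome.

    ``alleles`` is (n_lines, n_snps) with 0 = reference, 1 = alternate,
    -1 = missing (absent genotype or heterozygous call).  Positions are
    strictly increasing.
    """

    def __init__(self, chromosome: str, positions: np.ndarray, line_ids: Sequence[str],
                 alleles: np.ndarray):
        positions = np.asarray(positions, dtype=np.int64)
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.shape != (len(line_ids), len(positions)):
            raise ValueError("alleles shape must be (n_lines, n_snps)")
        if len(positions) > 1 and not np.all(np.diff(positions) > 0):
            raise ValueError("positions must be strictly increasing")
        self.chromosome = chromosome
        self.positions = positions
        self.line_ids = list(line_ids)
        self.alleles = alleles

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    def subset(self, keep: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.chromosome, self.positions[keep], self.line_ids, self.alleles[:, keep]
        )

    @classmethod
    def from_panel(
        cls,
        panel: VariantPanel,
        chromosome: str,
        drop_uninformative: bool = True,
    ) -> "HaplotypeMatrix":
        """Build the matrix from a panel's SNP calls on one chromosome.

        A line is alt (1) at a site iff it carries a homozygous-alt call for
        the site's consensus (most frequent) alternate allele; a heterozygous
        or discordant-allele call is missing (-1); absence of any call is
        reference (0) — per-line calling against a shared reference reports
        non-reference sites only.  With ``drop_uninformative``, sites that
        are monomorphic or carry the alternate in fewer than two lines are
        removed (they can never contribute a fourth gamete).
        """
        per_line: list[dict[int, tuple[str, str]]] = []
        for line in panel.line_ids:
            d: dict[int, tuple[str, str]] = {}
            for r in panel.records(line):
                if r.chromosome == chromosome and r.variant_class == "snp":
                    d[r.position] = (r.alt_allele, r.genotype)
            per_line.append(d)
        positions = sorted(set().union(*per_line) if per_line else set())
        # consensus alt per position
        consensus: dict[int, str] = {}
        for p in positions:
            alts: dict[str, int] = {}
            for d in per_line:
                if p in d:
                    alts[d[p][0]] = alts.get(d[p][0], 0) + 1
            consensus[p] = max(sorted(alts), key=lambda a: alts[a])
        alleles = np.zeros((len(per_line), len(positions)), dtype=np.int8)
        for i, d in enumerate(per_line):
            for j, p in enumerate(positions):
                if p in d:
                    alt, geno = d[p]
                    if geno == "hom_alt" and alt == consensus[p]:
                        alleles[i, j] = 1
                    else:
                        alleles[i, j] = MISSING
        m = cls(chromosome, np.array(positions, dtype=np.int64), panel.line_ids, alleles)
        if drop_uninformative and m.n_snps:
            alt_n = (m.alleles == 1).sum(axis=0)
            ref_n = (m.alleles == 0).sum(axis=0)
            m = m.subset((alt_n >= 2) & (ref_n >= 1))
        return m


def four_gamete_pair(
    i: int, j: int, matrix: HaplotypeMatrix, config: FourGameteConfig | None = None
) -> str:
    """Classify a SNP pair as ``compatible`` or ``recombinant``.

    Gamete types are counted over lines non-missing at both SNPs; the pair
    is recombinant iff all four types occur, each with frequency >=
    ``freq_threshold`` and count >= ``min_minor_count``.
    """
    config = config or FourGameteConfig()
    a = matrix.alleles[:, i]
    b = matrix.alleles[:, j]
    for col, idx in ((a, i), (b, j)):
        obs = col[col != MISSING]
        if len(obs) == 0 or np.all(obs == obs[0]):
            raise ValueError(f"SNP at index {idx} is monomorphic; pre-filter the matrix")
    mask = (a != MISSING) & (b != MISSING)
    n = int(mask.sum())
    if n == 0:
        return COMPATIBLE
    counts = np.zeros(4, dtype=np.int64)
    code = a[mask] * 2 + b[mask]
    for c in code:
        counts[c] += 1
    if np.all(counts >= config.min_minor_count) and np.all(
        counts / n >= config.freq_threshold
    ):
        return RECOMBINANT
    return COMPATIBLE


def _column_bits(matrix: HaplotypeMatrix) -> list[tuple[int, int]]:
    """Per SNP: (alt-carrier bitmask, non-missing bitmask) over lines."""
    bits = []
    for k in range(matrix.n_snps):
        col = matrix.alleles[:, k]
        alt = nm = 0
        for line_bit, allele in enumerate(col):
            if allele != MISSING:
                nm |= 1 << line_bit
                if allele == 1:
                    alt |= 1 << line_bit
        bits.append((alt, nm))
    return bits


def _bits_compatible(
    ai: int, nmi: int, aj: int, nmj: int, config: FourGameteConfig
) -> bool:
    mask = nmi & nmj
    n = mask.bit_count()
    if n == 0:
        return True
    c11 = (ai & aj & mask).bit_count()
    c10 = (ai & ~aj & mask).bit_count()
    c01 = (~ai & aj & mask).bit_count()
    c00 = n - c11 - c10 - c01
    least = min(c00, c01, c10, c11)
    return not (least >= config.min_minor_count and least / n >= config.freq_threshold)


def partition_blocks(
    matrix: HaplotypeMatrix,
    config: FourGameteConfig | None = None,
    region: int = 0,
) -> list[HapBlock]:
    """Greedy left-to-right maximal-extension block partition.

    A block absorbs the next SNP iff that SNP is pairwise compatible with
    *every* SNP already in the block; otherwise the block closes and a new
    one starts.  Singleton blocks are allowed; the blocks tile the SNP index
    range exactly.
    """
    config = config or FourGameteConfig()
    m = matrix.n_snps
    if m == 0:
        return []
    bits = _column_bits(matrix)
    blocks: list[HapBlock] = []
    start = 0
    for j in range(1, m):
        aj, nmj = bits[j]
        ok = all(
            _bits_compatible(bits[i][0], bits[i][1], aj, nmj, config)
            for i in range(start, j)
        )
        if not ok:
            blocks.append(_make_block(matrix, start, j - 1, region))
            start = j
    blocks.append(_make_block(matrix, start, m - 1, region))
    return blocks


def _make_block(matrix: HaplotypeMatrix, i: int, j: int, region: int) -> HapBlock:
    return HapBlock(
        start_idx=i,
        end_idx=j,
        start_bp=int(matrix.positions[i]),
        end_bp=int(matrix.positions[j]),
        n_snps=j - i + 1,
        region=region,
    )


def partition_regions(
    matrix: HaplotypeMatrix,
    config: FourGameteConfig | None = None,
    region_snps: int = 10_000,
) -> list[HapBlock]:
    """Partition the matrix in consecutive regions of ``region_snps`` SNPs.

    Mirrors a region-wise scan design where each region holds on the order
    of 10,000 SNPs; blocks never span region boundaries.
    """
    if region_snps < 2:
        raise ValueError("region_snps must be >= 2")
    blocks: list[HapBlock] = []
    for ridx, lo in enumerate(range(0, matrix.n_snps, region_snps)):
        keep = np.zeros(matrix.n_snps, dtype=bool)
        keep[lo : lo + region_snps] = True
        sub = matrix.subset(keep)
        for b in partition_blocks(sub, config, region=ridx):
            blocks.append(
                HapBlock(
                    start_idx=b.start_idx + lo,
                    end_idx=b.end_idx + lo,
                    start_bp=b.start_bp,
                    end_bp=b.end_bp,
                    n_snps=b.n_snps,
                    region=ridx,
                )
            )
    return blocks


LENGTH_BINS = ("lt_1kb", "1_to_10kb", "ge_10kb")


def block_stats(blocks: Sequence[HapBlock]) -> dict:
    """Length-distribution summary: bin counts/fractions, max, mean, median."""
    if not blocks:
        return {"n_blocks": 0}
    lengths = np.array([b.length_bp for b in blocks], dtype=np.int64)
    counts = {
        "lt_1kb": int((lengths < 1_000).sum()),
        "1_to_10kb": int(((lengths >= 1_000) & (lengths < 10_000)).sum()),
        "ge_10kb": int((lengths >= 10_000).sum()),
    }
    n = len(lengths)
    per_region: dict[int, int] = {}
    for b in blocks:
        per_region[b.region] = per_region.get(b.region, 0) + 1
    return {
        "n_blocks": n,
        "counts": counts,
        "fractions": {k: v / n for k, v in counts.items()},
        "max_length_bp": int(lengths.max()),
        "mean_length_bp": float(lengths.mean()),
        "median_length_bp": float(np.median(lengths)),
        "mean_blocks_per_region": float(np.mean(list(per_region.values()))),
    }


def hotspot_regions(region_counts: Mapping | Sequence[int]) -> list:
    """Flag regions whose block count exceeds mean + 2·SD (sample SD, n−1).

    Accepts a mapping region->count or a plain sequence (regions are then
    indices).  Requires at least 3 regions for a stable SD.
    """
    if isinstance(region_counts, Mapping):
        keys = list(region_counts)
        values = np.array([region_counts[k] for k in keys], dtype=float)
    else:
        values = np.asarray(region_counts, dtype=float)
        keys = list(range(len(values)))
    if len(values) < 3:
        raise ValueError("need >= 3 regions to estimate the SD")
    threshold = values.mean() + 2.0 * values.std(ddof=1)
    return [k for k, v in zip(keys, values) if v > threshold]
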