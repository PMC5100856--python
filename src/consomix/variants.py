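"""Per-line variant I/O, hard filtering, and panel summaries.

Variant calls for each substitution line come in as single-sample VCFs
against a shared reference.  This module reads them into lightweight
:class:`VariantRecord` objects, applies the pipeline's hard-filter policy
(minimum depth, per-line maximum depth, minimum site quality, minimum
alternate-supporting reads, and removal of SNPs adjacent to indels), the
structural-variant post-filters, and computes per-line and panel-level
summaries (private variants, hom/het split, SNP density, known/novel split
against a catalog of previously described sites).

Variant identity throughout the package is the normalized key
``(chromosome, position, ref, alt)``.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")

VariantKey = tuple[str, int, str, str]


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be parsed."""


@dataclass(frozen=True)
class VariantRecord:
    """One called variant for one line.

    ``position`` is 1-based, as in VCF.  ``variant_class`` is ``"snp"`` for
    1:1 substitutions and ``"indel"`` otherwise; alleles are stored in
    minimal (normalized) representation.
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    genotype: str = "hom_alt"
    depth: int = 0
    alt_depth: int = 0
    quality: float = 0.0
    filters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if not (self.depth >= self.alt_depth >= 0):
            raise ValueError(
                f"need depth >= alt_depth >= 0, got {self.depth}/{self.alt_depth}"
            )

    @property
    def variant_class(self) -> str:
        return "snp" if len(self.ref_allele) == 1 == len(self.alt_allele) else "indel"

    @property
    def key(self) -> VariantKey:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)

    @property
    def passed(self) -> bool:
        return not self.filters


def normalize_allele(position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Reduce an allele pair to minimal representation.

    Shared trailing bases are trimmed first, then shared leading bases
    (advancing the position), always keeping at least one base on each side.
    Reference-free, so it cannot shift an indel across identical flanking
    sequence; it does make keys from equivalent right-padded/left-padded
    spellings comparable.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    if ":" not in region:
        return region, None, None
    chrom, _, span = region.partition(":")
    try:
        lo, _, hi = span.partition("-")
        return chrom, int(lo.replace(",", "")), int(hi.replace(",", ""))
    except ValueError as exc:  # pragma: no cover - defensive
        raise ValueError(f"bad region {region!r}; expected chrom[:start-end]") from exc


def read_vcf(path: str | Path, region: str | None = None) -> list[VariantRecord]:
    """Read a single-sample VCF into sorted :class:`VariantRecord` objects.

    Multi-allelic sites are split into one record per alternate allele, with
    the genotype re-expressed relative to that allele.  ``region`` is
    ``"chrom"`` or ``"chrom:start-end"`` (1-based, inclusive); a region on a
    chromosome absent from the header yields an empty list with a logged
    warning.
    """
    path = str(path)
    vcf = VCF(path, gts012=True)
    chrom = lo = hi = None
    if region is not None:
        chrom, lo, hi = _parse_region(region)
        if chrom not in set(vcf.seqnames):
            logger.warning("region chromosome %s not in %s; empty result", chrom, path)
            vcf.close()
            return []

    records: list[VariantRecord] = []
    last_pos = "start of file"
    try:
        for v in vcf:
            if chrom is not None:
                if v.CHROM != chrom:
                    continue
                if lo is not None and not (lo <= v.POS <= hi):
                    continue
            gt = int(v.gt_types[0]) if len(v.gt_types) else 3
            alleles = v.genotypes[0][:-1] if v.genotypes else []
            dp = v.format("DP")
            depth = int(dp[0][0]) if dp is not None and dp[0][0] >= 0 else 0
            ad = v.format("AD")
            qual = float(v.QUAL) if v.QUAL is not None else 0.0
            for i, alt in enumerate(v.ALT):
                if len(v.ALT) == 1:
                    geno = GENOTYPES[gt] if 0 <= gt <= 3 else "missing"
                else:
                    # genotype relative to this alternate allele
                    k = i + 1
                    if any(a < 0 for a in alleles) or not alleles:
                        geno = "missing"
                    else:
                        n = sum(a == k for a in alleles)
                        geno = {2: "hom_alt", 1: "het", 0: "hom_ref"}[n]
                alt_depth = 0
                if ad is not None and ad.shape[1] > i + 1 and ad[0][i + 1] >= 0:
                    alt_depth = int(ad[0][i + 1])
                pos, ref_n, alt_n = normalize_allele(v.POS, v.REF, alt)
                records.append(
                    VariantRecord(
                        chromosome=v.CHROM,
                        position=pos,
                        ref_allele=ref_n,
                        alt_allele=alt_n,
                        genotype=geno,
                        depth=max(depth, alt_depth),
                        alt_depth=alt_depth,
                        quality=qual,
                    )
                )
            last_pos = f"{v.CHROM}:{v.POS}"
    except Exception as exc:
        raise VcfParseError(f"malformed VCF record in {path} after {last_pos}: {exc}") from exc
    finally:
        vcf.close()
    records.sort(key=lambda r: (r.chromosome, r.position, r.ref_allele, r.alt_allele))
    return records


def load_catalog(path: str | Path) -> set[VariantKey]:
    """Load a known-sites VCF as a set of normalized variant keys."""
    return {r.key for r in read_vcf(path)}


# ---------------------------------------------------------------------------
# Hard filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterPolicy:
    """Hard-filter thresholds for short-variant calls.

    Thresholds are inclusive (a record at the threshold passes) except as
    noted for SVs elsewhere.  ``snp_gap`` removes SNPs within that many bp of
    any indel in the same call set.  With ``hard`` False, failing records are
    annotated with the name of the first failing rule instead of removed.
    """

    min_depth: int = 5
    max_depth: int = 100
    min_quality: float = 20.0
    snp_gap: int = 2
    min_alt_bases: int = 5
    hard: bool = True

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")
        if min(self.min_depth, self.min_quality, self.snp_gap, self.min_alt_bases) < 0:
            raise ValueError("thresholds must be >= 0")


#: order in which a multiply-failing record is attributed to a single rule
FILTER_RULES = ("min_depth", "max_depth", "min_quality", "min_alt_bases", "snp_gap")


def _check_sorted(records: Sequence[VariantRecord]) -> None:
    seen: set[str] = set()
    prev_chrom, prev_pos = None, -1
    for r in records:
        if r.chromosome != prev_chrom:
            if r.chromosome in seen:
                raise ValueError("records not sorted: sort by (chromosome, position) first")
            seen.add(r.chromosome)
            prev_chrom, prev_pos = r.chromosome, r.position
        elif r.position < prev_pos:
            raise ValueError("records not sorted: sort by (chromosome, position) first")
        else:
            prev_pos = r.position


def filter_variants(
    records: Sequence[VariantRecord], policy: FilterPolicy | None = None
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the hard-filter policy; return (records, per-rule rejection counts).

    A record passes iff depth >= min_depth, depth <= max_depth,
    quality >= min_quality, alt_depth >= min_alt_bases, and — for SNPs — no
    indel lies within ``snp_gap`` bp in the same input set.  A record failing
    several rules is counted once, under the first failing rule in
    :data:`FILTER_RULES`.  With ``policy.hard`` every failing record is
    dropped; otherwise all records are returned, failures carrying the rule
    name in ``filters``.
    """
    policy = policy or FilterPolicy()
    _check_sorted(records)

    indel_pos: dict[str, list[int]] = {}
    for r in records:
        if r.variant_class == "indel":
            indel_pos.setdefault(r.chromosome, []).append(r.position)

    def near_indel(r: VariantRecord) -> bool:
        pos = indel_pos.get(r.chromosome)
        if not pos:
            return False
        i = bisect_left(pos, r.position - policy.snp_gap)
        return i < len(pos) and pos[i] <= r.position + policy.snp_gap

    counts = Counter()
    out: list[VariantRecord] = []
    for r in records:
        reason = None
        if r.depth < policy.min_depth:
            reason = "min_depth"
        elif r.depth > policy.max_depth:
            reason = "max_depth"
        elif r.quality < policy.min_quality:
            reason = "min_quality"
        elif r.alt_depth < policy.min_alt_bases:
            reason = "min_alt_bases"
        elif r.variant_class == "snp" and policy.snp_gap > 0 and near_indel(r):
            reason = "snp_gap"
        if reason is None:
            out.append(replace(r, filters=()))
        elif not policy.hard:
            counts[reason] += 1
            out.append(replace(r, filters=(reason,)))
        else:
            counts[reason] += 1
    return out, {rule: counts.get(rule, 0) for rule in FILTER_RULES}


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

SV_TYPES = ("deletion", "duplication", "inversion")


@dataclass(frozen=True)
class SvRecord:
    chromosome: str
    start: int
    end: int
    sv_type: str
    quality: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("SV end must be > start")
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def filter_svs(svs: Iterable[SvRecord]) -> list[SvRecord]:
    """Post-filter raw SV calls.

    Every SV needs calling quality strictly greater than 100.  Deletions must
    be 50–100,000 bp long (inclusive); duplications and inversions must be
    shorter than 3,000,000 bp.
    """
    out = []
    for sv in svs:
        if not sv.quality > 100:
            continue
        if sv.sv_type == "deletion":
            if 50 <= sv.length <= 100_000:
                out.append(sv)
        elif sv.length < 3_000_000:
            out.append(sv)
    return out


# ---------------------------------------------------------------------------
# Panels and summaries
# ---------------------------------------------------------------------------

class VariantPanel:
    """Per-line variant stores over a shared reference, position-indexed.

    Lines keep their input order; within a line records are sorted by
    (chromosome, position) and keys are unique.
    """

    def __init__(self, records_by_line: Mapping[str, Sequence[VariantRecord]]):
        self.line_ids: list[str] = list(records_by_line)
        self._records: dict[str, list[VariantRecord]] = {}
        self._pos_index: dict[str, dict[str, np.ndarray]] = {}
        for line, recs in records_by_line.items():
            srt = sorted(recs, key=lambda r: (r.chromosome, r.position, r.alt_allele))
            keys = [r.key for r in srt]
            if len(set(keys)) != len(keys):
                dup = Counter(keys).most_common(1)[0][0]
                raise ValueError(f"duplicate variant key in line {line}: {dup}")
            self._records[line] = srt
            by_chrom: dict[str, np.ndarray] = {}
            chroms = sorted({r.chromosome for r in srt})
            for c in chroms:
                by_chrom[c] = np.array(
                    [r.position for r in srt if r.chromosome == c], dtype=np.int64
                )
            self._pos_index[line] = by_chrom

    @classmethod
    def from_vcfs(cls, paths: Mapping[str, str | Path]) -> "VariantPanel":
        return cls({line: read_vcf(p) for line, p in paths.items()})

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def records(self, line_id: str) -> list[VariantRecord]:
        return self._records[line_id]

    def keys(self, line_id: str) -> set[VariantKey]:
        return {r.key for r in self._records[line_id]}

    def records_in_window(
        self, line_id: str, chromosome: str, start: int, end: int
    ) -> list[VariantRecord]:
        """Records with 0-based position-1 in [start, end)."""
        recs = [r for r in self._records[line_id] if r.chromosome == chromosome]
        pos = self._pos_index[line_id].get(chromosome)
        if pos is None or len(pos) == 0:
            return []
        i = int(np.searchsorted(pos, start + 1, side="left"))
        j = int(np.searchsorted(pos, end, side="right"))
        return recs[i:j]


def private_variants(panel: VariantPanel) -> dict[str, set[VariantKey]]:
    """Keys observed in exactly one line, mapped to that line.

    Privacy needs a comparison set, so a single-line panel is an error.
    Invariant under line reordering.
    """
    if panel.n_lines < 2:
        raise ValueError("private variants undefined for a panel of < 2 lines")
    occurrence: Counter = Counter()
    for line in panel.line_ids:
        occurrence.update(panel.keys(line))
    return {
        line: {k for k in panel.keys(line) if occurrence[k] == 1}
        for line in panel.line_ids
    }


@dataclass(frozen=True)
class LineSummary:
    line_id: str
    snp_count: int
    indel_count: int
    private_snp_count: int | None
    private_indel_count: int | None
    hom_fraction: float
    het_fraction: float
    snp_density_per_kb: float
    novel_count: int | None
    known_count: int | None


def summarize_line(
    records: Sequence[VariantRecord],
    chrom_length: int,
    catalog: set[VariantKey] | None = None,
    private_keys: set[VariantKey] | None = None,
    line_id: str = "",
) -> LineSummary:
    """Table-1-style summary of one line's (filtered) calls on one chromosome.

    SNP density is SNP count per kb of ``chrom_length``; hom/het fractions are
    over genotyped (non-missing) sites; with a catalog, novel + known = total.
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    snps = [r for r in records if r.variant_class == "snp"]
    indels = [r for r in records if r.variant_class == "indel"]
    genotyped = [r for r in records if r.genotype != "missing"]
    n_het = sum(r.genotype == "het" for r in genotyped)
    n_gt = len(genotyped)
    het_fraction = n_het / n_gt if n_gt else 0.0
    novel = known = None
    if catalog is not None:
        known = sum(r.key in catalog for r in records)
        novel = len(records) - known
    priv_snp = priv_indel = None
    if private_keys is not None:
        priv_snp = sum(r.key in private_keys for r in snps)
        priv_indel = sum(r.key in private_keys for r in indels)
    return LineSummary(
        line_id=line_id,
        snp_count=len(snps),
        indel_count=len(indels),
        private_snp_count=priv_snp,
        private_indel_count=priv_indel,
        hom_fraction=1.0 - het_fraction if n_gt else 0.0,
        het_fraction=het_fraction,
        snp_density_per_kb=len(snps) / (chrom_length / 1000.0),
        novel_count=novel,
        known_count=known,
    )


def summarize_panel(
    panel: VariantPanel,
    chrom_length: int,
    catalog: set[VariantKey] | None = None,
) -> list[LineSummary]:
    """Per-line summaries including private-variant counts for a whole panel."""
    private = private_variants(panel) if panel.n_lines >= 2 else {}
    return [
        summarize_line(
            panel.records(line),
            chrom_length,
            catalog=catalog,
            private_keys=private.get(line, set()),
            line_id=line,
        )
        for line in panel.line_ids
    ]
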