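"""Synthetic chromosome-substitution-line panels with known truth.

The generator emulates the genome structure of a panel of chromosome-1
substitution lines built from wild-caught donors on an inbred recipient
background:

* three subspecies lineages, each represented by a few founder haplotypes
  diverged from the reference at a per-bp rate (default 0.0082, i.e. about
  8.2 SNP/kb on the donor chromosome);
* each line's donor chromosome is a two-level mosaic — lineage segments with
  exponential lengths, and within each segment switches among that lineage's
  founders at a finer exponential spacing (this is what gives downstream
  ancestry painting 10-kb-scale truth and four-gamete blocks sub-100-kb
  scale truth);
* background chromosomes are variant-free except for occasional residual
  "wild islands" copied from a founder haplotype;
* optional recipient (reference-like, variant-free) segments on the donor
  chromosome mimic recombination during backcrossing;
* a small fraction of emitted genotypes are heterozygous (default 2.6%), and
  per-record DP/QUAL are drawn around configurable means.

Every stochastic feature is recorded in a per-line :class:`TruthTrack`, so
downstream stages can be scored against ground truth.  All randomness flows
from the single seed in :class:`SimConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .variants import VariantRecord

LINEAGES = ("musculus", "castaneus", "domesticus")
_BASES = "ACGT"

#: desk-scale default genome: three 2-Mb chromosomes, chr1 as donor
DEFAULT_CHROM_LENGTHS = {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}


def ref_base(position: int) -> str:
    """Deterministic synthetic reference base at a 1-based position."""
    return _BASES[position % 4]


def alt_base(position: int) -> str:
    """Deterministic synthetic alternate base, always != ref_base(position).

    Making the alternate a pure function of position means two haplotypes
    carrying a variant at the same site carry the *same* allele, so
    symmetric-difference counts between variant sets equal base-by-base
    consensus mismatch counts.
    """
    return _BASES[(position % 4 + 1 + position % 3) % 4]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic substitution-line panel.

    Defaults target the summary statistics of the emulated study: donor-
    chromosome divergence ~8.2 SNP/kb, ~2.6% heterozygous calls, haplotype
    blocks mostly below 100 kb, and background contamination of a few
    percent.
    """

    seed: int = 0
    n_lines: int = 18
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    donor_chrom: str = "chr1"
    subspecies_rates: Mapping[str, float] = field(
        default_factory=lambda: {lin: 0.0082 for lin in LINEAGES}
    )
    n_founders_per_lineage: int = 3
    founder_private_frac: float = 0.1
    ancestry_segment_mean_bp: float = 300_000.0
    ancestry_segment_min_bp: float = 0.0
    founder_switch_mean_bp: float = 30_000.0
    het_fraction: float = 0.026
    island_rate_per_line: float = 0.8
    island_mean_bp: float = 200_000.0
    island_min_bp: float = 0.0
    depth_mean: float = 30.0
    qual_mean: float = 60.0

    def __post_init__(self) -> None:
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if self.donor_chrom not in self.chrom_lengths:
            raise ValueError(f"donor_chrom {self.donor_chrom!r} not in chrom_lengths")
        for lin, rate in self.subspecies_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate for {lin} outside [0, 1]")
        for frac in (self.founder_private_frac, self.het_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for length in (
            self.ancestry_segment_mean_bp,
            self.founder_switch_mean_bp,
            self.island_mean_bp,
        ):
            if length <= 0:
                raise ValueError("mean segment lengths must be > 0")
        if self.n_lines < 1 or self.n_founders_per_lineage < 1:
            raise ValueError("n_lines and n_founders_per_lineage must be >= 1")

    @property
    def lineages(self) -> tuple[str, ...]:
        return tuple(self.subspecies_rates)

    @property
    def background_chroms(self) -> tuple[str, ...]:
        return tuple(c for c in self.chrom_lengths if c != self.donor_chrom)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["chrom_lengths"] = dict(self.chrom_lengths)
        d["subspecies_rates"] = dict(self.subspecies_rates)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass(frozen=True)
class FounderHaplotype:
    """A founder's variant sites per chromosome (sorted 1-based positions)."""

    lineage: str
    index: int
    sites: Mapping[str, np.ndarray]

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Positions p with start < p <= end (half-open 0-based [start, end))."""
        pos = self.sites.get(chrom)
        if pos is None:
            return np.empty(0, dtype=np.int64)
        i = np.searchsorted(pos, start + 1, side="left")
        j = np.searchsorted(pos, end, side="right")
        return pos[i:j]


@dataclass
class TruthTrack:
    """Ground truth for one simulated line.

    ``ancestry_segments`` partition the donor chromosome exactly (no gaps,
    no overlaps); ``island_segments`` and ``recipient_segments_on_donor_chrom``
    use 0-based half-open coordinates like the rest.
    """

    line_id: str
    ancestry_segments: list[tuple[str, int, int, str]]
    island_segments: list[tuple[str, int, int]]
    recipient_segments_on_donor_chrom: list[tuple[int, int]]


def _draw_sites(rng: np.random.Generator, length: int, rate: float) -> np.ndarray:
    """Binomial(length, rate) sites, uniform without replacement, sorted, 1-based."""
    n = rng.binomial(length, rate)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    pos = rng.choice(length, size=n, replace=False).astype(np.int64) + 1
    pos.sort()
    return pos


def simulate_founders(config: SimConfig) -> dict[str, list[FounderHaplotype]]:
    """Draw founder haplotypes for each lineage.

    Founders of a lineage share that lineage's core sites (drawn at
    ``rate * (1 - founder_private_frac)`` per bp) and add founder-private
    sites at ``rate * founder_private_frac``, so within-lineage haplotypes
    are similar and between-lineage haplotypes are distinct.
    """
    rng = np.random.default_rng([config.seed, 11])
    founders: dict[str, list[FounderHaplotype]] = {}
    for lineage in config.lineages:
        rate = config.subspecies_rates[lineage]
        core_rate = rate * (1.0 - config.founder_private_frac)
        private_rate = rate * config.founder_private_frac
        core = {
            chrom: _draw_sites(rng, length, core_rate)
            for chrom, length in config.chrom_lengths.items()
        }
        lin_founders = []
        for idx in range(config.n_founders_per_lineage):
            sites = {}
            for chrom, length in config.chrom_lengths.items():
                priv = _draw_sites(rng, length, private_rate)
                priv = np.setdiff1d(priv, core[chrom], assume_unique=True)
                sites[chrom] = np.union1d(core[chrom], priv)
            lin_founders.append(FounderHaplotype(lineage, idx, sites))
        founders[lineage] = lin_founders
    return founders


def _segment_breaks(
    rng: np.random.Generator, length: int, mean_bp: float, min_bp: float = 0.0
) -> list[tuple[int, int]]:
    """Partition [0, length) into segments with (min + exponential) lengths."""
    breaks: list[tuple[int, int]] = []
    pos = 0
    while pos < length:
        seg = int(round(min_bp + rng.exponential(mean_bp)))
        seg = max(seg, 1)
        end = min(pos + seg, length)
        breaks.append((pos, end))
        pos = end
    return breaks


def _merge_same_label(
    segments: list[tuple[int, int, str]]
) -> list[tuple[int, int, str]]:
    merged: list[tuple[int, int, str]] = []
    for start, end, label in segments:
        if merged and merged[-1][2] == label and merged[-1][1] == start:
            merged[-1] = (merged[-1][0], end, label)
        else:
            merged.append((start, end, label))
    return merged


def simulate_line(
    config: SimConfig,
    founders: Mapping[str, Sequence[FounderHaplotype]],
    line_index: int,
    recipient_segments: Sequence[tuple[int, int]] | None = None,
    island_segments: Sequence[tuple[str, int, int]] | None = None,
) -> tuple[list[VariantRecord], TruthTrack]:
    """Simulate one line's variant calls and its truth track.

    ``recipient_segments`` (donor chromosome) and ``island_segments``
    (background chromosomes) may be supplied explicitly for truth-controlled
    experiments; by default there are no recipient segments and islands are
    drawn stochastically (count ~ Poisson(island_rate_per_line), lengths
    ``island_min_bp`` + exponential, uniform placement).
    """
    if not 0 <= line_index < config.n_lines:
        raise ValueError(f"line_index {line_index} out of range [0, {config.n_lines})")
    rng = np.random.default_rng([config.seed, 1000, line_index])
    line_id = f"L{line_index + 1:02d}"
    donor = config.donor_chrom
    donor_len = config.chrom_lengths[donor]
    lineages = list(config.lineages)

    # Level 1: lineage segments tiling the donor chromosome.
    lineage_segs = [
        (s, e, lineages[rng.integers(len(lineages))])
        for s, e in _segment_breaks(
            rng, donor_len, config.ancestry_segment_mean_bp, config.ancestry_segment_min_bp
        )
    ]
    lineage_segs = _merge_same_label(lineage_segs)

    # Level 2: founder switches within each lineage segment.
    donor_positions: list[np.ndarray] = []
    for start, end, lineage in lineage_segs:
        pool = founders[lineage]
        pos = start
        while pos < end:
            chunk = max(1, int(round(rng.exponential(config.founder_switch_mean_bp))))
            chunk_end = min(pos + chunk, end)
            f = pool[rng.integers(len(pool))]
            donor_positions.append(f.sites_in(donor, pos, chunk_end))
            pos = chunk_end
    donor_pos = (
        np.concatenate(donor_positions) if donor_positions else np.empty(0, np.int64)
    )

    # Recipient (reference-like) segments: remove donor variants inside them.
    recipient = sorted(tuple(seg) for seg in (recipient_segments or []))
    for start, end in recipient:
        if not 0 <= start < end <= donor_len:
            raise ValueError(f"recipient segment ({start}, {end}) outside donor chromosome")
        donor_pos = donor_pos[(donor_pos <= start) | (donor_pos > end)]
    donor_pos = np.unique(donor_pos)

    # Background islands.
    all_founders = [f for lin in config.lineages for f in founders[lin]]
    islands: list[tuple[str, int, int]] = []
    if island_segments is not None:
        islands = [tuple(seg) for seg in island_segments]
    elif config.background_chroms and config.island_rate_per_line > 0:
        n_islands = rng.poisson(config.island_rate_per_line)
        for _ in range(n_islands):
            chrom = config.background_chroms[rng.integers(len(config.background_chroms))]
            clen = config.chrom_lengths[chrom]
            size = min(
                clen, max(1, int(round(config.island_min_bp + rng.exponential(config.island_mean_bp))))
            )
            start = int(rng.integers(0, clen - size + 1))
            islands.append((chrom, start, start + size))
    # merge overlaps per chromosome so the truth track is non-overlapping
    merged_islands: list[tuple[str, int, int]] = []
    for chrom in config.background_chroms:
        segs = sorted((s, e) for c, s, e in islands if c == chrom)
        for s, e in segs:
            if not 0 <= s < e <= config.chrom_lengths[chrom]:
                raise ValueError(f"island ({chrom}, {s}, {e}) outside chromosome")
            if merged_islands and merged_islands[-1][0] == chrom and s <= merged_islands[-1][2]:
                prev = merged_islands[-1]
                merged_islands[-1] = (chrom, prev[1], max(prev[2], e))
            else:
                merged_islands.append((chrom, s, e))

    background_positions: dict[str, np.ndarray] = {}
    for chrom, start, end in merged_islands:
        f = all_founders[rng.integers(len(all_founders))]
        pos = f.sites_in(chrom, start, end)
        prev = background_positions.get(chrom, np.empty(0, np.int64))
        background_positions[chrom] = np.union1d(prev, pos)

    # Emit records with genotypes, depths and qualities.
    records: list[VariantRecord] = []
    for chrom in config.chrom_lengths:
        pos = donor_pos if chrom == donor else background_positions.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        n = len(pos)
        het = rng.random(n) < config.het_fraction
        depth = np.maximum(1, rng.poisson(config.depth_mean, n))
        p_alt = np.where(het, 0.5, 0.98)
        alt_depth = np.minimum(depth, rng.binomial(depth, p_alt))
        qual = np.round(np.maximum(1.0, rng.normal(config.qual_mean, 8.0, n)), 1)
        for k in range(n):
            p = int(pos[k])
            records.append(
                VariantRecord(
                    chromosome=chrom,
                    position=p,
                    ref_allele=ref_base(p),
                    alt_allele=alt_base(p),
                    genotype="het" if het[k] else "hom_alt",
                    depth=int(depth[k]),
                    alt_depth=int(alt_depth[k]),
                    quality=float(qual[k]),
                )
            )

    truth = TruthTrack(
        line_id=line_id,
        ancestry_segments=[(donor, s, e, lin) for s, e, lin in lineage_segs],
        island_segments=merged_islands,
        recipient_segments_on_donor_chrom=recipient,
    )
    return records, truth


def simulate_panel(
    config: SimConfig,
    recipient_segments: Mapping[int, Sequence[tuple[int, int]]] | None = None,
    island_segments: Mapping[int, Sequence[tuple[str, int, int]]] | None = None,
) -> list[tuple[str, list[VariantRecord], TruthTrack]]:
    """Simulate the full panel: (line_id, records, truth) per line."""
    founders = simulate_founders(config)
    out = []
    for i in range(config.n_lines):
        recs, truth = simulate_line(
            config,
            founders,
            i,
            recipient_segments=(recipient_segments or {}).get(i),
            island_segments=(island_segments or {}).get(i),
        )
        out.append((truth.line_id, recs, truth))
    return out


def founder_records(founder: FounderHaplotype, chrom: str | None = None) -> list[VariantRecord]:
    """Render a founder haplotype as homozygous variant records.

    Used to expose one founder per lineage as that lineage's reference
    strain for ancestry painting.
    """
    chroms = [chrom] if chrom is not None else list(founder.sites)
    records = []
    for c in chroms:
        for p in founder.sites.get(c, ()):
            p = int(p)
            records.append(
                VariantRecord(
                    chromosome=c,
                    position=p,
                    ref_allele=ref_base(p),
                    alt_allele=alt_base(p),
                    genotype="hom_alt",
                    depth=40,
                    alt_depth=40,
                    quality=99.0,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

_VCF_GT = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample: str,
    chrom_lengths: Mapping[str, int],
) -> Path:
    """Write sorted records as a minimal single-sample VCF v4.2."""
    path = Path(path)
    recs = sorted(records, key=lambda r: (list(chrom_lengths).index(r.chromosome), r.position))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=consomix-simulate\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for r in recs:
            ad = f"{r.depth - r.alt_depth},{r.alt_depth}"
            fh.write(
                f"{r.chromosome}\t{r.position}\t.\t{r.ref_allele}\t{r.alt_allele}\t"
                f"{r.quality:.1f}\t.\t.\tGT:DP:AD\t{_VCF_GT[r.genotype]}:{r.depth}:{ad}\n"
            )
    return path


def _write_bed(rows: Sequence[tuple], path: Path) -> Path:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


def write_panel(
    lines: Sequence[tuple[str, Sequence[VariantRecord], TruthTrack]],
    out_dir: str | Path,
    config: SimConfig,
) -> dict[str, dict[str, Path]]:
    """Write one VCF + truth BEDs per line, plus a config/seed sidecar.

    BEDs are 0-based half-open.  Returns ``{line_id: {kind: path}}`` with a
    ``"config"`` entry for the sidecar.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, dict[str, Path]] = {}
    for line_id, records, truth in lines:
        entry = {
            "vcf": write_vcf(records, out_dir / f"{line_id}.vcf", line_id, config.chrom_lengths),
            "ancestry_bed": _write_bed(
                truth.ancestry_segments, out_dir / f"{line_id}.ancestry.bed"
            ),
            "islands_bed": _write_bed(
                truth.island_segments, out_dir / f"{line_id}.islands.bed"
            ),
            "recipient_bed": _write_bed(
                [
                    (config.donor_chrom, s, e)
                    for s, e in truth.recipient_segments_on_donor_chrom
                ],
                out_dir / f"{line_id}.recipient.bed",
            ),
        }
        paths[line_id] = entry
    sidecar = out_dir / "simconfig.json"
    sidecar.write_text(config.to_json() + "\n")
    paths["config"] = {"json": sidecar}
    chrom_tsv = out_dir / "chrom_lengths.tsv"
    with open(chrom_tsv, "w") as fh:
        for chrom, length in config.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    paths["config"]["chrom_lengths"] = chrom_tsv
    return paths
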