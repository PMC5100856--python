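"""Gold-standard (Sanger) vs pipeline (WGS) call-set concordance, and the
consolidated report.

Calls are matched on the normalized key (chromosome, position, ref, alt),
optionally restricted to evaluation intervals.  A gold call absent from the
test set is a false negative; a test call absent from the gold set is a
false positive.  Rates are FN/n_gold and FP/n_test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .variants import VariantKey, VariantRecord

Interval = tuple[str, int, int]  # 0-based half-open


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Sort and merge; overlapping inputs merge with a warning."""
    merged: list[Interval] = []
    overlapped = False
    for chrom, start, end in sorted(intervals):
        if end <= start:
            raise ValueError(f"empty interval ({chrom}, {start}, {end})")
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            overlapped = True
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    if overlapped:
        warnings.warn("overlapping evaluation intervals were merged", stacklevel=2)
    return merged


def _as_keys(calls: Iterable) -> set[VariantKey]:
    out = set()
    for c in calls:
        out.add(c.key if isinstance(c, VariantRecord) else tuple(c))
    return out


def _restrict(keys: set[VariantKey], intervals: list[Interval]) -> set[VariantKey]:
    kept = set()
    for chrom, pos, ref, alt in keys:
        for ichrom, start, end in intervals:
            if ichrom == chrom and start < pos <= end:
                kept.add((chrom, pos, ref, alt))
                break
    return kept


@dataclass(frozen=True)
class ConcordanceResult:
    n_gold: int
    n_test: int
    n_matched: int
    false_negatives: int
    false_positives: int
    intervals: tuple[Interval, ...] = ()

    @property
    def fn_rate(self) -> float | None:
        """FN / n_gold; None (not applicable) when the gold set is empty."""
        return None if self.n_gold == 0 else self.false_negatives / self.n_gold

    @property
    def fp_rate(self) -> float:
        """FP / n_test; 0 by convention when the test set is empty."""
        return 0.0 if self.n_test == 0 else self.false_positives / self.n_test

    @property
    def fp_rate_vs_gold(self) -> float | None:
        """FP / n_gold — the validated-set convention.

        Published validation experiments of this kind typically quote the
        false-positive rate against the size of the gold (e.g. Sanger)
        call set rather than against all test calls; both conventions are
        reported.  None when the gold set is empty.
        """
        return None if self.n_gold == 0 else self.false_positives / self.n_gold

    @property
    def fn_rate_pct(self) -> float | None:
        return None if self.fn_rate is None else round(100.0 * self.fn_rate, 2)

    @property
    def fp_rate_pct(self) -> float:
        return round(100.0 * self.fp_rate, 2)

    @property
    def fp_rate_vs_gold_pct(self) -> float | None:
        if self.fp_rate_vs_gold is None:
            return None
        return round(100.0 * self.fp_rate_vs_gold, 2)

    def to_dict(self) -> dict:
        return {
            "n_gold": self.n_gold,
            "n_test": self.n_test,
            "n_matched": self.n_matched,
            "false_negatives": self.false_negatives,
            "false_positives": self.false_positives,
            "fn_rate_pct": self.fn_rate_pct,
            "fp_rate_pct": self.fp_rate_pct,
            "fp_rate_vs_gold_pct": self.fp_rate_vs_gold_pct,
        }


def compare_callsets(
    gold: Iterable,
    test: Iterable,
    intervals: Sequence[Interval] | None = None,
    position_only: bool = False,
) -> ConcordanceResult:
    """Compare a gold call set against a test call set.

    Inputs may be :class:`VariantRecord` objects or raw
    ``(chrom, pos, ref, alt)`` keys.  With ``position_only`` (for gold sets
    lacking allele detail), matching collapses keys to (chrom, pos).
    Keys outside the (merged) intervals never affect the result.
    """
    gold_keys = _as_keys(gold)
    test_keys = _as_keys(test)
    merged: list[Interval] = []
    if intervals is not None:
        merged = merge_intervals(intervals)
        gold_keys = _restrict(gold_keys, merged)
        test_keys = _restrict(test_keys, merged)
    if position_only:
        gold_keys = {(c, p, "", "") for c, p, *_ in gold_keys}
        test_keys = {(c, p, "", "") for c, p, *_ in test_keys}
    matched = gold_keys & test_keys
    return ConcordanceResult(
        n_gold=len(gold_keys),
        n_test=len(test_keys),
        n_matched=len(matched),
        false_negatives=len(gold_keys - test_keys),
        false_positives=len(test_keys - gold_keys),
        intervals=tuple(merged),
    )


def read_gold_tsv(path: str | Path) -> list[VariantKey]:
    """Read gold calls from a 4-column TSV: chrom, pos (1-based), ref, alt."""
    keys = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: expected 4 columns (chrom, pos, ref, alt)")
        keys.append((parts[0], int(parts[1]), parts[2], parts[3]))
    return keys


def read_bed(path: str | Path) -> list[Interval]:
    """Read 0-based half-open intervals from the first 3 BED columns."""
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end, *_ = line.split("\t")
        intervals.append((chrom, int(start), int(end)))
    return intervals


# ---------------------------------------------------------------------------
# Consolidated report
# ---------------------------------------------------------------------------

REPORT_SECTIONS = ("variants", "ancestry", "hapblocks", "background", "concordance")


def _section_line_ids(section) -> list[str]:
    ids = []
    if isinstance(section, dict):
        ids = [str(k) for k in section]
    elif isinstance(section, list):
        for row in section:
            lid = getattr(row, "line_id", None)
            if lid is None and isinstance(row, dict):
                lid = row.get("line_id")
            if lid:
                ids.append(str(lid))
    return ids


def run_report(sections: dict, out_dir: str | Path) -> dict[str, Path]:
    """Bundle any subset of stage outputs into report.json + report.md.

    ``sections`` maps section names (:data:`REPORT_SECTIONS`) to
    JSON-serializable stage outputs keyed or tagged by line_id.  Missing
    stages are reported as absent; a line_id repeated within a section is an
    error naming the conflict.
    """
    unknown = set(sections) - set(REPORT_SECTIONS)
    if unknown:
        raise ValueError(f"unknown report sections: {sorted(unknown)}")
    for name, content in sections.items():
        ids = _section_line_ids(content)
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"conflicting line_ids in section {name!r}: {sorted(dup)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def default(o):
        if hasattr(o, "to_dict"):
            return o.to_dict()
        if hasattr(o, "__dataclass_fields__"):
            return {f: getattr(o, f) for f in o.__dataclass_fields__}
        raise TypeError(f"not JSON-serializable: {type(o)}")

    payload = {
        name: (sections[name] if name in sections else "absent")
        for name in REPORT_SECTIONS
    }
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=default) + "\n")

    md = ["# consomix report", ""]
    for name in REPORT_SECTIONS:
        md.append(f"## {name}")
        if name not in sections:
            md.append("_absent_")
        else:
            md.append("```json")
            md.append(json.dumps(sections[name], indent=2, sort_keys=True, default=default))
            md.append("```")
        md.append("")
    md_path = out_dir / "report.md"
    md_path.write_text("\n".join(md))
    return {"json": json_path, "markdown": md_path}
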