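"""VCF reading, hard-filter rules, SV post-filters, and panel summaries."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consomix import variants as var

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##contig=<ID=chr2,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def write_vcf_text(tmp_path, body: str, name: str = "x.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


def rec(pos=100, ref="A", alt="T", chrom="chr1", geno="hom_alt", depth=30,
        alt_depth=28, qual=60.0) -> var.VariantRecord:
    return var.VariantRecord(chrom, pos, ref, alt, geno, depth, alt_depth, qual)


class TestNormalize:
    @pytest.mark.parametrize(
        "pos,ref,alt,expected",
        [
            (100, "A", "T", (100, "A", "T")),
            (100, "AT", "ATT", (100, "A", "AT")),   # shared suffix trimmed
            (100, "ATT", "AT", (100, "AT", "A")),   # anchor base retained
            (100, "CAG", "CG", (100, "CA", "C")),   # suffix then nothing more
            (100, "GGG", "GG", (100, "GG", "G")),
            (100, "CAGG", "CTGG", (101, "A", "T")),  # prefix trim shifts position
        ],
    )
    def test_minimal_representation(self, pos, ref, alt, expected):
        assert var.normalize_allele(pos, ref, alt) == expected

    def test_idempotent(self):
        out = var.normalize_allele(50, "TCCA", "TCA")
        assert var.normalize_allele(*out) == out


class TestReadVcf:
    def test_header_only_gives_empty_list(self, tmp_path):
        assert var.read_vcf(write_vcf_text(tmp_path, "")) == []

    def test_multiallelic_site_splits_into_two_records(self, tmp_path):
        body = "chr1\t500\t.\tA\tT,C\t60.0\t.\t.\tGT:DP:AD\t1/2:30:0,14,16\n"
        records = var.read_vcf(write_vcf_text(tmp_path, body))
        assert len(records) == 2
        assert {r.alt_allele for r in records} == {"T", "C"}
        assert all(r.position == 500 and r.genotype == "het" for r in records)

    def test_region_restriction(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tT\t60.0\t.\t.\tGT:DP:AD\t1/1:30:2,28\n"
            "chr1\t900\t.\tG\tC\t60.0\t.\t.\tGT:DP:AD\t1/1:30:2,28\n"
            "chr2\t100\t.\tA\tG\t60.0\t.\t.\tGT:DP:AD\t1/1:30:2,28\n"
        )
        path = write_vcf_text(tmp_path, body)
        assert len(var.read_vcf(path)) == 3
        assert len(var.read_vcf(path, region="chr1")) == 2
        assert [r.position for r in var.read_vcf(path, region="chr1:500-1000")] == [900]

    def test_unknown_region_chromosome_is_empty_with_warning(self, tmp_path, caplog):
        path = write_vcf_text(tmp_path, "")
        with caplog.at_level("WARNING"):
            assert var.read_vcf(path, region="chrZ") == []
        assert "chrZ" in caplog.text


class TestFilterPolicy:
    def test_depth_below_threshold_rejected(self):
        passing, rejected = var.filter_variants([rec(depth=4, alt_depth=4)])
        assert passing == [] and rejected["min_depth"] == 1

    def test_thresholds_are_inclusive(self):
        r = rec(depth=5, alt_depth=5, qual=20.0)
        passing, rejected = var.filter_variants([r])
        assert len(passing) == 1 and sum(rejected.values()) == 0

    def test_soft_mode_keeps_and_flags(self):
        policy = var.FilterPolicy(hard=False)
        out, rejected = var.filter_variants([rec(depth=4, alt_depth=4), rec(pos=200)], policy)
        assert len(out) == 2
        assert out[0].filters == ("min_depth",) and out[1].filters == ()
        assert rejected["min_depth"] == 1

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sort"):
            var.filter_variants([rec(pos=200), rec(pos=100, ref="G", alt="C")])

    def test_snp_gap_measured_against_indels_only(self):
        records = sorted(
            [
                rec(pos=100, ref="A", alt="T"),          # 2 bp from the indel: drop
                rec(pos=102, ref="AT", alt="A"),         # indel itself: kept
                rec(pos=105, ref="G", alt="C"),          # 3 bp away: kept
                rec(pos=200, ref="C", alt="G"),          # SNP near a SNP: kept
                rec(pos=201, ref="T", alt="A"),
            ],
            key=lambda r: r.position,
        )
        passing, rejected = var.filter_variants(records)
        assert [r.position for r in passing] == [102, 105, 200, 201]
        assert rejected["snp_gap"] == 1

    def test_hand_enumerated_ten_record_fixture(self, tmp_path):
        """Ten hand-written records against an independent manual application
        of the five rules (d=5, q=20, w=2, a=5, max-depth=140)."""
        body = (
            "chr1\t100\t.\tA\tT\t60.0\t.\t.\tGT:DP:AD\t1/1:30:2,28\n"   # pass
            "chr1\t300\t.\tG\tC\t60.0\t.\t.\tGT:DP:AD\t1/1:4:0,4\n"     # depth 4 < 5
            "chr1\t500\t.\tC\tG\t60.0\t.\t.\tGT:DP:AD\t1/1:141:3,138\n" # depth 141 > 140
            "chr1\t700\t.\tT\tA\t19.0\t.\t.\tGT:DP:AD\t1/1:30:2,28\n"   # qual 19 < 20
            "chr1\t900\t.\tA\tG\t60.0\t.\t.\tGT:DP:AD\t0/1:30:26,4\n"   # alt reads 4 < 5
            "chr1\t1100\t.\tA\tT\t60.0\t.\t.\tGT:DP:AD\t1/1:30:2,28\n"  # SNP 2 bp from indel
            "chr1\t1102\t.\tAT\tA\t60.0\t.\t.\tGT:DP:AD\t1/1:30:2,28\n" # indel: pass
            "chr1\t1200\t.\tG\tC\t20.0\t.\t.\tGT:DP:AD\t1/1:5:0,5\n"    # all at threshold
            "chr1\t1300\t.\tC\tCAA\t60.0\t.\t.\tGT:DP:AD\t1/1:4:0,4\n"  # indel depth 4 < 5
            "chr1\t1400\t.\tT\tG\t60.0\t.\t.\tGT:DP:AD\t1/1:140:5,135\n" # depth at max
        )
        records = var.read_vcf(write_vcf_text(tmp_path, body))
        policy = var.FilterPolicy(max_depth=140)
        passing, rejected = var.filter_variants(records, policy)
        assert [r.position for r in passing] == [100, 1102, 1200, 1400]
        assert rejected == {
            "min_depth": 2,
            "max_depth": 1,
            "min_quality": 1,
            "min_alt_bases": 1,
            "snp_gap": 1,
        }
        assert sum(rejected.values()) == len(records) - len(passing)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(
        st.tuples(
            st.integers(1, 500),      # position
            st.integers(0, 50),       # depth
            st.integers(0, 50),       # alt depth cap
            st.floats(0, 99),         # quality
            st.booleans(),            # indel?
        ),
        max_size=30,
    ))
    def test_filter_is_idempotent(self, raw):
        records = sorted(
            (
                var.VariantRecord(
                    "chr1", pos, "AT" if indel else "A", "A" if indel else "T",
                    "hom_alt", depth, min(depth, ad), qual,
                )
                for pos, depth, ad, qual, indel in raw
            ),
            key=lambda r: r.position,
        )
        passing, _ = var.filter_variants(records)
        again, rejected = var.filter_variants(passing)
        assert again == passing and sum(rejected.values()) == 0


class TestSvFilter:
    def sv(self, sv_type="deletion", start=1000, length=500, qual=200.0):
        return var.SvRecord("chr1", start, start + length, sv_type, qual)

    def test_short_deletion_rejected(self):
        assert var.filter_svs([self.sv(length=49)]) == []

    def test_quality_bound_is_strict(self):
        assert var.filter_svs([self.sv(qual=100.0)]) == []
        assert len(var.filter_svs([self.sv(qual=100.5)])) == 1

    def test_inversion_just_under_size_cap_retained(self):
        kept = var.filter_svs([self.sv("inversion", length=2_999_999, qual=150.0)])
        assert len(kept) == 1
        assert var.filter_svs([self.sv("inversion", length=3_000_000, qual=150.0)]) == []

    def test_deletion_bounds_inclusive(self):
        assert len(var.filter_svs([self.sv(length=50)])) == 1
        assert len(var.filter_svs([self.sv(length=100_000)])) == 1
        assert var.filter_svs([self.sv(length=100_001)]) == []


class TestPrivateVariants:
    def panel_of(self, *key_sets):
        lines = {}
        for i, keys in enumerate(key_sets):
            lines[f"l{i}"] = [rec(pos=p) for p in sorted(keys)]
        return var.VariantPanel(lines)

    def test_key_in_one_of_three_lines_is_private(self):
        panel = self.panel_of({100, 200}, {200}, {200, 300})
        private = var.private_variants(panel)
        assert {k[1] for k in private["l0"]} == {100}
        assert private["l1"] == set()
        assert {k[1] for k in private["l2"]} == {300}

    def test_single_line_panel_rejected(self):
        with pytest.raises(ValueError, match="2 lines"):
            var.private_variants(self.panel_of({100}))

    def test_matches_bruteforce_tally_and_line_order(self):
        rng = random.Random(9)
        key_sets = [set(rng.sample(range(1, 400), 40)) for _ in range(5)]
        panel = self.panel_of(*key_sets)
        private = var.private_variants(panel)
        for i, keys in enumerate(key_sets):
            brute = {
                p for p in keys
                if sum(p in other for other in key_sets) == 1
            }
            assert {k[1] for k in private[f"l{i}"]} == brute
        # permutation invariance
        reordered = var.VariantPanel(
            {lid: panel.records(lid) for lid in reversed(panel.line_ids)}
        )
        assert var.private_variants(reordered) == private


class TestLineSummary:
    def test_empty_input(self):
        s = var.summarize_line([], chrom_length=1_000_000)
        assert s.snp_count == 0 and s.snp_density_per_kb == 0.0

    def test_density_arithmetic(self):
        records = [rec(pos=p) for p in range(1, 8201)]
        s = var.summarize_line(records, chrom_length=1_000_000)
        assert s.snp_density_per_kb == pytest.approx(8.2)

    def test_catalog_split_recovers_planted_half(self):
        records = [rec(pos=p) for p in range(1, 101)]
        catalog = {r.key for r in records[:50]}
        s = var.summarize_line(records, 1_000_000, catalog=catalog)
        assert s.known_count == 50 and s.novel_count == 50
        assert s.known_count + s.novel_count == len(records)

    def test_het_hom_fractions_sum_to_one(self):
        records = [rec(pos=1), rec(pos=2, geno="het", alt_depth=15), rec(pos=3)]
        s = var.summarize_line(records, 1000)
        assert s.hom_fraction + s.het_fraction == pytest.approx(1.0)
        assert s.het_fraction == pytest.approx(1 / 3)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError, match="chrom_length"):
            var.summarize_line([], chrom_length=0)
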