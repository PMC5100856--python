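# Methods

This note describes the models and procedures implemented in `consomix`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Setting

A chromosome substitution (consomic) line carries one donor chromosome on
an otherwise recipient-strain background, produced by repeated backcrossing
followed by sib mating. Whole-genome variant calls against the recipient's
reference separate the two compartments cleanly: the donor chromosome is
variant-dense (wild house mice run on the order of 8 SNP/kb against the
C57BL/6J-derived reference), while a clean background chromosome is nearly
variant-free. Everything in this package works from that contrast and from
per-line variant sets keyed as `(chromosome, position, ref, alt)` after
reference-free minimal-representation normalization (shared suffix trimmed,
then shared prefix, position advanced accordingly; full left-alignment
would require the reference FASTA, which no stage here needs).

## Variant hard filtering

Short-variant calls pass iff

    depth >= d     (default 5)
    depth <= max   (per-line, e.g. 100/120/140 depending on coverage)
    quality >= q   (default 20)
    alt reads >= a (default 5)
    and, for SNPs: no indel within w bp (default 2) in the same call set

Thresholds are inclusive. The SNP-near-indel rule mirrors the vcftools
`vcf-annotate` SnpGap semantics: alignment around indels is unreliable, so
SNPs within `w` bp of any indel in the same line are removed. A record
failing several rules is attributed to the first failing rule in the fixed
order depth → max-depth → quality → alt-reads → snp-gap, so per-rule
rejection counts are deterministic and sum to the rejected total. With
`hard=False` failing records are annotated instead of removed.

Structural variants are post-filtered only (discovery is out of scope):
quality strictly greater than 100 for every type; deletions 50–100,000 bp
inclusive; duplications and inversions below 3,000,000 bp.

## Subspecies-origin painting

The donor chromosome is tiled into fixed windows (default 10 kb; a
195,471,971-bp chromosome gives 19,548 windows, the final one partial). For
each window and each of three wild-derived reference strains (musculus→PWK,
castaneus→CAST, domesticus→WSB) the mismatch count is the size of the
symmetric difference of the homozygous SNP key sets in the window. For
SNP-only consensus sequences over a shared reference this equals the
base-by-base consensus mismatch count, so no sequence I/O is needed.
Percent similarity is `(window_length − mismatches) / window_length`, with
the partial final window using its true length.

A window's label is the lineage with the highest similarity, except:

* if at least two strains show fewer than `min_diff_snps` (default 5)
  differences, the window cannot discriminate — this is the signature of
  intersubspecies introgression among the reference strains or of missing
  signal — and it is left undetermined;
* an exact tie for the maximum similarity is also undetermined (no basis
  for preference).

Heterozygous and missing sites contribute nothing (phasing is out of
scope; the lines are inbred). Indels are excluded from similarity.
Contribution summaries are fractions over determinate windows, which
therefore sum to 1.

## Four-gamete haplotype blocks

Each inbred line contributes one haplotype; heterozygous calls are treated
as missing, and sites that are monomorphic or carry the alternate allele in
fewer than two lines are dropped (they can never complete a fourth gamete).
Two SNPs are *recombinant* iff, over lines non-missing at both, all four
two-locus gamete types are observed, each with frequency at least
`freq_threshold` (default 0.01, the Haploview GAM default — with ~18
haplotypes any observed gamete clears it, so a minimum count of 1 is the
effective rule). Blocks are built greedily left to right: a block absorbs
the next SNP iff it is pairwise compatible with every SNP already in the
block. This all-pairs rule (not consecutive-pairs) is deterministic and
matches the four-gamete block definition; the inner test runs on per-SNP
carrier bitmasks, so the sweep is linear-time per comparison.

Scanning is region-wise (default: consecutive chunks of 10,000 SNPs,
roughly 0.5 Mb at wild-mouse density); blocks never span region
boundaries. Block length is `end_bp − start_bp + 1` over the member SNPs.
Hotspot regions are those whose block count exceeds mean + 2·SD (sample SD,
n−1) over all scanned regions; at least 3 regions are required.

## Background contamination QC

The genome is tiled into 100-kb windows and per-window SNP counts are
computed from filtered calls. The donor chromosome provides the yardstick:
`lower = max(0, mean − 2·SD)` over its windows (sample SD). A background
window with count strictly above `lower` is residual wild-donor sequence;
consecutive flagged windows merge into one island (a gap tolerance in
windows is exposed, default 0). The contamination fraction is flagged
length over total background length. Conversely, runs of at least
`min_run_windows` (default 5, i.e. 500 kb — real recipient segments are
multi-Mb) donor windows at or below `lower` are recipient-strain segments,
classified proximal/internal/distal by position.

A resolution caveat that matters at small scale: detection is quantized to
whole 100-kb windows, and a window at exactly donor-level density falls
below a mean−2·SD boundary with probability ≈ 2.3% by construction. On a
full genome (hundreds of windows per island, thousands of background
windows) this is negligible, but on the desk-scale test genome a single
window is 2.5 percentage points of a 4-Mb background, so the recovery
tests bridge single-window dropouts (`max_gap_windows=1` — the bridged
window is itself island truth) and evaluate at fixed study seeds.

## Sanger concordance

Gold (capillary-sequenced) and test (WGS) call sets are intersected on
normalized keys, optionally restricted to merged evaluation intervals.
Gold-only calls are false negatives, test-only calls false positives;
`fn_rate = FN / n_gold`. Two false-positive conventions are reported:
`FP / n_test` (all test calls in the evaluated intervals) and
`FP / n_gold` (the validated-set convention, the one under which published
validation experiments of this kind typically quote their rate — e.g. 352
validated SNPs all confirmed plus 2 extra WGS calls gives 2/352 = 0.57%
against the validated set and 2/354 = 0.56% against all test calls).
Position-only matching is available for gold sets lacking allele detail.

## Synthetic panels

The generator emulates the genome structure the analyses are built for,
with all randomness flowing from one seed:

* **Founders.** Each lineage has a per-bp divergence rate (default 0.0082,
  matching ~8.2 SNP/kb wild-donor density). Lineage *core* sites are drawn
  binomially at `rate × (1 − founder_private_frac)`; each founder adds
  private sites at `rate × founder_private_frac` (default fraction 0.1).
  Founders within a lineage are therefore similar (differing at ~20% of
  the rate) and distinct between lineages (differing at ~2× the rate).
  Alleles are abstract: ref and alt bases are deterministic functions of
  position, so any two haplotypes carrying a site carry the same allele and
  set arithmetic equals consensus comparison. One founder per lineage
  doubles as that lineage's reference strain for painting.
* **Donor mosaic.** Lineage segments with exponential lengths (mean
  `ancestry_segment_mean_bp`, default 300 kb, optional floor, truncated at
  chromosome ends — a memoryless stand-in for accumulated historical
  recombination, not a pedigree model); within a segment the haplotype
  switches among that lineage's founders at a finer exponential spacing
  (`founder_switch_mean_bp`, default 30 kb), giving the sub-100-kb
  four-gamete block scale. The two levels give recoverable truth at both
  the 10-kb painting scale and the block scale.
* **Background.** Variant-free except islands (count ~
  Poisson(`island_rate_per_line`, default 0.8); lengths exponential, mean
  200 kb, so a few percent of the background — the observed contamination
  range for seven-generation backcross panels) copied from a random
  founder. Explicit island or recipient-segment placement can be supplied
  for truth-controlled experiments.
* **Genotypes.** A `het_fraction` (default 0.026, matching the ~2.6%
  residual heterozygosity of nearly-fixed inbred lines) of emitted sites
  are heterozygous; DP is Poisson around `depth_mean` (30), alt depth
  binomial (p = 0.98 hom / 0.5 het), QUAL normal around `qual_mean` (60).

Default test genome: three 2-Mb chromosomes with chr1 as donor — small
enough that the full suite runs in well under a minute per stage while
every window, block and island statistic still has hundreds of units.

What the generator does **not** emulate: coalescent or pedigree-exact
breeding structure, linkage disequilibrium within founder haplotypes,
sequencing reads (hence no mapping artifacts; depth/quality are
parametric), structural variants (SV filtering is tested on hand-written
records), recombination-rate heterogeneity along the chromosome, and sex
chromosomes. Passing recovery tests therefore demonstrate correctness of
the window arithmetic, set logic and detection rules under realistic
densities and scales — not robustness to alignment artifacts or to
reference bias in real data.

## Numerical and design choices

* Window and interval coordinates are 0-based half-open internally and in
  BED output; VCF positions are 1-based.
* Sample SD (n−1) everywhere a boundary or hotspot threshold is computed.
* Island flagging is strictly `> lower`; recipient flagging is the
  complementary `<= lower`.
* Similarity ties and sub-threshold ambiguity both map to "undetermined";
  the call records which rule fired.
* Variant identity ignores genotype: a site het in one line and hom in
  another is the same key for privacy/novelty, but het sites are excluded
  from painting and from the haplotype matrix.
* The greedy block partition is the only partition consistent with
  left-to-right maximal extension, so determinism needs no tie-breaks.
* `region_snps` defaults to 10,000 (the ~0.5-Mb regions used in practice);
  the desk-scale tests use 1,000 so that multiple regions exist on a 2-Mb
  chromosome.

## Known limitations

* The four-gamete sweep is quadratic in block length in the worst case
  (a panel with no recombination evidence); region chunking bounds this.
* Reference-free normalization cannot left-align indels across repeats;
  two spellings of the same indel separated by a repeat unit remain
  distinct keys.
* The mean−2SD boundary assumes the donor chromosome is fully wild-derived;
  a donor chromosome with large recipient segments inflates the SD and
  lowers the boundary (recipient segments should be masked before deriving
  boundaries on heavily recombined lines).
* Contamination fractions are window-quantized; sub-window islands are
  invisible and island edges are resolved to 100 kb.
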