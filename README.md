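# consomix

Genome characterization of chromosome substitution strains (consomic lines):
inbred lines in which one full chromosome of a recipient strain (typically
C57BL/6J) has been replaced by the homologous chromosome of a donor — here,
wild house mice. `consomix` implements the analyses needed to verify and
describe such a panel from per-line variant calls:

* **variants** — hard filtering of SNP/indel calls (minimum depth *d*,
  per-line maximum depth, minimum quality *q*, SNP-near-indel window *w*,
  minimum alternate-supporting reads *a*), structural-variant post-filters,
  and per-line/panel summaries (private variants, hom/het split, SNP
  density, known/novel split against a catalog of described sites).
* **ancestry** — subspecies-origin painting of the donor chromosome:
  each 10-kb window is labeled *M. m. musculus*, *M. m. castaneus* or
  *M. m. domesticus* by percent similarity to three wild-derived reference
  strains (PWK, CAST, WSB), with windows showing fewer than 5 SNP
  differences to at least two strains (intersubspecies introgression) or an
  exact similarity tie left undetermined.
* **hapblocks** — haplotype-block partitioning of the panel's donor
  chromosomes by the four-gamete rule (two SNPs are recombinant iff all four
  two-locus gamete types are observed), with block-length statistics and
  mean+2SD recombination-hotspot flagging.
* **backgroundqc** — residual "wild island" contamination on background
  chromosomes, detected as 100-kb windows whose SNP count exceeds the lower
  boundary mean − 2·SD derived from the donor chromosome, and recipient
  (B6-like) segments on the donor chromosome as low-density runs.
* **concordance** — false-negative/false-positive rates of pipeline calls
  against a gold-standard (Sanger-validated) call set, plus a consolidated
  report.
* **simulate** — a truth-tracked generator of synthetic substitution-line
  panels (founder haplotypes per lineage, two-level donor mosaic,
  contaminated backgrounds), so every stage can be tested end-to-end with
  known ground truth and no external data.

## Worked example

```python
from consomix import simulate as sim
from consomix import ancestry, variants

cfg = sim.SimConfig(seed=11, n_lines=6, ancestry_segment_min_bp=50_000,
                    island_rate_per_line=0.0)
founders = sim.simulate_founders(cfg)
strains = {lin: sim.founder_records(founders[lin][0], "chr1")
           for lin in cfg.lineages}

line_id, records, truth = sim.simulate_panel(cfg)[0]
kept, _ = variants.filter_variants(records)
calls, summary = ancestry.paint_chromosome(kept, strains, "chr1",
                                           cfg.chrom_lengths["chr1"],
                                           line_id=line_id)
print(f"{summary.n_windows} windows, "
      f"{summary.determinate_fraction:.1%} determinate")
for lin, frac in summary.fractions.items():
    print(f"  {lin:<11} {frac:.1%}")
```

prints

```
200 windows, 100.0% determinate
  musculus    20.0%
  castaneus   15.5%
  domesticus  64.5%
```

i.e. the 2-Mb donor chromosome of line L01 tiles into 200 10-kb windows,
every window is assignable, and this line's donor chromosome is a mosaic of
all three subspecies (here dominated by a long domesticus segment; each
line draws its own mosaic). The same objects feed the other stages:
`hapblocks.HaplotypeMatrix.from_panel(...)` for block partitioning and
`backgroundqc.density_track(...)` for contamination QC.

A shell workflow is available through the `consomix` command
(`simulate`, `variants`, `ancestry`, `hapblocks`, `background`,
`concordance`, and the `run` umbrella over a YAML config).

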