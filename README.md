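# regionkb

Archiving, overlap analysis and overlap significance for genomic region
sets — ChIP-seq/ChIP-chip peaks, histone-mark domains, or any other
interval catalogue.

Identifying where two transcription factors bind the same DNA, or where a
histone mark coincides with a binding event, is a routine question in
regulatory genomics. Answering it well needs three things this package
provides behind one scriptable library and CLI:

1. **An archive.** Region datasets (BED/GFF) are imported with their
   metadata — organism, cell line, factor, condition, peak caller, genome
   build — into an embedded SQLite knowledge base. Only datasets of one
   genome build can be active at a time, so every comparison is coherent.
2. **Overlap analyses.** Pairwise and multi-set overlap under a *signed*
   minimum-bp-overlap threshold (positive = required shared bases,
   negative = allowed separation, for factors that bind nearby without
   touching) and an optional maximum centre distance. Analyses report
   matching regions, complements, per-pair intersection *sections*,
   directional percentages, and 2–3-way Venn zone counts.
3. **A significance test.** For each query region of length *L*, the null
   model places an interval of length *L* uniformly over every start
   position inside a background *domain* (whole genome, promoter windows,
   intergenic space, or a custom BED). The per-region p-value is

   *p* = (# placements whose distance to the nearest in-domain reference ≤
   the observed distance) / (# valid placements),

   an exact integer ratio. The **Overlap Correlation Value (OCV)** is the
   fraction of query regions with *p* < 0.05 (configurable); values near 1
   mean strong colocalisation, and the mean of the two directional OCVs
   summarises a comparison.

Gene annotation (strand-aware signed distances to TSS and TES, with
negative meaning upstream in gene orientation) and proximal-feature queries
(archived regions near a locus or a gene's TSS/CDS) round out the toolkit.

## Worked example

Everything below runs on a seeded synthetic study: a base set of 800
"factorA" peaks on a 16.1 Mb toy genome, a "factorB" set of 600 peaks of
which 60% are planted within 50 bp of factorA peaks, and an unrelated
"factorC" set.

```python
import regionkb as rk
from regionkb.simulate import SimSpec, TOY_CHROM_SIZES, simulate_region_set, plant_overlap_structure

A = simulate_region_set(SimSpec(n_regions=800, seed=1), label="factorA")
B = plant_overlap_structure(A, SimSpec(n_regions=600, seed=2,
                                       overlap_fraction=0.6, jitter=50), label="factorB")

params = rk.OverlapParams(min_bp_overlap=1)
print(len(rk.regions_overlapping(A, B, params)))      # A peaks overlapping B
print(len(rk.overlap_sections(A, B, params)))         # per-pair intersection sections

domain = rk.build_genome_domain(TOY_CHROM_SIZES)
fwd, rev = rk.run_significance(A, B, domain), rk.run_significance(B, A, domain)
print(rk.ocv(fwd).ocv, rk.ocv(rev).ocv, rk.average_ocv(rk.ocv(fwd), rk.ocv(rev)))
```

With the seeds used by `scripts/acceptance.py --seed 1` this prints 297
overlapping regions but 374 sections — the section count exceeds the region
count because single peaks can intersect several partners — and directional
OCVs of 0.395 (A→B) and 0.615 (B→A), averaging 0.505. An average OCV above
0.5 indicates statistically significant colocalisation; the unrelated
factorC comparison averages 0.052, and a null calibration (2000 independent
uniform queries against 500 references) yields OCV 0.044, close to the 0.05
threshold as expected when nothing is planted.

The same analyses are available from the shell:

```sh
regionkb --store kb.sqlite import --file peaks.bed --format bed --build hg19 --label FoxA1
regionkb --store kb.sqlite overlap --mode d --a 1 --b 2 --min-bp 1
regionkb --store kb.sqlite stats --query 1 --ref 2 --domain whole_genome \
         --chrom-sizes hg19.chrom.sizes --both-directions
regionkb --store kb.sqlite venn --ids 1,2,3 --min-bp 1
```

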