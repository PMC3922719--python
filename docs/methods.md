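# Methods

## Coordinate model

All internal coordinates are 0-based half-open `[start, end)` (the BED
convention). GFF input (1-based inclusive) is converted at the parser
boundary: `start - 1`, `end` unchanged — the standard equivalence — and
never re-converted downstream. Records with `end < start` are classified
"inverted" and `end == start` "empty"; both are excluded from validated
region sets and surface either in the import report or through the
archive-hygiene scan (`find_invalid_regions`, which flags only the
inverted case, mirroring the classic `end < start` SQL check).

Import is line-forgiving but strictly accounted: every non-blank line
becomes either a validated interval or a failed record with a reason
(headers, track lines, wrong column count, non-numeric coordinates,
inverted/empty spans), and `n_imported + n_failed` always equals the
non-blank line count. An upload whose first 50 lines contain no valid
record is aborted — a cheap guard against uploading prose or the wrong
format wholesale. Blank lines are skipped silently. Delimiter
auto-detection tries tab first, then comma; an explicit flag overrides.

## The matching rule

Two regions on the same chromosome are compared through

- `bp_overlap(a, b) = min(ends) − max(starts)` — positive = shared bases,
  0 = bookended, negative = gap of that magnitude;
- `centre_distance(a, b) = |⌊(a.start+a.end)/2⌋ − ⌊(b.start+b.end)/2⌋|` —
  floor midpoints, so odd-length regions have a well-defined integer
  centre.

A pair qualifies when `bp_overlap ≥ min_bp_overlap` and, if set,
`centre_distance ≤ max_centre_distance`. The single-threshold reading
means a negative `min_bp_overlap` (proximity mode) also admits genuinely
overlapping pairs — the only semantics consistent with one signed
parameter covering both "bases in common" and "bases separating". For the
alternative reading (neighbours that must *not* touch) the
`exclusive_proximity` flag additionally requires `bp_overlap ≤ 0`; it is
off by default. Cross-chromosome pairs never match; chromosome names are
compared as exact strings.

The production matcher uses a per-chromosome interval tree over the
reference set, querying with the probe widened by the admissible gap plus
one so bookended and separated candidates surface; every candidate is then
re-checked with the exact rule. The O(n²) all-pairs enumeration is kept in
`regionkb.simulate` purely as a test oracle.

Analysis semantics that deserve a note:

- *Matching regions vs pairs.* Without the "extract both" flag each A
  region is reported once no matter how many partners it has; with the
  flag one row per qualifying pair is emitted. Sections (the intersection
  `[max(starts), min(ends))` of a qualifying pair) are inherently per-pair,
  which is why a section count can exceed the matching-region count.
  Exact-duplicate sections (identical coordinates) are collapsed;
  overlapping-but-distinct sections from different pairs are kept.
- *Three-way sections* are computed pairwise-then-third: sections of the
  first two sets (after duplicate collapse) are intersected with the third
  under the same parameters. The result depends on the order given, which
  the output records.
- *Venn zone counts* are region counts relative to the first-named set of
  each pair, and the triple zone is the three-way section count; both are
  therefore order-dependent, with the reference order printed in the
  legend. When a Venn is requested in proximity mode (negative threshold)
  the triple zone falls back to a 1-bp section rule, since intersection
  intervals are undefined for disjoint pairs. The diagram is a fixed-layout
  three-circle rendering with the counts as text; the text block is the
  authoritative output.

## Placement significance

For a query region of length `L`, the null model places an interval of
length `L` uniformly over every start position that keeps it fully inside
a single domain interval. With the observed distance `d` to the nearest
in-domain reference (gap size; 0 when overlapping or bookended),

```
denominator = Σ_domain max(0, len − L + 1)
numerator   = # valid starts s with  distance([s, s+L), nearest ref) ≤ d
p           = numerator / denominator
```

A placement is within distance `d` of reference `[r0, r1)` iff
`r0 − d − L ≤ s ≤ r1 + d`, so the numerator is the size of the union of
those per-reference windows intersected with the valid-start space — exact
integer arithmetic, no approximation. The observed placement is always
favorable, so `1/denominator ≤ p ≤ 1`. An exhaustive enumeration oracle
(walk every start, scan every reference) validates the interval arithmetic
on small domains in the test suite.

Containment is strict: both query and reference regions must lie fully
inside a single domain interval to participate (dropped counts are
reported), placements never straddle domain pieces, and references outside
the domain are invisible to the nearest-reference search. Nearest-reference
ties break to the lower `(start, end)`. Query regions on chromosomes with
no in-domain reference are skipped with a warning and excluded from the
tested count. Placements on such chromosomes still enter the denominator
but can never be favorable — the genome-wide placement measure does not
condition on the query's chromosome.

The OCV is the fraction of tested query regions with `p` strictly below
the threshold (default 0.05, overridable per call, via the CLI, or via the
`p_threshold` key of the config file). The statistic is directional; both
directions and their arithmetic mean are always available, and an average
above 0.5 is read as significant colocalisation.

Prebuilt domains: whole genome (`[0, size)` per chromosome from a
chromosome-sizes table), promoters (TSS ± 10 kb by default, clipped to
chromosome bounds and merged), and intergenic (complement of merged
transcript bodies). Custom domains come from any BED file; domain
intervals are always merged to disjointness on construction.

## Annotation conventions

`txStart < txEnd` are positional extremes on either strand, so the strand
decides which end is the TSS. Signed distances are measured from the
region's floor midpoint — the same point the proximal-feature queries use —
with negative meaning upstream in gene orientation: for centre `c`,
`bpTSS = c − txStart`, `bpTES = c − txEnd` on `+`; `bpTSS = txEnd − c`,
`bpTES = txStart − c` on `−`. Two consequences are used as test
invariants: an intragenic region has opposite-signed bpTSS/bpTES on either
strand, and `|bpTSS − bpTES|` always equals the transcript length.

A gene qualifies for a region when `|bpTSS| ≤ max_tss` **or**
`|bpTES| ≤ max_tes` — an OR, chosen to maximise recall since both signed
distances are reported for downstream filtering. Nearest-gene mode keeps
the qualifying gene minimising `min(|bpTSS|, |bpTES|)`, ties broken by
gene symbol for determinism. Regions with no qualifying gene produce no
output row; their count is logged. Custom gene tables need only
chromosome, strand and the two transcript coordinates (CDS defaults to the
transcript span); UCSC refFlat-style tables map all fields including
exons. The CDS anchor for proximal queries is the strand-aware translation
start (`cdsStart` on `+`, `cdsEnd` on `−`).

## Knowledge base

A single SQLite file holds `kbdetails` (metadata + active flag),
`kbsites` (regions keyed by dataset identity) and `annotation` (gene
models keyed by assembly, with a custom flag for bulk deletion). Dataset
identities are monotone increasing and never reused. Activation enforces
the single-build invariant: an activation that would leave the active set
spanning two builds fails naming the conflicting builds; deactivation is
always allowed. The start-coordinate window query (`query_window`)
deliberately filters on `start ∈ [lo, hi]` only — it is the archive-query
idiom, distinct from the overlap analyses. Saved analysis results re-enter
the store as ordinary datasets inheriting the parents' build, with the
derivation recorded in the notes. `vacuum` compacts the store file; an
embedded database has no transaction log to truncate, so that is all the
housekeeping there is.

## Synthetic data and study conditions

The toy genome is three chromosomes of 10, 5 and 1 Mb — large enough for
realistic peak densities, small enough that enumeration oracles stay
sub-second. Default region sets are 500 regions of 50–500 bp (typical
ChIP-seq peak sizes) with length-weighted uniform chromosome assignment
and uniform starts. Planted-overlap sets copy sampled base regions shifted
by at most `jitter` bp, which guarantees ≥1 bp of overlap whenever the
jitter is below the region size; the remainder is placed uniformly.

The calibration study uses 2000 query regions against a 500-region
reference set on the whole-genome toy domain. The reference density
matters: the minimum achievable p-value for an overlapping query is
roughly `n_ref × (ref_len + L) / genome`, ≈ 0.017 here, comfortably below
the 0.05 threshold, so planted overlaps are all detected (OCV 1.0) while
independent queries give OCV ≈ 0.05 (the p-values are the CDF of the
observed distance under the placement measure, hence near-uniform up to
discreteness, which makes the OCV mildly conservative). A denser reference
set would raise the p-value floor above the threshold and the OCV would
lose power by construction, not by implementation error.

What the generator does **not** emulate: peak-width/intensity
correlations, chromatin-driven clustering of binding sites, mappability
gaps, or chromosome-specific biases. Passing calibration therefore shows
the statistic behaves correctly under its own null, not that real binding
data satisfy that null — which is exactly why the domain restriction
exists (promoter-biased detection can be conditioned away by choosing the
promoter domain as background).

## Problem sizes in the test suite

The oracle-equivalence sweep checks 50 seeded random pairs of 50–250
regions per side across the full parameter grid (min bp overlap in
{−100, 0, 1, 50} × centre cap in {none, 50, 1000}); placement exactness
checks 100 random configurations on domains up to 10 kb against full
enumeration; calibration runs the 2000-query study described above. The
complete suite runs in well under a minute on one CPU. An independent
cross-check against `bedtools intersect -u` guards the 1-bp overlap
semantics against convention drift.

## Known limitations

- No base-pair-level (merged-bases) Jaccard statistics; counts are per
  region or per section by design.
- No multiple-testing correction across per-region p-values; the OCV is a
  descriptive summary, not a corrected family of tests.
- No liftover: datasets of different builds are simply not comparable, and
  the knowledge base enforces that rather than working around it.
- Venn layouts are schematic (fixed circles), not proportional-area.
- The placement model assumes a uniform placement measure within the
  domain; known biases must be expressed through the domain choice.
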