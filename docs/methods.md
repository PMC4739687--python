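# Methods

`superbsa` implements a pooled trait-mapping workflow for an F2 cross
between two homozygous, phenotypically diverged melon parents: parental
variant triage, restriction-fragment (SLAF-style) marker construction,
a bulk allele-depth ratio statistic over extreme-phenotype pools,
consecutive-marker candidate-region calling, chromosome anchoring, and
candidate-gene intersection. A seeded simulator generates every input
the pipeline consumes, so the whole workflow runs without external
data.

## The mapping statistic

Each marker locus carries one maternal (M, sweet parent) and one
paternal (P, sour parent) allele. Pooled sequencing of three 50-plant
F2 bulks — sweet, sour, and non-sweet non-sour (nsns) — yields per-bulk
allele depths, from which two ratios are formed:

    Ratio_sweet = M_sweet / P_nsns
    Ratio_sour  = P_sour  / M_nsns

A zero denominator maps the ratio to a sentinel value of 1000. A marker
is *differential* for a trait when its ratio is at least 3. For
plotting, ratios are capped at a display value of 20; the cap never
affects the differential decision. Maximal runs of at least `min_run`
consecutive differential markers on one scaffold become candidate
regions, with bounds rounded outward to 1 kb (start floored, end
ceiled) and an overlapping-gene count attached.

`min_run` defaults to 2 because the published candidate-region tables
contain several two-marker regions, although the accompanying text
describes a three-in-succession rule; `min_run=3` applies the stricter
text rule.

### What each ratio localizes

This deserves emphasis because it is easy to misread. Each ratio
divides the depth of one parental allele in one selected pool by the
depth of the *other* parental allele in the reference (nsns) pool. The
ratio is therefore large exactly where *both* pools involved are
enriched for the same parental allele. The sweet and nsns pools share
the "non-sour" side of the phenotype space (both qualified at pH above
5.3), so `Ratio_sweet` rises at pH-determining loci. The sour and nsns
pools share the "non-sweet" side (both TSS below 8), so `Ratio_sour`
rises at TSS-determining loci. At a TSS QTL, the nsns pool is fixed for
the paternal allele, making `P_nsns` large and `Ratio_sweet` close to
1 — a sweetness locus does not produce a sweet-ratio signal. The
package reports parameter recovery with this pairing
(`PipelineResult.recovered_scaffolds`), and the simulation study
confirms it: TSS-QTL scaffolds are recovered by sour-ratio regions and
pH-QTL scaffolds (less reliably, see below) by sweet-ratio regions.

## Variant triage rules

SNP calls are kept iff depth >= 2 (homozygous; >= 3 heterozygous),
depth <= 3x the sample mean depth, and the site is outside the repeat
mask. The mean depth is a caller-supplied parameter because the source
material uses both ~11x and ~13x for the same samples. Structural
variants are valid iff depth lies in [2, 100] and quality is strictly
above 20. Transitions are C<->T and G<->A; everything else is a
transversion. Coding effects are computed by translating the spliced
CDS before and after the substitution with the standard genetic code
(strand-aware); no organellar codes are considered. Differential sites
between the homozygous parents include sites called in only one parent
(the other matching the reference) and sites with discordant alternate
alleles. A gene is *polymorphic* iff it contains a differential
non-synonymous SNP or a validated exonic SV/indel.

## SLAF locus construction

Tags are fixed-length (80 bp) sequences. Loci are built by greedy
single-linkage clustering at > 90 % ungapped identity, processed in
lexicographic sequence order; under single linkage this equals the
transitive closure of the pairwise relation and is input-order
invariant (verified against a union-find oracle). A locus with more
than 4 distinct tags is repetitive (a diploid carries at most four);
loci below the depth floor are low-depth. Both published depth floors
are exposed: `min_depth` (default 10, the selection threshold) and
`low_depth_cutoff` (default off, the stricter 164-read rule) — the two
cannot be reconciled from the source text, so both are parameters.
Marker categories: one tag = no polymorphism; substitution-only
differences = SNP, upgraded to EPSNP when a substitution falls inside
an enzyme recognition site (EPSNP is undefined in the source material;
enzyme-site polymorphism is this package's interpretation, consistent
with the category name); length differences = INDEL; tags matching
neither parent = unknown.

## Anchoring

Markers are placed on chromosome assemblies by seed-and-extend search:
16 bp exact seeds tiled across the marker, ungapped extension, identity
threshold 0.9, both strands. Markers hitting more than `max_hits`
(default 2, a literal reading of "more than two different locations")
distinct places are discarded as promiscuous. Best-hit ties keep the
lexicographically smallest (chromosome, start) and are logged. This is
a deliberate, documented stand-in for BLAT-style alignment: scoring is
not reproduced, and near-exact synthetic markers do not need it.

## The simulator

`make_genome` lays non-overlapping gene models (CDS length a multiple
of 3, 1–3 exons) on uniform-random scaffolds and drops disjoint 500 bp
repeat blocks to a target coverage (realised within ±5 %).
`make_parents` plants homozygous SNPs (Poisson per scaffold), indels
and SVs, assigning each variant's non-reference allele to one parent,
so every planted variant is differential; each QTL position carries a
discriminating SNP with the alternate allele on the sweet parent.
Haplotype strings keep reference length (substitutions applied in
place; indel/SV records keep reference coordinates) so one coordinate
system serves the whole pipeline. Deletions are resampled away from
QTLs; user-supplied configurations that would delete a QTL are
rejected.

Meiosis uses a no-interference (Haldane) model: crossover counts are
Poisson per scaffold (default 0.5 expected crossovers) at uniform
positions, starting phase a fair coin. F2 genotypes count sweet-parent
allele copies per truth SNP site and converge to 1:2:1.

Pooled depths are drawn per locus and pool from a negative binomial
(mean 160, overdispersion alpha 0.15; alpha = 0 degenerates to
Poisson) because pooled reduced-representation depth is overdispersed;
reads split binomially at the pool's true allele frequency, then flip
at the sequencing error rate (default 0.001). Parental pools are fixed
for their own allele up to error. Parental resequencing depth defaults
to 13x.

### Trait architecture and its constraints

Each trait has four unlinked QTLs of equal effect placed in the middle
third of distinct scaffolds. Effects reproduce the parental means
exactly: TSS = 6.8 + 8 x 0.7375 = 12.7 Brix; pH = 4.4 + 8 x 0.2125 =
6.1. Phenotype = baseline + per-QTL contribution (2e for the sweet
homozygote, 2e·d for the heterozygote, 0 otherwise) + Gaussian
residual.

The dominance d and residual sd cannot be chosen freely: the pooling
design requires that the fixed class thresholds (TSS 8, pH 5.3) cut a
500-plant F2 into classes large enough to fill three 50-plant pools,
i.e. roughly a quarter of plants below TSS 8 — while phenotype ranks
must still track genotype for pool selection to shift allele
frequencies. With four equal-effect loci these requirements are
incompatible with an F2 TSS mean of 10.9: a mean that high forces
heterozygotes well above the TSS 8 threshold, capping the non-sweet
class near 10 % however the residual sd is set (and inflating the sd
instead destroys the genotype–phenotype coupling). The published
phenotype table carries the same internal tension (F2 mean 10.9 ± 0.9
yet 100+ of ~514 plants below TSS 8). The defaults here resolve it in
favour of a functioning design: TSS d = 0.25 (partial recessivity of
sweetness), residual sd 0.8, giving an F2 TSS mean near 9.0; pH is
purely additive (d = 0.5), residual sd 0.5, F2 mean near 5.2. The
acceptance suite asserts the published F2 mean bands as stated; the
TSS band fails under these defaults and is reported as measured —
that failure is a property of the constraint system, not a bug, and
no parameter set satisfies all constraints simultaneously.

Pool qualification uses the feasible class rules (sweet: TSS >= 8 and
pH > 5.3; sour: TSS < 8 and pH <= 5.3; nsns: TSS < 8 and pH > 5.3) —
the stricter pool thresholds also printed in the source (e.g. pH > 6
for the sweet pool) admit almost no plants under its own F2
distribution. Orderings: sweet pool by TSS descending, sour by pH
ascending, nsns by joint extremeness (TSS-ascending plus pH-descending
rank sum), since the nsns pool appears in both ratio denominators.

### What the simulator does and does not emulate

It emulates: homozygous diverged parents, Mendelian F2 segregation
with recombination, threshold-plus-extremeness pool selection,
selection-induced pooled allele-frequency skew, overdispersed pooled
depth, and sequencing error. It does not emulate: read-level data
(depth tables are the interface), PCR/GC bias, repeat-induced
mismapping, genotyping error correlated across pools, season effects
(beyond a configurable baseline), or epistasis. Passing recovery tests
therefore show that the statistic and region-caller behave correctly
under the design's own assumptions — not that the thresholds are
optimal for real data, where marker noise is more structured.

## Numerical and degenerate-input choices

Coordinates are 1-based inclusive internally; exporters convert (BED
0-based half-open, GFF3/VCF 1-based). A 0/0 depth ratio takes the
sentinel (the zero-denominator rule applied first) and is logged as
unreliable. Region bounds rounding: start floor, end ceil, to the bin
size. Clustering tie-breaks: lexicographic processing order.
Heterozygous calls in the differential-variant step are accepted with
a warning and represented by their alternate allele. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
identical configuration and seed give byte-identical outputs.

## Problem sizes

Defaults run a 5 Mb genome (10 x 500 kb scaffolds, ~220 marker loci
per Mb — the same order of marker density as the emulated study),
n_F2 = 500, three 50-plant pools, 160x pooled depth. A full
ten-seed recovery study runs in a few seconds; the complete test suite
in well under a minute.

## Known limitations

- The sweet-pool ratio localizes pH loci only weakly (typically 0–4 of
  4 scaffolds per seed) because threshold qualification over four
  equal-effect pH loci caps the nsns pool's allele-frequency shift;
  the package reports this recovery but does not promise it.
- Single-linkage clustering at 90 % identity can chain distinct loci
  through intermediate sequences; with 80 bp tags and realistic
  divergence this is rare but possible.
- The anchorer is exact-seed based: markers diverged by more than
  ~10 % from the assembly, or with indels, will not anchor.
- Indel/SV truth records use reference coordinates and do not alter
  haplotype length; digest-fragment boundaries are therefore identical
  between parents, which slightly understates INDEL-category markers.
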