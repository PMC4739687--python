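# superbsa

Pooled trait mapping for biparental crosses: parental variant triage,
restriction-fragment (SLAF-style) marker construction, bulk
allele-depth ratio statistics over extreme-phenotype F2 pools,
candidate-region calling, chromosome anchoring, and candidate-gene
reporting — plus a seeded simulator of the whole cross design, so the
entire workflow runs end to end without external data.

The package is aimed at plant-genetics analysts working with
bulked-segregant designs on reduced-representation sequencing: two
homozygous parents diverged for quantitative fruit traits (sweetness
as total soluble solids, TSS, in °Brix; sourness as juice pH), an F2
of ~500 plants, and three 50-plant pools of extreme phenotypes
sequenced to ~160× pooled depth.

## The statistic

Each marker carries a maternal (M) and a paternal (P) allele. With
pooled depths per bulk, the per-marker ratios

```
Ratio_sweet = M_sweet / P_nsns        Ratio_sour = P_sour / M_nsns
```

(`nsns` = non-sweet non-sour reference pool; denominator 0 → sentinel
1000) flag a marker as trait-associated when ≥ 3. Runs of ≥ 2
consecutive differential markers on a scaffold become candidate
regions with kb-rounded bounds and overlapping-gene counts. Display
values are capped at 20 for plotting only. Note that each ratio is
large where *both* of its pools are enriched for the same parental
allele — the sour-pool ratio is the one that localizes TSS
(sweetness) loci; see `docs/methods.md`.

## Worked example

```
$ python examples/04_bsa_mapping.py
markers: 1111; differential: 63 (sweet ratio >= 3), 118 (sour ratio >= 3)

sweet trait: 4 candidate regions
  scaffold0001:140,000-147,000 size 7,000 bp, 2 markers, 0.004 Mb/marker
  scaffold0002:262,000-270,000 size 8,000 bp, 2 markers, 0.004 Mb/marker
  ...

sour trait: 22 candidate regions
  scaffold0001:140,000-147,000 size 7,000 bp, 2 markers, 0.004 Mb/marker
  scaffold0001:247,000-255,000 size 8,000 bp, 2 markers, 0.004 Mb/marker
  ...

planted TSS-QTL scaffolds recovered (via the sour-pool ratio): 4/4 -> ['scaffold0001', 'scaffold0002', 'scaffold0003', 'scaffold0004']
planted pH-QTL scaffolds recovered (via the sweet-pool ratio): 0/4 -> []
```

A simulated study (5 Mb genome, four planted QTLs per trait, 500 F2
plants, three 50-plant pools at 160× depth) is genotyped at ~1,100
restriction-fragment marker loci; 118 markers exceed the sour-ratio
threshold and collapse into 22 regions, which include all four
scaffolds carrying planted sweetness QTLs. The pH side of this seed
illustrates the statistic's asymmetry discussed in the methods note.

Other examples: `01_simulate_cross.py` (genome/parents/F2/phenotypes),
`02_variant_triage.py` (SNP screening, Ts/Tv, polymorphic genes),
`03_slaf_markers.py` (digest, tag clustering, marker typing),
`05_anchor_and_candidates.py` (chromosome anchoring, candidate-gene
table).

## Layout

```
src/superbsa/
  sim.py         genome, parents, F2 cross, phenotypes, pooled depths
  variants.py    SNP/SV screening, annotation, differential variants
  slaf.py        digest, tag clustering, locus filters, marker typing
  bsa.py         ratio statistic, differential markers, region calling
  anchor.py      marker placement on chromosome assemblies
  candidates.py  phenotype classes, pool selection, candidate genes
  pipeline.py    end-to-end simulated mapping runs
  io.py          FASTA / GFF3 / BED / VCF / TSV readers and writers
```

`docs/methods.md` documents the model, parameter defaults and their
rationale, and known limitations.
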