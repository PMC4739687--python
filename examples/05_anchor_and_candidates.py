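"""Anchor markers on a chromosome assembly and report candidate genes.

Plants marker tags at known chromosome positions, recovers them by
seed-and-extend search, discards promiscuous markers, and intersects
anchored markers with gene models and a polymorphic-gene set to build
the candidate-gene table.
"""

import numpy as np

from superbsa import sim
from superbsa.anchor import anchor_markers, project_regions
from superbsa.bsa import TraitRegion
from superbsa.candidates import report_candidates

rng = np.random.default_rng(3)
assembly = {
    "chr06": "".join(rng.choice(list("ACGT"), 80_000)),
    "chr12": "".join(rng.choice(list("ACGT"), 80_000)),
}

# six unique markers planted at known positions, one promiscuous marker
markers = {f"SLAF{i}": assembly["chr06" if i % 2 else "chr12"][p : p + 80]
           for i, p in enumerate(rng.integers(0, 79_000, 6))}
repeat_seq = "".join(rng.choice(list("ACGT"), 80))
assembly["chr06"] += repeat_seq + "T" * 50 + repeat_seq + "A" * 50 + repeat_seq
markers["SLAF_repeat"] = repeat_seq

anchors, discarded = anchor_markers(markers, assembly, min_identity=0.9, max_hits=2)
print(f"anchored {len(anchors)} markers; discarded {discarded} (mapped to >2 loci)")
print(project_regions(anchors).to_string(index=False))

# candidate genes: gene models overlapping anchored markers inside regions
genes = [sim.Gene(f"MELO_{a.marker}", a.chromosome, max(1, a.start - 200),
                  a.start + 300 - ((a.start + 300 - max(1, a.start - 200) + 1) % 3),
                  "+", ()) for a in anchors[:3]]
regions = [TraitRegion("sweet", a.chromosome, max(1, a.start - 1000), a.end + 1000, [a.marker])
           for a in anchors[:3]]
rows = report_candidates(regions, anchors, genes, polymorphic_set={genes[0].gene_id})
print("\ncandidate genes (marker in gene in region):")
for r in rows:
    flag = "parental polymorphism" if r.parental_polymorphism else "no parental polymorphism"
    print(f"  {r.marker} -> {r.gene_id} [{r.trait}] ({flag})")
# A candidate row means a differential marker lies inside a gene inside a
# called trait region; the flag says whether parental resequencing found
# a coding polymorphism in that gene.
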