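"""Build restriction-fragment marker loci from tag sequences.

Digests a reference in silico with XhoI + MseI, clusters 80 bp tags at
90 % identity into loci, filters repetitive/low-depth loci and types
each marker, ending with the category summary table.
"""

import numpy as np

from superbsa import sim
from superbsa.slaf import SlafTag, cluster_tags, digest, filter_loci, slaf_summary, type_marker

rng = np.random.default_rng(5)
genome = sim.make_genome(1, 200_000, 0, 0.0, seed=5)
seq = genome.scaffolds["scaffold0001"]

fragments = digest(seq, size_window=(300, 500))
print(f"digest: {len(digest(seq))} fragments, {len(fragments)} in the 300-500 bp window")

# tags: the first 80 bp of each fragment, one allele per parent with a
# planted SNP on a third of the loci, plus one artificial repeat cluster
tags = []
for i, frag in enumerate(fragments[:60]):
    t = frag.sequence[:80]
    tags.append(SlafTag(f"f{i}_sweet", t, "sweet", int(rng.poisson(80)) + 1))
    if i % 3 == 0:
        alt = list(t)
        alt[40] = "A" if t[40] != "A" else "C"
        tags.append(SlafTag(f"f{i}_sour", "".join(alt), "sour", int(rng.poisson(80)) + 1))
    else:
        tags.append(SlafTag(f"f{i}_sour", t, "sour", int(rng.poisson(80)) + 1))

groups = cluster_tags(tags, identity_threshold=0.9)
loci = filter_loci(groups, max_tags=4, min_depth=10)
for locus in loci:
    type_marker(locus)
print(slaf_summary(loci))
# SNP rows are loci whose two tags differ by a substitution; loci with a
# single shared tag are "no_polymorphism" and carry no mapping signal.
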