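"""Simulate the cross design: genome, diverged parents, F2, phenotypes.

Builds a small reference, plants four QTLs per trait, selfs the F1 into
an F2 of 500 plants and prints the phenotype structure the pooling
design relies on.
"""

import numpy as np

from superbsa import sim
from superbsa.candidates import classify_phenotype

genome = sim.make_genome(n_scaffolds=6, scaffold_len=200_000, gene_density=50,
                         repeat_fraction=0.1, seed=42)
qtls_tss, qtls_ph = sim.default_qtls(genome, n_per_trait=4, seed=42)
parents = sim.make_parents(genome, snp_rate=5e-4, indel_rate=1e-5, sv_rate=2e-6,
                           qtls=qtls_tss + qtls_ph, seed=42)
geno = sim.simulate_cross(parents, sim.CrossConfig(n_f2=500, crossover_rate=0.5, seed=42))
plants = sim.assign_phenotypes(geno, qtls_tss, qtls_ph, seed=42)

tss = np.array([p.tss for p in plants])
ph = np.array([p.ph for p in plants])
print(f"genome: {genome.size/1e6:.1f} Mb in {len(genome.scaffolds)} scaffolds, "
      f"{len(genome.genes)} genes")
print(f"planted truth variants: {len(parents.truth)} "
      f"({sum(1 for v in parents.truth if v.kind == 'SNP')} SNPs)")
print(f"F2 TSS: mean {tss.mean():.2f} Brix (sd {tss.std():.2f}); "
      f"pH: mean {ph.mean():.2f} (sd {ph.std():.2f})")
classes = {}
for p in plants:
    classes[classify_phenotype(p.tss, p.ph)] = classes.get(classify_phenotype(p.tss, p.ph), 0) + 1
print("trait classes:", dict(sorted(classes.items())))
# The parents sit at 12.7/6.1 (sweet) and 6.8/4.4 (sour); the F2 spreads
# between them, and the class counts show enough extreme plants to fill
# three 50-plant pools.
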