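"""End-to-end simulated mapping run.

Wires the simulator to the mapping modules: generate a genome and
diverged parents, self the F1 into an F2, phenotype and pool the
plants, place restriction-fragment marker loci, simulate pooled depths,
compute both bulk ratios, and call candidate regions for both traits.

A note on what each ratio localizes: the sweet and non-sweet non-sour
pools are both selected for pH above 5.3, so at pH-determining loci
both pools are enriched for the maternal allele, the denominator
P_nsns shrinks, and Ratio_sweet rises. Symmetrically the sour and
nsns pools share the TSS < 8 qualification, so Ratio_sour spikes at
TSS-determining loci. Each ratio therefore flags the loci at which its
two pools were co-selected toward the same parental allele;
``recovered_scaffolds`` reports recovery with that pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import bsa, sim, slaf
from .candidates import PhenotypeRecord, select_bulks

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "marker_loci_from_digest"]


@dataclass(frozen=True)
class PipelineConfig:
    """Study-scale defaults for a desk-size simulated mapping run."""

    n_scaffolds: int = 10
    scaffold_len: int = 500_000
    gene_density: float = 50.0  # genes per Mb
    repeat_fraction: float = 0.1
    snp_rate: float = 1e-3
    indel_rate: float = 2e-5
    sv_rate: float = 5e-6
    n_qtl_per_trait: int = 4
    n_f2: int = 500
    crossover_rate: float = 0.5
    bulk_size: int = 50
    depth: sim.DepthModel = field(default_factory=sim.DepthModel)
    size_window: tuple[int, int] = (300, 500)
    min_run: int = 2
    bin_size: int = 1000


@dataclass
class PipelineResult:
    genome: sim.ReferenceGenome
    qtls_tss: list[sim.QtlSpec]
    qtls_ph: list[sim.QtlSpec]
    parents: sim.Parents
    genotypes: sim.F2Genotypes
    phenotypes: list[PhenotypeRecord]
    bulks: dict[str, list[str]]
    depth_table: pd.DataFrame
    ratios: list[bsa.BulkRatio]
    sweet_regions: list[bsa.TraitRegion]
    sour_regions: list[bsa.TraitRegion]

    def recovered_scaffolds(self) -> dict[str, set[str]]:
        """Planted QTL scaffolds recovered by the region calls.

        The sweet-pool ratio localizes pH-determining loci and the
        sour-pool ratio TSS-determining loci (see module docstring), so
        recovery is scored with that pairing.
        """
        sweet_sc = {r.scaffold for r in self.sweet_regions}
        sour_sc = {r.scaffold for r in self.sour_regions}
        return {
            "pH": {q.scaffold for q in self.qtls_ph} & sweet_sc,
            "TSS": {q.scaffold for q in self.qtls_tss} & sour_sc,
        }


def marker_loci_from_digest(
    genome: sim.ReferenceGenome,
    parents: sim.Parents,
    size_window: tuple[int, int],
) -> list[tuple[str, int]]:
    """Marker positions: truth SNP sites inside size-selected fragments.

    Each scaffold is digested in silico; a truth SNP falling inside a
    retained fragment becomes a polymorphic marker locus (one per
    fragment, the leftmost such site), mirroring how tag sequences
    acquire their discriminating variant.
    """
    snp_by_scaffold: dict[str, list[int]] = {}
    for sc, pos in parents.snp_sites():
        snp_by_scaffold.setdefault(sc, []).append(pos)
    loci: list[tuple[str, int]] = []
    for sc, seq in genome.scaffolds.items():
        positions = sorted(snp_by_scaffold.get(sc, []))
        if not positions:
            continue
        for frag in slaf.digest(seq, size_window=size_window):
            inside = [p for p in positions if frag.start <= p <= frag.end]
            if inside:
                loci.append((sc, inside[0]))
    return loci


def run_pipeline(seed: int, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full simulated super-BSA mapping workflow from one seed."""
    cfg = config or PipelineConfig()
    # decorrelated per-stage seeds, all below 2**31
    s = lambda k: (seed * 1_000_003 + k) % (2**31 - 1)

    genome = sim.make_genome(
        cfg.n_scaffolds, cfg.scaffold_len, cfg.gene_density, cfg.repeat_fraction, s(1)
    )
    qtls_tss, qtls_ph = sim.default_qtls(genome, cfg.n_qtl_per_trait, s(2))
    parents = sim.make_parents(
        genome, cfg.snp_rate, cfg.indel_rate, cfg.sv_rate, qtls_tss + qtls_ph, s(3)
    )
    genotypes = sim.simulate_cross(
        parents, sim.CrossConfig(n_f2=cfg.n_f2, crossover_rate=cfg.crossover_rate, seed=s(4))
    )
    phenotypes = sim.assign_phenotypes(genotypes, qtls_tss, qtls_ph, s(5))
    bulks = select_bulks(phenotypes, cfg.bulk_size)
    loci = marker_loci_from_digest(genome, parents, cfg.size_window)
    depth_table = sim.simulate_slaf_depths(
        genome, parents, genotypes, bulks, loci, cfg.depth, s(6)
    )
    ratios = bsa.bulk_ratios(depth_table)
    sweet_regions = bsa.call_regions(ratios, "sweet", cfg.min_run, cfg.bin_size)
    sour_regions = bsa.call_regions(ratios, "sour", cfg.min_run, cfg.bin_size)
    return PipelineResult(
        genome=genome, qtls_tss=qtls_tss, qtls_ph=qtls_ph, parents=parents,
        genotypes=genotypes, phenotypes=phenotypes, bulks=bulks,
        depth_table=depth_table, ratios=ratios,
        sweet_regions=sweet_regions, sour_regions=sour_regions,
    )
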