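"""Phenotype classification, bulk selection, and the candidate-gene report.

The trait classes follow the phenotype rules used to form the bulks:
sweet-and-sour (TSS > 12 and pH < 5, checked first since it overlaps no
other rule's territory yet describes the F1), sweet (TSS >= 8 and
pH > 5.3), sour (TSS < 8 and pH <= 5.3), non-sweet non-sour (TSS < 8
and pH > 5.3 — a subset of sour's complement kept distinct for pool
selection), and an explicit unclassified class closing the gaps the
four rules leave in the (TSS, pH) plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .anchor import ChromAnchor
from .bsa import TraitRegion
from .sim import Gene

__all__ = [
    "PhenotypeRecord",
    "CandidateGene",
    "classify_phenotype",
    "select_bulks",
    "report_candidates",
]


@dataclass
class PhenotypeRecord:
    """One plant's fruit phenotype: TSS in degrees Brix and juice pH."""

    plant_id: str
    generation: str  # P_female | P_male | F1 | F2
    tss: float
    ph: float
    trait_class: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.generation not in ("P_female", "P_male", "F1", "F2"):
            raise ValueError(f"unknown generation {self.generation!r}")
        if self.tss <= 0:
            raise ValueError("TSS must be > 0")
        if not (0 < self.ph < 14):
            raise ValueError("pH must lie in (0, 14)")
        if not self.trait_class:
            self.trait_class = classify_phenotype(self.tss, self.ph)


@dataclass(frozen=True)
class CandidateGene:
    """A differential marker anchored inside a gene within a trait region."""

    marker: str
    gene_id: str
    trait: str  # "sweet" | "sour"
    parental_polymorphism: bool
    annotation: str = ""


def classify_phenotype(tss: float, ph: float) -> str:
    """Classify one fruit by its TSS and pH.

    Checked in order: sweet_and_sour (TSS > 12, pH < 5), sweet
    (TSS >= 8, pH > 5.3), sour (TSS < 8, pH <= 5.3),
    non_sweet_non_sour (TSS < 8, pH > 5.3); everything else is
    unclassified. Every (TSS, pH) pair receives exactly one class.
    """
    if tss > 12 and ph < 5:
        return "sweet_and_sour"
    if tss >= 8 and ph > 5.3:
        return "sweet"
    if tss < 8 and ph <= 5.3:
        return "sour"
    if tss < 8 and ph > 5.3:
        return "non_sweet_non_sour"
    return "unclassified"


def select_bulks(
    records: Iterable[PhenotypeRecord], bulk_size: int = 50
) -> dict[str, list[str]]:
    """Select the three extreme-phenotype pools from F2 records.

    Qualification uses the trait classes (sweet: TSS >= 8 and pH > 5.3;
    sour: TSS < 8 and pH <= 5.3; non-sweet non-sour: TSS < 8 and
    pH > 5.3) and each pool keeps its ``bulk_size`` most extreme
    qualifiers: sweet by TSS descending, sour by pH ascending, and nsns
    by joint extremeness (sum of TSS-ascending and pH-descending ranks
    — the most non-sweet AND non-sour plants, since the nsns bulk
    serves as the reference pool against both traits). The classes are
    mutually exclusive, so pools are disjoint by construction.

    Returns {"sweet": ids, "sour": ids, "nsns": ids}; raises when a
    pool has fewer than ``bulk_size`` qualifying plants, naming it.
    """
    records = list(records)
    sweet_q = sorted(
        (r for r in records if r.tss >= 8 and r.ph > 5.3),
        key=lambda r: (-r.tss, r.plant_id),
    )
    sour_q = sorted(
        (r for r in records if r.tss < 8 and r.ph <= 5.3),
        key=lambda r: (r.ph, r.plant_id),
    )
    nsns_pool = [r for r in records if r.tss < 8 and r.ph > 5.3]
    tss_rank = {r.plant_id: i for i, r in enumerate(
        sorted(nsns_pool, key=lambda r: (r.tss, r.plant_id)))}
    ph_rank = {r.plant_id: i for i, r in enumerate(
        sorted(nsns_pool, key=lambda r: (-r.ph, r.plant_id)))}
    nsns_q = sorted(
        nsns_pool,
        key=lambda r: (tss_rank[r.plant_id] + ph_rank[r.plant_id], r.plant_id),
    )
    pools = {"sweet": sweet_q, "sour": sour_q, "nsns": nsns_q}
    for name, q in pools.items():
        if len(q) < bulk_size:
            raise ValueError(
                f"pool {name!r} has only {len(q)} qualifying plants, need {bulk_size}"
            )
    return {name: [r.plant_id for r in q[:bulk_size]] for name, q in pools.items()}


def report_candidates(
    regions: Iterable[TraitRegion],
    anchors: Iterable[ChromAnchor],
    genes: Iterable[Gene],
    polymorphic_set: set[str],
    scaffold_positions: Optional[dict[str, tuple[str, int]]] = None,
    gene_annotations: Optional[dict[str, str]] = None,
) -> list[CandidateGene]:
    """Intersect region markers, gene models and the polymorphic-gene set.

    For each differential marker belonging to a trait region, the
    marker's interval (its chromosome anchor, or its scaffold position
    from ``scaffold_positions`` when gene models live on scaffolds) is
    overlapped with every gene; each overlapping (marker, gene) pair
    yields one row — a marker spanning two genes yields two. The
    polymorphism flag records membership of the gene in
    ``polymorphic_set``; annotation text comes from
    ``gene_annotations`` (e.g. GFF3 attributes) when given.
    """
    genes = list(genes)
    anchor_by_marker = {a.marker: a for a in anchors}
    out: list[CandidateGene] = []
    seen: set[tuple[str, str, str]] = set()
    for region in regions:
        for marker in region.markers:
            a = anchor_by_marker.get(marker)
            if a is not None:
                ref, lo, hi = a.chromosome, a.start, a.end
            elif scaffold_positions and marker in scaffold_positions:
                sc, pos = scaffold_positions[marker]
                ref, lo, hi = sc, pos, pos
            else:
                continue
            for g in genes:
                if g.scaffold == ref and g.start <= hi and lo <= g.end:
                    key = (marker, g.gene_id, region.trait)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(
                        CandidateGene(
                            marker=marker,
                            gene_id=g.gene_id,
                            trait=region.trait,
                            parental_polymorphism=g.gene_id in polymorphic_set,
                            annotation=(gene_annotations or {}).get(g.gene_id, ""),
                        )
                    )
    return out
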