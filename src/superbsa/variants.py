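"""Parental variant triage and annotation.

Screens SNP calls by depth and repeat overlap, validates structural
variants, classifies substitutions as transitions or transversions,
annotates variants against gene models (genic/intergenic, exonic/
intronic, synonymous/non-synonymous) and extracts the differential
variant set and polymorphic genes between two homozygous parents.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Seq import Seq

from .sim import Gene, ReferenceGenome

logger = logging.getLogger(__name__)

__all__ = [
    "VariantCall",
    "VariantAnnotation",
    "VariantSummary",
    "SV_KINDS",
    "classify_substitution",
    "filter_snp_calls",
    "validate_sv",
    "annotate_variant",
    "differential_variants",
    "polymorphic_genes",
    "summarize_variants",
]

SV_KINDS = ("INS", "DEL", "CTX", "DII", "ITX", "INV")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class VariantCall:
    """One SNP or SV call in one sample (1-based position)."""

    sample: str
    scaffold: str
    position: int
    kind: str  # SNP or one of SV_KINDS
    ref: str
    alt: str
    depth: int
    quality: float
    zygosity: str  # "hom" | "het"
    end: Optional[int] = None  # second coordinate for DEL/INV/CTX/ITX/DII

    def __post_init__(self) -> None:
        if self.kind == "SNP":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError(f"bad SNP alleles {self.ref}>{self.alt}")
        elif self.kind not in SV_KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"zygosity must be hom/het, got {self.zygosity!r}")


@dataclass(frozen=True)
class VariantAnnotation:
    """Positional annotation of one variant against the gene models."""

    region: str  # "genic" | "intergenic"
    subclass: str  # "exonic" | "intronic" | "none"
    coding_effect: str  # "synonymous" | "non_synonymous" | "none"
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.coding_effect != "none" and self.subclass != "exonic":
            raise ValueError("coding effect requires an exonic variant")
        if self.subclass == "none" and self.region != "intergenic":
            raise ValueError("subclass none is reserved for intergenic variants")


@dataclass
class VariantSummary:
    """Annotation-cell counts plus substitution-class and SV-type breakdowns."""

    total: int
    genic: int
    intergenic: int
    exonic: int
    intronic: int
    synonymous: int
    non_synonymous: int
    transitions: int
    transversions: int
    ts_tv: float
    sv_fractions: dict[str, float]


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a single-base substitution.

    C<->T and G<->A (purine-purine / pyrimidine-pyrimidine exchanges)
    are transitions; the eight remaining ordered pairs transversions.
    """
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"alleles must be single bases in ACGT, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    return "transition" if (ref, alt) in _TRANSITIONS else "transversion"


def _in_repeat(scaffold: str, pos: int, repeats: dict[str, list[tuple[int, int]]]) -> bool:
    for s, e in repeats.get(scaffold, []):
        if s <= pos <= e:
            return True
    return False


def filter_snp_calls(
    calls: Iterable[VariantCall],
    mean_depth: float,
    repeats: dict[str, list[tuple[int, int]]],
    max_depth_factor: float = 3.0,
) -> tuple[list[VariantCall], dict[VariantCall, str]]:
    """Screen SNP calls by depth and repeat overlap.

    A call is kept iff depth >= 2 (homozygous) or >= 3 (heterozygous),
    depth <= max_depth_factor * mean_depth, and its base does not lie
    inside a repeat interval. Returns (kept, rejection reason per
    discarded call) with reasons in {low_depth, high_depth, repeat}.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    kept: list[VariantCall] = []
    reasons: dict[VariantCall, str] = {}
    cap = max_depth_factor * mean_depth
    for c in calls:
        if c.kind != "SNP":
            raise ValueError("filter_snp_calls accepts SNPs only")
        min_depth = 3 if c.zygosity == "het" else 2
        if c.depth < min_depth:
            reasons[c] = "low_depth"
        elif c.depth > cap:
            reasons[c] = "high_depth"
        elif _in_repeat(c.scaffold, c.position, repeats):
            reasons[c] = "repeat"
        else:
            kept.append(c)
    return kept, reasons


def validate_sv(call: VariantCall) -> str:
    """Validate a structural variant: 2-100x depth and quality strictly above 20."""
    if call.kind == "SNP":
        raise ValueError("validate_sv applies to structural variants, not SNPs")
    ok = 2 <= call.depth <= 100 and call.quality > 20
    return "valid" if ok else "invalid"


def _locate(v: VariantCall, genes: list[Gene]) -> tuple[Optional[Gene], str]:
    for g in genes:
        if g.scaffold == v.scaffold and g.start <= v.position <= g.end:
            for s, e in g.cds:
                if s <= v.position <= e:
                    return g, "exonic"
            return g, "intronic"
    return None, "none"


def annotate_variant(
    v: VariantCall, genes: list[Gene], genome: ReferenceGenome
) -> VariantAnnotation:
    """Annotate one variant against non-overlapping gene models.

    Exonic SNPs get a coding effect by translating the affected codon
    before and after the substitution with the standard genetic code,
    reverse-complementing for minus-strand genes. Exonic SVs/indels are
    annotated positionally with coding effect "none".
    """
    if v.scaffold not in genome.scaffolds:
        raise ValueError(f"unknown scaffold {v.scaffold}")
    gene, subclass = _locate(v, genes)
    if gene is None:
        return VariantAnnotation("intergenic", "none", "none")
    if subclass != "exonic" or v.kind != "SNP":
        return VariantAnnotation("genic", subclass, "none", gene.gene_id)

    # Stitch the spliced CDS, mutate the variant base, translate both.
    cds_parts = sorted(gene.cds)
    seq = "".join(genome.scaffolds[gene.scaffold][s - 1 : e] for s, e in cds_parts)
    offset = 0
    cds_pos = None  # 0-based position of the variant within the spliced CDS
    for s, e in cds_parts:
        if s <= v.position <= e:
            cds_pos = offset + (v.position - s)
            break
        offset += e - s + 1
    assert cds_pos is not None
    if len(seq) % 3 != 0:
        raise ValueError(f"gene {gene.gene_id}: CDS length inconsistent with frame")
    if seq[cds_pos] != v.ref:
        logger.warning(
            "reference base %s at %s:%d does not match call ref %s",
            seq[cds_pos], v.scaffold, v.position, v.ref,
        )
    mutated = seq[:cds_pos] + v.alt + seq[cds_pos + 1 :]
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
    aa_ref = str(Seq(seq).translate())
    aa_alt = str(Seq(mutated).translate())
    effect = "synonymous" if aa_ref == aa_alt else "non_synonymous"
    return VariantAnnotation("genic", "exonic", effect, gene.gene_id)


def differential_variants(
    parent_a: Iterable[VariantCall], parent_b: Iterable[VariantCall]
) -> list[VariantCall]:
    """Sites where the two homozygous parents carry different alleles.

    A site with a call in only one parent is differential (the silent
    parent matches the reference); a site called in both is differential
    only if the alternate alleles differ. Heterozygous inputs are
    accepted with a warning and represented by their alternate allele.
    Returns one representative call per differential site, position-sorted.
    """
    def index(calls: Iterable[VariantCall]) -> dict[tuple[str, int, str], VariantCall]:
        out = {}
        for c in calls:
            if c.zygosity == "het":
                logger.warning(
                    "heterozygous call at %s:%d in %s; using alt allele",
                    c.scaffold, c.position, c.sample,
                )
            out[(c.scaffold, c.position, c.kind)] = c
        return out

    ia, ib = index(parent_a), index(parent_b)
    diff: list[VariantCall] = []
    for key, c in ia.items():
        other = ib.get(key)
        if other is None or other.alt != c.alt:
            diff.append(c)
    for key, c in ib.items():
        if key not in ia:
            diff.append(c)
    diff.sort(key=lambda c: (c.scaffold, c.position, c.kind))
    return diff


def polymorphic_genes(
    differential: Iterable[VariantCall],
    annotations: dict[VariantCall, VariantAnnotation],
    sv_validity: Optional[dict[VariantCall, str]] = None,
) -> set[str]:
    """Genes carrying trait-relevant parental polymorphism.

    A gene qualifies iff it contains at least one differential
    non-synonymous SNP, or at least one exonic differential SV/indel
    that passed validation (all SVs assumed valid when no validity map
    is given).
    """
    out: set[str] = set()
    for v in differential:
        ann = annotations[v]
        if ann.subclass != "exonic" or not ann.gene_id:
            continue
        if v.kind == "SNP":
            if ann.coding_effect == "non_synonymous":
                out.add(ann.gene_id)
        else:
            if sv_validity is None or sv_validity.get(v, "valid") == "valid":
                out.add(ann.gene_id)
    return out


def summarize_variants(
    calls: Iterable[VariantCall],
    annotations: dict[VariantCall, VariantAnnotation],
) -> VariantSummary:
    """Tabulate annotation cells, Ts/Tv and SV-type fractions for one call set."""
    calls = list(calls)
    genic = intergenic = exonic = intronic = syn = nonsyn = ts = tv = 0
    sv_counts: Counter[str] = Counter()
    for c in calls:
        ann = annotations[c]
        if ann.region == "genic":
            genic += 1
            if ann.subclass == "exonic":
                exonic += 1
            elif ann.subclass == "intronic":
                intronic += 1
        else:
            intergenic += 1
        if c.kind == "SNP":
            if classify_substitution(c.ref, c.alt) == "transition":
                ts += 1
            else:
                tv += 1
            if ann.coding_effect == "synonymous":
                syn += 1
            elif ann.coding_effect == "non_synonymous":
                nonsyn += 1
        else:
            sv_counts[c.kind] += 1
    n_sv = sum(sv_counts.values())
    fractions = {k: v / n_sv for k, v in sv_counts.items()} if n_sv else {}
    return VariantSummary(
        total=len(calls), genic=genic, intergenic=intergenic,
        exonic=exonic, intronic=intronic,
        synonymous=syn, non_synonymous=nonsyn,
        transitions=ts, transversions=tv,
        ts_tv=(ts / tv) if tv else float("inf"),
        sv_fractions=fractions,
    )
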