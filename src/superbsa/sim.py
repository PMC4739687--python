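"""Synthetic cross simulator.

Generates the inputs the mapping pipeline consumes: a scaffold-level
reference genome with gene models and a repeat mask, two homozygous
diverged parents, an F2 population with quantitative sweetness (TSS,
degrees Brix) and sourness (pH) phenotypes, and pooled restriction-site
tag depth tables for extreme-phenotype bulks.

The default trait architecture places four QTLs per trait with effects
sized so that the parental means match the greenhouse phenotypes the
design emulates (sweet parent 12.7 Brix / pH 6.1, sour parent 6.8 Brix /
pH 4.4); dominance and residual noise are set so the extreme-phenotype
classes segregate at pool-fillable frequencies.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Gene",
    "ReferenceGenome",
    "QtlSpec",
    "CrossConfig",
    "DepthModel",
    "Parents",
    "F2Genotypes",
    "make_genome",
    "make_parents",
    "simulate_cross",
    "assign_phenotypes",
    "simulate_slaf_depths",
    "default_qtls",
    "TSS_BASELINE",
    "TSS_EFFECT",
    "TSS_DOMINANCE",
    "PH_BASELINE",
    "PH_EFFECT",
    "PH_DOMINANCE",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Trait architecture defaults. Effects are per copy of the sweet-parent
# allele; with four QTLs, baseline + 2*4*effect reproduces the high
# parent (6.8 + 8*0.7375 = 12.7 Brix; 4.4 + 8*0.2125 = 6.1 pH).
# Dominance (heterozygote contributes 2*effect*dominance; 0.5 = additive)
# and residual sd are set so the class thresholds (TSS 8, pH 5.3) cut the
# F2 into segregant classes large enough to fill three 50-plant pools
# out of 500 while phenotype ranks still track genotype — the constraint
# the pooled mapping design itself imposes (see docs/methods.md).
TSS_BASELINE = 6.8
TSS_EFFECT = 0.7375
TSS_DOMINANCE = 0.25  # sweetness partially recessive
TSS_RESIDUAL_SD = 0.8
PH_BASELINE = 4.4
PH_EFFECT = 0.2125
PH_DOMINANCE = 0.5  # additive
PH_RESIDUAL_SD = 0.5


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene model with 1-based inclusive coordinates."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str  # '+' or '-'
    cds: tuple[tuple[int, int], ...]  # 1-based inclusive CDS intervals
    frame: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        total = sum(e - s + 1 for s, e in self.cds)
        if self.cds and total % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {total} not a multiple of 3")


@dataclass
class ReferenceGenome:
    """Scaffold sequences plus gene models and a repeat mask.

    ``repeats`` maps scaffold id to a list of 1-based inclusive intervals.
    """

    scaffolds: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    repeats: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes:
            L = len(self.scaffolds[g.scaffold])
            if not (1 <= g.start <= g.end <= L):
                raise ValueError(f"gene {g.gene_id} outside scaffold {g.scaffold}")
        for sc, ivs in self.repeats.items():
            L = len(self.scaffolds[sc])
            for s, e in ivs:
                if not (1 <= s <= e <= L):
                    raise ValueError(f"repeat ({s},{e}) outside scaffold {sc}")

    @property
    def size(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())


@dataclass(frozen=True)
class QtlSpec:
    """One quantitative trait locus.

    ``effect`` is the phenotype change per copy of the sweet-parent
    allele (Brix for TSS, pH units for pH); ``dominance`` scales the
    heterozygote contribution (0.5 = additive). ``baseline`` and
    ``residual_sd`` describe the trait and are shared by all QTLs of a
    trait; they ride along on each spec for self-containment.
    """

    trait: str  # "TSS" or "pH"
    scaffold: str
    position: int
    effect: float
    baseline: float
    residual_sd: float
    dominance: float = 0.5

    def __post_init__(self) -> None:
        if self.trait not in ("TSS", "pH"):
            raise ValueError(f"trait must be TSS or pH, got {self.trait!r}")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


@dataclass(frozen=True)
class CrossConfig:
    """F2 design: population size and recombination intensity."""

    n_f2: int = 500
    crossover_rate: float = 0.5  # expected crossovers per scaffold per meiosis
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f2 < 1:
            raise ValueError("n_f2 must be >= 1")
        if self.crossover_rate < 0:
            raise ValueError("crossover_rate must be >= 0")


@dataclass(frozen=True)
class DepthModel:
    """Sequencing depth model for parental resequencing and pooled tags.

    ``overdispersion`` is the negative-binomial alpha: the pooled total
    depth has variance mean + alpha*mean^2; 0 degenerates to Poisson.
    """

    parental_depth: float = 13.0
    pooled_depth: float = 160.0
    error_rate: float = 0.001
    overdispersion: float = 0.15

    def __post_init__(self) -> None:
        if self.parental_depth <= 0 or self.pooled_depth <= 0:
            raise ValueError("mean depths must be > 0")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must lie in [0, 0.05]")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")


@dataclass
class Parents:
    """Two homozygous parent haplotypes plus the planted truth variants.

    ``sweet``/``sour`` hold one haplotype sequence per scaffold (each
    parent is homozygous, so one haplotype fully describes it). SNP
    alleles are substituted into the sequences; indel/SV truth records
    keep reference coordinates, with deletions tracked so downstream
    placement can avoid them.
    """

    genome: ReferenceGenome
    sweet: dict[str, str]
    sour: dict[str, str]
    truth: list  # list[VariantCall], avoids a circular import at type time

    def snp_sites(self) -> list[tuple[str, int]]:
        return [(v.scaffold, v.position) for v in self.truth if v.kind == "SNP"]


@dataclass
class F2Genotypes:
    """Per-plant genotypes at every truth SNP site.

    ``matrix[i, j]`` counts copies (0/1/2) of the sweet-parent allele in
    plant *i* at site *j*; ``sites`` gives (scaffold, position) per column.
    """

    sites: list[tuple[str, int]]
    matrix: np.ndarray
    plant_ids: list[str]

    def site_index(self, scaffold: str, position: int) -> int:
        return self.sites.index((scaffold, position))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def make_genome(
    n_scaffolds: int,
    scaffold_len: int,
    gene_density: float,
    repeat_fraction: float,
    seed: int,
) -> ReferenceGenome:
    """Generate a random annotated reference.

    Parameters
    ----------
    n_scaffolds, scaffold_len
        Number of scaffolds and their common length (>= 10 kb).
    gene_density
        Genes per megabase. Genes are non-overlapping, each with one or
        more CDS intervals whose total length is a multiple of 3.
    repeat_fraction
        Target fraction of the genome covered by declared repeat
        intervals, in [0, 0.5]; realised coverage lands within +-5 %.
    seed
        Everything is reproducible from this one integer.
    """
    if n_scaffolds < 1 or scaffold_len < 10_000:
        raise ValueError("need n_scaffolds >= 1 and scaffold_len >= 10000")
    if not (0.0 <= repeat_fraction <= 0.5):
        raise ValueError("repeat_fraction must lie in [0, 0.5]")
    if gene_density < 0:
        raise ValueError("gene_density must be >= 0")

    rng = np.random.default_rng(seed)
    scaffolds: dict[str, str] = {}
    genes: list[Gene] = []
    repeats: dict[str, list[tuple[int, int]]] = {}

    for i in range(n_scaffolds):
        sc = f"scaffold{i + 1:04d}"
        scaffolds[sc] = _random_seq(rng, scaffold_len)

        n_genes = int(round(gene_density * scaffold_len / 1e6))
        # Lay genes on a regular grid with jitter so they never overlap.
        genes_here: list[Gene] = []
        if n_genes > 0:
            slot = scaffold_len // n_genes
            gene_len = min(3000, max(300, slot // 2))
            gene_len -= gene_len % 3
            for j in range(n_genes):
                lo = j * slot + 1
                hi = (j + 1) * slot - gene_len
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                end = start + gene_len - 1
                strand = "+" if rng.random() < 0.5 else "-"
                # Split the CDS into 1-3 exons at codon boundaries; the
                # intronless total stays a multiple of 3 by construction.
                n_exons = int(rng.integers(1, 4))
                codons = gene_len // 3
                if n_exons == 1 or codons < n_exons * 10:
                    cds = ((start, end),)
                else:
                    cuts = sorted(
                        rng.choice(np.arange(1, codons), size=n_exons - 1, replace=False)
                    )
                    bounds = [0, *cuts, codons]
                    cds_list = []
                    pos = start
                    for k in range(n_exons):
                        exon_len = (bounds[k + 1] - bounds[k]) * 3
                        cds_list.append((pos, pos + exon_len - 1))
                        pos += exon_len
                    cds = tuple(cds_list)
                genes_here.append(
                    Gene(f"{sc}.g{j + 1}", sc, start, end, strand, cds)
                )
        genes.extend(genes_here)

        ivs: list[tuple[int, int]] = []
        if repeat_fraction > 0:
            target = repeat_fraction * scaffold_len
            covered = 0.0
            # Fixed-length repeat blocks dropped on a coarse grid keep
            # intervals disjoint and realised coverage near target.
            block = 500
            n_blocks = int(round(target / block))
            if n_blocks > 0:
                starts = rng.choice(
                    np.arange(0, scaffold_len - block, block), size=n_blocks, replace=False
                )
                for s in np.sort(starts):
                    ivs.append((int(s) + 1, int(s) + block))
                    covered += block
        repeats[sc] = ivs

    return ReferenceGenome(scaffolds=scaffolds, genes=genes, repeats=repeats)


def default_qtls(
    genome: ReferenceGenome, n_per_trait: int = 4, seed: int = 0
) -> tuple[list[QtlSpec], list[QtlSpec]]:
    """Place the default trait architecture on distinct scaffolds.

    Returns (TSS QTLs, pH QTLs); each trait gets ``n_per_trait`` loci on
    different scaffolds where possible, with the calibrated default
    effects, baselines and dominance. QTLs sit in the middle third of
    their scaffold so flanking markers on both sides stay linked.
    """
    rng = np.random.default_rng(seed)
    names = list(genome.scaffolds)
    order = [names[i % len(names)] for i in range(2 * n_per_trait)]

    def middle(sc: str) -> int:
        L = len(genome.scaffolds[sc])
        return int(rng.integers(L // 3, 2 * L // 3))

    qtls_tss = [
        QtlSpec("TSS", order[i], middle(order[i]),
                TSS_EFFECT, TSS_BASELINE, TSS_RESIDUAL_SD, TSS_DOMINANCE)
        for i in range(n_per_trait)
    ]
    qtls_ph = [
        QtlSpec("pH", order[n_per_trait + i], middle(order[n_per_trait + i]),
                PH_EFFECT, PH_BASELINE, PH_RESIDUAL_SD, PH_DOMINANCE)
        for i in range(n_per_trait)
    ]
    return qtls_tss, qtls_ph


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def make_parents(
    genome: ReferenceGenome,
    snp_rate: float,
    indel_rate: float,
    sv_rate: float,
    qtls: list[QtlSpec],
    seed: int,
):
    """Derive two homozygous parents from the reference.

    Each variant site gets the non-reference allele in exactly one
    parent (chosen at random), so every planted variant is differential
    between the parents; both parents are homozygous throughout. Each
    QTL position additionally carries a discriminating SNP whose
    alternate allele sits on the sweet parent.

    Returns a :class:`Parents` whose ``truth`` list holds
    :class:`~superbsa.variants.VariantCall` records (sample id names the
    carrier parent).
    """
    from .variants import VariantCall  # local import: variants also stands alone

    if min(snp_rate, indel_rate, sv_rate) < 0:
        raise ValueError("rates must be >= 0")
    for q in qtls:
        if q.scaffold not in genome.scaffolds:
            raise ValueError(f"QTL scaffold {q.scaffold} not in genome")
        if not (1 <= q.position <= len(genome.scaffolds[q.scaffold])):
            raise ValueError(f"QTL position {q.position} outside {q.scaffold}")

    rng = np.random.default_rng(seed)
    sweet: dict[str, str] = {}
    sour: dict[str, str] = {}
    truth: list[VariantCall] = []
    deletions: dict[str, list[tuple[int, int]]] = {sc: [] for sc in genome.scaffolds}

    for sc, ref in genome.scaffolds.items():
        L = len(ref)
        a = np.frombuffer(ref.encode(), dtype="S1").copy()
        b = a.copy()
        qtl_here = {q.position for q in qtls if q.scaffold == sc}

        n_snp = rng.poisson(snp_rate * L)
        positions = set(
            int(p) for p in rng.choice(L, size=min(n_snp, L), replace=False) + 1
        )
        positions -= qtl_here
        for pos in sorted(positions):
            refb = ref[pos - 1]
            altb = _other_base(rng, refb)
            carrier_sweet = bool(rng.random() < 0.5)
            carrier = "sweet" if carrier_sweet else "sour"
            (a if carrier_sweet else b)[pos - 1] = altb.encode()
            truth.append(
                VariantCall(
                    sample=carrier, scaffold=sc, position=pos, kind="SNP",
                    ref=refb, alt=altb, depth=0, quality=99.0, zygosity="hom",
                )
            )
        # QTL-discriminating SNPs: alt allele always on the sweet parent,
        # so "copies of the sweet allele" is well defined at every QTL.
        for pos in sorted(qtl_here):
            refb = ref[pos - 1]
            altb = _other_base(rng, refb)
            a[pos - 1] = altb.encode()
            truth.append(
                VariantCall(
                    sample="sweet", scaffold=sc, position=pos, kind="SNP",
                    ref=refb, alt=altb, depth=0, quality=99.0, zygosity="hom",
                )
            )

        # Indels and SVs are recorded against reference coordinates; the
        # haplotype strings keep reference length so every downstream
        # coordinate system stays shared. Deleted segments are tracked.
        for kind, rate in (("INDEL", indel_rate), ("SV", sv_rate)):
            n = rng.poisson(rate * L)
            for _ in range(n):
                # deletions must not swallow a QTL; resample if they would
                for _attempt in range(100):
                    pos = int(rng.integers(1, L + 1))
                    if all(abs(pos - q) > 2000 for q in qtl_here):
                        break
                carrier = "sweet" if rng.random() < 0.5 else "sour"
                if kind == "INDEL":
                    vkind = "INS" if rng.random() < 0.5 else "DEL"
                    length = int(rng.integers(1, 11))
                else:
                    vkind = str(rng.choice(["DEL", "INS", "CTX", "DII", "ITX", "INV"],
                                           p=[0.45, 0.45, 0.03, 0.03, 0.02, 0.02]))
                    length = int(rng.integers(50, 2000))
                end2 = pos + length - 1 if vkind in ("DEL", "DII", "INV", "ITX") else None
                if vkind in ("DEL", "DII"):
                    deletions[sc].append((pos, min(end2, L)))
                truth.append(
                    VariantCall(
                        sample=carrier, scaffold=sc, position=pos, kind=vkind,
                        ref=ref[pos - 1], alt=f"<{vkind}:{length}>", depth=0,
                        quality=99.0, zygosity="hom", end=end2,
                    )
                )

        sweet[sc] = a.tobytes().decode()
        sour[sc] = b.tobytes().decode()

    for q in qtls:
        for s, e in deletions[q.scaffold]:
            if s <= q.position <= e:
                raise ValueError(
                    f"QTL at {q.scaffold}:{q.position} falls inside a deleted segment"
                )

    truth.sort(key=lambda v: (v.scaffold, v.position))
    return Parents(genome=genome, sweet=sweet, sour=sour, truth=truth)


def _gamete_phase(
    rng: np.random.Generator, L: int, positions: np.ndarray, rate: float
) -> np.ndarray:
    """Phase (1 = sweet haplotype) of one recombinant gamete at given sites.

    Crossover count per scaffold is Poisson(rate) at uniform positions
    (a no-interference model); the starting haplotype is a fair coin.
    """
    n_x = rng.poisson(rate)
    start = int(rng.integers(0, 2))
    if n_x == 0:
        return np.full(len(positions), start, dtype=np.int8)
    cuts = np.sort(rng.integers(1, L + 1, size=n_x))
    # phase flips at each crossover left of the site
    flips = np.searchsorted(cuts, positions, side="left")
    return ((start + flips) % 2).astype(np.int8)


def simulate_cross(parents: Parents, cross: CrossConfig) -> F2Genotypes:
    """Self the F1 and genotype every truth SNP site in each F2 plant.

    Each F2 plant receives two independent recombinant gametes from the
    F1 (whose two haplotypes are the two parents); the genotype is the
    number of sweet-parent haplotype copies at each site.
    """
    rng = np.random.default_rng(cross.seed)
    sites = parents.snp_sites()
    by_scaffold: dict[str, list[int]] = {}
    for j, (sc, pos) in enumerate(sites):
        by_scaffold.setdefault(sc, []).append(j)

    n = cross.n_f2
    matrix = np.zeros((n, len(sites)), dtype=np.int8)
    for sc, cols in by_scaffold.items():
        L = len(parents.genome.scaffolds[sc])
        pos = np.array([sites[j][1] for j in cols])
        order = np.argsort(pos)
        pos_sorted = pos[order]
        cols_sorted = np.array(cols)[order]
        for i in range(n):
            g1 = _gamete_phase(rng, L, pos_sorted, cross.crossover_rate)
            g2 = _gamete_phase(rng, L, pos_sorted, cross.crossover_rate)
            matrix[i, cols_sorted] = g1 + g2

    plant_ids = [f"F2_{i + 1:04d}" for i in range(n)]
    return F2Genotypes(sites=sites, matrix=matrix, plant_ids=plant_ids)


def assign_phenotypes(
    genotypes: F2Genotypes,
    qtls_tss: list[QtlSpec],
    qtls_ph: list[QtlSpec],
    seed: int,
):
    """Assign TSS and pH to every plant from its QTL genotypes.

    phenotype = baseline + sum over QTLs of the genotype contribution
    (2*effect for sweet homozygotes, 2*effect*dominance for
    heterozygotes, 0 for sour homozygotes) + Gaussian residual.

    Returns a list of :class:`~superbsa.candidates.PhenotypeRecord`
    with generation "F2" and no trait class assigned yet.
    """
    from .candidates import PhenotypeRecord

    rng = np.random.default_rng(seed)

    def trait_values(qtls: list[QtlSpec]) -> np.ndarray:
        if not qtls:
            raise ValueError("need at least one QTL per trait")
        base = qtls[0].baseline
        sd = qtls[0].residual_sd
        vals = np.full(len(genotypes.plant_ids), base, dtype=float)
        for q in qtls:
            try:
                j = genotypes.site_index(q.scaffold, q.position)
            except ValueError:
                raise ValueError(
                    f"QTL site {q.scaffold}:{q.position} absent from genotype table"
                ) from None
            dose = genotypes.matrix[:, j].astype(float)
            contrib = np.where(
                dose == 2.0, 2.0 * q.effect,
                np.where(dose == 1.0, 2.0 * q.effect * q.dominance, 0.0),
            )
            vals += contrib
        vals += rng.normal(0.0, sd, size=len(vals))
        return vals

    tss = trait_values(qtls_tss)
    ph = trait_values(qtls_ph)
    return [
        PhenotypeRecord(plant_id=pid, generation="F2", tss=float(t), ph=float(p))
        for pid, t, p in zip(genotypes.plant_ids, tss, ph)
    ]


def _total_depth(rng: np.random.Generator, mean: float, alpha: float, size: int) -> np.ndarray:
    """Negative-binomial totals with variance mean + alpha*mean^2 (Poisson if alpha=0)."""
    if alpha <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_slaf_depths(
    genome: ReferenceGenome,
    parents: Parents,
    genotypes: F2Genotypes,
    bulks: dict[str, list[str]],
    loci: list[tuple[str, int]],
    model: DepthModel,
    seed: int,
):
    """Simulate pooled tag depths at marker loci for bulks and parents.

    Parameters
    ----------
    bulks
        Mapping of the three F2 pools ("sweet", "sour", "nsns") to their
        member plant ids; all three must be non-empty.
    loci
        Marker positions, each coinciding with a truth SNP site so the
        bulk's true sweet-allele frequency is defined there.

    Returns a :class:`pandas.DataFrame` with one row per locus and
    columns ``M_<pool>``/``P_<pool>`` for pools sweet, sour, nsns,
    parent_M, parent_P: reads attributed to the sweet (M) or sour (P)
    parental allele. Total depth per locus and pool is drawn around the
    pooled mean (negative binomial); reads split binomially at the
    pool's true allele frequency, then flip at the error rate.
    """
    import pandas as pd

    for name in ("sweet", "sour", "nsns"):
        if name not in bulks or not bulks[name]:
            raise ValueError(f"bulk {name!r} is missing or empty")

    rng = np.random.default_rng(seed)
    idx = {pid: i for i, pid in enumerate(genotypes.plant_ids)}
    rows = {pool: np.array([idx[p] for p in members]) for pool, members in bulks.items()}

    e = model.error_rate
    records = []
    for sc, pos in loci:
        j = genotypes.site_index(sc, pos)
        rec: dict[str, object] = {"scaffold": sc, "position": pos}
        for pool in ("sweet", "sour", "nsns"):
            freq = float(genotypes.matrix[rows[pool], j].mean()) / 2.0
            obs = freq * (1 - e) + (1 - freq) * e
            total = int(_total_depth(rng, model.pooled_depth, model.overdispersion, 1)[0])
            m = int(rng.binomial(total, obs)) if total > 0 else 0
            rec[f"M_{pool}"] = m
            rec[f"P_{pool}"] = total - m
        for pool, freq in (("parent_M", 1.0), ("parent_P", 0.0)):
            obs = freq * (1 - e) + (1 - freq) * e
            total = int(_total_depth(rng, model.pooled_depth, model.overdispersion, 1)[0])
            m = int(rng.binomial(total, obs)) if total > 0 else 0
            rec[f"M_{pool}"] = m
            rec[f"P_{pool}"] = total - m
        records.append(rec)

    df = pd.DataFrame.from_records(records)
    df.insert(0, "marker", [f"SLAF{i + 1}" for i in range(len(df))])
    return df
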