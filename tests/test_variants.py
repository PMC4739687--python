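"""Variant screening, annotation and differential-set extraction."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from superbsa import sim
from superbsa.variants import (
    VariantAnnotation,
    VariantCall,
    annotate_variant,
    classify_substitution,
    differential_variants,
    filter_snp_calls,
    polymorphic_genes,
    summarize_variants,
    validate_sv,
)


def snp(sample="a", scaffold="s1", pos=100, ref="G", alt="A", depth=10,
        qual=50.0, zyg="hom"):
    return VariantCall(sample, scaffold, pos, "SNP", ref, alt, depth, qual, zyg)


def sv(kind="DEL", depth=50, qual=30.0, pos=500, scaffold="s1", sample="a"):
    end = pos + 100 if kind in ("DEL", "DII", "INV", "ITX") else None
    return VariantCall(sample, scaffold, pos, kind, "N", f"<{kind}>", depth, qual, "hom", end)


class TestClassifySubstitution:
    def test_all_twelve_ordered_pairs(self):
        """Exactly the 4 purine-purine / pyrimidine-pyrimidine pairs are transitions."""
        results = {
            (r, a): classify_substitution(r, a)
            for r, a in itertools.permutations("ACGT", 2)
        }
        transitions = {p for p, c in results.items() if c == "transition"}
        assert transitions == {("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")}
        assert sum(c == "transversion" for c in results.values()) == 8

    @pytest.mark.parametrize("bad", [("A", "A"), ("N", "A"), ("A", "n")])
    def test_rejects_bad_alleles(self, bad):
        with pytest.raises(ValueError):
            classify_substitution(*bad)


class TestFilterSnpCalls:
    REPEATS = {"s1": [(1000, 2000)]}

    @pytest.mark.parametrize(
        "call,expected",
        [
            (snp(depth=2, zyg="hom"), "kept"),
            (snp(depth=1, zyg="hom"), "low_depth"),
            (snp(depth=2, zyg="het"), "low_depth"),
            (snp(depth=3, zyg="het"), "kept"),
            (snp(depth=33), "kept"),
            (snp(depth=34), "high_depth"),
            (snp(depth=10, pos=1500), "repeat"),
            (snp(depth=10, pos=2000), "repeat"),
            (snp(depth=10, pos=2001), "kept"),
        ],
    )
    def test_screening_rules(self, call, expected):
        kept, reasons = filter_snp_calls([call], mean_depth=11, repeats=self.REPEATS)
        if expected == "kept":
            assert kept == [call] and not reasons
        else:
            assert not kept and reasons[call] == expected

    def test_output_subset_and_idempotent(self, rng):
        calls = [
            snp(pos=int(p), depth=int(d), zyg=z)
            for p, d, z in zip(
                rng.integers(1, 3000, 200),
                rng.integers(0, 50, 200),
                rng.choice(["hom", "het"], 200),
            )
        ]
        kept, _ = filter_snp_calls(calls, 11, self.REPEATS)
        assert set(kept) <= set(calls)
        again, reasons = filter_snp_calls(kept, 11, self.REPEATS)
        assert again == kept and not reasons

    def test_rejects_sv_input(self):
        with pytest.raises(ValueError):
            filter_snp_calls([sv()], 11, {})


class TestValidateSv:
    @pytest.mark.parametrize(
        "depth,qual,verdict",
        [
            (50, 30.0, "valid"),
            (2, 21.0, "valid"),
            (100, 21.0, "valid"),
            (1, 30.0, "invalid"),
            (101, 30.0, "invalid"),
            (50, 20.0, "invalid"),  # strict >20
        ],
    )
    def test_bounds(self, depth, qual, verdict):
        assert validate_sv(sv(depth=depth, qual=qual)) == verdict

    def test_rejects_snp(self):
        with pytest.raises(ValueError):
            validate_sv(snp())


@pytest.fixture(scope="module")
def annotated_genome():
    """Two hand-built genes (one per strand) on a fixed sequence."""
    seq = list("A" * 300)
    # plus-strand gene: CDS 101..130 (10 codons)
    seq[100:130] = list("ATGGAAGAAGAAGAAGAAGAAGAAGAATGA")
    # minus-strand gene: CDS 201..230; reverse complement read as mRNA
    minus_mrna = "ATGCTTCTTCTTCTTCTTCTTCTTCTTTGA"
    seq[200:230] = list(str(Seq(minus_mrna).reverse_complement()))
    genome = sim.ReferenceGenome(scaffolds={"s1": "".join(seq)})
    genes = [
        sim.Gene("gplus", "s1", 101, 130, "+", ((101, 130),)),
        sim.Gene("gminus", "s1", 201, 230, "-", ((201, 230),)),
    ]
    return genome, genes


class TestAnnotateVariant:
    def test_synonymous_gaa_to_gag(self, annotated_genome):
        genome, genes = annotated_genome
        # codon 2 is GAA (104..106); third base A->G keeps Glu
        v = snp(pos=106, ref="A", alt="G")
        ann = annotate_variant(v, genes, genome)
        assert (ann.region, ann.subclass, ann.coding_effect) == ("genic", "exonic", "synonymous")
        assert ann.gene_id == "gplus"

    def test_nonsynonymous_gaa_to_gta(self, annotated_genome):
        genome, genes = annotated_genome
        v = snp(pos=105, ref="A", alt="T")  # GAA -> GTA, Glu -> Val
        ann = annotate_variant(v, genes, genome)
        assert ann.coding_effect == "non_synonymous"

    def test_intergenic(self, annotated_genome):
        genome, genes = annotated_genome
        ann = annotate_variant(snp(pos=50, ref="A", alt="C"), genes, genome)
        assert (ann.region, ann.subclass, ann.coding_effect) == ("intergenic", "none", "none")

    def test_minus_strand_matches_full_cds_translation(self, annotated_genome):
        """Every possible substitution in the minus-strand CDS agrees with a
        brute-force translation of the whole mutated CDS."""
        genome, genes = annotated_genome
        gene = genes[1]
        ref_seq = genome.scaffolds["s1"]
        for pos in range(gene.start, gene.end + 1):
            ref_base = ref_seq[pos - 1]
            for alt in "ACGT":
                if alt == ref_base:
                    continue
                ann = annotate_variant(snp(pos=pos, ref=ref_base, alt=alt), genes, genome)
                # oracle: translate the full mutated CDS on the minus strand
                cds = ref_seq[gene.start - 1 : gene.end]
                mut = cds[: pos - gene.start] + alt + cds[pos - gene.start + 1 :]
                before = Seq(cds).reverse_complement().translate()
                after = Seq(mut).reverse_complement().translate()
                expected = "synonymous" if before == after else "non_synonymous"
                assert ann.coding_effect == expected, f"pos {pos} {ref_base}>{alt}"

    def test_annotation_partition_invariants(self):
        with pytest.raises(ValueError):
            VariantAnnotation("intergenic", "none", "synonymous")
        with pytest.raises(ValueError):
            VariantAnnotation("genic", "none", "none")


class TestDifferentialVariants:
    def test_one_sided_call_is_differential(self):
        a = [snp(sample="A", pos=10)]
        assert len(differential_variants(a, [])) == 1

    def test_shared_call_is_not_differential(self):
        a = [snp(sample="A", pos=10)]
        b = [snp(sample="B", pos=10)]
        assert differential_variants(a, b) == []

    def test_toy_six_site_enumeration(self):
        """2 shared + 3 one-sided + 1 opposite-alt = 4 differential sites."""
        a = [
            snp(sample="A", pos=10), snp(sample="A", pos=20),  # shared
            snp(sample="A", pos=30), snp(sample="A", pos=40),  # A-only
            snp(sample="A", pos=60, ref="G", alt="A"),          # opposite alt
        ]
        b = [
            snp(sample="B", pos=10), snp(sample="B", pos=20),
            snp(sample="B", pos=50),                            # B-only
            snp(sample="B", pos=60, ref="G", alt="C"),
        ]
        diff = differential_variants(a, b)
        assert sorted(v.position for v in diff) == [30, 40, 50, 60]


class TestPolymorphicGenes:
    def test_rules(self, annotated_genome):
        genome, genes = annotated_genome
        syn = snp(pos=106, ref="A", alt="G")       # synonymous in gplus
        nonsyn = snp(pos=105, ref="A", alt="T")    # non-synonymous in gplus
        exonic_del = sv(kind="DEL", pos=205)       # exonic SV in gminus
        anns = {v: annotate_variant(v, genes, genome) for v in (syn, nonsyn, exonic_del)}
        assert polymorphic_genes([syn], anns) == set()
        assert polymorphic_genes([nonsyn], anns) == {"gplus"}
        assert polymorphic_genes([exonic_del], anns) == {"gminus"}
        assert polymorphic_genes(
            [exonic_del], anns, sv_validity={exonic_del: "invalid"}
        ) == set()

    def test_matches_brute_force_scan(self, toy_genome, rng):
        """Planted exonic/intergenic variants: gene set equals an exhaustive scan."""
        genes = toy_genome.genes[:6]
        variants, anns = [], {}
        for i in range(60):
            sc = "scaffold0001"
            pos = int(rng.integers(1, len(toy_genome.scaffolds[sc])))
            ref = toy_genome.scaffolds[sc][pos - 1]
            alt = "A" if ref != "A" else "C"
            v = snp(sample="A", scaffold=sc, pos=pos, ref=ref, alt=alt)
            variants.append(v)
            anns[v] = annotate_variant(v, genes, toy_genome)
        got = polymorphic_genes(variants, anns)
        expected = set()
        for v in variants:
            for g in genes:
                in_cds = g.scaffold == v.scaffold and any(s <= v.position <= e for s, e in g.cds)
                if in_cds and anns[v].coding_effect == "non_synonymous":
                    expected.add(g.gene_id)
        assert got == expected


class TestSummaries:
    def test_partition_conservation(self, toy_genome, rng):
        genes = toy_genome.genes
        calls, anns = [], {}
        for i in range(200):
            sc = rng.choice(list(toy_genome.scaffolds))
            pos = int(rng.integers(1, len(toy_genome.scaffolds[sc])))
            ref = toy_genome.scaffolds[sc][pos - 1]
            alt = "G" if ref != "G" else "T"
            v = snp(sample="A", scaffold=sc, pos=pos, ref=ref, alt=alt)
            calls.append(v)
            anns[v] = annotate_variant(v, genes, toy_genome)
        s = summarize_variants(calls, anns)
        assert s.genic + s.intergenic == s.total
        exonic_intronic = s.exonic + s.intronic
        assert exonic_intronic == s.genic
        assert s.transitions + s.transversions == s.total
        coding_assigned = sum(
            1 for v in calls if anns[v].coding_effect != "none"
        )
        assert s.synonymous + s.non_synonymous == coding_assigned

    def test_uniform_substitutions_give_ts_tv_half(self):
        """A uniform substitution process has 4 transition / 8 transversion pairs."""
        rng = np.random.default_rng(7)
        n = 10_000
        pairs = [tuple(rng.choice(list("ACGT"), 2, replace=False)) for _ in range(n)]
        ts = sum(classify_substitution(r, a) == "transition" for r, a in pairs)
        p = ts / n
        assert abs(p - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / n)
        # Ts/Tv = p/(1-p) near 0.5
        assert 0.45 < p / (1 - p) < 0.55

    def test_transition_enriched_process_reaches_observed_regime(self):
        """With transition probability 0.71 the Ts/Tv ratio lands near 2.4."""
        rng = np.random.default_rng(8)
        n = 10_000
        ts = 0
        transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
        for _ in range(n):
            ref = rng.choice(list("ACGT"))
            if rng.random() < 0.71:
                alt = transitions[ref]
            else:
                alt = rng.choice([b for b in "ACGT" if b != ref and b != transitions[ref]])
            ts += classify_substitution(ref, alt) == "transition"
        ratio = ts / (n - ts)
        assert 2.2 < ratio < 2.7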