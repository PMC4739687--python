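"""Generator behaviour: determinism, planted-truth arithmetic, Mendelian ratios."""

import math

import numpy as np
import pytest
from scipy import stats

from superbsa import sim


def _genome_fingerprint(g: sim.ReferenceGenome):
    return (
        tuple(sorted(g.scaffolds.items())),
        tuple((x.gene_id, x.scaffold, x.start, x.end, x.strand, x.cds) for x in g.genes),
        tuple(sorted((sc, tuple(iv)) for sc, iv in g.repeats.items())),
    )


class TestMakeGenome:
    def test_seed_determinism(self):
        a = sim.make_genome(2, 100_000, 50, 0.1, seed=1)
        b = sim.make_genome(2, 100_000, 50, 0.1, seed=1)
        assert _genome_fingerprint(a) == _genome_fingerprint(b)
        c = sim.make_genome(2, 100_000, 50, 0.1, seed=2)
        assert _genome_fingerprint(a) != _genome_fingerprint(c)

    def test_empty_annotation_case(self):
        g = sim.make_genome(1, 10_000, 0, 0.0, seed=7)
        assert len(g.scaffolds) == 1
        assert g.genes == []
        assert sum(len(v) for v in g.repeats.values()) == 0

    def test_repeat_fraction_realised(self):
        g = sim.make_genome(4, 500_000, 100, 0.2, seed=3)
        covered = sum(e - s + 1 for ivs in g.repeats.values() for s, e in ivs)
        assert 0.15 <= covered / 2_000_000 <= 0.25

    def test_gene_models_valid(self, toy_genome):
        for gene in toy_genome.genes:
            assert gene.cds, "every gene needs at least one CDS interval"
            total = sum(e - s + 1 for s, e in gene.cds)
            assert total % 3 == 0

    @pytest.mark.parametrize("args", [(0, 50_000), (1, 5_000)])
    def test_rejects_bad_sizes(self, args):
        n, L = args
        with pytest.raises(ValueError):
            sim.make_genome(n, L, 10, 0.1, seed=0)


class TestMakeParents:
    def test_no_variation_means_identical_parents(self, toy_genome):
        p = sim.make_parents(toy_genome, 0.0, 0.0, 0.0, [], seed=5)
        assert p.truth == []
        assert p.sweet == toy_genome.scaffolds
        assert p.sour == toy_genome.scaffolds

    def test_snp_count_binomial(self):
        g = sim.make_genome(2, 500_000, 0, 0.0, seed=9)
        p = sim.make_parents(g, 1e-3, 0.0, 0.0, [], seed=9)
        n = sum(1 for v in p.truth if v.kind == "SNP")
        mean, sd = 1e6 * 1e-3, math.sqrt(1e6 * 1e-3 * (1 - 1e-3))
        assert abs(n - mean) < 3 * sd

    def test_parent_means_from_qtl_arithmetic(self, toy_genome):
        """Four QTLs of effect 0.7375 on baseline 6.8 put the sweet parent at 12.7."""
        qtls, _ = sim.default_qtls(toy_genome, 4, seed=0)
        total = qtls[0].baseline + 2 * sum(q.effect for q in qtls)
        assert total == pytest.approx(12.7)
        _, ph = sim.default_qtls(toy_genome, 4, seed=0)
        assert ph[0].baseline + 2 * sum(q.effect for q in ph) == pytest.approx(6.1)

    def test_parents_homozygous_and_discriminating(self, toy_genome):
        qtls, _ = sim.default_qtls(toy_genome, 2, seed=1)
        p = sim.make_parents(toy_genome, 1e-4, 0.0, 0.0, qtls, seed=1)
        snp_sites = set(p.snp_sites())
        for q in qtls:
            assert (q.scaffold, q.position) in snp_sites
            assert (
                p.sweet[q.scaffold][q.position - 1] != p.sour[q.scaffold][q.position - 1]
            )
        for v in p.truth:
            assert v.zygosity == "hom"
            assert v.sample in ("sweet", "sour")


@pytest.fixture(scope="module")
def parents():
    g = sim.make_genome(1, 1_000_000, 0, 0.0, seed=21)
    return sim.make_parents(g, 2e-5, 0.0, 0.0, [], seed=21)


@pytest.fixture(scope="module")
def depth_setup():
    g = sim.make_genome(1, 50_000, 0, 0.0, seed=31)
    q = sim.QtlSpec("TSS", "scaffold0001", 25_000, 0.7, 6.8, 0.0)
    p = sim.make_parents(g, 5e-4, 0.0, 0.0, [q], seed=31)
    geno = sim.simulate_cross(p, sim.CrossConfig(n_f2=60, crossover_rate=0.5, seed=31))
    bulks = {
        "sweet": geno.plant_ids[:20],
        "sour": geno.plant_ids[20:40],
        "nsns": geno.plant_ids[40:60],
    }
    return g, p, geno, bulks


class TestSimulateCross:
    def test_no_recombination_gives_constant_genotype(self, parents):
        geno = sim.simulate_cross(parents, sim.CrossConfig(n_f2=20, crossover_rate=0.0, seed=3))
        by_sc = {}
        for j, (sc, pos) in enumerate(geno.sites):
            by_sc.setdefault(sc, []).append(j)
        for cols in by_sc.values():
            block = geno.matrix[:, cols]
            assert (block == block[:, [0]]).all()

    def test_single_site_heterozygote_fraction(self):
        g = sim.make_genome(1, 10_000, 0, 0.0, seed=2)
        q = sim.QtlSpec("TSS", "scaffold0001", 5_000, 0.7, 6.8, 0.8)
        p = sim.make_parents(g, 0.0, 0.0, 0.0, [q], seed=2)
        geno = sim.simulate_cross(p, sim.CrossConfig(n_f2=2000, crossover_rate=0.5, seed=4))
        het = (geno.matrix[:, 0] == 1).mean()
        assert abs(het - 0.5) < 3 * math.sqrt(0.25 / 2000)

    def test_two_site_recombinant_fraction_matches_haldane(self, parents):
        """Sites 1 Mb apart at 1 crossover/Mb recombine at (1 - e^-2)/2 per gamete."""
        sites = [(sc, pos) for sc, pos in parents.snp_sites()]
        lo = min(p for _, p in sites)
        hi = max(p for _, p in sites)
        assert hi - lo > 900_000  # random SNPs span most of the megabase
        geno = sim.simulate_cross(parents, sim.CrossConfig(n_f2=4000, crossover_rate=1.0, seed=8))
        j_lo = geno.site_index("scaffold0001", lo)
        j_hi = geno.site_index("scaffold0001", hi)
        d_morgan = (hi - lo) / 1_000_000  # map length between the two sites
        r = 0.5 * (1 - math.exp(-2 * d_morgan))
        # F2 double-heterozygote phase is unobservable from dosage; use
        # homozygote-homozygote combinations, where the parental:recombinant
        # split is (1-r)^2 : r^2 per plant (two independent gametes).
        a = geno.matrix[:, j_lo]
        b = geno.matrix[:, j_hi]
        hom = (a != 1) & (b != 1)
        recomb = (hom & (a != b)).sum()
        parental = (hom & (a == b)).sum()
        expected = r**2 / (r**2 + (1 - r) ** 2)
        frac = recomb / (recomb + parental)
        sd = math.sqrt(expected * (1 - expected) / (recomb + parental))
        assert abs(frac - expected) < 4 * sd

    def test_genotype_frequencies_fit_1_2_1(self):
        g = sim.make_genome(1, 10_000, 0, 0.0, seed=6)
        q = sim.QtlSpec("TSS", "scaffold0001", 5_000, 0.7, 6.8, 0.8)
        p = sim.make_parents(g, 0.0, 0.0, 0.0, [q], seed=6)
        geno = sim.simulate_cross(p, sim.CrossConfig(n_f2=2000, crossover_rate=0.5, seed=7))
        counts = [int((geno.matrix[:, 0] == k).sum()) for k in (0, 1, 2)]
        chi2 = stats.chisquare(counts, f_exp=[500, 1000, 500]).pvalue
        assert chi2 > 0.001


class TestAssignPhenotypes:
    def test_noiseless_homozygote_hits_parent_mean(self, toy_genome):
        qtls_t, qtls_p = sim.default_qtls(toy_genome, 2, seed=3)
        qtls_t = [sim.QtlSpec(q.trait, q.scaffold, q.position, q.effect, q.baseline, 0.0, q.dominance) for q in qtls_t]
        qtls_p = [sim.QtlSpec(q.trait, q.scaffold, q.position, q.effect, q.baseline, 0.0, q.dominance) for q in qtls_p]
        parents = sim.make_parents(toy_genome, 0.0, 0.0, 0.0, qtls_t + qtls_p, seed=3)
        geno = sim.simulate_cross(parents, sim.CrossConfig(n_f2=50, crossover_rate=0.5, seed=3))
        recs = sim.assign_phenotypes(geno, qtls_t, qtls_p, seed=3)
        sites_t = [geno.site_index(q.scaffold, q.position) for q in qtls_t]
        for rec, row in zip(recs, geno.matrix):
            if all(row[j] == 2 for j in sites_t):
                assert rec.tss == pytest.approx(6.8 + 2 * sum(q.effect for q in qtls_t))

    def test_missing_qtl_site_is_configuration_error(self, toy_genome):
        qtls_t, qtls_p = sim.default_qtls(toy_genome, 2, seed=4)
        parents = sim.make_parents(toy_genome, 0.0, 0.0, 0.0, qtls_t, seed=4)  # pH sites absent
        geno = sim.simulate_cross(parents, sim.CrossConfig(n_f2=10, crossover_rate=0.5, seed=4))
        with pytest.raises(ValueError, match="absent"):
            sim.assign_phenotypes(geno, qtls_t, qtls_p, seed=4)


class TestSimulateSlafDepths:
    def test_error_free_parent_pools_are_fixed(self, depth_setup):
        g, p, geno, bulks = depth_setup
        model = sim.DepthModel(error_rate=0.0, overdispersion=0.0)
        loci = p.snp_sites()[:50]
        df = sim.simulate_slaf_depths(g, p, geno, bulks, loci, model, seed=1)
        assert (df["P_parent_M"] == 0).all()
        assert (df["M_parent_P"] == 0).all()

    def test_balanced_bulk_mean_fraction(self, depth_setup):
        g, p, geno, bulks = depth_setup
        model = sim.DepthModel(error_rate=0.0, overdispersion=0.0, pooled_depth=160)
        loci = p.snp_sites()
        df = sim.simulate_slaf_depths(g, p, geno, bulks, loci, model, seed=2)
        frac = (df["M_sweet"] / (df["M_sweet"] + df["P_sweet"])).mean()
        true_frac = np.mean(
            [geno.matrix[[geno.plant_ids.index(x) for x in bulks["sweet"]],
                         geno.site_index(sc, pos)].mean() / 2
             for sc, pos in loci]
        )
        assert abs(frac - true_frac) < 0.02

    def test_parental_pool_depth_near_configured_mean(self):
        g = sim.make_genome(1, 1_000_000, 0, 0.0, seed=33)
        p = sim.make_parents(g, 1e-3, 0.0, 0.0, [], seed=33)
        geno = sim.simulate_cross(p, sim.CrossConfig(n_f2=30, crossover_rate=0.5, seed=33))
        bulks = {
            "sweet": geno.plant_ids[:10],
            "sour": geno.plant_ids[10:20],
            "nsns": geno.plant_ids[20:30],
        }
        loci = p.snp_sites()[:1000]
        df = sim.simulate_slaf_depths(g, p, geno, bulks, loci, sim.DepthModel(pooled_depth=160), seed=3)
        total = df["M_parent_M"] + df["P_parent_M"]
        assert abs(total.mean() - 160) / 160 < 0.1

    def test_empty_bulk_rejected(self, depth_setup):
        g, p, geno, _ = depth_setup
        with pytest.raises(ValueError, match="sour"):
            sim.simulate_slaf_depths(
                g, p, geno, {"sweet": geno.plant_ids[:5], "sour": [], "nsns": geno.plant_ids[5:10]},
                p.snp_sites()[:5], sim.DepthModel(), seed=1,
            )
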