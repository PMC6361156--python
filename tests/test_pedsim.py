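"""Unit and property tests for the cohort simulator."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import wilcoxon

from enumap._rng import stage_rng
from enumap.io.plink import MISSING
from enumap.pedsim import (
    CausalPlant,
    EnuModel,
    GenomeSpec,
    Individual,
    Pedigree,
    SiteMap,
    assign_phenotypes,
    breed_pedigree,
    default_design,
    founder_haplotypes,
    genotype_markers,
    simulate_founder_mutations,
)
from enumap.pedsim.breed import _draw_gamete
from enumap.pedsim.cohort import SimParams, simulate_cohort
from enumap.pedsim.pedigree import AFFECTED, BreedingDesign, FEMALE, MALE, UNAFFECTED
from enumap.assoc.permute import tdt_scan

import pandas as pd


SPEC2 = GenomeSpec(chromosomes=(("chr1", 10_000_000), ("chr2", 5_000_000)))


def _site_map(rows_by_chrom):
    tables = {}
    for chrom, rows in rows_by_chrom.items():
        tables[chrom] = pd.DataFrame(
            rows, columns=["pos", "kind", "name", "ref", "alt", "maf"]
        )
    return SiteMap(tables)


class TestGenomeSpec:
    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(chromosomes=(("chr1", 0),))

    def test_base_composition_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GenomeSpec(chromosomes=(("chr1", 100),), base_composition=(0.5, 0.5, 0.5, 0.5))

    def test_negative_recombination_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(chromosomes=(("chr1", 100),), recombination_rate=-1)


class TestFounderMutations:
    def test_zero_mean_gives_empty_list(self):
        assert simulate_founder_mutations(SPEC2, EnuModel(0.0), 1) == []

    def test_same_seed_identical(self):
        a = simulate_founder_mutations(SPEC2, EnuModel(50.0), 123)
        b = simulate_founder_mutations(SPEC2, EnuModel(50.0), 123)
        assert a == b

    def test_different_seed_differs(self):
        a = simulate_founder_mutations(SPEC2, EnuModel(50.0), 123)
        b = simulate_founder_mutations(SPEC2, EnuModel(50.0), 124)
        assert a != b

    def test_poisson_mean_monte_carlo(self):
        # 1000 replicate seeds: empirical mean within 3 s.e. of the Poisson mean
        mean = 100.0
        n_rep = 1000
        counts = [
            len(simulate_founder_mutations(SPEC2, EnuModel(mean), s))
            for s in range(n_rep)
        ]
        se = np.sqrt(mean / n_rep)
        assert abs(np.mean(counts) - mean) < 3 * se

    def test_alt_differs_from_ref_and_spectrum_respected(self):
        variants = simulate_founder_mutations(SPEC2, EnuModel(500.0), 7)
        assert all(v.ref != v.alt for v in variants)
        # A -> G transitions carry half the A-row mass by default
        a_refs = [v for v in variants if v.ref == "A"]
        frac_ag = np.mean([v.alt == "G" for v in a_refs])
        assert abs(frac_ag - 0.5) < 3 * np.sqrt(0.25 / len(a_refs))


def _two_founder_cross(n_children: int, hap_sire, hap_dam, rate: float = 0.0):
    """Minimal sire x dam cross over one chromosome with explicit haplotypes."""
    spec = GenomeSpec(chromosomes=(("chr1", 1_000_000),), recombination_rate=rate)
    n_sites = len(hap_sire[0])
    positions = np.linspace(1, 1_000_000, n_sites, dtype=int)
    sites = _site_map(
        {
            "chr1": [
                (int(p), "marker", f"m{i}", "A", "G", 0.5)
                for i, p in enumerate(positions)
            ]
        }
    )
    inds = [
        Individual("S", sex=MALE, generation="G0", phenotype=UNAFFECTED),
        Individual("D", sex=FEMALE, generation="G0", phenotype=UNAFFECTED),
    ]
    for i in range(n_children):
        inds.append(Individual(f"C{i}", sire="S", dam="D", generation="G1"))
    design = BreedingDesign(pedigree=Pedigree(inds), requirements={}, founder_carrier="S")
    haps = {
        "S": {"chr1": np.array(hap_sire, dtype=np.int8)},
        "D": {"chr1": np.array(hap_dam, dtype=np.int8)},
    }
    return design, spec, sites, haps


class TestBreeding:
    def test_no_recombination_transmits_intact_haplotype(self):
        n_sites = 40
        hap = [[0] * n_sites, [1] * n_sites]
        design, spec, sites, haps = _two_founder_cross(30, hap, hap, rate=0.0)
        truth = breed_pedigree(design, spec, sites, haps, 5)
        for i in range(2, 2 + 30):
            for h in range(2):
                gamete = truth.diplotypes["chr1"][i, h]
                assert gamete.min() == gamete.max()  # all-0 or all-1

    def test_missing_founder_haplotype_raises(self):
        design, spec, sites, haps = _two_founder_cross(1, [[0], [1]], [[0], [1]])
        del haps["D"]
        with pytest.raises(ValueError, match="missing haplotypes"):
            breed_pedigree(design, spec, sites, haps, 5)

    def test_crossover_count_poisson_mean(self):
        # 100 cM chromosome: mean crossover count 1.0, observed as strand
        # switches over a dense site grid (10,000 gametes, 3 s.e. tolerance)
        rng = np.random.default_rng(99)
        n_sites = 2000
        positions = np.linspace(1, 100_000_000, n_sites)
        hap_pair = np.array([[0] * n_sites, [1] * n_sites], dtype=np.int8)
        switches = []
        for _ in range(10_000):
            g = _draw_gamete(rng, positions, hap_pair, 100_000_000, 1.0)
            switches.append(int((np.diff(g) != 0).sum()))
        se = np.sqrt(1.0 / len(switches))
        assert abs(np.mean(switches) - 1.0) < 3 * se

    def test_carrier_cross_recessive_fraction(self):
        # carrier x carrier, penetrance 1, 400 free-segregating offspring:
        # affected fraction inside the 99% binomial interval around 0.25
        hap = [[1], [0]]
        design, spec, sites, haps = _two_founder_cross(400, hap, hap)
        plant = CausalPlant(
            chromosome="chr1",
            position=int(sites.positions("chr1")[0]),
            ref_allele="A",
            alt_allele="G",
            gene="g",
            cds_position=3,
        )
        truth = breed_pedigree(design, spec, sites, haps, 17, causal=plant)
        phen = assign_phenotypes(truth, plant, 18)
        n_aff = sum(
            1 for i, p in phen.items() if p == AFFECTED and i not in ("S", "D")
        )
        half_width = 2.576 * np.sqrt(0.25 * 0.75 / 400)
        assert 0.25 - half_width < n_aff / 400 < 0.25 + half_width

    def test_determinism_same_seed(self):
        hap = [[1, 0, 1], [0, 1, 0]]
        design, spec, sites, haps = _two_founder_cross(20, hap, hap, rate=2.0)
        t1 = breed_pedigree(design, spec, sites, haps, 21)
        t2 = breed_pedigree(design, spec, sites, haps, 21)
        assert np.array_equal(t1.diplotypes["chr1"], t2.diplotypes["chr1"])


class TestPhenotypes:
    def test_recessive_penetrant_rules(self, small_cohort):
        dosages = small_cohort.truth.causal_dosage()
        for ind in small_cohort.truth.pedigree.individuals:
            if dosages[ind.id] == 2:
                assert ind.phenotype == AFFECTED
            else:
                assert ind.phenotype == UNAFFECTED

    def test_heterozygote_unaffected(self, small_cohort):
        dosages = small_cohort.truth.causal_dosage()
        hets = [i for i, d in dosages.items() if d == 1]
        assert hets, "design should produce carriers"
        for i in hets:
            assert small_cohort.truth.pedigree[i].phenotype == UNAFFECTED

    def test_zero_penetrance_all_unaffected(self):
        hap = [[1], [0]]
        design, spec, sites, haps = _two_founder_cross(50, hap, hap)
        plant = CausalPlant(
            chromosome="chr1",
            position=int(sites.positions("chr1")[0]),
            ref_allele="A",
            alt_allele="G",
            gene="g",
            cds_position=3,
            penetrance=0.0,
        )
        truth = breed_pedigree(design, spec, sites, haps, 3, causal=plant)
        phen = assign_phenotypes(truth, plant, 4)
        assert set(phen.values()) == {UNAFFECTED}


class TestDesign:
    def test_default_design_counts(self):
        design = default_design()
        ped = design.pedigree
        assert len(ped) == 3 + 4 + 8 + 40
        g3 = [i for i in ped.individuals if i.generation == "G3"]
        assert len(g3) == 40
        assert len(ped.founders()) == 3

    def test_design_cohort_hits_requested_counts(self, small_cohort):
        ped = small_cohort.truth.pedigree
        affected = [i for i in ped.individuals if i.phenotype == AFFECTED]
        assert len(affected) == 15
        g3 = [i for i in ped.individuals if i.generation == "G3"]
        assert len(g3) - len(affected) == 25

    def test_pedigree_rejects_unknown_parent(self):
        with pytest.raises(ValueError):
            Pedigree([Individual("kid", sire="nobody", dam="nobody2")])

    def test_pedigree_rejects_child_before_parent(self):
        kid = Individual("kid", sire="S", dam="D")
        s = Individual("S", sex=MALE)
        d = Individual("D", sex=FEMALE)
        with pytest.raises(ValueError):
            Pedigree([kid, s, d])


class TestMarkers:
    def test_zero_missing_rate_full_call_rate(self, small_cohort):
        assert (small_cohort.matrix.call_rate() == 1.0).all()

    def test_mendelian_consistency_exhaustive(self, small_cohort):
        # error-free calls must be transmissible in every trio at every marker
        matrix = small_cohort.matrix
        ped = small_cohort.truth.pedigree
        contributions = {0: {0}, 1: {0, 1}, 2: {1}}
        for sire, dam, child in ped.trios():
            gf = matrix.geno[:, matrix.sample_index(sire.id)]
            gm = matrix.geno[:, matrix.sample_index(dam.id)]
            gc = matrix.geno[:, matrix.sample_index(child.id)]
            for f, m, c in zip(gf, gm, gc):
                assert any(
                    a + b == c for a in contributions[f] for b in contributions[m]
                )

    def test_missing_rate_binomial_moment(self, small_cohort):
        matrix = genotype_markers(small_cohort.truth, 0.2, 0.0, 31)
        calls = matrix.geno != MISSING
        n = calls.size
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(calls.mean() - 0.8) < 3 * se

    def test_invalid_rates_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            genotype_markers(small_cohort.truth, -0.1, 0.0, 1)
        with pytest.raises(ValueError):
            genotype_markers(small_cohort.truth, 0.0, 1.5, 1)


class TestCohortDeterminism:
    def test_same_seed_same_cohort(self):
        p = SimParams(n_markers=200, enu_mean=100, n_background_genes=10)
        c1 = simulate_cohort(p, 5)
        c2 = simulate_cohort(p, 5)
        assert np.array_equal(c1.matrix.geno, c2.matrix.geno)
        for chrom in c1.truth.sites.chromosomes:
            assert np.array_equal(c1.truth.diplotypes[chrom], c2.truth.diplotypes[chrom])

    def test_emitted_files_byte_identical(self, tmp_path):
        from enumap.pedsim.cohort import emit_cohort

        p = SimParams(n_markers=150, enu_mean=100, n_background_genes=10)
        paths1 = emit_cohort(simulate_cohort(p, 9), tmp_path / "a", 9)
        paths2 = emit_cohort(simulate_cohort(p, 9), tmp_path / "b", 9)
        for name in ("ped", "map", "vcf", "gff", "fasta", "truth"):
            assert paths1[name].read_bytes() == paths2[name].read_bytes(), name


class TestLinkageSignal:
    def test_markers_near_causal_score_higher(self):
        # over 50 replicates the mean TDT statistic within 10 cM of the
        # causal site stochastically dominates the unlinked background
        near_means, far_means = [], []
        params = SimParams(
            n_markers=300, enu_mean=0.0, n_background_genes=0,
            n_shared_variants=0, n_controls=0, missing_rate=0.0,
        )
        for seed in range(50):
            cohort = simulate_cohort(params, 1000 + seed)
            res = tdt_scan(cohort.matrix, cohort.truth.pedigree)
            causal = cohort.truth.causal
            near = res[
                (res["chrom"] == causal.chromosome)
                & ((res["pos"] - causal.position).abs() <= 10_000_000)
            ]
            far = res[res["chrom"] != causal.chromosome]
            near_means.append(near["chi2"].mean())
            far_means.append(far["chi2"].mean())
        stat = wilcoxon(near_means, far_means, alternative="greater")
        assert stat.pvalue < 1e-6


class TestFixtureGene:
    def test_reference_base_at_cds_1226(self, fx):
        assert fx.cds[1225] == "A"

    def test_exon10_length(self, fx):
        assert fx.transcript.exon("ex10").length == 103

    def test_codon_409_is_aspartate(self, fx):
        from enumap.splice import translate_cds

        protein, _, _ = translate_cds(fx.cds)
        assert protein[408] == "D"

    def test_at_least_11_exons(self, fx):
        assert len(fx.transcript.exons) >= 11

    def test_motif_context(self, fx):
        assert fx.cds[1224:1233] == "GATCTGAGG"

    def test_minigene_definition(self, fx):
        assert fx.minigene.vector_contribution == 169
        assert sorted(fx.minigene.segments.values()) == [91, 103, 164]

    def test_fragment_sequence_matches_cds_at_causal(self, fx):
        pos = fx.gene.genomic_position_of_cds(1226)
        assert pos == fx.plant.position
        assert fx.fragments.base_at(fx.gene.chrom, pos) == "A"


class TestExomeEmission:
    def test_sequenced_homozygotes_written_1_1(self, small_cohort, tmp_path):
        from enumap.pedsim import emit_exome_vcf

        path = emit_exome_vcf(small_cohort.truth, small_cohort.sequenced, tmp_path / "x.vcf")
        causal = small_cohort.truth.causal
        causal_lines = [
            line
            for line in path.read_text().splitlines()
            if line.startswith(f"{causal.chromosome}\t{causal.position}\t")
        ]
        assert len(causal_lines) == 1
        fields = causal_lines[0].split("\t")
        assert fields[9:] == ["1/1", "1/1"]

    def test_zero_sequenced_header_only(self, small_cohort, tmp_path):
        from enumap.pedsim import emit_exome_vcf

        path = emit_exome_vcf(small_cohort.truth, [], tmp_path / "empty.vcf")
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body == []

    def test_round_trip_reproduces_truth(self, small_cohort, tmp_path):
        from enumap.io.vcfio import read_vcf
        from enumap.pedsim import emit_exome_vcf

        path = emit_exome_vcf(small_cohort.truth, small_cohort.sequenced, tmp_path / "r.vcf")
        records, samples = read_vcf(path)
        assert samples == small_cohort.sequenced
        for rec in records:
            want = small_cohort.truth.genotype_at(rec.chrom, rec.pos)
            for s in samples:
                assert rec.genotypes[s] == want[s]

    def test_unknown_individual_rejected(self, small_cohort, tmp_path):
        from enumap.pedsim import emit_exome_vcf

        with pytest.raises(KeyError):
            emit_exome_vcf(small_cohort.truth, ["ghost"], tmp_path / "g.vcf")
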