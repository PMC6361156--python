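"""Coverage, annotation and filter-cascade tests."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from enumap.assoc.regions import RegionCall
from enumap.exome import (
    Annotation,
    CascadeThresholds,
    CoverageConfig,
    FragmentStore,
    GeneModel,
    Variant,
    annotate_effect,
    cds_pos_to_codon,
    count_genes_in_region,
    coverage_summary,
    filter_cascade,
    novelty_check,
    segregation_test,
)
from enumap.splice.transcript import CODON_TABLE

from oracles import coverage_fraction_naive, overlap_count_naive


class TestCoverage:
    def test_simple_fraction(self):
        depths = {("chr1", 1, 4): np.array([25, 25, 10, 30])}
        frac, hist = coverage_summary(depths, CoverageConfig(min_depth=20))
        assert frac == pytest.approx(0.75)
        assert hist.sum() == 4

    def test_boundary_inclusive(self):
        depths = {("chr1", 1, 5): np.full(5, 20)}
        frac, _ = coverage_summary(depths, CoverageConfig(min_depth=20))
        assert frac == 1.0

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            coverage_summary({}, CoverageConfig())

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(8)
        depths = {}
        tracks = []
        pos = 1
        for _ in range(6):
            n = int(rng.integers(5, 40))
            track = rng.poisson(22, size=n)
            depths[("chr1", pos, pos + n - 1)] = track
            tracks.append(track.tolist())
            pos += n + 10
        frac, hist = coverage_summary(depths, CoverageConfig(min_depth=20))
        assert frac == pytest.approx(coverage_fraction_naive(tracks, 20))
        assert hist.sum() == sum(len(t) for t in tracks)

    def test_mismatched_track_length_rejected(self):
        with pytest.raises(ValueError):
            coverage_summary({("chr1", 1, 3): np.array([1, 2])}, CoverageConfig())


class TestCdsPosToCodon:
    def test_paper_position(self):
        assert cds_pos_to_codon(1226) == (409, 2)

    def test_first_base(self):
        assert cds_pos_to_codon(1) == (1, 1)

    def test_third_base(self):
        assert cds_pos_to_codon(3) == (1, 3)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            cds_pos_to_codon(0)


class TestAnnotate:
    def test_fixture_causal_missense(self, fx):
        ann = annotate_effect(
            fx.gene.chrom, fx.plant.position, "A", "G", [fx.gene], fx.fragments
        )
        assert ann.effect == "missense"
        assert ann.hgvs_c == "c.1226A>G"
        assert ann.hgvs_p == "p.D409G"
        assert ann.codon_index == 409

    def test_synonymous_third_position(self, fx):
        # find a codon whose third-base change is synonymous
        cds = fx.cds
        for codon_idx in range(2, 200):
            cds_pos = codon_idx * 3  # third base of codon codon_idx
            codon = cds[cds_pos - 3 : cds_pos]
            for alt in "ACGT":
                if alt == codon[2]:
                    continue
                if CODON_TABLE[codon[:2] + alt] == CODON_TABLE[codon]:
                    pos = fx.gene.genomic_position_of_cds(cds_pos)
                    ann = annotate_effect(
                        fx.gene.chrom, pos, codon[2], alt, [fx.gene], fx.fragments
                    )
                    assert ann.effect == "synonymous"
                    assert ann.hgvs_p.endswith("=")
                    return
        pytest.fail("no synonymous change found in the first 200 codons")

    def test_nonsense_creation(self, fx):
        cds = fx.cds
        for codon_idx in range(2, 400):
            start = (codon_idx - 1) * 3
            codon = cds[start : start + 3]
            for off in range(3):
                for alt in "ACGT":
                    if alt == codon[off]:
                        continue
                    mutated = codon[:off] + alt + codon[off + 1 :]
                    if CODON_TABLE[mutated] == "*":
                        pos = fx.gene.genomic_position_of_cds(start + off + 1)
                        ann = annotate_effect(
                            fx.gene.chrom, pos, codon[off], alt, [fx.gene], fx.fragments
                        )
                        assert ann.effect == "nonsense"
                        return
        pytest.fail("no stop-creating change found")

    def test_intergenic_is_non_coding(self, fx):
        ann = annotate_effect(fx.gene.chrom, 1_000, "A", "G", [fx.gene], fx.fragments)
        assert ann.effect == "non_coding"
        assert ann.gene is None

    def test_splice_site_within_two_bp(self, fx):
        donor_pos = fx.gene.exons[0][1] + 1  # first intron base
        ref = fx.fragments.base_at(fx.gene.chrom, donor_pos)
        alt = "A" if ref != "A" else "C"
        ann = annotate_effect(fx.gene.chrom, donor_pos, ref, alt, [fx.gene], fx.fragments)
        assert ann.effect == "splice_site"

    def test_deep_intron_non_coding(self, fx):
        mid_intron = (fx.gene.exons[0][1] + fx.gene.exons[1][0]) // 2
        ref = fx.fragments.base_at(fx.gene.chrom, mid_intron)
        alt = "A" if ref != "A" else "C"
        ann = annotate_effect(fx.gene.chrom, mid_intron, ref, alt, [fx.gene], fx.fragments)
        assert ann.effect == "non_coding"

    def test_reference_mismatch_rejected(self, fx):
        wrong = "C" if fx.cds[1225] != "C" else "T"
        with pytest.raises(ValueError, match="mismatch"):
            annotate_effect(
                fx.gene.chrom, fx.plant.position, wrong, "G", [fx.gene], fx.fragments
            )

    def test_alt_codon_round_trip(self, fx):
        # re-applying the alt base and translating reproduces aa_alt
        rng = np.random.default_rng(3)
        for _ in range(25):
            cds_pos = int(rng.integers(4, len(fx.cds) - 3))
            pos = fx.gene.genomic_position_of_cds(cds_pos)
            ref = fx.cds[cds_pos - 1]
            alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(3))) % 4]
            if alt == ref:
                continue
            ann = annotate_effect(fx.gene.chrom, pos, ref, alt, [fx.gene], fx.fragments)
            codon_start = (ann.codon_index - 1) * 3
            codon = list(fx.cds[codon_start : codon_start + 3])
            codon[(cds_pos - 1) % 3] = alt
            assert CODON_TABLE["".join(codon)] == ann.aa_alt


class TestSegregation:
    PHEN = {
        "A1": "affected",
        "A2": "affected",
        "U1": "unaffected",
        "U2": "unaffected",
        "U3": "unaffected",
    }

    def test_perfect_pattern_passes(self):
        geno = {"A1": 2, "A2": 2, "U1": 0, "U2": 1, "U3": 1}
        ok, detail = segregation_test(geno, self.PHEN)
        assert ok
        assert detail["consistent"].dropna().all()

    def test_unaffected_homozygote_fails(self):
        geno = {"A1": 2, "A2": 2, "U1": 2, "U2": 1, "U3": 0}
        ok, _ = segregation_test(geno, self.PHEN)
        assert not ok

    def test_het_affected_fails(self):
        geno = {"A1": 1, "A2": 2, "U1": 0, "U2": 0, "U3": 0}
        ok, _ = segregation_test(geno, self.PHEN)
        assert not ok

    def test_missing_genotypes_skipped_but_listed(self):
        geno = {"A1": 2, "A2": 2, "U1": 0}
        ok, detail = segregation_test(geno, self.PHEN)
        assert ok
        skipped = detail[detail["dosage"].isna()]
        assert set(skipped["individual"]) == {"U2", "U3"}

    def test_no_affected_typed_rejected(self):
        with pytest.raises(ValueError, match="uninformative"):
            segregation_test({"U1": 0}, self.PHEN)


class TestNovelty:
    def _panel(self, dosage):
        return pd.DataFrame(
            {
                "chrom": ["chr1"],
                "pos": [500],
                "ref": ["A"],
                "alt": ["G"],
                "ctrl001": [dosage],
            }
        )

    def test_seen_in_controls_not_novel(self):
        v = Variant("chr1", 500, "A", "G")
        assert novelty_check(v, [self._panel(1)]) is False

    def test_absent_from_controls_novel(self):
        v = Variant("chr1", 500, "A", "G")
        assert novelty_check(v, [self._panel(0)]) is True

    def test_empty_panels_vacuously_novel(self):
        v = Variant("chr1", 500, "A", "G")
        assert novelty_check(v, []) is True
        assert novelty_check(v, [pd.DataFrame()]) is True

    def test_planted_causal_novel_in_simulated_panel(self, small_cohort):
        causal = small_cohort.truth.causal
        v = Variant(causal.chromosome, causal.position, causal.ref_allele, causal.alt_allele)
        assert novelty_check(v, [small_cohort.control_panel]) is True


def _toy_setup(fx):
    """Six handcrafted variants exercising one elimination path each."""
    region = RegionCall("chr1", 49_000_000, 51_000_000, 1, "peak")
    phen = {"A1": "affected", "A2": "affected", "U1": "unaffected", "U2": "unaffected"}
    sequenced = ["A1", "A2"]

    # an off-region gene on the same chromosome
    off_cds = "ATG" + "GAT" * 20 + "TAA"
    off_gene = GeneModel(
        "offG", "chr1", exons=((80_000_000, 80_000_000 + len(off_cds) - 1),),
        cds=((80_000_000, 80_000_000 + len(off_cds) - 1),),
    )
    fragments = FragmentStore()
    chrom_frag = fx.fragments.fragments()["chr1"][0]
    fragments.add("chr1", chrom_frag[0], chrom_frag[2])
    fragments.add("chr1", 80_000_000, off_cds)
    genes = [fx.gene, off_gene]

    def seq_geno(a1=2, a2=2):
        return {"A1": a1, "A2": a2}

    causal = Variant("chr1", fx.plant.position, "A", "G", qual=60, genotypes=seq_geno())

    # synonymous in-region: reuse the search from the annotation tests
    syn = None
    for codon_idx in range(2, 300):
        cds_pos = codon_idx * 3
        codon = fx.cds[cds_pos - 3 : cds_pos]
        for alt in "ACGT":
            if alt != codon[2] and CODON_TABLE[codon[:2] + alt] == CODON_TABLE[codon]:
                syn = Variant(
                    "chr1", fx.gene.genomic_position_of_cds(cds_pos), codon[2], alt,
                    qual=60, genotypes=seq_geno(),
                )
                break
        if syn:
            break

    off_region = Variant(
        "chr1", 80_000_000 + 4, off_cds[4], "A" if off_cds[4] != "A" else "C",
        qual=60, genotypes=seq_geno(),
    )

    # an in-region missense seen in the controls: perturb a non-engineered codon
    def missense_at(codon_idx):
        start = (codon_idx - 1) * 3
        codon = fx.cds[start : start + 3]
        for off, alt in itertools.product(range(3), "ACGT"):
            mutated = codon[:off] + alt + codon[off + 1 :]
            if alt != codon[off] and CODON_TABLE[mutated] not in ("*", CODON_TABLE[codon]):
                return fx.gene.genomic_position_of_cds(start + off + 1), codon[off], alt
        raise AssertionError

    pos_ctrl, ref_ctrl, alt_ctrl = missense_at(50)
    seen_in_controls = Variant("chr1", pos_ctrl, ref_ctrl, alt_ctrl, qual=60, genotypes=seq_geno())
    panel = pd.DataFrame(
        {
            "chrom": ["chr1"],
            "pos": [pos_ctrl],
            "ref": [ref_ctrl],
            "alt": [alt_ctrl],
            "ctrl001": [1],
        }
    )

    pos_het, ref_het, alt_het = missense_at(120)
    het_in_affected = Variant(
        "chr1", pos_het, ref_het, alt_het, qual=60, genotypes=seq_geno(a2=1)
    )

    intergenic = Variant("chr1", 49_500_000, "A", "G", qual=60, genotypes=seq_geno())

    variants = [causal, syn, off_region, seen_in_controls, het_in_affected, intergenic]
    full = {
        (v.chromosome, v.position): {"A1": 2, "A2": 2, "U1": 1, "U2": 0}
        for v in variants
    }
    lookup = lambda v: full[(v.chromosome, v.position)]
    return variants, region, genes, fragments, panel, phen, sequenced, lookup, causal


class TestCascade:
    def test_toy_cascade_isolates_causal(self, fx):
        variants, region, genes, fragments, panel, phen, sequenced, lookup, causal = _toy_setup(fx)
        table, report = filter_cascade(
            variants, region, genes, fragments, [panel], phen, sequenced,
            full_genotypes=lookup,
        )
        frame = report.to_frame()
        assert list(frame["variants_in"]) == [6, 6, 5, 3, 2, 1]
        assert list(frame["variants_out"]) == [6, 5, 3, 2, 1, 1]
        assert len(table) == 1
        assert table.iloc[0]["hgvs_p"] == "p.D409G"
        assert table.iloc[0]["pos"] == causal.position

    def test_empty_variant_list(self, fx):
        _, region, genes, fragments, panel, phen, sequenced, lookup, _ = _toy_setup(fx)
        table, report = filter_cascade(
            [], region, genes, fragments, [panel], phen, sequenced, full_genotypes=lookup
        )
        assert table.empty
        assert (report.to_frame()["variants_out"] == 0).all()

    def test_monotone_counts(self, fx):
        variants, region, genes, fragments, panel, phen, sequenced, lookup, _ = _toy_setup(fx)
        _, report = filter_cascade(
            variants, region, genes, fragments, [panel], phen, sequenced,
            full_genotypes=lookup,
        )
        frame = report.to_frame()
        assert (frame["variants_out"] <= frame["variants_in"]).all()
        assert (frame["variants_in"].values[1:] == frame["variants_out"].values[:-1]).all()

    def test_pure_steps_commute(self, fx):
        # steps 2-5 are per-variant predicates: the surviving set equals the
        # intersection of the predicate sets regardless of order
        variants, region, genes, fragments, panel, phen, sequenced, lookup, _ = _toy_setup(fx)
        from enumap.exome.annotate import DAMAGING_EFFECTS

        def in_region(v):
            return region.contains(v.chromosome, v.position)

        def damaging(v):
            return (
                annotate_effect(v.chromosome, v.position, v.ref, v.alt, genes, fragments).effect
                in DAMAGING_EFFECTS
            )

        def recessive(v):
            return all(v.genotypes.get(s, -1) == 2 for s in sequenced)

        def novel(v):
            return novelty_check(v, [panel])

        expected = {
            id(v) for v in variants if in_region(v) and damaging(v) and recessive(v) and novel(v)
        }
        for order in itertools.permutations([in_region, damaging, recessive, novel]):
            current = list(variants)
            for pred in order:
                current = [v for v in current if pred(v)]
            assert {id(v) for v in current} == expected

    def test_missing_region_rejected(self, fx):
        variants, _, genes, fragments, panel, phen, sequenced, lookup, _ = _toy_setup(fx)
        with pytest.raises(ValueError):
            filter_cascade(
                variants, None, genes, fragments, [panel], phen, sequenced,
                full_genotypes=lookup,
            )

    def test_quality_step_drops_low_qual(self, fx):
        variants, region, genes, fragments, panel, phen, sequenced, lookup, _ = _toy_setup(fx)
        variants[0].qual = 5.0  # the causal variant fails step 1
        table, report = filter_cascade(
            variants, region, genes, fragments, [panel], phen, sequenced,
            full_genotypes=lookup,
        )
        assert report.to_frame().loc[0, "variants_out"] == 5
        assert table.empty


class TestGeneCounting:
    REGION = RegionCall("chr1", 1000, 2000, 1, "m")

    def _gene(self, gene_id, chrom, start, end):
        return GeneModel(gene_id, chrom, exons=((start, end),), cds=((start, end),))

    def test_no_genes(self):
        assert count_genes_in_region([], self.REGION) == 0

    def test_single_base_overlap_counts(self):
        abutting = self._gene("g", "chr1", 2000, 2500)
        assert count_genes_in_region([abutting], self.REGION) == 1
        outside = self._gene("g2", "chr1", 2001, 2500)
        assert count_genes_in_region([outside], self.REGION) == 0

    def test_matches_naive_scan(self):
        rng = np.random.default_rng(12)
        genes = []
        intervals = []
        for i in range(300):
            chrom = f"chr{int(rng.integers(1, 4))}"
            start = int(rng.integers(1, 10_000))
            end = start + int(rng.integers(1, 500))
            genes.append(self._gene(f"g{i}", chrom, start, end))
            intervals.append((chrom, start, end))
        for _ in range(20):
            chrom = f"chr{int(rng.integers(1, 4))}"
            start = int(rng.integers(1, 10_000))
            end = start + int(rng.integers(1, 2_000))
            region = RegionCall(chrom, start, end, 1, "m")
            assert count_genes_in_region(genes, region) == overlap_count_naive(
                intervals, (chrom, start, end)
            )
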