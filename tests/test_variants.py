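"""Variant filtering, TR masking, region annotation and coding effects."""

import pytest
from Bio.Seq import Seq
from hypothesis import given, strategies as st

from evoland import (
    CodingEffect,
    GeneModel,
    RegionClass,
    VariantCall,
    annotate_region,
    classify_coding_effect,
    filter_variants,
    fixed_mutation_rate,
    genotype_specific_mutations,
    mask_tandem_repeats,
    parallel_evolution,
    resolve_region_precedence,
)
from evoland.variants import UnclassifiableVariant, read_variants_tsv


def call(pos=100, ref="A", alt="T", alt_reads=80, depth=113, chrom="chrI"):
    return VariantCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        alt_reads=alt_reads, depth=depth, population_id="p1",
    )


class TestFilterVariants:
    @pytest.mark.parametrize(
        "alt_reads, depth, kept",
        [
            (9, 10, False),    # fails the 10-read support floor
            (60, 113, True),   # 53% at study-like depth: both thresholds met
            (10, 21, False),   # 48% frequency: below the 50% threshold
            (10, 20, True),    # exactly 50%: boundary is inclusive
        ],
    )
    def test_read_and_frequency_thresholds(self, alt_reads, depth, kept):
        calls = [call(alt_reads=alt_reads, depth=depth)]
        assert (len(filter_variants(calls)) == 1) is kept

    def test_empty_input(self):
        assert filter_variants([]) == []

    def test_idempotent_and_order_preserving(self, study):
        calls = study.population_calls("cog7_msh2_1")
        once = filter_variants(calls)
        assert filter_variants(once) == once
        positions = [c.pos for c in once]
        assert positions == sorted(positions)

    def test_commutes_with_tr_masking(self, study):
        calls = study.population_calls("msh2_1")
        trs = {study.genome.chrom: study.genome.tr_intervals}
        a, _ = mask_tandem_repeats(filter_variants(calls), trs)
        kept, _ = mask_tandem_repeats(calls, trs)
        b = filter_variants(kept)
        assert a == b


class TestTandemRepeatMask:
    TRS = {"chrI": [(99, 120)]}  # 0-based half-open = 1-based 100..120

    def test_snp_inside_interval_masked(self):
        retained, masked = mask_tandem_repeats([call(pos=100)], self.TRS)
        assert masked and not retained

    def test_deletion_straddling_boundary_masked(self):
        # 5-base deletion starting before the interval; brute-force check of
        # every base in the ref span against interval membership
        c = call(pos=96, ref="AACGT", alt="A")
        span_bases = range(96, 96 + 5)
        overlaps = any(100 <= p <= 120 for p in span_bases)
        retained, masked = mask_tandem_repeats([c], self.TRS)
        assert overlaps and masked == [c] and not retained

    def test_snp_adjacent_retained(self):
        retained, masked = mask_tandem_repeats([call(pos=99)], self.TRS)
        assert retained and not masked

    def test_empty_mask_retains_all(self):
        calls = [call(pos=p) for p in (1, 50, 1000)]
        retained, masked = mask_tandem_repeats(calls, {})
        assert retained == calls and masked == []

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            mask_tandem_repeats([call()], {"chrI": [(50, 40)]})

    def test_partition_of_input(self, study):
        calls = study.population_calls("nup133_msh2_2")
        trs = {study.genome.chrom: study.genome.tr_intervals}
        retained, masked = mask_tandem_repeats(calls, trs)
        assert sorted(retained + masked, key=lambda c: c.pos) == sorted(
            calls, key=lambda c: c.pos
        )


PLUS_GENE = GeneModel(gene="GP", chrom="chrI", strand="+", cds_start=1000, cds_end=1899)
MINUS_GENE = GeneModel(gene="GM", chrom="chrI", strand="-", cds_start=1000, cds_end=2000)


class TestAnnotateRegion:
    def test_plus_strand_promoter_window(self):
        hits = annotate_region(call(pos=600), [PLUS_GENE])
        assert hits == [("GP", RegionClass.PROMOTER)]

    def test_plus_strand_window_enumeration(self):
        """Every position 500-999 is promoter; 499 and 1000 are not."""
        for pos in range(500, 1000):
            assert annotate_region(call(pos=pos), [PLUS_GENE]) == [
                ("GP", RegionClass.PROMOTER)
            ]
        assert annotate_region(call(pos=499), [PLUS_GENE]) == [
            (None, RegionClass.INTERGENIC)
        ]
        assert annotate_region(call(pos=1000), [PLUS_GENE]) == [
            ("GP", RegionClass.ORF)
        ]

    def test_minus_strand_promoter_is_downstream_in_coordinates(self):
        hits = annotate_region(call(pos=2300), [MINUS_GENE])
        assert hits == [("GM", RegionClass.PROMOTER)]

    def test_minus_strand_terminator_below_start(self):
        hits = annotate_region(call(pos=900), [MINUS_GENE])
        assert hits == [("GM", RegionClass.TERMINATOR)]

    def test_far_variant_is_intergenic(self):
        assert annotate_region(call(pos=20000), [PLUS_GENE]) == [
            (None, RegionClass.INTERGENIC)
        ]

    def test_multi_gene_annotation_preserved(self):
        other = GeneModel(
            gene="GX", chrom="chrI", strand="-", cds_start=100, cds_end=400
        )
        # pos 600: promoter of GP (starts 1000) and promoter of GX (- strand,
        # upstream = above cds_end 400)
        hits = annotate_region(call(pos=600), [PLUS_GENE, other])
        assert set(hits) == {("GP", RegionClass.PROMOTER), ("GX", RegionClass.PROMOTER)}


class TestRegionPrecedence:
    @pytest.mark.parametrize(
        "annotations, expected",
        [
            ([("g1", RegionClass.PROMOTER), ("g2", RegionClass.ORF)], RegionClass.ORF),
            (
                [("g1", RegionClass.PROMOTER), ("g2", RegionClass.TERMINATOR)],
                RegionClass.PROMOTER,
            ),
            ([("g1", RegionClass.TERMINATOR)], RegionClass.TERMINATOR),
            ([], RegionClass.INTERGENIC),
        ],
    )
    def test_orf_over_promoter_over_terminator(self, annotations, expected):
        assert resolve_region_precedence(annotations) is expected


def _toy_gene_and_genome(cds: str, strand: str = "+", offset: int = 10):
    """Place ``cds`` (coding strand) at 1-based position offset+1."""
    genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
    seq = "T" * offset + genomic + "T" * 10
    gene = GeneModel(
        gene="TOY1", chrom="c", strand=strand,
        cds_start=offset + 1, cds_end=offset + len(cds),
    )
    return gene, {"c": seq}


class TestCodingEffect:
    # ATG TGG CTT AAA TAA: Met-Trp-Leu-Lys-stop
    CDS = "ATGTGGCTTAAATAA"

    def test_stop_gain_is_nonsense(self):
        gene, genome = _toy_gene_and_genome(self.CDS)
        # TGG -> TGA: third base of codon 2, genome pos 10+6
        c = call(pos=16, ref="G", alt="A", chrom="c")
        assert classify_coding_effect(c, gene, genome) is CodingEffect.NONSENSE

    def test_wobble_substitution_is_synonymous(self):
        gene, genome = _toy_gene_and_genome(self.CDS)
        # CTT -> CTC, both Leu
        c = call(pos=19, ref="T", alt="C", chrom="c")
        assert classify_coding_effect(c, gene, genome) is CodingEffect.SYNONYMOUS

    def test_missense_is_nonsynonymous(self):
        gene, genome = _toy_gene_and_genome(self.CDS)
        # AAA (Lys) -> AGA (Arg)
        c = call(pos=21, ref="A", alt="G", chrom="c")
        assert classify_coding_effect(c, gene, genome) is CodingEffect.NONSYNONYMOUS

    def test_two_base_deletion_is_frameshift(self):
        gene, genome = _toy_gene_and_genome(self.CDS)
        c = call(pos=13, ref="GCT", alt="G", chrom="c")
        assert classify_coding_effect(c, gene, genome) is CodingEffect.FRAMESHIFT

    def test_three_base_deletion_is_inframe(self):
        gene, genome = _toy_gene_and_genome(self.CDS)
        c = call(pos=13, ref="GCTT", alt="G", chrom="c")
        assert classify_coding_effect(c, gene, genome) is CodingEffect.INFRAME_INDEL

    def test_minus_strand_stop_gain(self):
        gene, genome = _toy_gene_and_genome(self.CDS, strand="-")
        # coding TGG->TGA is genome complement: coding offset 5 maps to
        # genome pos cds_end - 5; coding alt A -> genome T
        pos = gene.cds_end - 5
        ref = genome["c"][pos - 1]
        c = call(pos=pos, ref=ref, alt="T", chrom="c")
        assert classify_coding_effect(c, gene, genome) is CodingEffect.NONSENSE

    def test_outside_cds_is_contract_violation(self):
        gene, genome = _toy_gene_and_genome(self.CDS)
        with pytest.raises(ValueError, match="outside CDS"):
            classify_coding_effect(call(pos=5, chrom="c"), gene, genome)

    def test_ref_mismatch_rejected(self):
        gene, genome = _toy_gene_and_genome(self.CDS)
        with pytest.raises(ValueError, match="does not match"):
            classify_coding_effect(call(pos=16, ref="C", alt="A", chrom="c"), gene, genome)

    def test_ambiguous_base_unclassifiable(self):
        gene, genome = _toy_gene_and_genome("ATGTGNCTTAAATAA")
        with pytest.raises(UnclassifiableVariant):
            classify_coding_effect(call(pos=16, ref="N", alt="A", chrom="c"), gene, genome)

    def test_agrees_with_full_cds_retranslation(self, study):
        """Oracle: re-translate the whole mutated CDS for every planted ORF
        SNV and compare protein sequences directly."""
        genome = study.genome
        checked = 0
        for planted in study.truth.variants.values():
            for v in planted:
                if v.region != "ORF" or len(v.ref) != 1 or len(v.alt) != 1:
                    continue
                gene = next(g for g in genome.genes if g.gene == v.gene)
                got = classify_coding_effect(v.to_call(), gene, genome.genome)
                seq = genome.sequence
                mutated = seq[: v.pos - 1] + v.alt + seq[v.pos:]
                cds_ref = seq[gene.cds_start - 1 : gene.cds_end]
                cds_alt = mutated[gene.cds_start - 1 : gene.cds_end]
                if gene.strand == "-":
                    cds_ref = str(Seq(cds_ref).reverse_complement())
                    cds_alt = str(Seq(cds_alt).reverse_complement())
                prot_ref = str(Seq(cds_ref).translate())
                prot_alt = str(Seq(cds_alt).translate())
                if "*" in prot_alt[:-1]:
                    expected = CodingEffect.NONSENSE
                elif prot_alt == prot_ref:
                    expected = CodingEffect.SYNONYMOUS
                else:
                    expected = CodingEffect.NONSYNONYMOUS
                assert got is expected
                checked += 1
        assert checked > 10


class TestFixedMutationRate:
    def test_worked_example(self):
        assert fixed_mutation_rate(120, 12_000_000, 200) == pytest.approx(5e-8)

    def test_zero_mutations(self):
        assert fixed_mutation_rate(0, 1000, 10) == 0.0

    @given(
        n=st.integers(1, 500),
        size=st.integers(1, 10**7),
        gens=st.floats(1, 1000),
    )
    def test_scaling_laws(self, n, size, gens):
        base = fixed_mutation_rate(n, size, gens)
        assert fixed_mutation_rate(2 * n, size, gens) == pytest.approx(2 * base)
        assert fixed_mutation_rate(n, size, gens / 2) == pytest.approx(2 * base)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            fixed_mutation_rate(1, 0, 10)
        with pytest.raises(ValueError):
            fixed_mutation_rate(1, 10, 0)


class TestGenotypeSpecific:
    GROUPS = {"cog7_msh2": "mutator", "nup133_msh2": "mutator", "msh2": "mutator"}

    def test_gene_shared_within_group_excluded(self):
        sets = {
            "cog7_msh2": {"PMR1", "SEO1"},
            "nup133_msh2": {"CEX1"},
            "msh2": {"SEO1", "URE2"},
        }
        out = genotype_specific_mutations(sets, self.GROUPS)
        assert out["cog7_msh2"] == {"PMR1"}
        assert out["msh2"] == {"URE2"}
        assert out["nup133_msh2"] == {"CEX1"}

    def test_matches_brute_force_set_difference(self):
        import itertools, random
        rng = random.Random(5)
        genes = [f"G{i}" for i in range(12)]
        sets = {s: set(rng.sample(genes, rng.randint(0, 8))) for s in self.GROUPS}
        out = genotype_specific_mutations(sets, self.GROUPS)
        for strain in sets:
            others = set().union(
                *(sets[o] for o in sets if o != strain)
            )
            assert out[strain] == sets[strain] - others

    def test_unassigned_strain_rejected(self):
        with pytest.raises(ValueError):
            genotype_specific_mutations({"x": set()}, {})


class TestParallelEvolution:
    def test_within_and_across_split(self):
        pops = {
            ("nup133", 1): {"WHI2"},
            ("nup133", 2): {"CAN1"},
            ("nup133", 3): {"WHI2"},
            ("wt", 1): {"HOG1"},
            ("cog7", 1): {"HOG1"},
        }
        within, across = parallel_evolution(pops)
        assert within == {"nup133": {"WHI2"}}
        assert across == {"WHI2", "HOG1"}

    def test_all_singletons(self):
        pops = {("a", 1): {"G1"}, ("a", 2): {"G2"}, ("b", 1): {"G3"}}
        within, across = parallel_evolution(pops)
        assert within == {} and across == set()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            parallel_evolution({})


class TestVariantTSV:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\talt_reads\tdepth\n"
            "chrI\t100\tA\tT\t60\t113\n"
        )
        calls = read_variants_tsv(path, population_id="p9")
        assert calls == [
            VariantCall(
                chrom="chrI", pos=100, ref="A", alt="T", alt_reads=60,
                depth=113, population_id="p9",
            )
        ]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\nchrI\t1\n")
        with pytest.raises(ValueError, match="lacks columns"):
            read_variants_tsv(path)
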