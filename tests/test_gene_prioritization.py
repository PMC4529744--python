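import numpy as np
import pytest

from messi.gene_prioritization import (
    accumulated_score,
    four_gamete_blocks,
    gene_pvalue,
    score_genes,
    select_targets,
)
from messi.model_io import GeneAnnotation
from messi.variant_association import AssociationResult

from conftest import make_genotypes


def brute_force_blocks(G, threshold=0.01):
    """Independent oracle: loop over adjacent pairs, count haplotypes."""
    boundaries = []
    for i in range(len(G) - 1):
        pairs = [
            (a, b) for a, b in zip(G[i], G[i + 1]) if a >= 0 and b >= 0
        ]
        n = len(pairs)
        counts = {h: 0 for h in [(0, 0), (0, 1), (1, 0), (1, 1)]}
        for p in pairs:
            counts[p] += 1
        if n and all(c / n >= threshold for c in counts.values()):
            boundaries.append(i)
    blocks = []
    start = 0
    for b in boundaries:
        blocks.append((start, b))
        start = b + 1
    blocks.append((start, len(G) - 1))
    return blocks


class TestFourGameteBlocks:
    def test_two_gametes_stay_in_one_block(self):
        gm = make_genotypes([[0, 0, 1, 1], [0, 0, 1, 1]])
        blocks = four_gamete_blocks(gm)
        assert [(b.first, b.last) for b in blocks] == [(0, 1)]

    def test_four_gametes_split(self):
        gm = make_genotypes([[0, 0, 1, 1], [0, 1, 0, 1]])
        blocks = four_gamete_blocks(gm)
        assert [(b.first, b.last) for b in blocks] == [(0, 0), (1, 1)]

    def test_five_variants_single_recombination(self):
        # all four haplotypes only between indices 2 and 3
        G = np.array(
            [
                [0, 0, 1, 1, 0, 0],
                [0, 0, 1, 1, 0, 0],
                [0, 0, 1, 1, 0, 0],
                [0, 1, 0, 1, 1, 0],
                [0, 1, 0, 1, 1, 0],
            ]
        )
        blocks = four_gamete_blocks(make_genotypes(G))
        assert [(b.first, b.last) for b in blocks] == [(0, 2), (3, 4)]
        assert brute_force_blocks(G) == [(0, 2), (3, 4)]

    def test_chromosomes_never_share_blocks(self):
        G = [[0, 0, 1, 1], [0, 0, 1, 1]]
        gm = make_genotypes(np.vstack([G, G]))
        # move last two variants to another chromosome
        for i in (2, 3):
            object.__setattr__(gm.variants[i], "chromosome", "chr2")
        gm = gm.sort()
        blocks = four_gamete_blocks(gm)
        assert len(blocks) == 2
        assert {b.chromosome for b in blocks} == {"chr1", "chr2"}

    def test_unsorted_input_rejected(self):
        gm = make_genotypes([[0, 1], [1, 0]], positions=[500, 100])
        with pytest.raises(ValueError, match="sorted"):
            four_gamete_blocks(gm)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 22))
            G = rng.integers(0, 2, size=(20, n))
            gm = make_genotypes(G)
            got = [(b.first, b.last) for b in four_gamete_blocks(gm)]
            assert got == brute_force_blocks(G)

    def test_partition_covers_all_variants(self, rng):
        G = rng.integers(0, 2, size=(25, 15))
        blocks = four_gamete_blocks(make_genotypes(G))
        covered = sorted(i for b in blocks for i in range(b.first, b.last + 1))
        assert covered == list(range(25))


def assoc_for(gm, pvals, pathway="PW1", adjusted=None):
    out = []
    for v, p in zip(gm.variants, pvals):
        a = AssociationResult(variant_key=v.key, pathway_id=pathway, beta=0.1,
                              p_value=p)
        out.append(a)
    if adjusted is not None:
        for a, q in zip(out, adjusted):
            a.adjusted_p = q
    return out


class TestGenePvalue:
    def _gm(self):
        # one block of 2 variants (positions 1000, 1100)
        return make_genotypes([[0, 0, 1, 1], [0, 0, 1, 1]])

    def test_min_over_block(self):
        gm = self._gm()
        genes = [GeneAnnotation("g1", "chr1", 1050, 1200, "+")]
        assoc = assoc_for(gm, [0.03, 0.001])
        blocks = four_gamete_blocks(gm)
        assert gene_pvalue(blocks, assoc, genes, gm)["g1"] == 0.001

    def test_block_expansion_can_lower_gene_p(self):
        """A variant outside the gene body but inside an overlapping block
        counts for the gene."""
        gm = self._gm()
        genes = [GeneAnnotation("g1", "chr1", 1090, 1200, "-")]  # body excludes pos 1000
        assoc = assoc_for(gm, [0.0001, 0.5])
        blocks = four_gamete_blocks(gm)
        assert gene_pvalue(blocks, assoc, genes, gm)["g1"] == 0.0001

    def test_min_across_two_blocks(self):
        gm = make_genotypes([[0, 0, 1, 1], [0, 1, 0, 1], [0, 1, 0, 1]])
        genes = [GeneAnnotation("g1", "chr1", 900, 1300, "+")]
        assoc = assoc_for(gm, [0.2, 0.05, 0.01])
        blocks = four_gamete_blocks(gm)
        assert len(blocks) == 2
        assert gene_pvalue(blocks, assoc, genes, gm)["g1"] == 0.01

    def test_gene_without_overlap_absent(self):
        gm = self._gm()
        genes = [GeneAnnotation("far", "chr1", 50000, 51000, "+")]
        assoc = assoc_for(gm, [0.03, 0.001])
        assert gene_pvalue(four_gamete_blocks(gm), assoc, genes, gm) == {}


class TestAccumulatedScore:
    def test_hand_example(self):
        # gene body 200 bp + 800 upstream -> L = 1000
        gm = make_genotypes([[0, 1], [1, 0]], positions=[1910, 1950])
        genes = [GeneAnnotation("g1", "chr1", 1801, 2000, "+")]
        assoc = assoc_for(gm, [0.01, 0.001], adjusted=[0.01, 0.001])
        out = accumulated_score(assoc, genes, gm)
        assert out["g1"] == pytest.approx((2 + 3) / 1000)

    def test_no_significant_variants_zero(self):
        gm = make_genotypes([[0, 1]], positions=[1910])
        genes = [GeneAnnotation("g1", "chr1", 1801, 2000, "+")]
        assoc = assoc_for(gm, [0.5], adjusted=[0.5])
        assert accumulated_score(assoc, genes, gm)["g1"] == 0.0

    def test_doubling_length_halves_score(self):
        gm = make_genotypes([[0, 1]], positions=[1910])
        g1 = GeneAnnotation("g1", "chr1", 1801, 2000, "+")
        g2 = GeneAnnotation("g2", "chr1", 1801, 3000, "+")  # twice the region
        assoc = assoc_for(gm, [0.01], adjusted=[0.01])
        out = accumulated_score(assoc, [g1, g2], gm)
        assert out["g1"] == pytest.approx(2 * out["g2"])

    def test_invariant_to_nonsignificant_variants(self):
        gm = make_genotypes([[0, 1], [1, 0]], positions=[1910, 1950])
        genes = [GeneAnnotation("g1", "chr1", 1801, 2000, "+")]
        both = assoc_for(gm, [0.01, 0.4], adjusted=[0.01, 0.4])
        only = [both[0]]
        a1 = accumulated_score(both, genes, gm)["g1"]
        a2 = accumulated_score(only, genes, gm)["g1"]
        assert a1 == a2

    def test_adding_significant_variant_increases_score(self):
        gm = make_genotypes([[0, 1], [1, 0]], positions=[1910, 1950])
        genes = [GeneAnnotation("g1", "chr1", 1801, 2000, "+")]
        one = assoc_for(gm, [0.01, 0.5], adjusted=[0.01, 0.5])
        two = assoc_for(gm, [0.01, 0.02], adjusted=[0.01, 0.02])
        assert accumulated_score(two, genes, gm)["g1"] > accumulated_score(one, genes, gm)["g1"]

    def test_upstream_extension_is_strand_aware(self):
        gm = make_genotypes([[0, 1]], positions=[2100])
        plus = GeneAnnotation("gp", "chr1", 1000, 2000, "+")  # upstream is 200-999
        minus = GeneAnnotation("gm", "chr1", 1000, 2000, "-")  # upstream is 2001-2800
        assoc = assoc_for(gm, [0.01], adjusted=[0.01])
        out = accumulated_score(assoc, [plus, minus], gm)
        assert out["gp"] == 0.0 and out["gm"] > 0.0


class TestSelectTargets:
    def _scores(self):
        from messi.gene_prioritization import GeneScore

        def gs(gid, p, a):
            return GeneScore(gid, p, a, 1000, 3, 1, {})

        return {
            "PW1": [gs("gA", 0.001, 0.004), gs("gB", 0.01, 0.002),
                    gs("gX", 0.0001, 0.01)],
            "PW2": [gs("gC", 0.02, 0.001)],
        }

    def test_level0_empty(self):
        assert select_targets(0, self._scores(), ["PW1"]) == []

    def test_level1_requires_compounds(self):
        with pytest.raises(ValueError, match="compound"):
            select_targets(1, self._scores(), ["PW1"])

    def test_level3_includes_level2_sections(self, rng):
        from messi.pathway_correlation import CorrelationResult

        corr = [CorrelationResult("PW1", "PW2", 0.99, 1e-6, 1e-5, True)]
        sections = select_targets(3, self._scores(), ["PW1"], corr=corr)
        kinds = [s.source_kind for s in sections]
        assert "target_pathway" in kinds and "correlated_pathway" in kinds

    def test_membership_restricts_below_level4(self):
        scores = self._scores()
        membership = {"PW1": {"gA", "gB"}}
        lvl2 = select_targets(2, scores, ["PW1"], pathway_genes=membership)
        assert "gX" not in lvl2[0].top_by_p
        lvl4 = select_targets(4, scores, ["PW1"], corr=[], pathway_genes=membership)
        genome = [s for s in lvl4 if s.source_kind == "genome"][0]
        assert "gX" in genome.top_by_p  # strong outside gene surfaces genome-wide

    def test_top3_orderings(self):
        sections = select_targets(2, self._scores(), ["PW1"])
        s = sections[0]
        assert s.top_by_p == ["gX", "gA", "gB"]
        # by AS: gX (0.01) > gA (0.004) > gB (0.002)
        assert s.top_by_as == ["gX", "gA", "gB"]


def test_score_genes_counts_effects(rng):
    G = rng.integers(0, 2, size=(4, 8))
    gm = make_genotypes(G, positions=[1900, 1950, 2000, 5000],
                        effects=["missense", "missense", "upstream", "synonymous"])
    genes = [GeneAnnotation("g1", "chr1", 1801, 2100, "+")]
    assoc = assoc_for(gm, [0.01, 0.2, 0.03, 0.9], adjusted=[0.01, 0.2, 0.03, 0.9])
    blocks = four_gamete_blocks(gm)
    scores = score_genes(blocks, assoc, genes, gm)
    s = scores[0]
    assert s.n_variants_total == 3
    assert s.n_variants_significant == 2
    assert s.effect_counts == {"missense": 2, "upstream": 1}
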