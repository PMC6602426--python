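import numpy as np
import pytest

from casdesign import _intervals
from casdesign.enumeration import cut_site
from casdesign.errors import ContractError, CoordinateError
from casdesign.modes import (
    DesignConfig,
    design_knockdown,
    design_knockin,
    design_knockin_arms,
    design_knockout,
    design_nanopore_pairs,
    design_promoter_targeting,
    downstream_atgs,
    promoter_window,
    resolve_isoforms,
)
from casdesign.sequence_io import GeneModel, GenomeIndex, Transcript


class TestIntervals:
    def test_merge(self):
        assert _intervals.merge([(5, 10), (1, 3), (9, 12)]) == [(1, 3), (5, 12)]

    def test_intersect_all(self):
        sets = [[(0, 10), (20, 30)], [(5, 25)]]
        assert _intervals.intersect_all(sets) == [(5, 10), (20, 25)]

    def test_union_all(self):
        sets = [[(0, 10)], [(5, 15)], [(20, 21)]]
        assert _intervals.union_all(sets) == [(0, 15), (20, 21)]

    def test_contains_and_overlaps(self):
        ivs = [(0, 10), (20, 30)]
        assert _intervals.contains(ivs, 2, 8)
        assert not _intervals.contains(ivs, 8, 22)
        assert _intervals.overlaps(ivs, 8, 22)
        assert not _intervals.overlaps(ivs, 12, 18)


class TestResolveIsoforms:
    def test_matches_fixture_manifest(self, standard_fixture):
        for gene, truth in zip(
            standard_fixture.genes, standard_fixture.manifest["genes"]
        ):
            res = resolve_isoforms(gene)
            assert [list(iv) for iv in res.intersection] == truth["intersection"]
            assert [list(iv) for iv in res.union] == truth["union"]

    def test_intersection_subset_of_union(self, standard_fixture):
        for gene in standard_fixture.genes:
            res = resolve_isoforms(gene)
            for s, e in res.intersection:
                assert _intervals.contains(res.union, s, e)

    def test_constitutive_excludes_cassette(self, standard_fixture):
        gene = standard_fixture.genes[0]
        res = resolve_isoforms(gene)
        cassette = next(
            (s, e)
            for s, e in res.union
            if not _intervals.contains(res.intersection, s, e)
        )
        assert not res.is_constitutive(cassette[0], cassette[0] + 10)
        a1 = res.intersection[0]
        assert res.is_constitutive(a1[0], a1[0] + 10)

    def test_bad_mode(self, standard_fixture):
        with pytest.raises(ContractError):
            resolve_isoforms(standard_fixture.genes[0], "both")


class TestKnockout:
    def test_guides_lie_in_cds_and_intersection(self, standard_fixture, cas9):
        gene = standard_fixture.genes[0]
        res = design_knockout(gene, standard_fixture.genome, cas9)
        assert res.guides, "expected at least one knockout guide"
        cds_cov = _intervals.merge(iv for t in gene.transcripts for iv in t.cds)
        for g in res.guides:
            c = g.candidate
            assert _intervals.contains(
                res.resolution.intersection, c.start, c.end
            )
            assert _intervals.overlaps(cds_cov, c.start, c.end)
            assert g.cds_overlap is True
            assert g.constitutive is True
            assert g.cut is not None
            assert g.frameshift is not None
            assert 0.0 <= g.frameshift.frameshift_fraction <= 1.0
            assert g.offtargets.mm0 >= 0
        assert [g.rank for g in res.guides] == list(
            range(1, len(res.guides) + 1)
        )

    def test_cut_sites_consistent(self, standard_fixture, cas9):
        res = design_knockout(
            standard_fixture.genes[0], standard_fixture.genome, cas9
        )
        for g in res.guides:
            assert g.cut == cut_site(g.candidate, cas9)

    def test_noncoding_toggle(self, standard_fixture, cas9):
        gene = standard_fixture.genes[0]
        strict = design_knockout(gene, standard_fixture.genome, cas9)
        relaxed = design_knockout(
            gene,
            standard_fixture.genome,
            cas9,
            DesignConfig(require_cds_overlap=False),
        )
        assert len(relaxed.guides) >= len(strict.guides)
        noncoding_kept = {
            (g.candidate.start, g.candidate.strand)
            for g in relaxed.guides
            if not g.cds_overlap
        }
        noncoding_rejected = {
            (c.start, c.strand)
            for c, reasons in strict.rejected
            if "non_coding" in reasons
        }
        assert noncoding_kept == noncoding_rejected

    def test_empty_intersection_notice(self, cas9):
        genome = GenomeIndex({"c1": "ACGT" * 300})
        t1 = Transcript("t1", "g", "c1", "+", ((100, 200),))
        t2 = Transcript("t2", "g", "c1", "+", ((300, 400),))
        res = design_knockout(GeneModel("g", (t1, t2)), genome, cas9)
        assert res.guides == []
        assert any("empty" in n for n in res.notices)

    def test_rna_effector_rejected(self, standard_fixture, cas13a):
        with pytest.raises(ContractError):
            design_knockout(
                standard_fixture.genes[0], standard_fixture.genome, cas13a
            )

    def test_spiked_offtarget_counts(self, spiked_fixture, cas9):
        # the planted spacer occurs at 2 exact + 1 single-mismatch loci;
        # annotate one exact copy and check the summary bins
        from casdesign.enumeration import GuideCandidate
        from casdesign.modes import _annotate

        spacer, fx = spiked_fixture
        p0 = next(p for p in fx.manifest["planted"] if p["mismatches"] == 0)
        cand = GuideCandidate(
            id="on", space="genomic", contig_or_tx=p0["contig"],
            start=p0["target_start"], strand="+", target_seq=spacer,
            motif_seq="AGG", spacer_seq=spacer,
        )
        g = _annotate(
            cand, cas9, DesignConfig(), "raw", search_space=fx.genome,
            genome=fx.genome,
        )
        # one other exact copy, one 1-mismatch copy (background hits possible
        # in principle but vanishingly unlikely for a random 20-mer)
        assert g.offtargets.mm0 == 1
        assert g.offtargets.mm1 == 1


def _small_rna_gene(seed=5):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    genome = GenomeIndex({"c1": seq})
    shared1, cassette, shared2 = (50, 140), (170, 190), (230, 320)
    t1 = Transcript("t1", "g", "c1", "+", (shared1, shared2))
    t2 = Transcript("t2", "g", "c1", "+", (shared1, cassette, shared2))
    return genome, GeneModel("g", (t1, t2)), cassette


@pytest.fixture(scope="module")
def run(cas13a):
    genome, gene, cassette = _small_rna_gene()
    inter = design_knockdown(gene, genome, cas13a)
    union = design_knockdown(
        gene, genome, cas13a, DesignConfig(isoform_mode="union")
    )
    return genome, gene, cassette, inter, union


class TestKnockdown:
    def test_intersection_guides_constitutive(self, run):
        _, gene, cassette, inter, _ = run
        assert inter.guides
        for g in inter.guides:
            assert g.constitutive is True
            assert g.mean_unpaired is not None
            assert 0.0 <= g.mean_unpaired <= 1.0
            assert g.mean_structure == pytest.approx(1 - g.mean_unpaired)

    def test_cassette_guides_only_in_union(self, run):
        genome, gene, cassette, inter, union = run
        tx2 = gene.transcripts[1]
        gpos = tx2.genomic_positions()

        def touches_cassette(g):
            c = g.candidate
            if c.contig_or_tx != "t2":
                return False
            return any(
                cassette[0] <= p < cassette[1] for p in gpos[c.start : c.end]
            )

        assert not any(touches_cassette(g) for g in inter.guides)
        assert any(not g.constitutive for g in union.guides)
        assert any(
            "not_in_every_isoform" in reasons for _, reasons in inter.rejected
        )

    def test_union_superset_of_intersection(self, run):
        _, gene, _, inter, union = run

        def footprints(res):
            out = set()
            for g in res.guides:
                t = next(
                    t for t in gene.transcripts if t.id == g.candidate.contig_or_tx
                )
                gpos = t.genomic_positions()
                out.add(tuple(sorted(gpos[g.candidate.start : g.candidate.end])))
            return out

        assert footprints(inter) <= footprints(union)

    def test_no_duplicate_footprints(self, run):
        _, gene, _, inter, union = run
        for res in (inter, union):
            seen = set()
            for g in res.guides:
                t = next(
                    t for t in gene.transcripts if t.id == g.candidate.contig_or_tx
                )
                gpos = t.genomic_positions()
                fp = tuple(sorted(gpos[g.candidate.start : g.candidate.end]))
                assert fp not in seen
                seen.add(fp)

    def test_spacers_are_revcomp_of_target(self, run):
        from casdesign.sequence_io import revcomp

        _, _, _, inter, _ = run
        for g in inter.guides:
            assert g.candidate.spacer_seq == revcomp(g.candidate.target_seq)

    def test_dna_effector_rejected(self, cas9):
        genome, gene, _ = _small_rna_gene()
        with pytest.raises(ContractError):
            design_knockdown(gene, genome, cas9)


class TestKnockin:
    def test_arm_clamping(self):
        genome = GenomeIndex({"c1": "A" * 10_000})
        arms = design_knockin_arms(5000, genome, "c1", 3000, cap=2000)
        assert (arms.left_len, arms.right_len) == (2000, 2000)

    def test_contig_edge_truncates(self):
        genome = GenomeIndex({"c1": "A" * 10_000})
        arms = design_knockin_arms(500, genome, "c1", 2000)
        assert (arms.left_len, arms.right_len) == (500, 2000)

    def test_arms_flank_the_cut(self):
        seq = "".join("ACGT"[(i // 3) % 4] for i in range(4000))
        genome = GenomeIndex({"c1": seq})
        arms = design_knockin_arms(2000, genome, "c1", 100)
        assert arms.left_seq == seq[1900:2000]
        assert arms.right_seq == seq[2000:2100]

    def test_bad_inputs(self):
        genome = GenomeIndex({"c1": "A" * 100})
        with pytest.raises(ContractError):
            design_knockin_arms(50, genome, "c1", 0)
        with pytest.raises(CoordinateError):
            design_knockin_arms(500, genome, "c1", 100)

    def test_design_knockin_attaches_arms(self, standard_fixture, cas9):
        res = design_knockin(
            standard_fixture.genes[0], standard_fixture.genome, cas9,
            arm_len_requested=300,
        )
        assert res.mode == "knockin"
        assert len(res.arms) == len([g for g in res.guides if g.cut is not None])
        by_cut = {a.cut_site: a for a in res.arms}
        seq = standard_fixture.genome.contigs["c1"]
        for g in res.guides:
            a = by_cut[g.cut]
            assert a.left_seq == seq[g.cut - a.left_len : g.cut]
            assert a.right_seq == seq[g.cut : g.cut + a.right_len]
            assert a.left_len <= 300 and a.right_len <= 300


class TestPromoterModes:
    def test_window_arithmetic_plus_strand(self, standard_fixture):
        gene = standard_fixture.genes[0]  # '+', TSS 600
        tss = standard_fixture.manifest["genes"][0]["tss"]
        win = promoter_window(gene, "activate", genome=standard_fixture.genome)
        assert win.genomic == (tss - 400, tss - 50)
        win = promoter_window(gene, "repress", genome=standard_fixture.genome)
        assert win.genomic == (tss - 50, tss + 300)

    def test_window_arithmetic_minus_strand(self, standard_fixture):
        gene = standard_fixture.genes[1]  # '-' strand
        tss = standard_fixture.manifest["genes"][1]["tss"]
        assert gene.strand == "-"
        win = promoter_window(gene, "activate", genome=standard_fixture.genome)
        assert win.genomic == (tss + 50, tss + 400)
        win = promoter_window(gene, "repress", genome=standard_fixture.genome)
        assert win.genomic == (tss - 300, tss + 50)

    def test_five_prime_most_tss(self):
        genome = GenomeIndex({"c1": "ACGT" * 500})
        t1 = Transcript("t1", "g", "c1", "+", ((900, 1000),))
        t2 = Transcript("t2", "g", "c1", "+", ((800, 1000),))
        win = promoter_window(GeneModel("g", (t1, t2)), "repress", genome=genome)
        assert win.tss == 800

    def test_clipped_empty_window_rejected(self):
        genome = GenomeIndex({"c1": "ACGT" * 50})
        t1 = Transcript("t1", "g", "c1", "+", ((10, 100),))
        with pytest.raises(ContractError):
            promoter_window(GeneModel("g", (t1,)), "activate", genome=genome)

    def test_guides_inside_window(self, standard_fixture, cas9):
        gene = standard_fixture.genes[0]
        res = design_promoter_targeting(
            gene, standard_fixture.genome, cas9, "repress"
        )
        win = promoter_window(gene, "repress", genome=standard_fixture.genome)
        assert res.guides, "repress window should contain guides"
        for g in res.guides:
            assert win.genomic[0] <= g.candidate.start
            assert g.candidate.end <= win.genomic[1]

    def test_unknown_purpose(self, standard_fixture):
        with pytest.raises(ContractError):
            promoter_window(standard_fixture.genes[0], "silence")


class TestNanopore:
    def test_pairs_flank_region(self, standard_fixture, cas9):
        genome = standard_fixture.genome
        region = (4000, 4400)
        res = design_nanopore_pairs(region, genome, "c1", cas9)
        assert res.pairs, "expected flanking pairs on the fixture contig"
        for p in res.pairs:
            assert p.left.cut < region[0]
            assert p.right.cut > region[1]
            assert p.span == p.right.cut - p.left.cut
            assert p.span <= DesignConfig().span_max
            for g in (p.left, p.right):
                assert g.selfcomp == 0
                assert g.efficiency is None or g.efficiency >= 0.3

    def test_pair_ordering(self, standard_fixture, cas9):
        res = design_nanopore_pairs(
            (4000, 4400), standard_fixture.genome, "c1", cas9
        )
        keys = [
            (max(p.left.rank, p.right.rank), p.span - 400, p.left.cut, p.right.cut)
            for p in res.pairs
        ]
        assert keys == sorted(keys)

    def test_span_cap_refuses_long_region(self, standard_fixture, cas9):
        cfg = DesignConfig(span_max=1000)
        res = design_nanopore_pairs(
            (3000, 4500), standard_fixture.genome, "c1", cas9, cfg
        )
        assert res.pairs == [] and res.guides == []
        assert any("span cap" in n for n in res.notices)

    def test_region_bounds_checked(self, standard_fixture, cas9):
        with pytest.raises(CoordinateError):
            design_nanopore_pairs(
                (100, 10**7), standard_fixture.genome, "c1", cas9
            )


class TestDownstreamAtgs:
    def test_matches_manifest_both_strands(self, standard_fixture):
        for gene, truth in zip(
            standard_fixture.genes, standard_fixture.manifest["genes"]
        ):
            t = gene.transcripts[0]
            cds_pos = t.cds_genomic_positions()
            # guide position 4 bases into the CDS (just past the start codon)
            position = cds_pos[3]
            got = downstream_atgs(t, standard_fixture.genome, position)
            assert got == truth["inframe_atg_offsets"]
            assert all(o % 3 == 0 for o in got)

    def test_position_past_planted_atg_drops_it(self, standard_fixture):
        gene = standard_fixture.genes[0]
        truth = standard_fixture.manifest["genes"][0]
        t = gene.transcripts[0]
        cds_pos = t.cds_genomic_positions()
        last_atg = truth["inframe_atg_offsets"][-1]
        position = cds_pos[last_atg + 2]  # inside the planted ATG codon
        got = downstream_atgs(t, standard_fixture.genome, position)
        assert last_atg not in got

    def test_no_cds_returns_empty(self, standard_fixture):
        t = Transcript("t", "g", "c1", "+", ((100, 200),))
        assert downstream_atgs(t, standard_fixture.genome, 150) == []
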