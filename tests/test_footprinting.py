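"""Promoter extraction, PWM scanning, conservation filtering, substring
parsimony and consensus scanning."""

import numpy as np
import pytest

from _oracles import substring_parsimony_best
from globinevo.footprinting import (ConsensusPattern, PromoterRegion,
                                    extract_promoter_region, iupac_scan,
                                    match_motif_library,
                                    pair_hits_by_flank_identity,
                                    positional_conservation_filter,
                                    PWMHit, scan_consensus_patterns, scan_pwm,
                                    substring_parsimony_search)
from globinevo.pwm import PWM
from globinevo.seqio import GeneModel, SeqRecord, revcomp
from globinevo.synthetic import (MotifSpec, plant_promoter_family)
from globinevo.trees import read_newick


def region_from(seq, tis_index, taxon="t"):
    return PromoterRegion(taxon, seq, tis_index)


class TestPromoterExtraction:
    def test_utr_zero_gives_1020(self):
        rng = np.random.default_rng(0)
        scaffold = SeqRecord("s", "".join(rng.choice(list("ACGT"), 3000)))
        gene = GeneModel("g", "s", "+", [(1500, 2100)], [(1500, 2100)],
                         tss=1500, tis=1500)
        region = extract_promoter_region(gene, scaffold)
        assert len(region) == 1020
        assert not region.truncated

    def test_fixture_utr_355_gives_1375(self, vertebrate_gene):
        scaffold, gene = vertebrate_gene
        region = extract_promoter_region(gene, scaffold)
        assert len(region) == 1375
        # +1 is the A of the ATG
        assert region.seq[region.index_of(1):region.index_of(1) + 3] == "ATG"

    def test_minus_strand_is_revcomp_of_plus_interval(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 3000))
        scaffold = SeqRecord("s", seq)
        minus = GeneModel("g", "s", "-", [(500, 1100)], [(500, 1100)],
                          tss=1099, tis=1099)
        region = extract_promoter_region(minus, scaffold)
        assert region.seq == revcomp(seq[1099 - 19: 1099 + 1001])
        assert len(region) == 1020

    def test_short_scaffold_truncates_with_flag(self):
        scaffold = SeqRecord("s", "ACGT" * 100)  # 400 bp
        gene = GeneModel("g", "s", "+", [(300, 360)], [(300, 360)],
                         tss=300, tis=300)
        region = extract_promoter_region(gene, scaffold)
        assert region.truncated
        assert len(region) == 320

    def test_offset_map_has_no_zero(self):
        region = region_from("ACGTACGT", 4)
        offsets = [region.offset_at(i) for i in range(8)]
        assert 0 not in offsets
        assert offsets == [-4, -3, -2, -1, 1, 2, 3, 4]
        for off in offsets:
            assert region.offset_at(region.index_of(off)) == off


def toy_pwm():
    # strongly biased 4-column PWM with consensus TGAC
    counts = np.zeros((4, 4))
    for i, base in enumerate("TGAC"):
        counts["ACGT".index(base), i] = 20
    return PWM.from_counts("toy", counts)


class TestScanPWM:
    def test_planted_consensus_scores_one(self):
        rng = np.random.default_rng(2)
        bg = "".join(rng.choice(list("ACGT"), 200))
        seq = bg[:100] + "TGAC" + bg[104:]
        region = region_from(seq, len(seq) - 20)
        hits = scan_pwm(region, toy_pwm(), rel_threshold=0.99)
        offsets = {h.offset for h in hits if h.strand == "+"}
        assert region.offset_at(100) in offsets
        assert any(h.rel_score == pytest.approx(1.0) for h in hits)

    def test_threshold_one_on_background_empty(self):
        rng = np.random.default_rng(3)
        # background without any TGAC or GTCA occurrence
        while True:
            seq = "".join(rng.choice(list("ACGT"), 300))
            if "TGAC" not in seq and "GTCA" not in seq:
                break
        hits = scan_pwm(region_from(seq, 150), toy_pwm(), rel_threshold=1.0)
        assert hits == []

    def test_hand_computed_log_odds(self):
        counts = np.array([[3, 0], [1, 0], [0, 4], [0, 0]], dtype=float)
        pwm = PWM.from_counts("t2", counts)
        seq = "AGCGTA"
        region = region_from(seq, 3)
        hits = scan_pwm(region, pwm, rel_threshold=0.0)
        lo = pwm.log_odds
        expected_first = lo["ACGT".index("A"), 0] + lo["ACGT".index("G"), 1]
        first = [h for h in hits if h.strand == "+" and
                 region.index_of(h.offset) == 0][0]
        assert first.score == pytest.approx(expected_first)

    def test_ambiguous_windows_skipped(self):
        region = region_from("ANGTGACT", 4)
        hits = scan_pwm(region, toy_pwm(), rel_threshold=0.0)
        assert all(region.index_of(h.offset) >= 2 for h in hits)

    def test_revcomp_mirror_symmetry(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 60))
        fwd = scan_pwm(region_from(seq, 30), toy_pwm(), 0.7)
        rev = scan_pwm(region_from(revcomp(seq), 30), toy_pwm(), 0.7)
        assert sorted(h.score for h in fwd) == sorted(h.score for h in rev)
        assert len([h for h in fwd if h.strand == "+"]) == \
            len([h for h in rev if h.strand == "-"])


class TestFlankIdentity:
    @staticmethod
    def make(seq_a, seq_b, hit_index, width):
        regions = {
            "a": region_from(seq_a, len(seq_a), "a"),
            "b": region_from(seq_b, len(seq_b), "b"),
        }
        off = regions["a"].offset_at(hit_index)
        ha = PWMHit("a", "p", off, "+", 1.0, 1.0)
        hb = PWMHit("b", "p", off, "+", 1.0, 1.0)
        return ha, hb, regions

    def test_identical_regions_always_pair(self):
        seq = "ACGTACGTAACCGGTTACGT"
        ha, hb, regions = self.make(seq, seq, 8, 4)
        assert pair_hits_by_flank_identity(ha, hb, regions, 4,
                                           identity_threshold=1.0)

    def test_divergent_flanks_fail(self):
        # identical 4-bp hit (GGGG at index 5), fully divergent 5-bp flanks
        seq_a = "AAAAA" + "GGGG" + "CCCCCAAAAA"
        seq_b = "TTTTT" + "GGGG" + "AAAAATTTTT"
        ha, hb, regions = self.make(seq_a, seq_b, 5, 4)
        assert not pair_hits_by_flank_identity(ha, hb, regions, 4,
                                               identity_threshold=0.1)

    def test_six_of_ten_threshold_boundary(self):
        #           lllllWWWWrrrrr  (l/r = flanks, W = hit of width 4)
        seq_a = "AACTGTGACCATGA"
        seq_b = "AACTTTGACCATTT"  # left flank differs at 1, right at 3
        ha, hb, regions = self.make(seq_a, seq_b, 5, 4)
        assert pair_hits_by_flank_identity(ha, hb, regions, 4,
                                           identity_threshold=0.5)
        assert not pair_hits_by_flank_identity(ha, hb, regions, 4,
                                               identity_threshold=0.75)

    def test_different_pwm_names_rejected(self):
        ha = PWMHit("a", "p1", -10, "+", 1, 1)
        hb = PWMHit("b", "p2", -10, "+", 1, 1)
        with pytest.raises(ValueError):
            pair_hits_by_flank_identity(ha, hb, {}, 4)


def hit(taxon, pwm, offset):
    return PWMHit(taxon, pwm, offset, "+", 1.0, 1.0)


class TestPositionalConservation:
    def test_single_taxon_everything_conserved(self):
        sites = positional_conservation_filter(
            {"a": [hit("a", "p", -100), hit("a", "p", -300)]})
        assert len(sites) == 2

    def test_within_window_emitted(self):
        sites = positional_conservation_filter({
            "a": [hit("a", "p", -100)],
            "b": [hit("b", "p", -130)],
            "c": [hit("c", "p", -120)],
        }, window=50)
        assert len(sites) == 1
        assert sites[0].max_deviation == 30

    def test_outside_window_dropped(self):
        sites = positional_conservation_filter({
            "a": [hit("a", "p", -100)],
            "b": [hit("b", "p", -160)],
        }, window=50)
        assert sites == []

    def test_missing_taxon_blocks_site_not_error(self):
        sites = positional_conservation_filter({
            "a": [hit("a", "p", -100)],
            "b": [],
        }, window=50)
        assert sites == []

    def test_closest_candidate_selected(self):
        sites = positional_conservation_filter({
            "a": [hit("a", "p", -100)],
            "b": [hit("b", "p", -140), hit("b", "p", -110)],
        }, window=50)
        offsets = dict(sites[0].offsets)
        assert offsets["b"] == -110

    def test_fewer_taxa_weaker_requirement(self):
        hits = {
            "a": [hit("a", "p", -100)],
            "b": [hit("b", "p", -120)],
            "c": [hit("c", "p", -200)],
        }
        with_all = positional_conservation_filter(hits, window=50)
        without_c = positional_conservation_filter(
            {k: v for k, v in hits.items() if k != "c"}, window=50)
        assert len(with_all) == 0
        assert len(without_c) == 1


class TestSubstringParsimony:
    TREE = "((a:1,b:1):1,(c:1,d:1):1);"

    def test_identical_planted_kmer_scores_zero(self):
        rng = np.random.default_rng(7)
        motif = "TTGACGTC"
        seqs = {}
        for t in "abcd":
            bg = "".join(rng.choice(list("ACGT"), 60))
            seqs[t] = bg[:20] + motif + bg[28:]
        found = substring_parsimony_search(seqs, read_newick(self.TREE), k=8)
        zero = [m for m in found if m.score == 0]
        assert any(all(inst[2] == motif for inst in m.instances) for m in zero)

    def test_one_leaf_mismatch_scores_one(self):
        motif = "TTGACGTC"
        variant = "TTGACGTA"
        rng = np.random.default_rng(8)
        seqs = {}
        for t in "abcd":
            bg = "".join(rng.choice(list("ACGT"), 60))
            planted = variant if t == "a" else motif
            seqs[t] = bg[:20] + planted + bg[28:]
        found = substring_parsimony_search(seqs, read_newick(self.TREE), k=8)
        match = [m for m in found
                 if {i[2] for i in m.instances} == {motif, variant}]
        assert match
        best = min(match, key=lambda m: m.score)
        assert best.score == 1
        counts = dict(best.branch_counts)
        assert counts.get("a") == 1

    def test_double_mutant_leaf_forces_routing_or_exclusion(self):
        """A leaf whose instance is 2 mutations from everyone else's cannot
        be explained with 1 change on its own branch: the search must route
        the second change through its ancestor (costing an extra change on
        the sister branch, total 3), so the motif survives at total budget 3
        but is excluded when the budget is 2."""
        motif = "TTGACGTC"
        double = "TTGACGAA"  # two changes relative to the others
        rng = np.random.default_rng(9)
        seqs = {}
        for t in "abcd":
            bg = "".join(rng.choice(list("ACGT"), 40))
            planted = double if t == "a" else motif
            seqs[t] = bg[:10] + planted + bg[18:]
        relaxed = substring_parsimony_search(seqs, read_newick(self.TREE),
                                             k=8, max_total=3, max_per_branch=1)
        hit = [m for m in relaxed
               if {i[2] for i in m.instances} == {motif, double}]
        assert hit and min(m.score for m in hit) == 3
        assert all(c <= 1 for m in hit for _, c in m.branch_counts)
        strict = substring_parsimony_search(seqs, read_newick(self.TREE),
                                            k=8, max_total=2, max_per_branch=1)
        assert not any({i[2] for i in m.instances} == {motif, double}
                       for m in strict)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle_three_taxa(self, seed):
        """Oracle suite: minimum parsimony score equals brute-force
        enumeration of all k-mer tuples × internal labelings (3 taxa)."""
        rng = np.random.default_rng(100 + seed)
        seqs = {t: "".join(rng.choice(list("ACGT"), 14)) for t in ("a", "b", "c")}
        oracle_best, _ = substring_parsimony_best(seqs, 3, max_per_branch=1)
        found = substring_parsimony_search(
            seqs, read_newick("((a:1,b:1):1,c:1);"), k=3,
            max_total=3, max_per_branch=1)
        impl_best = min((m.score for m in found), default=None)
        if oracle_best > 3:
            assert impl_best is None
        else:
            assert impl_best == oracle_best

    def test_planted_family_recovered_end_to_end(self):
        """Motifs planted with <=1 mutation per branch and total <=3 are
        recovered with matching offsets."""
        tree = read_newick(self.TREE)
        spec = MotifSpec("TTGACGTC", -150, jitter_bp=0,
                         max_mutations_per_branch=1, max_total_mutations=3,
                         name="m")
        records, truth = plant_promoter_family(tree, 300, [spec], seed=13)
        seqs = {t: r.seq for t, r in records.items()}
        found = substring_parsimony_search(seqs, read_newick(self.TREE), k=8)
        planted = {t.taxon: (300 + t.offset_from_tis, t.instance) for t in truth}
        assert any(
            {(i[0], i[1], i[2]) for i in m.instances} ==
            {(tax, pos, inst) for tax, (pos, inst) in planted.items()}
            for m in found
        )


class TestConsensusScan:
    NRSE = "TTCAGCACCACGGACAGCGCC"

    def test_planted_exact_pattern_single_hit(self):
        rng = np.random.default_rng(14)
        while True:
            bg = "".join(rng.choice(list("ACGT"), 400))
            if self.NRSE not in bg:
                break
        seq = bg[:200] + self.NRSE + bg[221:]
        pattern = ConsensusPattern("NRSE", self.NRSE)
        hits = iupac_scan(seq, pattern)
        assert [h for h in hits if h[1] == "+"] == [(200, "+", 0)]

    def test_one_mismatch_rejected_at_zero_allowed(self):
        seq = "AAAA" + self.NRSE[:10] + "T" + self.NRSE[11:] + "AAAA"
        pattern = ConsensusPattern("NRSE", self.NRSE)
        hits = iupac_scan(seq, pattern)
        assert hits == []

    def test_nnn_matches_everywhere_both_strands(self):
        hits = iupac_scan("ACG", ConsensusPattern("n3", "NNN"))
        assert len(hits) == 2  # one per strand at the single position
        assert {h[1] for h in hits} == {"+", "-"}

    def test_invalid_iupac_symbol_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            ConsensusPattern("bad", "ACGTQ")

    def test_gene_relative_coordinates(self, vertebrate_gene):
        scaffold, gene = vertebrate_gene
        seq = scaffold.seq
        insert_at = gene.tss - 500
        seq2 = seq[:insert_at] + self.NRSE + seq[insert_at + 21:]
        hits = scan_consensus_patterns(
            SeqRecord(scaffold.id, seq2), gene,
            [ConsensusPattern("NRSE", self.NRSE)])
        assert any(h.offset == -500 and h.strand == "+" for h in hits)

    def test_zero_branch_mutation_family_always_recovered(self):
        """Planted ground truth is recovered at 0 mismatches whenever the
        per-branch mutation limit is 0 (spec invariant, end to end)."""
        tree = read_newick("((a:0.1,b:0.1):0.1,c:0.1);")
        spec = MotifSpec(self.NRSE, -200, jitter_bp=15, name="nrse")
        records, truth = plant_promoter_family(tree, 400, [spec], seed=21)
        pattern = ConsensusPattern("nrse", self.NRSE)
        for site in truth:
            hits = iupac_scan(records[site.taxon].seq, pattern)
            positions = [h[0] for h in hits if h[1] == "+"]
            assert 400 + site.offset_from_tis in positions


class TestMotifLibrary:
    def test_identical_matrix_ranks_first_with_similarity_one(self):
        instances = ["TGACGTCA"] * 5
        counts = np.zeros((4, 8))
        for i, b in enumerate("TGACGTCA"):
            counts["ACGT".index(b), i] = 5
        target = PWM.from_counts("target", counts)
        decoy_counts = np.zeros((4, 8))
        for i, b in enumerate("AAAAAAAA"):
            decoy_counts["ACGT".index(b), i] = 5
        decoy = PWM.from_counts("decoy", decoy_counts)
        matches = match_motif_library(instances, [decoy, target])
        assert matches[0].name == "target"
        assert matches[0].similarity == pytest.approx(1.0)

    def test_reverse_complement_found_via_orientation_search(self):
        instances = ["TGACGTCA"] * 4
        counts = np.zeros((4, 8))
        for i, b in enumerate(revcomp("TGACGTCA")):
            counts["ACGT".index(b), i] = 5
        rc_pwm = PWM.from_counts("rc", counts)
        (match,) = match_motif_library(instances, [rc_pwm])
        assert match.similarity == pytest.approx(1.0)

    def test_uniform_motif_flagged_uninformative(self):
        instances = ["ACGT"[i % 4] * 4 for i in range(4)]  # AAAA CCCC GGGG TTTT
        counts = np.zeros((4, 6))
        counts[0, :3] = 8
        counts[3, 3:] = 8
        lib = PWM.from_counts("lib", counts)
        (match,) = match_motif_library(instances, [lib])
        assert match.uninformative
        assert np.isnan(match.similarity)

    def test_too_short_motif_rejected(self):
        with pytest.raises(ValueError, match="short"):
            match_motif_library(["ACG"], [toy_pwm()])
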