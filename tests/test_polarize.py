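"""Polarization rule, region splitting, locus trees, consensus and iteration."""

import dendropy
import numpy as np
import pytest

import polyorigin as po
from polyorigin.polarize import _pairwise_distance, encode

from conftest import brute_force_polarize, make_genotypes, make_sites

ALPHABET = "ACGTRYSWKMBDHVN-"
CLADES = {"DET": ("TAU", "DIF", "EXS")}


def rooted(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


class TestPolarizeRule:
    @pytest.mark.parametrize(
        "poly,ref,out",
        [
            ("R", "A", "G"),  # reference allele masked, other allele retained
            ("A", "A", "A"),  # homozygous unchanged
            ("M", "G", "M"),  # reference not among the two alleles
            ("Y", "N", "Y"),  # unpolarizable column
            ("Y", "-", "Y"),
            ("N", "C", "N"),
            ("-", "C", "-"),
            ("K", "T", "G"),
            ("B", "C", "B"),  # three-allele codes never polarized
        ],
    )
    def test_single_columns(self, poly, ref, out):
        assert po.polarize_sequence(poly, ref) == out

    def test_matches_brute_force_oracle_on_random_columns(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            poly = "".join(rng.choice(list(ALPHABET), 1000))
            ref = "".join(rng.choice(list(ALPHABET), 1000))
            assert po.polarize_sequence(poly, ref) == brute_force_polarize(poly, ref)

    def test_idempotent_given_same_reference(self):
        rng = np.random.default_rng(7)
        poly = "".join(rng.choice(list(ALPHABET), 500))
        ref = "".join(rng.choice(list("ACGT"), 500))
        once = po.polarize_sequence(poly, ref)
        assert po.polarize_sequence(once, ref) == once

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            po.polarize_sequence("AC", "A")


class TestConsensus:
    def test_depth_dosage_and_missing_rules(self):
        sites = make_sites(3, ref="C", alt="T")
        g = make_genotypes(np.array([[1.0, 0.0, np.nan]]), ploidy=4, sites=sites)
        d = po.AlleleDepthMatrix(np.array([[15, 3, 20]]), np.array([[5, 1, 10]]))
        call = po.consensus_from_depths(d, g, "s0", min_dp=5)
        assert list(call) == ["Y", "N", "N"]  # het; depth 4 < 5; missing genotype

    def test_homozygous_calls(self):
        sites = make_sites(2, ref="A", alt="G")
        g = make_genotypes(np.array([[0.0, 2.0]]), ploidy=2, sites=sites)
        d = po.AlleleDepthMatrix(np.full((1, 2), 20), np.full((1, 2), 5))
        assert list(po.consensus_from_depths(d, g, "s0")) == ["A", "G"]


class TestSplitRegions:
    def test_equal_and_remainder_block_sizes(self):
        pos = np.arange(1, 81) * 100
        rs = po.split_regions({"chr1": pos}, 4)
        assert [r.n_snps for r in rs.regions] == [20, 20, 20, 20]
        rs = po.split_regions({"chr1": np.arange(1, 83) * 100}, 4)
        assert [r.n_snps for r in rs.regions] == [21, 21, 20, 20]

    def test_default_region_count_over_six_chromosomes(self):
        pos = {f"chr{i}": np.arange(1, 41) * 150 for i in range(1, 7)}
        assert len(po.split_regions(pos)) == 120

    def test_regions_disjoint_cover_all_snps(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            pos = np.unique(rng.integers(1, 2_000_000, size=rng.integers(60, 400)))
            rs = po.split_regions({"chrX": pos}, 20)
            covered = []
            last_end = 0
            for r in rs.regions:
                assert r.start > last_end  # disjoint, ordered
                last_end = r.end
                assert all(r.start <= p <= r.end for p in r.snp_positions)
                covered.extend(r.snp_positions)
            assert sorted(covered) == list(pos)
            counts = [r.n_snps for r in rs.regions]
            assert max(counts) - min(counts) <= 1

    def test_too_few_snps_names_chromosome(self):
        with pytest.raises(ValueError, match="chr9"):
            po.split_regions({"chr9": np.arange(1, 10) * 50}, 20)


class TestLocusTree:
    def test_ambiguity_match_score(self):
        assert _pairwise_distance(encode("R"), encode("A")) == pytest.approx(0.5)
        assert _pairwise_distance(encode("RN"), encode("AC")) == pytest.approx(0.5)  # N column excluded
        assert _pairwise_distance(encode("A"), encode("A")) == 0.0

    def test_recovers_generating_topology(self):
        # two cherries: (A,B) and (C,OUT); within-pair differences small
        seqs = {
            "A":   "AAAAAAAAAACCCCC",
            "B":   "AAAAAAAAAGCCCCC",
            "C":   "TTTTTAAAAACCCCC",
            "OUT": "TTTTTAAAAGCCCCC",
        }
        aln = po.IUPACAlignment(po.Region("chr1", 1, 15, tuple(range(1, 16))), seqs)
        tree = po.locus_tree(aln, outgroup="OUT")
        assert po.sister_of(tree, "A") == "B"

    def test_duplicate_sequences_form_cherry(self):
        seqs = {"A": "ACGTACGT", "B": "ACGTACGT", "C": "TTTTACGT", "OUT": "TTGGACGT"}
        aln = po.IUPACAlignment(po.Region("chr1", 1, 8, tuple(range(1, 9))), seqs)
        tree = po.locus_tree(aln, outgroup="OUT")
        assert po.sister_of(tree, "A") == "B"
        for e in tree.preorder_edge_iter():
            assert e.length is None or e.length >= 0

    def test_too_few_taxa_rejected(self):
        aln = po.IUPACAlignment(po.Region("chr1", 1, 3, (1, 2, 3)), {"A": "AAA", "B": "AAA", "C": "AAA"})
        with pytest.raises(ValueError, match=">= 4"):
            po.locus_tree(aln, outgroup="C")


class TestSisterAndPairing:
    def test_single_species_sister(self):
        t = rooted("((POLY,TAU),(DIF,EXS));")
        assert po.sister_of(t, "POLY", clades=CLADES) == "TAU"

    def test_clade_sister(self):
        t = rooted("((POLY,(TAU,EXS)),(CAM,PAL));")
        assert po.sister_of(t, "POLY", clades=CLADES) == "DET"

    def test_uncovered_multi_species_sister_unresolved(self):
        t = rooted("((POLY,(CAM,EXS)),(TAU,PAL));")
        assert po.sister_of(t, "POLY", clades=CLADES) == "unresolved"

    def test_missing_focal_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            po.sister_of(rooted("((A,B),(C,D));"), "Z")

    def test_pairing_tally(self):
        trees = [rooted("((POLY,TAU),(DIF,EXS));")] * 3 + [rooted("((POLY,DIF),(TAU,EXS));")] * 2
        counts = po.pairing_frequencies(trees, "POLY", clades=CLADES)
        assert counts == {"TAU": 3, "DIF": 2}
        with pytest.raises(ValueError):
            po.pairing_frequencies([], "POLY")


class TestSummaryTree:
    def test_identical_inputs_full_support(self):
        trees = [rooted("((A,B),(C,(D,E)));") for _ in range(4)]
        cons = po.summary_tree(trees)
        labels = {
            frozenset(l.taxon.label for l in n.leaf_iter()): n.label
            for n in cons.preorder_node_iter()
            if not n.is_leaf() and n.label
        }
        assert labels[frozenset("AB")] == "1.0000"
        assert labels[frozenset("DE")] == "1.0000"

    def test_majority_clade_wins_conflict(self):
        trees = [rooted("((A,B),(C,D));")] * 7 + [rooted("((A,C),(B,D));")] * 3
        cons = po.summary_tree(trees)
        clades = {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in cons.preorder_node_iter()
            if not n.is_leaf()
        }
        assert frozenset("AB") in clades
        assert frozenset("AC") not in clades

    def test_compatible_clades_from_different_trees_union(self):
        # hand-worked: 2 trees over 5 taxa; (A,B) from both, (D,E) only in first,
        # ((A,B),C) only in second; all mutually compatible -> all retained
        trees = [rooted("((A,B),(D,E),C);"), rooted("(((A,B),C),D,E);")]
        cons = po.summary_tree(trees)
        clades = {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in cons.preorder_node_iter()
            if not n.is_leaf()
        }
        assert {frozenset("AB"), frozenset("DE"), frozenset("ABC")} <= clades

    def test_differing_leaf_sets_rejected(self):
        with pytest.raises(ValueError, match="leaf sets"):
            po.summary_tree([rooted("((A,B),(C,D));"), rooted("((A,B),(C,E));")])


class TestIterateParents:
    @pytest.fixture(scope="class")
    def small_replicate(self):
        cfg = po.parent_inference_config(seed=11, n_loci=2400, samples_per_population=12)
        table = po.draw_species_frequencies(cfg)
        mats = [po.sample_diploid_genotypes(table, s, 12, 300 + i) for i, s in enumerate(cfg.species_labels)]
        at, truth = po.sample_allotetraploid(table, "TAU", "PAL", 12, 999)
        g = po.stack_samples(mats + [at])
        g = po.inject_missing(g, 0.1, 77)
        alns = po.genotypes_to_alignments(g, seed=5)
        meta = {
            "species_of": {s.id: s.species for s in g.samples},
            "ploidy_of": {s.id: s.ploidy for s in g.samples},
            "focal": at.samples[0].id,
        }
        return alns, meta, truth

    def test_recovers_true_parents_and_audits_iterations(self, small_replicate):
        alns, meta, truth = small_replicate
        iters, parents = po.iterate_parents(
            alns, meta["focal"], candidates=list(po.simdata.DEFAULT_SPECIES),
            start_reference="CAM", outgroup="NIV", clades=CLADES,
            species_of=meta["species_of"], ploidy_of=meta["ploidy_of"],
        )
        assert parents == tuple(sorted(truth.parents))
        assert iters[0].reference == "CAM"
        assert iters[-1].converged
        # audit: pairing counts cover all regions
        assert sum(iters[-1].pairing_counts.values()) == len(alns)
        # convergence rule: last two (reference, sister) pairs coincide
        last, prev = iters[-1], iters[-2]
        assert {last.reference, last.next_reference} == {prev.reference, prev.next_reference}

    def test_non_convergence_reports_trajectory(self, small_replicate):
        alns, meta, _ = small_replicate
        iters, parents = po.iterate_parents(
            alns, meta["focal"], candidates=list(po.simdata.DEFAULT_SPECIES),
            start_reference="CAM", outgroup="NIV", clades=CLADES,
            species_of=meta["species_of"], ploidy_of=meta["ploidy_of"], max_iter=1,
        )
        assert parents is None
        assert len(iters) == 1

    def test_hexaploid_focal_rejected(self, small_replicate):
        alns, meta, _ = small_replicate
        ploidy_of = dict(meta["ploidy_of"])
        ploidy_of[meta["focal"]] = 6
        with pytest.raises(ValueError, match="tetraploids only"):
            po.iterate_parents(
                alns, meta["focal"], candidates=list(po.simdata.DEFAULT_SPECIES),
                start_reference="CAM", outgroup="NIV", clades=CLADES,
                species_of=meta["species_of"], ploidy_of=ploidy_of,
            )
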