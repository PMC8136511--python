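"""Character histories (Fitch/ACCTRAN/DELTRAN), reconciliation and
duplication bookkeeping, each against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from helpers import random_rooted_tree

from lbagrid.datasets import ohnolog_fixture, reconstruction_fixture
from lbagrid.phylo_core import read_newick
from lbagrid.phylo_core.reference import enumerate_mprs, reconcile_oracle
from lbagrid.rgc import (
    CharacterMatrix,
    acctran,
    deltran,
    duplication_tally,
    fitch_length,
    lca_reconcile,
    motif_filter,
    paralog_screen,
    shared_duplication,
)


@pytest.fixture(scope="module")
def fixture():
    return reconstruction_fixture()


class TestFitch:
    def test_constant_character(self, fixture):
        tree, _ = fixture
        char = CharacterMatrix("flat", {t: 0 for t in tree.leaf_names()})
        assert fitch_length(tree, char)[0] == 0

    def test_courtship_dance_length_two(self, fixture):
        tree, chars = fixture
        length, _ = fitch_length(tree, chars["promenade_a_deux"])
        best, _ = enumerate_mprs(
            tree, dict(chars["promenade_a_deux"].states), (0, 1))
        assert length == best == 2

    def test_book_lungs_length_two(self, fixture):
        tree, chars = fixture
        length, _ = fitch_length(tree, chars["book_lungs"])
        best, _ = enumerate_mprs(tree, dict(chars["book_lungs"].states), (0, 1))
        assert length == best == 2

    def test_unknown_states_are_free(self, fixture):
        tree, chars = fixture
        states = dict(chars["book_lungs"].states)
        states["Araneae"] = "?"
        length, _ = fitch_length(tree, CharacterMatrix("bl", states))
        assert length == 2

    def test_unknown_tip_rejected(self, fixture):
        tree, _ = fixture
        with pytest.raises(ValueError):
            fitch_length(tree, CharacterMatrix("bad", {"NotATip": 1}))

    def test_random_trees_match_enumeration(self, rng):
        for _ in range(25):
            tree = random_rooted_tree(rng, int(rng.integers(4, 9)))
            states = {l: int(rng.integers(0, 2)) for l in tree.leaf_names()}
            length, _ = fitch_length(tree, CharacterMatrix("c", states))
            best, _ = enumerate_mprs(tree, dict(states), (0, 1))
            assert length == best


class TestAcctranDeltran:
    def test_courtship_dance_resolutions(self, fixture):
        """An early gain with a loss in spiders, versus two parallel
        gains — equally parsimonious."""
        tree, chars = fixture
        char = chars["promenade_a_deux"]
        acc = acctran(tree, char, outgroup=["Onychophora"])
        del_ = deltran(tree, char, outgroup=["Onychophora"])
        assert {(c.branch, c.from_state, c.to_state) for c in acc.changes} == {
            ("Arachnopulmonata", 0, 1), ("Araneae", 1, 0)}
        assert {(c.branch, c.from_state, c.to_state) for c in del_.changes} == {
            ("Panscorpiones", 0, 1), ("Pedipalpi", 0, 1)}
        assert acc.length == del_.length == 2

    def test_book_lungs_acctran_loss_in_pseudoscorpions(self, fixture):
        tree, chars = fixture
        acc = acctran(tree, chars["book_lungs"], outgroup=["Onychophora"])
        assert {(c.branch, c.from_state, c.to_state) for c in acc.changes} == {
            ("Arachnopulmonata", 0, 1), ("Pseudoscorpiones", 1, 0)}

    def test_behavior_characters_admit_exactly_two_mprs(self, fixture):
        tree, chars = fixture
        for name in ("promenade_a_deux", "maternal_brood_care"):
            _, mprs = enumerate_mprs(tree, dict(chars[name].states), (0, 1))
            assert len(mprs) == 2

    def test_equal_length_on_random_instances(self, rng):
        for _ in range(25):
            tree = random_rooted_tree(rng, int(rng.integers(4, 10)))
            states = {l: int(rng.integers(0, 2)) for l in tree.leaf_names()}
            char = CharacterMatrix("c", states)
            fl, _ = fitch_length(tree, char)
            acc = acctran(tree, char)
            dl = deltran(tree, char)
            assert acc.length == dl.length == fl
            # both are genuine MPR assignments
            best, mprs = enumerate_mprs(tree, dict(states), (0, 1))
            assert fl == best


class TestReconciliation:
    def test_textbook_root_duplication(self):
        gene = read_newick("((a_1,b_1),(a_2,b_2));")
        species = read_newick("(a,b);")
        rec = lca_reconcile(gene, species, {l: l.split("_")[0] for l in gene.leaf_names()})
        assert rec.duplication_count == 1
        assert sorted(rec.events.values()) == ["duplication", "speciation", "speciation"]

    def test_congruent_single_copy_no_duplications(self):
        gene = read_newick("((a_1,b_1),(c_1,d_1));")
        species = read_newick("((a,b),(c,d));")
        rec = lca_reconcile(gene, species, {l: l.split("_")[0] for l in gene.leaf_names()})
        assert rec.duplication_count == 0

    def test_unmapped_leaf_rejected(self):
        gene = read_newick("((a_1,b_1),(c_1,d_1));")
        species = read_newick("((a,b),(c,d));")
        with pytest.raises(ValueError, match="unmapped"):
            lca_reconcile(gene, species, {"a_1": "a"})

    def test_random_gene_trees_match_oracle(self, rng):
        species = read_newick("(((a,b),(c,d)),((e,f),g));")
        sp_names = species.leaf_names()
        for _ in range(60):
            gene = random_rooted_tree(rng, 12)
            leaf_map = {
                l: sp_names[int(rng.integers(0, len(sp_names)))]
                for l in gene.leaf_names()
            }
            rec = lca_reconcile(gene, species, leaf_map)
            oracle = reconcile_oracle(gene, species, leaf_map)
            by_label = {}
            for node in gene.internal_nodes():
                label = "{" + ",".join(sorted(gene.leafset(node))) + "}"
                by_label[id(node)] = rec.events[label]
            assert all(by_label[k] == v for k, v in oracle.items())


class TestSharedDuplication:
    def test_ohnolog_fixture_shared_by_arachnopulmonates(self):
        gene, species, leaf_map = ohnolog_fixture()
        rec = lca_reconcile(gene, species, leaf_map)
        assert rec.duplication_count == 1
        calls = shared_duplication(rec, species, {"spider", "scorpion", "pseudoscorpion"})
        assert list(calls.values()) == ["shared"]

    def test_in_paralogs_are_lineage_specific(self):
        gene = read_newick("((a_1,a_2),b_1);")
        species = read_newick("(a,b);")
        rec = lca_reconcile(gene, species, {l: l.split("_")[0] for l in gene.leaf_names()})
        calls = shared_duplication(rec, species, {"a", "b"})
        assert list(calls.values()) == ["lineage_specific"]

    def test_duplication_outside_clade_absent(self):
        gene = read_newick("(((a_1,b_1),(a_2,b_2)),(c_1,d_1));")
        species = read_newick("((a,b),(c,d));")
        rec = lca_reconcile(gene, species, {l: l.split("_")[0] for l in gene.leaf_names()})
        calls = shared_duplication(rec, species, {"c", "d"})
        assert list(calls.values()) == ["absent"]

    def test_empty_clade_rejected(self):
        gene, species, leaf_map = ohnolog_fixture()
        rec = lca_reconcile(gene, species, leaf_map)
        with pytest.raises(ValueError):
            shared_duplication(rec, species, set())


class TestParalogScreen:
    def test_identical_sequences_merge(self):
        seq = "M" * 150
        count, _ = paralog_screen({"x": seq, "y": seq})
        assert count == 1

    def test_divergent_overlap_keeps_two_copies(self):
        a = "M" * 150
        b = "M" * 145 + "KKKKK"
        count, calls = paralog_screen({"x": a, "y": b})
        assert count == 2
        assert (calls["call"] == "paralogs").all()

    def test_single_substitution_is_allele(self):
        a = "M" * 150
        b = "M" * 149 + "K"
        count, _ = paralog_screen({"x": a, "y": b})
        assert count == 1

    def test_short_overlap_merges_conservatively(self):
        a = "M" * 80 + "-" * 70
        b = "K" * 80 + "-" * 70
        count, _ = paralog_screen({"x": a, "y": b})
        assert count == 1

    def test_nonoverlapping_fragments_collapse(self):
        """Two non-overlapping fragments that each conflict with a third
        full-length sequence yield two copies."""
        frag1 = "M" * 120 + "-" * 130
        frag2 = "-" * 130 + "M" * 120
        full = "K" * 5 + "M" * 240 + "K" * 5
        count, _ = paralog_screen({"f1": frag1, "f2": frag2, "full": full})
        assert count == 2

    def test_order_invariance(self, rng):
        seqs = {
            "a": "M" * 150,
            "b": "M" * 140 + "KRKRKRKRKR",
            "c": "M" * 75 + "-" * 75,
            "d": "-" * 75 + "M" * 75,
        }
        base, _ = paralog_screen(seqs)
        items = list(seqs.items())
        rng.shuffle(items)
        again, _ = paralog_screen(dict(items))
        assert base == again

    def test_empty_input(self):
        count, calls = paralog_screen({})
        assert count == 0 and calls.empty


class TestMotifAndTally:
    def test_both_motifs_required(self):
        peptides = {
            "both": "AAELEKEFAAKIWFQNAA",
            "one": "AAELEKEFAA",
            "none": "AAAA",
        }
        assert set(motif_filter(peptides)) == {"both"}

    def test_empty_motif_list_keeps_all(self):
        peptides = {"a": "MM", "b": "KK"}
        assert motif_filter(peptides, required_motifs=()) == peptides

    def test_tally_shared_flag(self):
        counts = pd.DataFrame(
            {"pseudo": [2, 2, 1], "scorpion": [2, 1, 1], "mite": [1, 1, 1]},
            index=["lab", "Dfd", "Hox3"],
        )
        tally = duplication_tally(counts, ["pseudo"], ["scorpion"])
        assert tally.shared_flags.tolist() == [True, False, False]

    def test_all_single_copy_no_flags(self):
        counts = pd.DataFrame({"a": [1, 1], "b": [1, 1]}, index=["g1", "g2"])
        tally = duplication_tally(counts, ["a"], ["b"])
        assert not tally.shared_flags.any()
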