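"""ΔGLS properties, sister-group classification and grid assembly."""

import numpy as np
import pandas as pd
import pytest
from helpers import classify_scenario_tree

from lbagrid.phylo_core import poisson, read_newick, tree_loglik
from lbagrid.signal import (
    HypothesisPair,
    PlacementResult,
    classify_sister,
    category_matches,
    delta_gls,
    dgls_summary,
    gene_loglik_on_topology,
    hypothesis_support,
    sensitivity_grid,
)
from lbagrid.study_design import AnalysisPlan, MatrixGridCell
from lbagrid.supermatrix import LocusAlignment, concatenate
from lbagrid.synthetic_data import (
    attractor_alternative,
    lba_scenario,
    simulate_alignment,
    simulate_locus_set,
)


@pytest.fixture(scope="module")
def scenario():
    return lba_scenario(n_loci=12, sites_min=120, sites_max=200, seed=17)


@pytest.fixture(scope="module")
def scenario_loci(scenario):
    loci, _ = simulate_locus_set(scenario.config)
    return loci


class TestGeneLoglik:
    def test_full_taxon_locus_uses_whole_tree(self, scenario, poisson_model):
        locus = LocusAlignment(
            id="full",
            rows=simulate_alignment(scenario.true_tree, poisson_model, 100, seed=1).rows,
        )
        score = gene_loglik_on_topology(locus, scenario.true_tree, [poisson_model])
        assert score.loglik is not None and score.flag is None

    def test_missing_taxon_contracts_tree(self, scenario, poisson_model):
        rows = simulate_alignment(scenario.true_tree, poisson_model, 80, seed=2).rows
        rows.pop("Sister_1")
        locus = LocusAlignment(id="partial", rows=rows)
        score = gene_loglik_on_topology(locus, scenario.true_tree, [poisson_model])
        assert score.loglik is not None

    def test_too_few_taxa_skipped(self, scenario, poisson_model):
        rows = simulate_alignment(scenario.true_tree, poisson_model, 50, seed=3).rows
        keep = list(rows)[:3]
        locus = LocusAlignment(id="tiny", rows={k: rows[k] for k in keep})
        score = gene_loglik_on_topology(locus, scenario.true_tree, [poisson_model])
        assert score.loglik is None and score.flag

    def test_true_topology_beats_random_alternative(self, scenario, poisson_model):
        wins = 0
        alt = attractor_alternative(scenario)
        for rep in range(5):
            locus = LocusAlignment(
                id=f"r{rep}",
                rows=simulate_alignment(scenario.true_tree, poisson_model, 400,
                                        seed=600 + rep).rows,
            )
            a = gene_loglik_on_topology(locus, scenario.true_tree, [poisson_model])
            b = gene_loglik_on_topology(locus, alt, [poisson_model])
            if a.loglik >= b.loglik:
                wins += 1
        assert wins >= 4


class TestDeltaGls:
    def test_identical_hypotheses_zero(self, scenario, scenario_loci, poisson_model):
        pair = HypothesisPair("x", "y", scenario.true_tree, scenario.true_tree.copy())
        value = delta_gls(scenario_loci[0], pair, [poisson_model])
        assert value == pytest.approx(0.0, abs=1e-6)

    def test_antisymmetric_under_swap(self, scenario, scenario_loci, poisson_model):
        alt = attractor_alternative(scenario)
        fwd = HypothesisPair("t", "a", scenario.true_tree, alt)
        rev = HypothesisPair("a", "t", alt, scenario.true_tree)
        v1 = delta_gls(scenario_loci[1], fwd, [poisson_model])
        v2 = delta_gls(scenario_loci[1], rev, [poisson_model])
        assert v1 == pytest.approx(-v2, abs=1e-4)

    def test_majority_favor_true_hypothesis(self, scenario, scenario_loci, poisson_model):
        alt = attractor_alternative(scenario)
        pair = HypothesisPair("true", "attractor", scenario.true_tree, alt)
        values = {
            locus.id: delta_gls(locus, pair, [poisson_model])
            for locus in scenario_loci
        }
        summary = dgls_summary(values)
        assert summary["prop_favoring_1"] > 0.6


class TestDglsSummary:
    def test_all_positive(self):
        s = dgls_summary({"a": 1.0, "b": 2.0})
        assert s["prop_favoring_1"] == 1.0 and s["n_neutral"] == 0

    def test_tie_rule(self):
        s = dgls_summary({"a": 2.0, "b": -1.0, "c": 0.0})
        assert s["prop_favoring_1"] == pytest.approx(0.5)
        assert s["prop_favoring_2"] == pytest.approx(0.5)
        assert s["n_neutral"] == 1

    def test_skipped_counted(self):
        s = dgls_summary({"a": 1.0, "b": None})
        assert s["n_skipped"] == 1 and s["n_defined"] == 1

    def test_no_defined_values_rejected(self):
        with pytest.raises(ValueError):
            dgls_summary({"a": None})


class TestClassifySister:
    GROUPS = {
        **{f"out{i}": "Out" for i in (1, 2)},
        **{f"acar{i}": "Acari" for i in (1, 2)},
        **{f"scorp{i}": "Scorp" for i in (1, 2)},
        **{f"ps{i}": "Pseudo" for i in (1, 2)},
    }

    def classify(self, nwk):
        tree = read_newick(nwk)
        focal = {l for l, g in self.GROUPS.items() if g == "Pseudo" and l in tree.leaf_names()}
        out = {l for l, g in self.GROUPS.items() if g == "Out"}
        return classify_sister(tree, focal, self.GROUPS, out)

    def test_named_group_sister(self):
        res = self.classify(
            "((out1,out2),((acar1,acar2),((scorp1,scorp2),(ps1,ps2))));")
        assert res.focal_monophyletic and res.category == "Scorp"

    def test_non_monophyletic_focal(self):
        res = self.classify(
            "((out1,out2),((ps1,(acar1,acar2)),(ps2,(scorp1,scorp2))));")
        assert not res.focal_monophyletic and res.category == "non-monophyletic"

    def test_composite_sister_label(self):
        res = self.classify(
            "((out1,out2),(((acar1,acar2),(scorp1,scorp2)),(ps1,ps2)));")
        assert res.category == "Acari+Scorp"

    def test_partial_group_is_other(self):
        res = self.classify(
            "((out1,out2),(acar2,((acar1,(scorp1,scorp2)),(ps1,ps2))));")
        assert res.category == "other"

    def test_single_focal_leaf_unresolved(self):
        tree = read_newick("((out1,out2),(acar1,(scorp1,ps1)));")
        res = classify_sister(tree, {"ps1"}, self.GROUPS, {"out1", "out2"})
        assert res.category == "unresolved"

    def test_rooting_invariance(self):
        base = "((out1,out2),((acar1,acar2),((scorp1,scorp2),(ps1,ps2))));"
        tree = read_newick(base)
        for anchor in (["acar1"], ["scorp1", "scorp2"], ["ps1", "ps2"]):
            rerooted = tree.reroot_above(anchor)
            focal = {"ps1", "ps2"}
            res = classify_sister(rerooted, focal, self.GROUPS, {"out1", "out2"})
            assert res.category == "Scorp"

    def test_leaf_order_invariance(self):
        a = self.classify("((out1,out2),((acar1,acar2),((scorp1,scorp2),(ps1,ps2))));")
        b = self.classify("((out2,out1),(((ps2,ps1),(scorp2,scorp1)),(acar2,acar1)));")
        assert a.category == b.category == "Scorp"

    def test_nonmonophyletic_outgroup_flagged(self):
        res = self.classify("((out1,(acar1,acar2)),(out2,((scorp1,scorp2),(ps1,ps2))));")
        assert any("outgroup" in f for f in res.flags)

    def test_nestedness_counts_upward(self):
        res = self.classify(
            "((out1,out2),((acar1,acar2),((scorp1,scorp2),(ps1,ps2))));")
        assert category_matches(res, {"Scorp"})
        assert category_matches(res, {"Scorp", "Acari"})  # larger clade containing it
        assert not category_matches(res, {"Acari"})


class TestHypothesisSupport:
    TREE = "((out1:1,out2:1):1,((acar1:1,acar2:1)88:1,((scorp1:1,scorp2:1)70:1,(ps1:1,ps2:1)99:1)97:1):1);"

    def test_clade_present_returns_label(self):
        tree = read_newick(self.TREE)
        value, found = hypothesis_support(
            tree, {"scorp1", "scorp2", "ps1", "ps2"}, {"out1", "out2"})
        assert found and value == 97.0

    def test_clade_absent_not_recovered(self):
        tree = read_newick(self.TREE)
        value, found = hypothesis_support(
            tree, {"acar1", "ps1", "ps2"}, {"out1", "out2"})
        assert not found and value == "not recovered"


class TestSensitivityGrid:
    @staticmethod
    def _plan():
        cells = [
            MatrixGridCell(f"G{g}", f"T-{t}" if t else "T0")
            for g in range(1, 7)
            for t in range(7)
        ]
        return AnalysisPlan(cells=cells)

    def test_full_grid_has_42_rows(self):
        plan = self._plan()
        results = {
            c: PlacementResult(True, "Sister", frozenset({"s1"}), support=90.0)
            for c in plan.cells
        }
        table, missing = sensitivity_grid(plan, results)
        assert len(table) == 42 and not missing

    def test_empty_results_all_missing(self):
        plan = self._plan()
        table, missing = sensitivity_grid(plan, {})
        assert table.empty and len(missing) == 42

    def test_unknown_cell_rejected(self):
        plan = self._plan()
        rogue = MatrixGridCell("G9", "T0")
        with pytest.raises(ValueError):
            sensitivity_grid(plan, {rogue: PlacementResult(True, "x", frozenset())})

    def test_category_flip_block_pattern(self):
        """A pruned-most misclassification next to correct unpruned cells
        reproduces the qualitative block structure."""
        cells = [MatrixGridCell("G1", s) for s in ("T0", "T-1", "T-2", "T-3")]
        plan = AnalysisPlan(cells=cells)
        results = {
            c: PlacementResult(
                True,
                "Attractor" if c.taxon_subset == "T-3" else "Sister",
                frozenset(),
            )
            for c in cells
        }
        table, _ = sensitivity_grid(plan, results)
        assert list(table.category) == ["Sister", "Sister", "Sister", "Attractor"]


def test_per_gene_sum_equals_concatenated_loglik(poisson_model):
    """With a fixed common tree and fixed branch lengths, summed per-gene
    log-likelihoods equal the concatenated log-likelihood."""
    sc = lba_scenario(n_loci=4, sites_min=40, sites_max=60, dropout=0.0, seed=23)
    loci, _ = simulate_locus_set(sc.config)
    bundle = concatenate(loci)
    whole = tree_loglik(sc.true_tree, bundle.alignment, poisson_model).log_likelihood
    parts = sum(
        tree_loglik(sc.true_tree, locus.rows, poisson_model).log_likelihood
        for locus in loci
    )
    assert whole == pytest.approx(parts, abs=1e-6)
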