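"""Gene-wise likelihood signal (ΔGLS), placement classification and
sensitivity grids.

ΔGLS for a locus is lnL(locus | T1) − lnL(locus | T2): the constrained
topologies are pruned to the taxa present in the locus (suppressing
degree-2 nodes and summing branch lengths), a substitution model is
chosen per gene by BIC, and branch lengths are re-optimized on each
constraint.  A positive value means the gene favors the first
hypothesis.  Loci that cannot resolve a hypothesis (fewer than four
taxa after restriction) are skipped and flagged rather than guessed.

Placement classification roots an inferred tree on its outgroup,
checks monophyly of the focal clade and names its sister group —
either a single registered group, a composite "A+B" label when the
sister is exactly a union of groups, or "other"/"non-monophyletic".
Because hypotheses can be nested (a named group inside a larger named
clade), :func:`category_matches` counts a sister group toward every
hypothesis clade that contains it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_core.likelihood import LikelihoodResult, select_model
from .phylo_core.models import SubstitutionModel
from .phylo_core.tree import Phylogeny
from .study_design import AnalysisPlan, MatrixGridCell
from .supermatrix import LocusAlignment


@dataclass
class HypothesisPair:
    label_1: str
    label_2: str
    tree_1: Phylogeny
    tree_2: Phylogeny

    def __post_init__(self):
        if self.label_1 == self.label_2:
            raise ValueError("hypothesis labels must be distinct")


@dataclass
class PlacementResult:
    focal_monophyletic: bool
    category: str
    sister_leaves: frozenset[str]
    support: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class GeneScore:
    locus: str
    loglik: float | None
    model: str | None
    flag: str | None = None


# ---- per-gene likelihoods ------------------------------------------

def gene_loglik_on_topology(
    locus: LocusAlignment,
    constraint_tree: Phylogeny,
    model_candidates: list[SubstitutionModel],
    tol: float = 1e-3,
    max_sweeps: int = 20,
) -> GeneScore:
    """Best (BIC-chosen) log-likelihood of one locus on a constraint
    topology restricted to the locus's taxa."""
    present = set(locus.present_taxa()) & set(constraint_tree.leaf_names())
    if len(present) < 4:
        return GeneScore(locus.id, None, None, flag="fewer than 4 taxa after restriction")
    pruned = constraint_tree.prune_to(present)
    rows = {t: locus.rows[t] for t in present}
    model, result, _ = select_model(
        rows, pruned, model_candidates, tol=tol, max_sweeps=max_sweeps
    )
    return GeneScore(locus.id, result.log_likelihood, model.name)


def delta_gls(
    locus: LocusAlignment,
    hypotheses: HypothesisPair,
    model_candidates: list[SubstitutionModel],
    tol: float = 1e-3,
    max_sweeps: int = 20,
) -> float | None:
    """lnL(gene | T1) − lnL(gene | T2); ``None`` when either side is
    unresolvable for this locus."""
    a = gene_loglik_on_topology(locus, hypotheses.tree_1, model_candidates, tol, max_sweeps)
    b = gene_loglik_on_topology(locus, hypotheses.tree_2, model_candidates, tol, max_sweeps)
    if a.loglik is None or b.loglik is None:
        return None
    return a.loglik - b.loglik


def dgls_summary(values: dict[str, float | None]) -> dict:
    """Proportions favoring each side over the defined, non-neutral loci
    (exact zeros are neutral and reported separately), plus quantiles
    of the magnitude distribution."""
    defined = {k: v for k, v in values.items() if v is not None}
    if not defined:
        raise ValueError("no defined values")
    arr = np.array(list(defined.values()))
    neutral = int((arr == 0).sum())
    signed = arr[arr != 0]
    n_signed = len(signed)
    prop_1 = float((signed > 0).sum()) / n_signed if n_signed else 0.0
    prop_2 = float((signed < 0).sum()) / n_signed if n_signed else 0.0
    mags = np.abs(arr)
    qs = np.quantile(mags, [0.25, 0.5, 0.75]) if len(mags) else np.full(3, np.nan)
    return {
        "n_defined": len(defined),
        "n_neutral": neutral,
        "n_skipped": len(values) - len(defined),
        "prop_favoring_1": prop_1,
        "prop_favoring_2": prop_2,
        "magnitude_q25": float(qs[0]),
        "magnitude_median": float(qs[1]),
        "magnitude_q75": float(qs[2]),
    }


# ---- placement classification --------------------------------------

def _root_on_outgroup(tree: Phylogeny, outgroup_leaves: set[str], flags: list[str]) -> Phylogeny:
    """Root on the largest outgroup-only clade; if the outgroup is not
    monophyletic under any rooting, fall back to the first outgroup
    leaf with a flag."""
    present = sorted(n for n in tree.leaf_names() if n in outgroup_leaves)
    if not present:
        raise ValueError("no outgroup leaf present in tree")
    all_leaves = frozenset(tree.leaf_names())
    out_set = frozenset(present)
    in_set = all_leaves - out_set
    # the outgroup is monophyletic iff some edge separates it exactly
    for node in tree.postorder():
        if node is tree.root:
            continue
        side = tree.leafset(node)
        if side == out_set or side == in_set:
            return tree.reroot_above(side)
    flags.append("outgroup not monophyletic; rooted on first outgroup leaf")
    return tree.reroot_above([present[0]])


def classify_sister(
    tree: Phylogeny,
    focal_leaves,
    group_of: dict[str, str],
    outgroup_leaves,
) -> PlacementResult:
    """Root on the outgroup and name the sister group of the focal clade.

    ``group_of`` maps every leaf to its order-level group label.
    """
    flags: list[str] = []
    focal = frozenset(focal_leaves) & frozenset(tree.leaf_names())
    outgroup = frozenset(outgroup_leaves)
    if len(focal) < 2:
        return PlacementResult(False, "unresolved", frozenset(),
                               flags=["focal clade has fewer than 2 leaves present"])
    rooted = _root_on_outgroup(tree, set(outgroup), flags)
    node = rooted.find_clade(focal)
    if node is None:
        return PlacementResult(False, "non-monophyletic", frozenset(), flags=flags)
    parent = node.parent
    if parent is None:
        return PlacementResult(True, "unresolved", frozenset(),
                               flags=flags + ["focal clade spans the root"])
    sister = rooted.leafset(parent) - focal
    groups = sorted({group_of.get(leaf, "?") for leaf in sister})
    members_present = {
        g: {l for l in rooted.leaf_names() if group_of.get(l, "?") == g} for g in groups
    }
    exact_union = sister == frozenset().union(*(members_present[g] for g in groups))
    if exact_union:
        category = "+".join(groups)
    else:
        category = "other"
        flags.append(f"sister set {sorted(sister)} is not a union of whole groups")
    support = parent.support if parent.support is not None else None
    return PlacementResult(True, category, sister, support=support, flags=flags)


def category_matches(result: PlacementResult, hypothesis_groups) -> bool:
    """Does the placement count toward a hypothesis clade?

    Compared at group-label level: every group named in the category
    must belong to *hypothesis_groups*.  Nested hypotheses count
    upward — a sister of one member group also counts toward any
    larger named clade that contains it.
    """
    if result.category in {"non-monophyletic", "unresolved", "other"}:
        return False
    return set(result.category.split("+")) <= set(hypothesis_groups)


def hypothesis_support(
    tree: Phylogeny,
    clade_leafset,
    outgroup_leaves,
) -> tuple[float | str, bool]:
    """Support label of the node whose descendant set equals
    *clade_leafset* under outgroup rooting; ``("not recovered", False)``
    when the clade is absent (plotted as 0 by convention)."""
    flags: list[str] = []
    rooted = _root_on_outgroup(tree, set(outgroup_leaves), flags)
    node = rooted.find_clade(frozenset(clade_leafset))
    if node is None:
        return "not recovered", False
    return (node.support if node.support is not None else 0.0), True


# ---- grid assembly --------------------------------------------------

def sensitivity_grid(
    plan: AnalysisPlan,
    results: dict[MatrixGridCell, PlacementResult],
) -> tuple[pd.DataFrame, list[MatrixGridCell]]:
    """Long-format table of one row per plan cell with its placement
    category and support; returns also the list of cells lacking
    results.  Results for cells outside the plan are rejected."""
    plan_cells = set(plan.cells)
    unknown = [c for c in results if c not in plan_cells]
    if unknown:
        raise ValueError(f"results for cells outside the plan: {unknown[:3]}")
    rows = []
    missing = []
    for cell in plan.cells:
        res = results.get(cell)
        if res is None:
            missing.append(cell)
            continue
        rows.append(
            {
                "occupancy_family": cell.occupancy_family,
                "taxon_subset": cell.taxon_subset,
                "method": cell.method,
                "tertile": cell.tertile or "",
                "category": res.category,
                "focal_monophyletic": res.focal_monophyletic,
                "support": res.support if res.support is not None else np.nan,
            }
        )
    columns = ["occupancy_family", "taxon_subset", "method", "tertile",
               "category", "focal_monophyletic", "support"]
    return pd.DataFrame(rows, columns=columns), missing
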