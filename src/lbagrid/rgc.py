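"""Rare genomic changes: parsimony character histories, gene-tree /
species-tree reconciliation, and duplication bookkeeping.

Character reconstruction uses Fitch parsimony.  Among the equally
parsimonious reconstructions, ACCTRAN (accelerated transformation)
places state changes as close to the root as possible — preferring an
early gain followed by reversal over parallel later gains — while
DELTRAN (delayed transformation) pushes changes tipward, preferring
parallel gains.  Both are computed exactly with a Sankoff-style
dynamic program over lexicographic costs (number of changes first,
then the sum of root-depths of change edges, minimized for ACCTRAN
and maximized for DELTRAN), so the two histories always have the same
total length, equal to the Fitch minimum.

Reconciliation is the standard last-common-ancestor (LCA) mapping of
a rooted binary gene tree onto a rooted species tree: a gene-tree
node is a duplication iff its mapping equals the mapping of one of
its children.  Duplications mapped at or above the most recent common
ancestor of a named clade, with genes of clade members on both sides,
are evidence of a duplication shared by that clade (the
whole-genome-duplication signature); duplications confined within one
member are in-paralogs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_core.tree import Node, Phylogeny

MISSING = "?"


@dataclass
class CharacterMatrix:
    name: str
    states: dict[str, object]  # tip -> state, "?" allowed
    alphabet: tuple = (0, 1)

    def state_set(self, tip: str) -> frozenset:
        v = self.states.get(tip, MISSING)
        return frozenset(self.alphabet) if v == MISSING else frozenset([v])


@dataclass
class Change:
    branch: str  # child-node name, or sorted leafset string for anonymous nodes
    from_state: object
    to_state: object


@dataclass
class CharacterHistory:
    mode: str  # "acctran" | "deltran"
    node_states: dict[str, object]  # branch label -> state
    changes: list[Change]
    length: int


def _branch_label(tree: Phylogeny, node: Node) -> str:
    if node.name:
        return node.name
    return "{" + ",".join(sorted(tree.leafset(node))) + "}"


def _check_tips(tree: Phylogeny, character: CharacterMatrix):
    tips = set(tree.leaf_names())
    missing = [t for t in character.states if t not in tips]
    if missing:
        raise ValueError(f"character scores tips absent from tree: {sorted(missing)}")


def fitch_length(tree: Phylogeny, character: CharacterMatrix) -> tuple[int, dict[str, frozenset]]:
    """Fitch downpass: minimum change count and per-node state sets."""
    _check_tips(tree, character)
    sets: dict[int, frozenset] = {}
    out: dict[str, frozenset] = {}
    length = 0
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = character.state_set(node.name)
        else:
            acc = None
            for ch in node.children:
                s = sets[id(ch)]
                if acc is None:
                    acc = s
                elif acc & s:
                    acc = acc & s
                else:
                    acc = acc | s
                    length += 1
            sets[id(node)] = acc
        out[_branch_label(tree, node)] = sets[id(node)]
    return length, out


def _resolve(tree: Phylogeny, character: CharacterMatrix, sign: int,
             outgroup: list[str] | None) -> CharacterHistory:
    """Sankoff DP over lexicographic cost (changes, sign * depth-sum)."""
    _check_tips(tree, character)
    alphabet = list(character.alphabet)
    depth: dict[int, int] = {id(tree.root): 0}
    for node in tree.preorder():
        for ch in node.children:
            depth[id(ch)] = depth[id(node)] + 1
    # cost[node][state] = (changes, sign*depth_sum) for the subtree,
    # given the node has `state`
    INF = (10**9, 0)
    cost: dict[int, dict] = {}
    for node in tree.postorder():
        if node.is_leaf:
            allowed = character.state_set(node.name)
            cost[id(node)] = {
                s: (0, 0) if s in allowed else INF for s in alphabet
            }
            continue
        table = {}
        for s in alphabet:
            total = (0, 0)
            for ch in node.children:
                best = None
                for t in alphabet:
                    c_changes, c_depth = cost[id(ch)][t]
                    if t != s:
                        c_changes += 1
                        c_depth += sign * depth[id(ch)]
                    cand = (c_changes, c_depth)
                    if best is None or cand < best:
                        best = cand
                total = (total[0] + best[0], total[1] + best[1])
            table[s] = total
        cost[id(node)] = table

    root_costs = cost[id(tree.root)]
    best_cost = min(root_costs.values())
    optimal = [s for s in alphabet if root_costs[s] == best_cost]
    if len(optimal) > 1:
        # tie: prefer the state observed in the outgroup
        ref = outgroup if outgroup else [tree.leaves()[0].name]
        observed = [character.states.get(t) for t in ref]
        observed = [v for v in observed if v != MISSING and v is not None]
        for s in observed:
            if s in optimal:
                optimal = [s]
                break
    root_state = optimal[0]

    # backtrack: each child takes the state achieving its parent's best,
    # ties broken toward the parent state (no change), then alphabet order
    assignment: dict[int, object] = {id(tree.root): root_state}
    for node in tree.preorder():
        s = assignment[id(node)]
        for ch in node.children:
            best, best_t = None, None
            for t in alphabet:
                c_changes, c_depth = cost[id(ch)][t]
                if t != s:
                    c_changes += 1
                    c_depth += sign * depth[id(ch)]
                cand = (c_changes, c_depth, t != s)
                if best is None or cand < best:
                    best, best_t = cand, t
            assignment[id(ch)] = best_t

    changes = []
    node_states = {}
    for node in tree.preorder():
        label = _branch_label(tree, node)
        node_states[label] = assignment[id(node)]
        if node.parent is not None and assignment[id(node)] != assignment[id(node.parent)]:
            changes.append(Change(label, assignment[id(node.parent)], assignment[id(node)]))
    return CharacterHistory(
        mode="acctran" if sign > 0 else "deltran",
        node_states=node_states,
        changes=changes,
        length=len(changes),
    )


def acctran(tree: Phylogeny, character: CharacterMatrix,
            outgroup: list[str] | None = None) -> CharacterHistory:
    """Minimum-length history with changes as rootward as possible."""
    return _resolve(tree, character, sign=+1, outgroup=outgroup)


def deltran(tree: Phylogeny, character: CharacterMatrix,
            outgroup: list[str] | None = None) -> CharacterHistory:
    """Minimum-length history with changes as tipward as possible."""
    return _resolve(tree, character, sign=-1, outgroup=outgroup)


# ---- reconciliation -------------------------------------------------

@dataclass
class DuplicationEvent:
    gene_node_label: str
    species_node: str  # species name or leafset label
    left_species: frozenset[str]
    right_species: frozenset[str]

    @property
    def species(self) -> frozenset[str]:
        return self.left_species | self.right_species


@dataclass
class ReconciliationResult:
    events: dict[str, str]  # gene-node label -> "speciation" | "duplication"
    mappings: dict[str, frozenset[str]]  # gene-node label -> mapped species leafset
    duplications: list[DuplicationEvent]

    @property
    def duplication_count(self) -> int:
        return len(self.duplications)


def lca_reconcile(
    gene_tree: Phylogeny,
    species_tree: Phylogeny,
    leaf_to_species: dict[str, str],
) -> ReconciliationResult:
    """LCA mapping of a rooted binary gene tree onto a species tree."""
    for node in gene_tree.internal_nodes():
        if len(node.children) != 2:
            raise ValueError("gene tree must be rooted and binary")
    species_leaves = set(species_tree.leaf_names())
    unmapped = [l for l in gene_tree.leaf_names() if l not in leaf_to_species]
    if unmapped:
        raise ValueError(f"unmapped gene leaves: {unmapped}")
    bad = {s for s in leaf_to_species.values() if s not in species_leaves}
    if bad:
        raise ValueError(f"species absent from species tree: {sorted(bad)}")

    # species node for each gene node, via MRCA over mapped species
    mapping: dict[int, Node] = {}
    sp_leafsets = {id(n): species_tree.leafset(n) for n in species_tree.postorder()}

    def species_mrca(species: frozenset[str]) -> Node:
        return species_tree.mrca(species)

    events: dict[str, str] = {}
    mappings: dict[str, frozenset[str]] = {}
    dups: list[DuplicationEvent] = []
    for node in gene_tree.postorder():
        if node.is_leaf:
            mapping[id(node)] = species_tree.mrca([leaf_to_species[node.name]])
            continue
        child_maps = [mapping[id(c)] for c in node.children]
        all_species = frozenset(
            leaf_to_species[l] for l in gene_tree.leafset(node)
        )
        own = species_mrca(all_species)
        mapping[id(node)] = own
        label = _branch_label(gene_tree, node)
        mappings[label] = sp_leafsets[id(own)]
        is_dup = any(cm is own for cm in child_maps)
        events[label] = "duplication" if is_dup else "speciation"
        if is_dup:
            left, right = node.children
            dups.append(
                DuplicationEvent(
                    gene_node_label=label,
                    species_node=_branch_label(species_tree, own),
                    left_species=frozenset(
                        leaf_to_species[l] for l in gene_tree.leafset(left)
                    ),
                    right_species=frozenset(
                        leaf_to_species[l] for l in gene_tree.leafset(right)
                    ),
                )
            )
    return ReconciliationResult(events=events, mappings=mappings, duplications=dups)


def shared_duplication(
    reconciliation: ReconciliationResult,
    species_tree: Phylogeny,
    clade_species_set,
) -> dict[str, str]:
    """Classify each duplication as shared by the clade, lineage
    specific, or unrelated to it ("absent").

    Shared: mapped at or above the clade's MRCA, with clade members on
    both sides of the duplication.  Lineage-specific: mapped strictly
    inside the clade below its MRCA, or involving a single member.
    """
    clade = frozenset(clade_species_set)
    if not clade:
        raise ValueError("empty clade set")
    mrca_set = species_tree.leafset(species_tree.mrca(clade))
    out: dict[str, str] = {}
    for dup in reconciliation.duplications:
        mapped = reconciliation.mappings[dup.gene_node_label]
        involved = dup.species & clade
        if mapped >= mrca_set and dup.left_species & clade and dup.right_species & clade:
            out[dup.gene_node_label] = "shared"
        elif (mapped < mrca_set and mapped <= clade) or len(involved) == 1:
            out[dup.gene_node_label] = "lineage_specific"
        else:
            out[dup.gene_node_label] = "absent"
    return out


# ---- paralogy screening ---------------------------------------------

def _pair_relation(seq_a: str, seq_b: str, min_overlap: int = 100,
                   min_substitutions: int = 2) -> str:
    """Relation between two aligned fragments on a common frame.

    ``paralogs`` needs an overlap exceeding *min_overlap* residues with
    at least *min_substitutions* differences; fragments that do not
    overlap, or that differ at most once, are the same putative copy
    (``merge``); short overlaps with many differences are inconclusive
    and merged conservatively.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("fragments must be aligned to a common frame")
    pairs = [
        (x, y)
        for x, y in zip(seq_a.upper(), seq_b.upper())
        if x != "-" and y != "-"
    ]
    overlap = len(pairs)
    subs = sum(1 for x, y in pairs if x != y)
    if overlap > min_overlap and subs >= min_substitutions:
        return "paralogs"
    return "merge"


def paralog_screen(candidates: dict[str, str], min_overlap: int = 100,
                   min_substitutions: int = 2) -> tuple[int, pd.DataFrame]:
    """Copy count for one gene in one species from aligned candidate
    fragments.

    Pairs are classified (allele/fragment pairs merge, paralog pairs
    do not) and the copy count is the number of connected components
    of the merge graph — invariant to input order.
    """
    names = sorted(candidates)
    if not names:
        return 0, pd.DataFrame(columns=["a", "b", "call"])
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    calls = []
    for a, b in itertools.combinations(names, 2):
        rel = _pair_relation(candidates[a], candidates[b], min_overlap, min_substitutions)
        calls.append({"a": a, "b": b, "call": rel})
        if rel == "merge":
            parent[find(a)] = find(b)
    count = len({find(n) for n in names})
    return count, pd.DataFrame(calls)


def motif_filter(peptides: dict[str, str],
                 required_motifs=("ELEKEF", "KIWFQN")) -> dict[str, str]:
    """Retain peptides containing every required motif as an exact
    substring (an empty motif list retains everything)."""
    return {
        name: seq
        for name, seq in peptides.items()
        if all(m in seq for m in required_motifs)
    }


@dataclass
class DuplicationTally:
    counts: pd.DataFrame  # gene/family x species, integer copy counts
    shared_flags: pd.Series  # per row: duplicated in focal AND reference clade


def duplication_tally(
    counts: pd.DataFrame,
    focal_species,
    reference_species,
) -> DuplicationTally:
    """Copy-count matrix with a per-row shared-duplication flag: true
    iff some focal-clade species and some reference-clade species both
    have two or more copies."""
    if (counts.fillna(0) < 0).any().any():
        raise ValueError("copy counts must be non-negative")
    focal = [s for s in focal_species if s in counts.columns]
    ref = [s for s in reference_species if s in counts.columns]
    dup = counts.fillna(0) >= 2
    flags = dup[focal].any(axis=1) & dup[ref].any(axis=1)
    return DuplicationTally(counts=counts, shared_flags=flags)
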