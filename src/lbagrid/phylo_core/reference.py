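"""Slow, direct reference computations used to validate the fast paths.

Everything here works by explicit enumeration or closed form and never
touches the pruning/DP machinery it is used to check.  Intended for
small problems (a handful of leaves, short alignments).
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .models import SubstitutionModel, encode_sequence
from .tree import Phylogeny


def exhaustive_loglik(tree: Phylogeny, alignment: dict[str, str], model: SubstitutionModel) -> float:
    """Log-likelihood by summation over every interior-state assignment.

    The full 20^(number of internal nodes) assignment table is
    enumerated explicitly (vectorized across assignments and sites);
    exponential in the number of internal nodes, so use on trees with
    at most ~5 leaves.
    """
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    codes = {n.name: encode_sequence(alignment[n.name]) for n in leaves}
    n_sites = len(next(iter(codes.values())))
    rates = model.category_rates
    pi = model.frequencies
    idx = {id(n): i for i, n in enumerate(internals)}
    # every interior assignment as one row
    A = np.array(
        list(itertools.product(range(20), repeat=len(internals))), dtype=np.intp
    )
    root_col = A[:, idx[id(tree.root)]]

    site_lik = np.zeros(n_sites)
    for r in rates:
        P = {
            id(n): model.transition_matrix((n.length or 0.0) * r)
            for n in nodes
            if n.parent is not None
        }
        w = pi[root_col].copy()  # (n_assignments,)
        for node in internals:
            if node.parent is None:
                continue
            w *= P[id(node)][A[:, idx[id(node.parent)]], A[:, idx[id(node)]]]
        lik = np.repeat(w[:, None], n_sites, axis=1)  # (n_assignments, n_sites)
        for leaf in leaves:
            rows = P[id(leaf)][A[:, idx[id(leaf.parent)]], :]  # (n_assignments, 20)
            code = codes[leaf.name]
            obs = np.where(code >= 0, code, 0)
            term = rows[:, obs]
            ambiguous = code < 0
            if ambiguous.any():
                term = term.copy()
                term[:, ambiguous] = rows.sum(axis=1)[:, None]
            lik *= term
        site_lik += lik.sum(axis=0) / len(rates)
    with np.errstate(divide="ignore"):
        logs = np.where(site_lik > 0, np.log(np.maximum(site_lik, 1e-320)), -745.0)
    return float(logs.sum())


def jc20_distance(p: float) -> float:
    """Closed-form MLE branch length for the 20-state equal-rates chain."""
    return -(19.0 / 20.0) * math.log(1.0 - 20.0 * p / 19.0)


def jc20_transition_probability(t: float, same: bool) -> float:
    """Analytic P(t) entry for the 20-state equal-rates chain."""
    e = math.exp(-t * 20.0 / 19.0)
    if same:
        return 1.0 / 20.0 + (19.0 / 20.0) * e
    return 1.0 / 20.0 - (1.0 / 20.0) * e


def enumerate_mprs(tree: Phylogeny, states: dict[str, int | None], alphabet: tuple[int, ...]):
    """All minimum-length reconstructions by brute force.

    ``states`` maps leaf name to state, ``None`` meaning unknown.
    Yields ``(length, assignment)`` where assignment maps node id to
    state for every node; only the minimal-length assignments are
    returned.
    """
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    best = None
    results = []
    free_leaves = [lf for lf in leaves if states[lf.name] is None]
    for leaf_fill in itertools.product(alphabet, repeat=len(free_leaves)):
        fixed = dict(states)
        for lf, st in zip(free_leaves, leaf_fill):
            fixed[lf.name] = st
        for assignment in itertools.product(alphabet, repeat=len(internals)):
            node_state = {id(n): s for n, s in zip(internals, assignment)}
            for lf in leaves:
                node_state[id(lf)] = fixed[lf.name]
            length = sum(
                1
                for n in nodes
                if n.parent is not None and node_state[id(n)] != node_state[id(n.parent)]
            )
            if best is None or length < best:
                best = length
                results = [(length, node_state)]
            elif length == best:
                results.append((length, node_state))
    return best, results


def reconcile_oracle(gene_tree: Phylogeny, species_tree: Phylogeny, leaf_map: dict[str, str]):
    """Independent duplication/speciation labelling.

    Maps every gene-tree node to the smallest species-tree clade whose
    leaf set covers the node's species (found by scanning all species
    clades), then labels a node a duplication iff its species overlap
    with either child is non-empty under the LCA criterion — checked
    directly from leaf sets rather than via parent pointers.
    """
    clades = []
    for node in species_tree.postorder():
        clades.append((species_tree.leafset(node), node))
    clades.sort(key=lambda t: len(t[0]))

    def smallest_covering(species: frozenset[str]):
        for leafset, node in clades:
            if species <= leafset:
                return node
        raise ValueError(f"species {sorted(species)} not covered by species tree")

    events = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            continue
        child_species = [
            frozenset(leaf_map[l] for l in gene_tree.leafset(c)) for c in node.children
        ]
        own = smallest_covering(frozenset().union(*child_species))
        dup = any(smallest_covering(cs) is own for cs in child_species)
        events[id(node)] = "duplication" if dup else "speciation"
    return events
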