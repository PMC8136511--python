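"""Shared test utilities: random trees/alignments and scenario classification."""

from __future__ import annotations

import numpy as np

from lbagrid.phylo_core.tree import Node, Phylogeny
from lbagrid.signal import PlacementResult, classify_sister

AA = "ARNDCQEGHILKMFPSTWYV"


def random_rooted_tree(rng: np.random.Generator, n_leaves: int,
                       min_bl: float = 0.01, max_bl: float = 1.0) -> Phylogeny:
    nodes = [Node(f"L{i}", float(rng.uniform(min_bl, max_bl))) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = Node(None, float(rng.uniform(min_bl, max_bl)))
        parent.add(a)
        parent.add(b)
        nodes.append(parent)
    nodes[0].length = None
    return Phylogeny(nodes[0])


def random_alignment(rng: np.random.Generator, names, n_sites: int,
                     alphabet: str = AA) -> dict[str, str]:
    return {n: "".join(rng.choice(list(alphabet), n_sites)) for n in names}


def has_split(tree: Phylogeny, side) -> bool:
    """True when the unrooted tree contains the bipartition with *side*
    on either half."""
    side = frozenset(side)
    complement = frozenset(tree.leaf_names()) - side
    bips = tree.bipartitions()
    return side in bips or complement in bips


def scenario_group(leaf: str) -> str:
    return leaf.rsplit("_", 1)[0].replace("FocalBasal1", "Focal").replace(
        "FocalBasal2", "Focal").replace("FocalBasal3", "Focal").replace(
        "FocalDerived", "Focal")


def classify_scenario_tree(tree: Phylogeny) -> PlacementResult:
    """Sister-group classification for trees over scenario taxa."""
    leaves = tree.leaf_names()
    group_of = {l: scenario_group(l) for l in leaves}
    focal = {l for l in leaves if group_of[l] == "Focal"}
    outgroup = {l for l in leaves if group_of[l] == "Outgroup"}
    return classify_sister(tree, focal, group_of, outgroup)
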