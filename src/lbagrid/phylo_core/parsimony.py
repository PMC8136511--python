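"""Fitch parsimony on alignments, and a parsimony tree search.

Residues are encoded as 20-bit state masks so the Fitch downpass
(vectorized over alignment columns) is a couple of integer operations
per node.  Ambiguity codes carry the full mask and therefore never
cost a change.  The tree search is the parsimony analog of the
likelihood search: an NJ starting tree on uncorrected p-distances
followed by NNI hill climbing on the Fitch score — deliberately a
*model-free* method, which is exactly the kind of inference that is
statistically inconsistent in the Felsenstein zone.
"""

from __future__ import annotations

import numpy as np

from .models import AA_INDEX, AMBIGUOUS
from .search import nj_from_alignment, nni_neighbors
from .tree import Phylogeny

FULL_MASK = (1 << 20) - 1

# byte-value lookup table: residue -> one-hot bit, ambiguity -> full mask
_LUT = np.zeros(256, dtype=np.int64)
for _ch, _i in AA_INDEX.items():
    _LUT[ord(_ch)] = 1 << _i
    _LUT[ord(_ch.lower())] = 1 << _i
for _ch in AMBIGUOUS:
    _LUT[ord(_ch)] = FULL_MASK


def encode_masks(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = _LUT[raw]
    if (out == 0).any():
        bad = int(np.argmax(out == 0))
        raise ValueError(f"unknown residue {seq[bad]!r} at column {bad + 1}")
    return out


def fitch_score(tree: Phylogeny, alignment: dict) -> int:
    """Minimum number of changes over all columns (Fitch downpass).

    ``alignment`` maps leaf name to an aligned string or to an
    already-encoded mask array (see :func:`encode_masks`).
    """
    masks = {}
    changes = 0
    for node in tree.postorder():
        if node.is_leaf:
            row = alignment[node.name]
            masks[id(node)] = row if isinstance(row, np.ndarray) else encode_masks(row)
            continue
        acc = None
        for ch in node.children:
            m = masks[id(ch)]
            if acc is None:
                acc = m
                continue
            inter = acc & m
            union = acc | m
            empty = inter == 0
            changes += int(empty.sum())
            acc = np.where(empty, union, inter)
        masks[id(node)] = acc
    return changes


def parsimony_search(
    alignment: dict[str, str],
    start_tree: Phylogeny | None = None,
    max_rounds: int = 200,
) -> tuple[Phylogeny, int]:
    """NNI hill climbing on the Fitch score from an NJ(p-distance) start."""
    current = (start_tree or nj_from_alignment(alignment, corrected=False)).unroot()
    encoded = {name: encode_masks(seq) for name, seq in alignment.items()}
    score = fitch_score(current, encoded)
    for _ in range(max_rounds):
        best_tree, best_score = None, score
        for cand in nni_neighbors(current):
            s = fitch_score(cand, encoded)
            if s < best_score:
                best_tree, best_score = cand, s
        if best_tree is None:
            break
        current, score = best_tree, best_score
    return current, score


def best_quartet_topology(alignment: dict[str, str], scorer=fitch_score) -> tuple[Phylogeny, int | float]:
    """Exhaustive scoring of the three unrooted quartet topologies.

    ``scorer(tree, alignment)`` must return a value to minimize; the
    default is the Fitch score.
    """
    from .tree import read_newick

    names = sorted(alignment)
    if len(names) != 4:
        raise ValueError("quartet inference needs exactly 4 taxa")
    a, b, c, d = names
    topologies = [
        f"(({a},{b}),{c},{d});",
        f"(({a},{c}),{b},{d});",
        f"(({a},{d}),{b},{c});",
    ]
    best = None
    for nwk in topologies:
        tree = read_newick(nwk)
        s = scorer(tree, alignment)
        if best is None or s < best[1]:
            best = (tree, s)
    return best
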