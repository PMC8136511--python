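"""Distance-based starting trees, NNI hill climbing and site bootstrap.

The tree search is deliberately modest: neighbor joining on
Poisson-corrected pairwise distances provides a starting topology,
and nearest-neighbor-interchange hill climbing under the likelihood
engine refines it.  Support values come from a plain nonparametric
site bootstrap (columns resampled with replacement, the whole search
rerun per replicate).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np

from .likelihood import LikelihoodResult, TreeLikelihood
from .models import SubstitutionModel, encode_sequence
from .tree import Node, Phylogeny

SATURATION_CAP = 20.0


def ml_pairwise_distance(seq_a: str, seq_b: str) -> tuple[float, bool]:
    """Poisson-corrected (20-state Jukes-Cantor) distance.

    Returns ``(distance, saturated)``.  Only mutually unambiguous
    columns are compared; a mismatch proportion at or beyond the
    19/20 saturation point is capped at 20 substitutions/site.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences have unequal lengths")
    a = encode_sequence(seq_a)
    b = encode_sequence(seq_b)
    mask = (a >= 0) & (b >= 0)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no mutually unambiguous columns")
    p = float((a[mask] != b[mask]).mean())
    if p >= 19.0 / 20.0:
        return SATURATION_CAP, True
    return -(19.0 / 20.0) * np.log(1.0 - 20.0 * p / 19.0), False


def distance_matrix(alignment: dict[str, str], corrected: bool = True) -> tuple[np.ndarray, list[str]]:
    """All-pairs distances; ``corrected=False`` gives raw p-distances."""
    names = sorted(alignment)
    codes = {n: encode_sequence(alignment[n]) for n in names}
    n = len(names)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = codes[names[i]], codes[names[j]]
        mask = (a >= 0) & (b >= 0)
        if not mask.any():
            raise ValueError(f"no comparable columns between {names[i]} and {names[j]}")
        p = float((a[mask] != b[mask]).mean())
        if corrected:
            if p >= 19.0 / 20.0:
                d = SATURATION_CAP
            else:
                d = -(19.0 / 20.0) * np.log(1.0 - 20.0 * p / 19.0)
        else:
            d = p
        D[i, j] = D[j, i] = d
    return D, names


def nj_tree(D: np.ndarray, names: list[str]) -> Phylogeny:
    """Saitou & Nei neighbor joining; negative branch lengths are
    clamped to zero (with a warning).  Returns an unrooted tree
    (trifurcating root)."""
    D = np.asarray(D, dtype=float)
    n = len(names)
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric and match names")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [Node(name) for name in names]
    D = D.copy()
    active = list(range(n))
    clamped = False

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qm = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Qm), Qm.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        gi, gj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
        parent = Node()
        a, b = nodes[gi], nodes[gj]
        a.length = max(li, 0.0)
        b.length = max(lj, 0.0)
        parent.add(a)
        parent.add(b)
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (D[gi] + D[gj] - dij)
        nodes.append(parent)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row)] = new_row
        D[: len(new_row), -1] = new_row
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    # join the last three around a trifurcating root
    x, y, z = active
    dxy, dxz, dyz = D[x, y], D[x, z], D[y, z]
    root = Node()
    lx = 0.5 * (dxy + dxz - dyz)
    ly = 0.5 * (dxy + dyz - dxz)
    lz = 0.5 * (dxz + dyz - dxy)
    for g, ln in ((x, lx), (y, ly), (z, lz)):
        if ln < 0:
            clamped = True
        nodes[g].length = max(ln, 0.0)
        root.add(nodes[g])
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0", RuntimeWarning, stacklevel=2)
    return Phylogeny(root)


def nj_from_alignment(alignment: dict[str, str], corrected: bool = True) -> Phylogeny:
    D, names = distance_matrix(alignment, corrected=corrected)
    return nj_tree(D, names)


# ---- NNI ------------------------------------------------------------

def nni_neighbors(tree: Phylogeny):
    """All trees one nearest-neighbor interchange away (unrooted sense).

    Works on the rooted representation: for each internal non-root node
    with a parent-side partner, swap each of its first two children with
    a fixed representative of the parent side.
    """
    out = []
    nodes = [n for n in tree.postorder() if not n.is_leaf and n.parent is not None]
    for idx, node in enumerate(nodes):
        parent = node.parent
        partners = [c for c in parent.children if c is not node]
        if parent.parent is None and len(partners) < 2:
            # bifurcating root: this edge has no third parent-side
            # component; callers should unroot first
            continue
        for child_pos in range(min(2, len(node.children))):
            new = tree.copy()
            new_nodes = [n for n in new.postorder() if not n.is_leaf and n.parent is not None]
            v = new_nodes[idx]
            u = v.parent
            w = [c for c in u.children if c is not v][0]
            c = v.children[child_pos]
            # swap w and c (edges keep their lengths)
            u.children[u.children.index(w)] = c
            v.children[child_pos] = w
            c.parent, w.parent = u, v
            v.support = None
            out.append(new)
    return out


def nni_search(
    start_tree: Phylogeny,
    alignment: dict[str, str],
    model: SubstitutionModel,
    improve_tol: float = 1e-3,
    sweep_tol: float = 1e-3,
    max_sweeps: int = 8,
    max_rounds: int = 50,
) -> tuple[Phylogeny, LikelihoodResult]:
    """Hill-climb over NNIs, re-optimizing branch lengths after each
    accepted swap; stops when no interchange improves lnL by more than
    *improve_tol*."""
    current = start_tree.unroot()
    result = TreeLikelihood(current, alignment, model).optimize(
        tol=sweep_tol, max_sweeps=max_sweeps
    )
    for _ in range(max_rounds):
        best_tree, best_res = None, None
        for cand in nni_neighbors(current):
            res = TreeLikelihood(cand, alignment, model).optimize(
                tol=sweep_tol, max_sweeps=max_sweeps
            )
            if res.log_likelihood > result.log_likelihood + improve_tol and (
                best_res is None or res.log_likelihood > best_res.log_likelihood
            ):
                best_tree, best_res = cand, res
        if best_tree is None:
            break
        current, result = best_tree, best_res
    return current, result


# ---- bootstrap ------------------------------------------------------

def _resample_columns(alignment: dict[str, str], rng: np.random.Generator) -> dict[str, str]:
    n = len(next(iter(alignment.values())))
    idx = rng.integers(0, n, size=n)
    return {name: "".join(seq[i] for i in idx) for name, seq in alignment.items()}


def bootstrap_support(
    alignment: dict[str, str],
    model: SubstitutionModel,
    n_reps: int,
    seed: int,
    use_nni: bool = True,
    point_tree: Phylogeny | None = None,
) -> Phylogeny:
    """Nonparametric site bootstrap.

    The point estimate (NJ + optional NNI) is annotated with the
    percentage of replicates whose re-estimated tree contains each of
    its bipartitions.  Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)

    def infer(aln: dict[str, str]) -> Phylogeny:
        t = nj_from_alignment(aln)
        if use_nni:
            t, _ = nni_search(t, aln, model)
        return t

    point = point_tree.copy() if point_tree is not None else infer(alignment)
    counts: dict[frozenset, int] = {split: 0 for split in point.bipartitions()}
    for _ in range(n_reps):
        rep = infer(_resample_columns(alignment, rng))
        for split in rep.bipartitions():
            if split in counts:
                counts[split] += 1
    all_leaves = frozenset(point.leaf_names())
    ref = min(all_leaves)
    for node in point.postorder():
        if node.is_leaf or node is point.root:
            continue
        side = point.leafset(node)
        if ref in side:
            side = all_leaves - side
        if side in counts:
            node.support = 100.0 * counts[side] / n_reps
    return point
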