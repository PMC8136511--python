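"""Felsenstein pruning, branch-length optimization and model selection.

The engine computes per-site log-likelihoods under a GTR-form
amino-acid model with optional discrete-gamma rate categories
(equal-weight category averaging before the log).  Gaps and other
ambiguity codes contribute a partial likelihood of one for every
state.  Underflow is handled by per-node rescaling with accumulated
log scalers, so alignments with many taxa stay finite.

Branch lengths are optimized coordinate-wise: for each edge the
likelihood is a cheap function of that edge's length once the
"down" (subtree) and "up" (rest-of-tree, root prior folded in)
conditionals are in hand, and each one-dimensional problem is solved
by bounded Brent search.  Sweeps repeat until the total
log-likelihood improves by less than a tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .models import SubstitutionModel, encode_sequence
from .tree import Phylogeny, Node

MIN_BRANCH = 1e-8
MAX_BRANCH = 20.0
#: floor for a per-site log-likelihood of zero (impossible site)
LOG_ZERO_FLOOR = -745.0


@dataclass
class LikelihoodResult:
    log_likelihood: float
    site_log_likelihoods: np.ndarray
    tree: Phylogeny
    model: SubstitutionModel
    converged: bool = True
    n_sweeps: int = 0
    extra: dict = field(default_factory=dict)


class TreeLikelihood:
    """Likelihood machinery bound to one (tree, alignment, model) triple.

    The tree is used in place; optimization mutates its branch lengths.
    """

    def __init__(self, tree: Phylogeny, alignment: dict[str, str], model: SubstitutionModel):
        self.tree = tree
        self.model = model
        leaf_names = tree.leaf_names()
        missing = [n for n in leaf_names if n not in alignment]
        if missing:
            raise ValueError(f"leaves missing from alignment: {missing}")
        lengths = {len(alignment[n]) for n in leaf_names}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        self.n_sites = lengths.pop()
        if self.n_sites < 1:
            raise ValueError("alignment has no sites")
        self.codes = {n: encode_sequence(alignment[n]) for n in leaf_names}
        self.rates = model.category_rates
        self.k = len(self.rates)
        self.pi = model.frequencies
        # fixed leaf conditionals, shared across categories
        self._leaf_partial: dict[str, np.ndarray] = {}
        eye = np.eye(20)
        for name in leaf_names:
            codes = self.codes[name]
            part = np.ones((self.n_sites, 20))
            obs = codes >= 0
            part[obs] = eye[codes[obs]]
            self._leaf_partial[name] = part
        for node in self.tree.preorder():
            if node is self.tree.root:
                continue
            if node.length is None:
                node.length = MIN_BRANCH
            elif node.length < 0:
                raise ValueError("negative branch length")

    # ---- passes ----------------------------------------------------
    def _edge_P(self, length: float) -> list[np.ndarray]:
        return [self.model.transition_matrix(length * r) for r in self.rates]

    def _downpass(self):
        """Down conditionals D[node][cat] (n_sites, 20) with log scalers."""
        D: dict[int, list[np.ndarray]] = {}
        ds: dict[int, list[np.ndarray]] = {}
        for node in self.tree.postorder():
            if node.is_leaf:
                D[id(node)] = [self._leaf_partial[node.name]] * self.k
                ds[id(node)] = [np.zeros(self.n_sites)] * self.k
                continue
            parts, scals = [], []
            for c in range(self.k):
                acc = np.ones((self.n_sites, 20))
                sc = np.zeros(self.n_sites)
                for ch in node.children:
                    P = self.model.transition_matrix(ch.length * self.rates[c])
                    acc = acc * (D[id(ch)][c] @ P.T)
                    sc = sc + ds[id(ch)][c]
                mx = acc.max(axis=1)
                mx[mx <= 0] = 1.0
                acc = acc / mx[:, None]
                sc = sc + np.log(mx)
                parts.append(acc)
                scals.append(sc)
            D[id(node)] = parts
            ds[id(node)] = scals
        return D, ds

    def _uppass(self, D, ds):
        """Up conditionals A[node][cat]: likelihood of everything outside
        the node's subtree, expressed at the node's own states, with the
        root prior pi folded in."""
        A: dict[int, list[np.ndarray]] = {}
        asc: dict[int, list[np.ndarray]] = {}
        root = self.tree.root
        A[id(root)] = [np.tile(self.pi, (self.n_sites, 1)) for _ in range(self.k)]
        asc[id(root)] = [np.zeros(self.n_sites)] * self.k
        for node in self.tree.preorder():
            if node.is_leaf:
                continue
            # per-child "message" through that child's edge
            msgs = {}
            for ch in node.children:
                msgs[id(ch)] = [
                    D[id(ch)][c] @ self.model.transition_matrix(ch.length * self.rates[c]).T
                    for c in range(self.k)
                ]
            for ch in node.children:
                parts, scals = [], []
                for c in range(self.k):
                    acc = A[id(node)][c].copy()
                    sc = asc[id(node)][c].copy()
                    for sib in node.children:
                        if sib is ch:
                            continue
                        acc = acc * msgs[id(sib)][c]
                        sc = sc + ds[id(sib)][c]
                    Pch = self.model.transition_matrix(ch.length * self.rates[c])
                    acc = acc @ Pch
                    mx = acc.max(axis=1)
                    mx[mx <= 0] = 1.0
                    acc = acc / mx[:, None]
                    sc = sc + np.log(mx)
                    parts.append(acc)
                    scals.append(sc)
                A[id(ch)] = parts
                asc[id(ch)] = scals
        return A, asc

    def _edge_context(self, child: Node, D, ds, A, asc):
        """B (parent-side, pre-edge) conditionals for optimizing the
        edge above *child*."""
        parent = child.parent
        B, bs = [], []
        for c in range(self.k):
            acc = A[id(parent)][c].copy()
            sc = asc[id(parent)][c].copy()
            for sib in parent.children:
                if sib is child:
                    continue
                P = self.model.transition_matrix(sib.length * self.rates[c])
                acc = acc * (D[id(sib)][c] @ P.T)
                sc = sc + ds[id(sib)][c]
            B.append(acc)
            bs.append(sc)
        return B, bs

    # ---- likelihood ------------------------------------------------
    def _site_logs_from_root(self, D, ds) -> np.ndarray:
        root = self.tree.root
        per_cat = np.empty((self.k, self.n_sites))
        for c in range(self.k):
            lik = D[id(root)][c] @ self.pi
            with np.errstate(divide="ignore"):
                per_cat[c] = np.log(lik) + ds[id(root)][c]
        site = logsumexp(per_cat, axis=0) - np.log(self.k)
        bad = ~np.isfinite(site) | (site < LOG_ZERO_FLOOR)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} site(s) with zero likelihood floored at {LOG_ZERO_FLOOR}",
                RuntimeWarning,
                stacklevel=3,
            )
            site = np.where(bad, LOG_ZERO_FLOOR, site)
        return site

    def loglik(self) -> float:
        D, ds = self._downpass()
        return float(self._site_logs_from_root(D, ds).sum())

    def site_log_likelihoods(self) -> np.ndarray:
        D, ds = self._downpass()
        return self._site_logs_from_root(D, ds)

    def _edge_loglik(self, B, bs, Dv, dsv, length: float) -> float:
        per_cat = np.empty((self.k, self.n_sites))
        for c in range(self.k):
            P = self.model.transition_matrix(length * self.rates[c])
            lik = (B[c] * (Dv[c] @ P.T)).sum(axis=1)
            with np.errstate(divide="ignore"):
                per_cat[c] = np.log(lik) + bs[c] + dsv[c]
        site = logsumexp(per_cat, axis=0) - np.log(self.k)
        site = np.where(np.isfinite(site) & (site >= LOG_ZERO_FLOOR), site, LOG_ZERO_FLOOR)
        return float(site.sum())

    # ---- optimization ----------------------------------------------
    def _optimize_edge(self, child: Node, D, ds, A, asc) -> None:
        """Brent on one edge length given (possibly stale) context."""
        B, bs = self._edge_context(child, D, ds, A, asc)
        Dv, dsv = D[id(child)], ds[id(child)]
        here = self._edge_loglik(B, bs, Dv, dsv, child.length)
        res = minimize_scalar(
            lambda t: -self._edge_loglik(B, bs, Dv, dsv, t),
            bounds=(MIN_BRANCH, MAX_BRANCH),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if -res.fun > here:
            child.length = float(res.x)

    def _sweep_fast(self, edges) -> None:
        """One pass pair, then every edge against that shared context.

        Contexts go stale as edges change within the sweep, so the
        result is checked (and reverted) by the caller.
        """
        D, ds = self._downpass()
        A, asc = self._uppass(D, ds)
        for child in edges:
            self._optimize_edge(child, D, ds, A, asc)

    def _sweep_exact(self, edges) -> None:
        """Fresh passes before each edge; guaranteed non-decreasing."""
        for child in edges:
            D, ds = self._downpass()
            A, asc = self._uppass(D, ds)
            self._optimize_edge(child, D, ds, A, asc)

    def optimize(self, tol: float = 1e-4, max_sweeps: int = 50) -> LikelihoodResult:
        current = self.loglik()
        converged = False
        sweeps = 0
        edges = [n for n in self.tree.preorder() if n is not self.tree.root]
        for sweeps in range(1, max_sweeps + 1):
            snapshot = [(ch, ch.length) for ch in edges]
            self._sweep_fast(edges)
            new = self.loglik()
            if new < current - 1e-9:
                # shared-context sweep overshot: revert and redo exactly
                for ch, length in snapshot:
                    ch.length = length
                self._sweep_exact(edges)
                new = self.loglik()
            if new - current < tol:
                current = max(new, current)
                converged = True
                break
            current = new
        if not converged:
            warnings.warn(
                f"branch-length optimization did not converge in {max_sweeps} sweeps",
                RuntimeWarning,
                stacklevel=2,
            )
        site = self.site_log_likelihoods()
        return LikelihoodResult(
            log_likelihood=float(site.sum()),
            site_log_likelihoods=site,
            tree=self.tree,
            model=self.model,
            converged=converged,
            n_sweeps=sweeps,
        )


def tree_loglik(tree: Phylogeny, alignment: dict[str, str], model: SubstitutionModel) -> LikelihoodResult:
    """Log-likelihood of *alignment* on *tree* with fixed branch lengths."""
    engine = TreeLikelihood(tree, alignment, model)
    site = engine.site_log_likelihoods()
    return LikelihoodResult(
        log_likelihood=float(site.sum()),
        site_log_likelihoods=site,
        tree=tree,
        model=model,
    )


def optimize_branch_lengths(
    tree: Phylogeny,
    alignment: dict[str, str],
    model: SubstitutionModel,
    tol: float = 1e-4,
    max_sweeps: int = 50,
) -> LikelihoodResult:
    """Maximize the likelihood over branch lengths (topology fixed).

    Operates on a copy; the optimized tree is in the result.
    """
    work = tree.copy()
    return TreeLikelihood(work, alignment, model).optimize(tol=tol, max_sweeps=max_sweeps)


def _optimize_alpha(tree, alignment, model, alpha0: float):
    """One round of gamma-shape optimization at fixed branch lengths."""
    def neg(log_a):
        m = model.with_gamma(float(np.exp(log_a)), model.n_categories)
        return -tree_loglik(tree, alignment, m).log_likelihood

    res = minimize_scalar(neg, bounds=(np.log(0.02), np.log(100.0)), method="bounded",
                          options={"xatol": 1e-3})
    return float(np.exp(res.x))


def select_model(
    alignment: dict[str, str],
    tree: Phylogeny,
    candidates: list[SubstitutionModel],
    tol: float = 1e-4,
    max_sweeps: int = 50,
    alpha_rounds: int = 2,
) -> tuple[SubstitutionModel, LikelihoodResult, list[dict]]:
    """BIC model choice over *candidates*; ties break by candidate order.

    BIC = -2 lnL + p ln(n_sites) with p = free branch lengths plus one
    for a gamma shape.  Gamma candidates alternate shape and
    branch-length optimization for *alpha_rounds* rounds.
    """
    if not candidates:
        raise ValueError("no candidate models")
    n_branches = sum(1 for n in tree.preorder() if n.parent is not None)
    table = []
    best = None
    for model in candidates:
        result = optimize_branch_lengths(tree, alignment, model, tol=tol, max_sweeps=max_sweeps)
        if model.gamma_shape is not None:
            for _ in range(alpha_rounds):
                alpha = _optimize_alpha(result.tree, alignment, model, model.gamma_shape)
                model = model.with_gamma(alpha, model.n_categories)
                result = optimize_branch_lengths(
                    result.tree, alignment, model, tol=tol, max_sweeps=max_sweeps
                )
        params = n_branches + model.n_rate_parameters
        bic = -2.0 * result.log_likelihood + params * np.log(len(next(iter(alignment.values()))))
        table.append({"model": model.name, "loglik": result.log_likelihood,
                      "params": params, "bic": bic})
        if best is None or bic < best[2] - 1e-9:
            best = (model, result, bic)
    return best[0], best[1], table
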