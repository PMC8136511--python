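"""Rooted/unrooted phylogeny container with Newick I/O.

Trees are stored rooted; an "unrooted" tree is represented with a
trifurcating root.  Internal Newick labels that parse as numbers are
interpreted as node supports (the common support-as-label dialect);
anything else is kept as a node name.
"""

from __future__ import annotations

import math
from typing import Iterator


class NewickError(ValueError):
    """Malformed Newick input; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.support: float | None = None
        self.children: list[Node] = []
        self.parent: Node | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.name or '(internal)'}>"


class Phylogeny:
    """A tree of :class:`Node` objects with unique leaf names."""

    def __init__(self, root: Node):
        self.root = root
        names = [lf.name for lf in self.leaves()]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate leaf names: {sorted(dup)}")

    # ---- traversal -------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    # ---- basic queries ---------------------------------------------
    def leafset(self, node: Node) -> frozenset[str]:
        return frozenset(
            lf.name for lf in self._subtree_leaves(node)
        )

    @staticmethod
    def _subtree_leaves(node: Node) -> list[Node]:
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            stack.extend(n.children)
        return out

    def find_clade(self, names: frozenset[str] | set[str]) -> Node | None:
        """Node whose descendant leaf set equals *names*, if any."""
        target = frozenset(names)
        for node in self.postorder():
            if self.leafset(node) == target:
                return node
        return None

    def mrca(self, names) -> Node:
        target = set(names)
        missing = target - set(self.leaf_names())
        if missing:
            raise ValueError(f"leaves not in tree: {sorted(missing)}")
        for node in self.postorder():
            if target <= self.leafset(node):
                return node
        return self.root

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial splits as the leaf set on the child side, normalized
        to the side not containing the alphabetically first leaf."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = self.leafset(node)
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits

    # ---- copies and edits ------------------------------------------
    def copy(self) -> "Phylogeny":
        def _copy(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.support = node.support
            for ch in node.children:
                new.add(_copy(ch))
            return new

        return Phylogeny(_copy(self.root))

    def prune_to(self, keep) -> "Phylogeny":
        """Restrict to the leaves in *keep*, suppressing unifurcations by
        summing branch lengths.  Returns a new tree."""
        keep = set(keep)
        present = keep & set(self.leaf_names())
        if not present:
            raise ValueError("no requested leaves present in tree")
        tree = self.copy()

        def _prune(node: Node) -> Node | None:
            if node.is_leaf:
                return node if node.name in present else None
            kept = [c for c in (_prune(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if node.length is not None:
                    child.length = (child.length or 0.0) + node.length
                return child
            node.children = kept
            for c in kept:
                c.parent = node
            return node

        new_root = _prune(tree.root)
        if new_root is None:  # pragma: no cover - guarded above
            raise ValueError("pruning removed the whole tree")
        new_root.parent = None
        # a root left with a single child is collapsed onto that child
        while len(new_root.children) == 1:
            new_root = new_root.children[0]
            new_root.parent = None
            new_root.length = None
        return Phylogeny(new_root)

    def unroot(self) -> "Phylogeny":
        """Collapse a bifurcating root into a trifurcation (new tree)."""
        tree = self.copy()
        root = tree.root
        if len(root.children) != 2:
            return tree
        a, b = root.children
        keeper, absorbed = (a, b) if not a.is_leaf else (b, a)
        if keeper.is_leaf:
            return tree  # two-leaf tree cannot be unrooted further
        absorbed.length = (absorbed.length or 0.0) + (keeper.length or 0.0)
        keeper.length = None
        keeper.parent = None
        keeper.add(absorbed)
        keeper.support = None
        return Phylogeny(keeper)

    def reroot_above(self, names) -> "Phylogeny":
        """Root on the edge above the MRCA of *names* (new tree).

        The edge is split at its midpoint.  Supports travel with their
        splits: the support stored on the child end of each re-oriented
        edge is moved to the node that subtends the same split after
        rerooting.
        """
        tree = self.copy()
        target = tree.mrca(names)
        if target is tree.root:
            return tree
        if target.parent is tree.root and len(tree.root.children) == 2:
            return tree  # already rooted on this edge
        path = []
        n = target.parent
        while n is not None:
            path.append(n)
            n = n.parent
        new_root = Node()
        half = (target.length or 0.0) / 2.0
        target.parent.children.remove(target)
        target.parent = None
        target.length = half
        new_root.add(target)
        attach = new_root
        prev_len: float | None = half
        prev_support = target.support  # other half of the same split
        for node in path:
            par = node.parent
            if par is not None:
                par.children.remove(node)
            node.parent = None
            up_len, up_support = node.length, node.support
            node.length = prev_len
            node.support = prev_support
            attach.add(node)
            prev_len, prev_support = up_len, up_support
            attach = node
        # a bifurcating old root is left with one child: splice it out
        old_root = attach
        if len(old_root.children) == 1:
            par = old_root.parent
            child = old_root.children[0]
            par.children.remove(old_root)
            child.parent = None
            child.length = (child.length or 0.0) + (old_root.length or 0.0)
            par.add(child)
        return Phylogeny(new_root)


# ---- Newick ---------------------------------------------------------

def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (single tree).  Numeric internal labels are
    stored as supports; other labels as names."""
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError("missing terminating ';'", len(s))
    s = s[:-1]
    pos = 0

    def error(msg: str):
        raise NewickError(msg, pos)

    def parse_label() -> str:
        nonlocal pos
        start = pos
        if pos < len(s) and s[pos] in "'\"":
            quote = s[pos]
            pos += 1
            while pos < len(s) and s[pos] != quote:
                pos += 1
            if pos >= len(s):
                error("unterminated quoted label")
            label = s[start + 1 : pos]
            pos += 1
            return label
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add(parse_node())
                if pos >= len(s):
                    error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                error(f"unexpected character {s[pos]!r}")
            label = parse_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            label = parse_label()
            if not label:
                error("empty leaf label")
            node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),;":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                error(f"bad branch length {s[start:pos]!r}")
            if not math.isfinite(node.length):
                error("non-finite branch length")
        return node

    root = parse_node()
    if pos != len(s):
        error("trailing characters after tree")
    return Phylogeny(root)


def write_newick(tree: Phylogeny, support_format: str = "g") -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf:
            out = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = format(node.support, support_format)
            elif node.name:
                label = node.name
            out = f"({inner}){label}"
        if node.length is not None:
            out += f":{node.length:.17g}"
        return out

    return fmt(tree.root) + ";"
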