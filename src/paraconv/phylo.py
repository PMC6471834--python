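"""Rooted phylogenies: Newick I/O, node labeling, and branch-pair enumeration.

A tree is stored as a flat table of named nodes.  A *branch* is the edge
above a non-root node and is identified by that node's name; its length is
measured in expected replacements per site.  Two branches form a
*comparable pair* when the replacements along them can have occurred
independently: the branches must not be siblings (sharing a parent node)
and must not lie on a single root-to-tip path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import dendropy

__all__ = [
    "Tree",
    "TreeNode",
    "Branch",
    "BranchPair",
    "NewickError",
    "parse_newick",
    "write_newick",
    "label_unnamed_internals",
    "is_ancestor",
    "comparable_pairs",
]


class NewickError(ValueError):
    """Raised for malformed or inconsistent Newick input."""


@dataclass(frozen=True)
class TreeNode:
    name: str
    parent: str | None
    children: tuple[str, ...]
    length: float | None  # None when the input gave no length


@dataclass(frozen=True)
class Branch:
    """The edge above ``child``; ``t`` is its length (0 when absent)."""

    child: str
    parent: str
    t: float


@dataclass(frozen=True, order=True)
class BranchPair:
    """Unordered branch pair stored canonically with ``first < second``."""

    first: str
    second: str

    def __post_init__(self) -> None:
        if not self.first < self.second:
            raise ValueError(f"pair not in canonical order: {self.first!r}, {self.second!r}")

    @classmethod
    def of(cls, a: str, b: str) -> "BranchPair":
        return cls(a, b) if a < b else cls(b, a)

    def __str__(self) -> str:
        return f"{self.first}-{self.second}"


@dataclass(frozen=True)
class Tree:
    """Rooted tree as an immutable name-indexed node table."""

    root: str
    nodes: dict[str, TreeNode] = field(compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            name = stack.pop()
            if name in seen:
                raise NewickError(f"cycle or repeated node {name!r}")
            seen.add(name)
            stack.extend(self.nodes[name].children)
        if seen != set(self.nodes):
            raise NewickError("disconnected nodes present")
        for node in self.nodes.values():
            if node.length is not None and node.length < 0:
                raise NewickError(f"negative branch length on {node.name!r}")

    # --- structure queries -------------------------------------------------

    def preorder(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            name = stack.pop()
            out.append(name)
            stack.extend(reversed(self.nodes[name].children))
        return out

    def tips(self) -> list[str]:
        return [n for n in self.preorder() if not self.nodes[n].children]

    def internals(self) -> list[str]:
        return [n for n in self.preorder() if self.nodes[n].children]

    def branches(self) -> list[Branch]:
        """One branch per non-root node, preorder; absent lengths read as 0."""
        out = []
        for name in self.preorder():
            node = self.nodes[name]
            if node.parent is not None:
                out.append(Branch(name, node.parent, node.length if node.length is not None else 0.0))
        return out

    def branch(self, child: str) -> Branch:
        node = self.nodes.get(child)
        if node is None:
            raise KeyError(f"unknown node {child!r}")
        if node.parent is None:
            raise KeyError(f"{child!r} is the root and has no branch")
        return Branch(child, node.parent, node.length if node.length is not None else 0.0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        if self.root != other.root or set(self.nodes) != set(other.nodes):
            return False
        for name, a in self.nodes.items():
            b = other.nodes[name]
            if a.parent != b.parent or a.children != b.children:
                return False
            if (a.length is None) != (b.length is None):
                return False
            if a.length is not None and abs(a.length - b.length) > 1e-8 * max(1.0, abs(a.length)):
                return False
        return True

    __hash__ = None  # type: ignore[assignment]


# --- Newick reading / writing -----------------------------------------------


def parse_newick(text: str) -> Tree:
    """Parse a single Newick statement into a :class:`Tree`.

    Names are taken verbatim (underscores preserved); a node without a
    ``:length`` suffix gets ``length=None``.  Unnamed nodes receive
    placeholder names only at :func:`label_unnamed_internals` time; here an
    unnamed internal is temporarily keyed by a reserved ``\x00<k>`` token so
    the structure survives until labeling.
    """
    if not text or not text.strip():
        raise NewickError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise NewickError(f"malformed Newick: {exc}") from exc

    nodes: dict[str, TreeNode] = {}
    counter = itertools.count(1)

    def name_of(dnode) -> str:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if label is None or label == "":
            label = f"\x00{next(counter)}"
            dnode.label = label
        return label

    def build(dnode, parent_name: str | None) -> str:
        name = name_of(dnode)
        if name in nodes:
            raise NewickError(f"duplicate node name {name!r}")
        nodes[name] = TreeNode(name, parent_name, (), dnode.edge.length)
        kids = tuple(build(ch, name) for ch in dnode.child_nodes())
        nodes[name] = replace(nodes[name], children=kids)
        return name

    root_name = build(dtree.seed_node, None)
    # the root edge length, if any, is ignored (a root has no branch)
    nodes[root_name] = replace(nodes[root_name], length=None)
    return Tree(root=root_name, nodes=nodes)


def _fmt_length(x: float) -> str:
    return format(x, ".9g")


def write_newick(tree: Tree) -> str:
    """Serialize, emitting children in stored order; lengths at 9 sig. digits."""

    def render(name: str) -> str:
        node = tree.nodes[name]
        label = "" if name.startswith("\x00") else name
        inner = ""
        if node.children:
            inner = "(" + ",".join(render(c) for c in node.children) + ")"
        suffix = "" if node.length is None or node.parent is None else f":{_fmt_length(node.length)}"
        return f"{inner}{label}{suffix}"

    return render(tree.root) + ";"


# --- labeling and ancestry ---------------------------------------------------


def label_unnamed_internals(tree: Tree) -> Tree:
    """Name every unnamed internal node ``N<k>``, k counted in preorder from 1.

    Names already present in the tree are skipped so no collision can occur;
    applying the function twice is a no-op.
    """
    taken = {n for n in tree.nodes if not n.startswith("\x00")}
    counter = itertools.count(1)

    def fresh() -> str:
        while True:
            cand = f"N{next(counter)}"
            if cand not in taken:
                taken.add(cand)
                return cand

    mapping: dict[str, str] = {}
    for name in tree.preorder():
        if name.startswith("\x00"):
            mapping[name] = fresh()

    if not mapping:
        return tree

    def rename(name: str) -> str:
        return mapping.get(name, name)

    nodes = {
        rename(n.name): TreeNode(
            rename(n.name),
            None if n.parent is None else rename(n.parent),
            tuple(rename(c) for c in n.children),
            n.length,
        )
        for n in tree.nodes.values()
    }
    return Tree(root=rename(tree.root), nodes=nodes)


def is_ancestor(tree: Tree, u: str, v: str) -> bool:
    """True iff ``u`` lies strictly on the path from the root to ``v``."""
    if u not in tree.nodes:
        raise KeyError(f"unknown node {u!r}")
    if v not in tree.nodes:
        raise KeyError(f"unknown node {v!r}")
    cur = tree.nodes[v].parent
    while cur is not None:
        if cur == u:
            return True
        cur = tree.nodes[cur].parent
    return False


def comparable_pairs(tree: Tree) -> set[BranchPair]:
    """All branch pairs on which independent replacements can be scored.

    A pair {b1, b2} of branches (non-root nodes) is comparable iff the two
    branches are not siblings and neither branch's child node is an ancestor
    of the other's — i.e. the branches neither share a parent node nor an
    evolutionary path.  Works for multifurcating trees; edges hanging off
    the root are ordinary branches.
    """
    names = [n for n in tree.preorder() if tree.nodes[n].parent is not None]
    out: set[BranchPair] = set()
    for a, b in itertools.combinations(names, 2):
        if tree.nodes[a].parent == tree.nodes[b].parent:
            continue
        if is_ancestor(tree, a, b) or is_ancestor(tree, b, a):
            continue
        out.add(BranchPair.of(a, b))
    return out
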