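"""Gene trees with dual (bootstrap / posterior) edge supports.

Newick dialect: internal-node labels are either empty, a single number, or
``M/B`` where ``M`` is a maximum-likelihood bootstrap percentage in [0, 100]
and ``B`` is a Bayesian posterior probability in [0, 1].  A lone number is
read as a bootstrap percentage when it exceeds 1, otherwise as a posterior
(overridable via ``label_as``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

__all__ = [
    "SupportPair",
    "Node",
    "GeneTree",
    "NewickError",
    "parse_newick",
    "write_newick",
]


@dataclass(frozen=True)
class SupportPair:
    """Support on an internal edge; either component may be absent."""

    mlbp: Optional[float] = None
    bpp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mlbp is not None and not (0.0 <= self.mlbp <= 100.0):
            raise ValueError(f"mlbp out of range [0, 100]: {self.mlbp}")
        if self.bpp is not None and not (0.0 <= self.bpp <= 1.0):
            raise ValueError(f"bpp out of range [0, 1]: {self.bpp}")

    @property
    def is_absent(self) -> bool:
        return self.mlbp is None and self.bpp is None


class NewickError(ValueError):
    """Malformed newick input; ``offset`` is the character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class Node:
    """Tree node; ``support`` and ``length`` describe the edge above it."""

    __slots__ = ("name", "length", "support", "children")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[SupportPair] = None,
        children: Optional[list["Node"]] = None,
    ):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_nodes(self) -> Iterator["Node"]:
        """Preorder traversal of this subtree."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tip_names(self) -> list[str]:
        return [n.name for n in self.iter_nodes() if n.is_leaf]

    def copy(self) -> "Node":
        clone = Node(self.name, self.length, self.support)
        clone.children = [c.copy() for c in self.children]
        return clone


class GeneTree:
    """A (possibly unrooted) tip-labeled tree with per-edge supports."""

    def __init__(self, root: Node):
        self.root = root
        names = root.tip_names()
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate tip names: {sorted(dup)}")

    # -- basic queries ----------------------------------------------------

    def tips(self) -> list[str]:
        return self.root.tip_names()

    def iter_nodes(self) -> Iterator[Node]:
        return self.root.iter_nodes()

    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy())

    def parents(self) -> dict[Node, Node]:
        out: dict[Node, Node] = {}
        for node in self.iter_nodes():
            for child in node.children:
                out[child] = node
        return out

    def find_tip(self, name: str) -> Node:
        for node in self.iter_nodes():
            if node.is_leaf and node.name == name:
                return node
        raise KeyError(f"tip {name!r} not in tree")

    def clades(self) -> dict[Node, frozenset[str]]:
        """Tip set below every node (postorder aggregation)."""
        out: dict[Node, frozenset[str]] = {}

        def visit(node: Node) -> frozenset[str]:
            if node.is_leaf:
                s = frozenset([node.name])
            else:
                s = frozenset().union(*(visit(c) for c in node.children))
            out[node] = s
            return s

        visit(self.root)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Canonical unrooted splits: each internal edge as the tip side not
        containing the lexicographically smallest tip."""
        all_tips = frozenset(self.tips())
        anchor = min(all_tips)
        splits: set[frozenset[str]] = set()
        for node, below in self.clades().items():
            if node is self.root or node.is_leaf:
                continue
            side = all_tips - below if anchor in below else below
            if 0 < len(side) < len(all_tips) - 1:
                splits.add(side)
        return splits

    # -- rerooting --------------------------------------------------------

    def rerooted_above(self, target: Node) -> "GeneTree":
        """Return a copy rooted on the edge above ``target``: the new root has
        two children, the ``target`` subtree and everything else.

        The rerooted copy preserves each edge's support; the edge being split
        contributes half its length to each root child and its support to both
        (both root children describe the same bipartition).
        """
        if target is self.root:
            return self.copy()
        parents = self.parents()
        path = [target]
        while path[-1] is not self.root:
            path.append(parents[path[-1]])
        # Work on a copy: map path nodes via preorder positions.
        index = {id(n): i for i, n in enumerate(self.iter_nodes())}
        copy_nodes = list(self.copy().iter_nodes())
        cpath = [copy_nodes[index[id(n)]] for n in path]

        ctarget = cpath[0]
        half = None if ctarget.length is None else ctarget.length / 2.0
        sup = ctarget.support

        if len(cpath) == 2:  # target hangs directly off the root
            old_root = cpath[1]
            if len(old_root.children) == 2:
                # already rooted on this edge; just put the target first
                old_root.children.sort(key=lambda c: c is not ctarget)
                return GeneTree(old_root)
            old_root.children.remove(ctarget)
            other = Node(support=sup, length=half, children=old_root.children)
            ctarget.length = half
            return GeneTree(Node(children=[ctarget, other]))

        # Reverse parent pointers along the path above the target.
        for i in range(1, len(cpath)):
            cpath[i].children.remove(cpath[i - 1])
        for i in range(1, len(cpath) - 1):
            # edge (cpath[i], cpath[i+1]) flips direction
            cpath[i].children.append(cpath[i + 1])
        # edge attributes stay with whichever node is now the lower one
        for i in range(len(cpath) - 1, 1, -1):
            cpath[i].length = cpath[i - 1].length
            cpath[i].support = cpath[i - 1].support
        old_root = cpath[-1]
        if len(old_root.children) == 1:
            # old (binary) root became degree-2 after reversal: splice it out
            grand = cpath[-2]
            orphan = old_root.children[0]
            if orphan.length is not None and old_root.length is not None:
                orphan.length += old_root.length
            elif old_root.length is not None:
                orphan.length = old_root.length
            if orphan.support is None or orphan.support.is_absent:
                orphan.support = old_root.support
            grand.children.remove(old_root)
            grand.children.append(orphan)

        other = cpath[1]
        other.length = half
        other.support = sup
        ctarget.length = half
        ctarget.support = sup
        new_root = Node(children=[ctarget, other])
        return GeneTree(new_root)


# ---------------------------------------------------------------------------
# newick reading / writing
# ---------------------------------------------------------------------------

_LABEL_MODES = ("auto", "mlbp", "bpp")


def _parse_support_label(label: str, offset: int, label_as: str) -> SupportPair:
    if label == "":
        return SupportPair()
    if "/" in label:
        parts = label.split("/")
        if len(parts) != 2:
            raise NewickError(f"bad support label {label!r}", offset)
        try:
            mlbp, bpp = float(parts[0]), float(parts[1])
        except ValueError:
            raise NewickError(f"non-numeric support label {label!r}", offset) from None
        try:
            return SupportPair(mlbp=mlbp, bpp=bpp)
        except ValueError as exc:
            raise NewickError(str(exc), offset) from None
    try:
        value = float(label)
    except ValueError:
        raise NewickError(f"non-numeric support label {label!r}", offset) from None
    if label_as == "mlbp" or (label_as == "auto" and value > 1.0):
        kind = "mlbp"
    else:
        kind = "bpp"
    try:
        return SupportPair(**{kind: value})
    except ValueError as exc:
        raise NewickError(str(exc), offset) from None


def parse_newick(text: str, label_as: str = "auto") -> GeneTree:
    """Parse a newick string into a :class:`GeneTree`.

    ``label_as`` controls how a single-number internal label is read:
    ``auto`` (>1 means MLBP, else BPP), ``mlbp``, or ``bpp``.
    """
    if label_as not in _LABEL_MODES:
        raise ValueError(f"label_as must be one of {_LABEL_MODES}")
    s = text.strip()
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(msg, pos)

    def peek() -> str:
        return s[pos] if pos < len(s) else ""

    def read_token(stop: str) -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in stop:
            pos += 1
        return s[start:pos].strip()

    def read_length() -> Optional[float]:
        nonlocal pos
        if peek() != ":":
            return None
        pos += 1
        tok = read_token(",():;")
        try:
            length = float(tok)
        except ValueError:
            raise error(f"non-numeric branch length {tok!r}") from None
        if length < 0:
            raise error(f"negative branch length {length}")
        return length

    def read_clade() -> Node:
        nonlocal pos
        if peek() == "(":
            open_at = pos
            pos += 1
            children = [read_clade()]
            while peek() == ",":
                pos += 1
                children.append(read_clade())
            if peek() != ")":
                raise NewickError("unmatched '('", open_at)
            pos += 1
            label_at = pos
            label = read_token(",():;")
            support = _parse_support_label(label, label_at, label_as)
            length = read_length()
            return Node(length=length, support=support, children=children)
        name = read_token(",():;")
        if not name:
            raise error("empty tip name")
        length = read_length()
        return Node(name=name, length=length)

    root = read_clade()
    if peek() != ";":
        raise error("expected ';' at end of tree")
    pos += 1
    if s[pos:].strip():
        raise error("trailing characters after ';'")
    # the root carries no subtending edge
    root.support = None
    root.length = None
    return GeneTree(root)


def _fmt(x: float) -> str:
    return format(x, "g")


def _support_label(sup: Optional[SupportPair]) -> str:
    if sup is None or sup.is_absent:
        return ""
    if sup.mlbp is not None and sup.bpp is not None:
        return f"{_fmt(sup.mlbp)}/{_fmt(sup.bpp)}"
    if sup.mlbp is not None:
        return _fmt(sup.mlbp)
    return _fmt(sup.bpp)


def write_newick(tree: GeneTree) -> str:
    """Serialize in the same dialect :func:`parse_newick` reads."""

    def render(node: Node, is_root: bool) -> str:
        if node.is_leaf:
            out = node.name
        else:
            inner = ",".join(render(c, False) for c in node.children)
            out = f"({inner})"
            if not is_root:
                out += _support_label(node.support)
        if not is_root and node.length is not None:
            out += f":{_fmt(node.length)}"
        return out

    return render(tree.root, True) + ";"
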