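"""Rooted phylogenetic tree container and Newick serialization.

The tree model is intentionally minimal: ordered children, optional labels,
and branch lengths in arbitrary units.  Child order is significant — the
layout engine assigns vertical positions in child order — and is preserved
exactly through a parse/write round trip.

Newick dialect notes:

* underscores in unquoted labels are kept verbatim (no space conversion);
* single-quoted labels are supported, with ``''`` as the escaped quote;
* missing branch lengths default to 1.0 so cladograms remain drawable
  (``strict=True`` rejects them instead);
* multifurcations are accepted and preserved.
"""

from __future__ import annotations

from typing import Iterator, Optional

__all__ = [
    "PhyloNode",
    "PhyloTree",
    "NewickError",
    "parse_newick",
    "write_newick",
    "read_newick",
    "postorder",
]

#: characters that force a label to be quoted on output
_NEEDS_QUOTE = set("()[]{}:;,'\" \t\n")


class NewickError(ValueError):
    """Malformed Newick input; ``offset`` is the 0-based character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class PhyloNode:
    """A node of a rooted tree.

    Parameters
    ----------
    label:
        Node name; empty string means unlabeled.
    branch_length:
        Length of the edge to the parent, ``None`` for the root (treated
        as 0 wherever a number is needed).  Must be >= 0.
    """

    __slots__ = ("label", "branch_length", "children", "parent")

    def __init__(
        self,
        label: str = "",
        branch_length: Optional[float] = None,
        children: Optional[list["PhyloNode"]] = None,
    ):
        self.label = label
        self.branch_length = branch_length
        self.children: list[PhyloNode] = []
        self.parent: Optional[PhyloNode] = None
        for child in children or ():
            self.add_child(child)

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def length(self) -> float:
        """Branch length with the root's ``None`` mapped to 0."""
        return 0.0 if self.branch_length is None else self.branch_length

    def add_child(self, child: "PhyloNode") -> "PhyloNode":
        child.parent = self
        self.children.append(child)
        return child

    def iter_postorder(self) -> Iterator["PhyloNode"]:
        for child in self.children:
            yield from child.iter_postorder()
        yield self

    def iter_preorder(self) -> Iterator["PhyloNode"]:
        yield self
        for child in self.children:
            yield from child.iter_preorder()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal[{len(self.children)}]"
        return f"<PhyloNode {self.label!r} {kind} bl={self.branch_length}>"


class PhyloTree:
    """A rooted tree: a root node plus convenience accessors."""

    def __init__(self, root: PhyloNode):
        self.root = root

    @property
    def node_count(self) -> int:
        return sum(1 for _ in self.root.iter_postorder())

    @property
    def tip_count(self) -> int:
        return sum(1 for n in self.root.iter_postorder() if n.is_tip)

    def tips(self) -> list[PhyloNode]:
        """Tips in traversal (drawing) order."""
        return [n for n in self.root.iter_preorder() if n.is_tip]

    def postorder(self) -> list[PhyloNode]:
        return list(self.root.iter_postorder())

    def preorder(self) -> list[PhyloNode]:
        return list(self.root.iter_preorder())

    def newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PhyloTree tips={self.tip_count} nodes={self.node_count}>"


def postorder(tree: PhyloTree) -> list[PhyloNode]:
    """All nodes, every node after all of its descendants, root last."""
    return tree.postorder()


# ---------------------------------------------------------------------------
# Newick parsing


class _Parser:
    def __init__(self, text: str, strict: bool):
        self.text = text
        self.pos = 0
        self.strict = strict

    def error(self, message: str, offset: Optional[int] = None) -> NewickError:
        return NewickError(message, self.pos if offset is None else offset)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos] in " \t\r\n":
            self.pos += 1

    def parse(self) -> PhyloNode:
        self.skip_ws()
        if self.pos >= len(self.text):
            raise self.error("empty Newick string")
        root = self.parse_subtree(is_root=True)
        self.skip_ws()
        if self.peek() != ";":
            raise self.error("unterminated Newick string: expected ';'")
        self.pos += 1
        self.skip_ws()
        if self.pos < len(self.text):
            raise self.error("trailing characters after ';'")
        return root

    def parse_subtree(self, is_root: bool = False) -> PhyloNode:
        self.skip_ws()
        node = PhyloNode()
        if self.peek() == "(":
            open_at = self.pos
            self.pos += 1
            while True:
                node.add_child(self.parse_subtree())
                self.skip_ws()
                ch = self.peek()
                if ch == ",":
                    self.pos += 1
                    continue
                if ch == ")":
                    self.pos += 1
                    break
                raise self.error(
                    "malformed parentheses: '(' never closed", open_at
                )
        node.label = self.parse_label()
        node.branch_length = self.parse_branch_length(is_root)
        return node

    def parse_label(self) -> str:
        self.skip_ws()
        if self.peek() == "'":
            start = self.pos
            self.pos += 1
            out = []
            while True:
                if self.pos >= len(self.text):
                    raise self.error("unterminated quoted label", start)
                ch = self.text[self.pos]
                if ch == "'":
                    if self.pos + 1 < len(self.text) and self.text[self.pos + 1] == "'":
                        out.append("'")
                        self.pos += 2
                        continue
                    self.pos += 1
                    break
                out.append(ch)
                self.pos += 1
            return "".join(out)
        out = []
        while self.pos < len(self.text):
            ch = self.text[self.pos]
            if ch in "():;,[]" or ch in " \t\r\n":
                break
            out.append(ch)
            self.pos += 1
        return "".join(out)

    def parse_branch_length(self, is_root: bool) -> Optional[float]:
        self.skip_ws()
        if self.peek() != ":":
            if is_root:
                return None
            if self.strict:
                raise self.error("missing branch length in strict mode")
            return 1.0
        self.pos += 1
        self.skip_ws()
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] in "+-0123456789.eE":
            self.pos += 1
        token = self.text[start:self.pos]
        try:
            value = float(token)
        except ValueError:
            raise self.error("invalid branch length", start) from None
        if value < 0:
            raise self.error("negative branch length", start)
        return value


def parse_newick(text: str, strict: bool = False) -> PhyloTree:
    """Parse a single rooted tree from a Newick string.

    Parameters
    ----------
    text:
        Newick string terminated by ``;``.
    strict:
        Reject missing branch lengths instead of defaulting them to 1.0.

    Raises
    ------
    NewickError
        On malformed input; the message names the 0-based character offset.
    """
    return PhyloTree(_Parser(text, strict).parse())


def _format_label(label: str) -> str:
    if not label:
        return ""
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_node(node: PhyloNode, out: list[str]) -> None:
    if node.children:
        out.append("(")
        for i, child in enumerate(node.children):
            if i:
                out.append(",")
            _format_node(child, out)
        out.append(")")
    out.append(_format_label(node.label))
    if node.branch_length is not None:
        # repr() of a float round-trips exactly, well inside 1e-12 relative
        out.append(":" + repr(node.branch_length))


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to Newick; lossless for labels and branch lengths."""
    out: list[str] = []
    _format_node(tree.root, out)
    out.append(";")
    return "".join(out)


def read_newick(path) -> list[PhyloTree]:
    """Read one or more ``;``-terminated trees from a UTF-8 Newick file."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    trees = []
    chunk: list[str] = []
    depth = 0
    in_quote = False
    for ch in text:
        chunk.append(ch)
        if ch == "'":
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            elif ch == ";" and depth == 0:
                trees.append(parse_newick("".join(chunk)))
                chunk = []
    if "".join(chunk).strip():
        raise NewickError("unterminated Newick string: expected ';'", len(text) - 1)
    return trees
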