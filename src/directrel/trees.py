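"""Penn-Treebank-style constituency trees.

Bracketed parses arrive in the sentence-analysis sidecar as plain strings
("(S (NP (DT The) (NN patient)) ...)").  This module parses them into
:class:`ConstituencyNode` objects with half-open token-index spans, writes
them back out, and converts them to head-percolated dependency triples.
"""

from __future__ import annotations

from typing import Iterator, Optional


class TreeParseError(ValueError):
    """Raised on malformed bracketed input; carries the character offset."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at offset {position})")
        self.position = position


class ConstituencyNode:
    """A constituent with a label, ordered children and a token span.

    ``start``/``end`` are half-open token indices over the sentence.
    Terminal nodes carry the surface token in ``token`` and span exactly
    one token.  ``parent`` is populated for every node below the root.
    """

    __slots__ = ("label", "children", "start", "end", "token", "parent")

    def __init__(
        self,
        label: str,
        children: Optional[list["ConstituencyNode"]] = None,
        token: Optional[str] = None,
    ):
        self.label = label
        self.children: list[ConstituencyNode] = children or []
        self.token = token
        self.start = 0
        self.end = 0
        self.parent: Optional[ConstituencyNode] = None

    @property
    def is_terminal(self) -> bool:
        return self.token is not None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def leaves(self) -> list["ConstituencyNode"]:
        if self.is_terminal:
            return [self]
        out: list[ConstituencyNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def tokens(self) -> list[str]:
        return [leaf.token for leaf in self.leaves()]  # type: ignore[misc]

    def iter_nodes(self) -> Iterator["ConstituencyNode"]:
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def covers(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def ancestors(self) -> Iterator["ConstituencyNode"]:
        node = self.parent
        while node is not None:
            yield node
            node = node.parent

    def is_ancestor_of(self, other: "ConstituencyNode") -> bool:
        return any(a is self for a in other.ancestors())

    def smallest_covering(self, start: int, end: int) -> "ConstituencyNode":
        """Smallest descendant (or self) whose span covers [start, end)."""
        node = self
        while True:
            narrower = None
            for child in node.children:
                if child.covers(start, end):
                    narrower = child
                    break
            if narrower is None or narrower.is_terminal and not (
                narrower.start <= start and end <= narrower.end
            ):
                return node
            if narrower is node:
                return node
            node = narrower
            if node.is_terminal:
                return node

    def exact_node(self, start: int, end: int) -> Optional["ConstituencyNode"]:
        """A descendant (or self) whose span equals [start, end), if any."""
        for node in self.iter_nodes():
            if node.start == start and node.end == end:
                return node
        return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{self.label} {self.start}:{self.end} {' '.join(self.tokens())!r}>"


def _finalize(root: ConstituencyNode) -> ConstituencyNode:
    index = 0

    def assign(node: ConstituencyNode) -> None:
        nonlocal index
        if node.is_terminal:
            node.start = index
            node.end = index + 1
            index += 1
            return
        node.start = index
        for child in node.children:
            child.parent = node
            assign(child)
        node.end = index

    assign(root)
    return root


def parse_bracketed_tree(text: str) -> ConstituencyNode:
    """Parse a PTB-style bracketed string into a tree.

    Terminals are ``(POS token)``; a bare token inside a multi-element
    constituent is wrapped as a terminal with label ``XX``.  Unbalanced
    brackets raise :class:`TreeParseError` with the character offset.
    """
    pos = 0
    n = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def read_atom() -> str:
        nonlocal pos
        begin = pos
        while pos < n and not text[pos].isspace() and text[pos] not in "()":
            pos += 1
        return text[begin:pos]

    def read_node() -> ConstituencyNode:
        nonlocal pos
        skip_ws()
        if pos >= n or text[pos] != "(":
            raise TreeParseError("expected '('", pos)
        open_at = pos
        pos += 1
        skip_ws()
        label = read_atom()
        if not label and (pos >= n or text[pos] not in "("):
            raise TreeParseError("constituent label missing", pos)
        label = label or "TOP"  # PTB empty-label root convention
        elements: list[ConstituencyNode | str] = []
        while True:
            skip_ws()
            if pos >= n:
                raise TreeParseError("unbalanced brackets", max(open_at, pos - 1))
            if text[pos] == ")":
                pos += 1
                break
            if text[pos] == "(":
                elements.append(read_node())
            else:
                elements.append(read_atom())
        if len(elements) == 1 and isinstance(elements[0], str):
            return ConstituencyNode(label, token=elements[0])
        children: list[ConstituencyNode] = []
        for element in elements:
            if isinstance(element, str):
                children.append(ConstituencyNode("XX", token=element))
            else:
                children.append(element)
        if not children:
            raise TreeParseError("empty constituent", open_at)
        return ConstituencyNode(label, children=children)

    root = read_node()
    skip_ws()
    if pos != n:
        raise TreeParseError("trailing material after tree", pos)
    return _finalize(root)


def format_bracketed_tree(node: ConstituencyNode) -> str:
    """Write a tree back to single-line bracketed notation."""
    if node.is_terminal:
        return f"({node.label} {node.token})"
    inner = " ".join(format_bracketed_tree(c) for c in node.children)
    return f"({node.label} {inner})"
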