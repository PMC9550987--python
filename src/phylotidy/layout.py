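"""Rectangular phylogram and non-layered tidy tree layouts.

The classical rectangular phylogram places tips at equal vertical spacing
and every internal node midway between its first and last child; the
horizontal coordinate of every node is its cumulative branch length from
the root.  When the tree is not ultrametric this leaves large empty areas.

The tidy layout removes that slack.  Every subtree is bounded by an
"envelop" of axis-parallel segments; its topmost pieces form the subtree's
*top contour* and its bottommost pieces the *bottom contour*, both
piecewise-constant step functions of x.  Visiting nodes children-before-
parent, each child subtree after the first is rigidly translated
vertically until the minimum distance between the facing contours (the
top contour of the block of already-placed siblings and the bottom
contour of the moving child) equals a fixed separation ``d``; the parent
is then re-centered on its children.  Tip label widths are absorbed into
the terminal branches before compression, so labels can never overlap
other branches.

Geometry conventions (matching the field's reference implementation of
this layout):

* a horizontal segment from x1 to x2 covers the half-open interval
  (x1, x2] — two branches meeting end-to-start at a single x do not
  constrain each other;
* the minimum distance between two facing contours is found by a merge
  scan over their pieces, advancing whichever piece ends first;
* x grows root-to-tips in branch-length units; y grows in tip-spacing
  units from the first tip towards later tips (a renderer may flip it);
* x coordinates are identical in the classical and tidy layouts; the
  tidy pass only translates subtrees vertically.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional

from .tree import PhyloNode, PhyloTree

__all__ = [
    "TidyConfig",
    "LayoutCoordinates",
    "Segment",
    "Contour",
    "classical_phylogram",
    "subtree_segments",
    "top_contour",
    "bottom_contour",
    "contour_gap",
    "merge_contour",
    "tidy_layout",
    "coords_to_table",
]

#: absolute tolerance for gap equalities, in y (tip-spacing) units
GAP_TOL = 1e-9


@dataclass
class TidyConfig:
    """Parameters of the tidy layout.

    Attributes
    ----------
    d:
        Minimum vertical separation enforced between the facing contours
        of adjacent sibling subtrees, in tip-spacing units.  With
        ``d == tip_spacing`` (the default) the minimum distance between
        contemporaneous branches is the same in the classical and tidy
        layouts, so tidying can only shrink the drawing.
    tip_spacing:
        Vertical distance between consecutive tips in the classical
        layout.
    label_widths:
        Tip label -> width in branch-length units; the width is added to
        the tip's terminal branch before compression.  Tips absent from
        the mapping get width 0.
    label_height:
        Optional label box height in tip-spacing units (0, the default,
        disables the box; labels then only widen the terminal branch).
    """

    d: float = 1.0
    tip_spacing: float = 1.0
    label_widths: Mapping[str, float] = field(default_factory=dict)
    label_height: float = 0.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("separation d must be positive")
        if self.tip_spacing <= 0:
            raise ValueError("tip_spacing must be positive")
        if self.label_height < 0:
            raise ValueError("label_height must be >= 0")
        for key, width in self.label_widths.items():
            if width < 0:
                raise ValueError(f"negative label width for tip {key!r}")

    def label_width(self, node: PhyloNode) -> float:
        if node.is_tip and node.label:
            return float(self.label_widths.get(node.label, 0.0))
        return 0.0


class LayoutCoordinates:
    """Per-node (x, y) assignment, keyed by node identity."""

    def __init__(self, x: dict[PhyloNode, float], y: dict[PhyloNode, float]):
        self.x = x
        self.y = y

    def copy(self) -> "LayoutCoordinates":
        return LayoutCoordinates(dict(self.x), dict(self.y))


@dataclass(frozen=True)
class Segment:
    """Axis-parallel drawing primitive.

    ``level`` is y for a horizontal segment and x for a vertical one;
    ``span`` is the (x-)interval covered by a horizontal segment or the
    (y-)interval of a vertical connector.  A degenerate (point) span is
    allowed (zero-length branches).
    """

    orientation: Literal["h", "v"]
    level: float
    span: tuple[float, float]
    owner: PhyloNode

    def __post_init__(self) -> None:
        if self.span[0] > self.span[1]:
            raise ValueError("segment span lower bound exceeds upper bound")


def classical_phylogram(tree: PhyloTree, config: Optional[TidyConfig] = None) -> LayoutCoordinates:
    """Classical rectangular phylogram coordinates.

    Tips get y = 0, tip_spacing, 2*tip_spacing, ... in traversal order;
    each internal node sits midway between its first and last child;
    x is the cumulative branch length from the root (root at x = 0).
    """
    config = config or TidyConfig()
    x: dict[PhyloNode, float] = {}
    y: dict[PhyloNode, float] = {}
    for node in tree.preorder():
        x[node] = 0.0 if node.parent is None else x[node.parent] + node.length
    next_tip = 0
    for node in tree.postorder():
        if node.is_tip:
            y[node] = next_tip * config.tip_spacing
            next_tip += 1
        else:
            y[node] = 0.5 * (y[node.children[0]] + y[node.children[-1]])
    return LayoutCoordinates(x, y)


def _attachment_x(node: PhyloNode, coords: LayoutCoordinates) -> float:
    """x where the node's branch leaves its parent (its own x for the root)."""
    if node.parent is None:
        return coords.x[node]
    return coords.x[node.parent]


def _node_segments(
    node: PhyloNode, coords: LayoutCoordinates, config: TidyConfig
) -> list[Segment]:
    """Segments owned by a single node: its branch, connector, label box."""
    segs: list[Segment] = []
    x0 = _attachment_x(node, coords)
    x1 = coords.x[node] + config.label_width(node)
    yv = coords.y[node]
    segs.append(Segment("h", yv, (x0, x1), node))
    if node.children:
        child_ys = [coords.y[c] for c in node.children]
        segs.append(
            Segment("v", coords.x[node], (min(child_ys), max(child_ys)), node)
        )
    elif config.label_height > 0 and config.label_width(node) > 0:
        half = 0.5 * config.label_height
        lab = (coords.x[node], x1)
        segs.append(Segment("h", yv - half, lab, node))
        segs.append(Segment("h", yv + half, lab, node))
    return segs


def subtree_segments(
    node: PhyloNode, coords: LayoutCoordinates, config: Optional[TidyConfig] = None
) -> list[Segment]:
    """All segments of the subtree rooted at ``node``, stem included.

    For every node v in the subtree: one horizontal segment at y(v) from
    v's attachment x to x(v) (extended by the label width for tips), and
    one vertical connector at x(v) spanning its children's y for internal
    nodes.  The subtree root's stem starts at its attachment in the full
    tree, so sibling subtrees always share their parent's x.
    """
    config = config or TidyConfig()
    segs: list[Segment] = []
    for v in node.iter_preorder():
        segs.extend(_node_segments(v, coords, config))
    return segs


# ---------------------------------------------------------------------------
# Contours


class Contour:
    """Piecewise-constant upper or lower envelope of a set of segments.

    Stored as contiguous ``pieces`` — triples ``(x1, x2, value)`` with
    each piece covering the half-open interval (x1, x2] — whose
    breakpoints are the distinct segment endpoints.  A piece value of
    ``None`` marks a hole (only possible after merging contours with
    disjoint domains); a degenerate piece (x1 == x2) carries an isolated
    point contribution, e.g. from a zero-length branch.
    """

    __slots__ = ("side", "pieces")

    def __init__(
        self,
        side: Literal["top", "bottom"],
        pieces: list[tuple[float, float, Optional[float]]],
    ):
        if not pieces:
            raise ValueError("contour requires at least one piece")
        for (a, b, _), (c, _, _) in zip(pieces, pieces[1:]):
            if b != c or a > b:
                raise ValueError("contour pieces must be contiguous and ordered")
        self.side = side
        self.pieces = pieces

    # -- construction -------------------------------------------------------

    @classmethod
    def from_segments(
        cls, segments: Iterable[Segment], side: Literal["top", "bottom"]
    ) -> "Contour":
        """Envelope of a segment set.

        Horizontal segments cover (x1, x2]; vertical segments contribute
        the extreme of their y-interval at their single x, retained as a
        degenerate piece only where it sticks out of (or falls outside)
        the horizontal coverage.
        """
        segments = list(segments)
        if not segments:
            raise ValueError("cannot build a contour from an empty segment set")
        pick = max if side == "top" else min
        intervals: list[tuple[float, float, float]] = []
        points: list[tuple[float, float]] = []
        for s in segments:
            if s.orientation == "h":
                if s.span[0] == s.span[1]:
                    points.append((s.span[0], s.level))
                else:
                    intervals.append((s.span[0], s.span[1], s.level))
            else:
                points.append((s.level, pick(s.span)))
        return cls(side, _build_pieces(intervals, points, side))

    # -- queries -------------------------------------------------------------

    @property
    def x_min(self) -> float:
        return self.pieces[0][0]

    @property
    def x_max(self) -> float:
        return self.pieces[-1][1]

    @property
    def breakpoints(self) -> list[float]:
        bps = [self.pieces[0][0]]
        for _, b, _ in self.pieces:
            if b != bps[-1]:
                bps.append(b)
        return bps

    @property
    def values(self) -> list[Optional[float]]:
        return [v for a, b, v in self.pieces if a != b]

    def value_at(self, x: float) -> Optional[float]:
        """Envelope value at x; None outside the domain or inside a hole.

        The domain's left edge takes the first piece's value; elsewhere a
        piece covers (x1, x2], and a degenerate piece covers its point.
        """
        if x < self.x_min or x > self.x_max:
            return None
        if x == self.x_min:
            return self.pieces[0][2]
        starts = [p[0] for p in self.pieces]
        i = bisect.bisect_left(starts, x)
        # pieces[i-1] has x1 < x; among pieces starting at x, a degenerate
        # one covers the point itself
        for j in range(i, len(self.pieces)):
            a, b, v = self.pieces[j]
            if a != x:
                break
            if a == b:
                return v
        return self.pieces[i - 1][2]

    def translate(self, dy: float) -> "Contour":
        if dy == 0:
            return self
        return Contour(
            self.side,
            [(a, b, None if v is None else v + dy) for a, b, v in self.pieces],
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<Contour {self.side} [{self.x_min}, {self.x_max}] "
            f"pieces={len(self.pieces)}>"
        )


def _build_pieces(
    intervals: list[tuple[float, float, float]],
    points: list[tuple[float, float]],
    side: Literal["top", "bottom"],
) -> list[tuple[float, float, Optional[float]]]:
    """Assemble contour pieces from interval and point contributions."""
    pick = max if side == "top" else min
    bps = sorted(
        {x for a, b, _ in intervals for x in (a, b)} | {p for p, _ in points}
    )
    pieces: list[tuple[float, float, Optional[float]]] = []
    for a, b in zip(bps, bps[1:]):
        covering = [y for x1, x2, y in intervals if x1 <= a and x2 >= b]
        pieces.append((a, b, pick(covering) if covering else None))
    # collapse point contributions per x, keep only those sticking out of
    # the interval coverage around them
    by_x: dict[float, float] = {}
    for p, v in points:
        by_x[p] = pick(by_x[p], v) if p in by_x else v
    for p in sorted(by_x):
        v = by_x[p]
        neighbours = [
            pv
            for a, b, pv in pieces
            if pv is not None and (b == p or a == p) and a != b
        ]
        if neighbours and (v <= max(neighbours) if side == "top" else v >= min(neighbours)):
            continue
        idx = bisect.bisect_left([q[0] for q in pieces], p)
        pieces.insert(idx, (p, p, v))
    return _coalesce(pieces)


def _coalesce(
    pieces: list[tuple[float, float, Optional[float]]]
) -> list[tuple[float, float, Optional[float]]]:
    """Fuse consecutive non-degenerate pieces with equal values."""
    out: list[tuple[float, float, Optional[float]]] = []
    for a, b, v in pieces:
        if out:
            pa, pb, pv = out[-1]
            if pv == v and pa != pb and a != b:
                out[-1] = (pa, b, v)
                continue
        out.append((a, b, v))
    return out


def top_contour(segments: Iterable[Segment]) -> Contour:
    """Topmost envelope (maximum y covering each x) of a segment set."""
    return Contour.from_segments(segments, "top")


def bottom_contour(segments: Iterable[Segment]) -> Contour:
    """Bottommost envelope (minimum y covering each x) of a segment set."""
    return Contour.from_segments(segments, "bottom")


def merge_contour(accumulated: Contour, placed: Contour) -> Contour:
    """Pointwise max (top) or min (bottom) of two same-side contours.

    Domains may overlap, touch, or be disjoint; a gap between disjoint
    domains is kept as a hole (piece value None).
    """
    if accumulated.side != placed.side:
        raise ValueError("cannot merge contours of different sides")
    side = accumulated.side
    intervals: list[tuple[float, float, float]] = []
    points: list[tuple[float, float]] = []
    for contour in (accumulated, placed):
        for a, b, v in contour.pieces:
            if v is None:
                continue
            if a == b:
                points.append((a, v))
            else:
                intervals.append((a, b, v))
    return Contour(side, _build_pieces(intervals, points, side))


def contour_gap(lower_top: Contour, upper_bottom: Contour) -> Optional[float]:
    """Minimum of upper_bottom(x) - lower_top(x) over the shared x-domain.

    Computed by the reference merge scan over contour pieces: the current
    pair of pieces is compared, then whichever ends first is advanced.
    Returns None when the x-domains do not intersect (cannot happen for
    sibling subtrees, whose stems share the parent's x).
    """
    lo = max(lower_top.x_min, upper_bottom.x_min)
    hi = min(lower_top.x_max, upper_bottom.x_max)
    if lo > hi:
        return None
    tp = lower_top.pieces
    bp = upper_bottom.pieces
    i = j = 0
    while i < len(tp) and tp[i][1] < lo:
        i += 1
    while j < len(bp) and bp[j][1] < lo:
        j += 1
    best: Optional[float] = None
    while i < len(tp) and j < len(bp):
        tv = tp[i][2]
        bv = bp[j][2]
        if tv is not None and bv is not None:
            gap = bv - tv
            if best is None or gap < best:
                best = gap
        if bp[j][1] < tp[i][1]:
            j += 1
        else:
            i += 1
    return best


# ---------------------------------------------------------------------------
# Layouts


def _translate_subtree(node: PhyloNode, coords: LayoutCoordinates, dy: float) -> None:
    for v in node.iter_preorder():
        coords.y[v] += dy


def tidy_layout(
    tree: PhyloTree,
    config: Optional[TidyConfig] = None,
    start: Optional[LayoutCoordinates] = None,
) -> LayoutCoordinates:
    """Compressed (tidy) coordinates for a rooted tree.

    Starting from the classical phylogram, nodes are visited children-
    before-parent (equivalent to the decreasing-x sweep when branch
    lengths are positive, and well defined under x ties).  At each
    internal node the first child subtree stays fixed; every subsequent
    child, in y order, is rigidly translated so that the minimum distance
    between the top contour of the accumulated block of placed siblings
    and the moving child's bottom contour equals ``config.d`` exactly
    (children too far are moved closer, children too close are moved
    apart).  The node is then centered midway between its first and last
    child.  x coordinates are never modified.

    Per-subtree contours are maintained incrementally: placing a child
    translates its stored contours rigidly, and the block contours are
    the running merge of the placed children's contours plus the node's
    own branch.

    ``start`` supplies alternative starting coordinates (e.g. to check
    that an already-tidy layout is a fixed point); it is not modified.
    """
    config = config or TidyConfig()
    coords = (start or classical_phylogram(tree, config)).copy()
    if tree.tip_count == 1:
        return coords

    contours: dict[PhyloNode, tuple[Contour, Contour]] = {}
    for node in tree.postorder():
        if node.is_tip:
            segs = _node_segments(node, coords, config)
            contours[node] = (top_contour(segs), bottom_contour(segs))
            continue
        block_top, block_bottom = contours.pop(node.children[0])
        for child in node.children[1:]:
            child_top, child_bottom = contours.pop(child)
            gap = contour_gap(block_top, child_bottom)
            if gap is None:  # stems share x(node); domains always intersect
                raise RuntimeError("internal error: disjoint sibling contours")
            delta = config.d - gap
            if delta != 0.0:
                _translate_subtree(child, coords, delta)
                child_top = child_top.translate(delta)
                child_bottom = child_bottom.translate(delta)
            block_top = merge_contour(block_top, child_top)
            block_bottom = merge_contour(block_bottom, child_bottom)
        coords.y[node] = 0.5 * (
            coords.y[node.children[0]] + coords.y[node.children[-1]]
        )
        own = _node_segments(node, coords, config)
        contours[node] = (
            merge_contour(block_top, top_contour(own)),
            merge_contour(block_bottom, bottom_contour(own)),
        )
    return coords


def coords_to_table(
    tree: PhyloTree,
    classical: LayoutCoordinates,
    tidy: LayoutCoordinates,
):
    """Coordinate table with columns node_id, label, is_tip, x, y_classical,
    y_tidy; node_id is the node's postorder index."""
    import pandas as pd

    rows = []
    for i, node in enumerate(tree.postorder()):
        rows.append(
            {
                "node_id": i,
                "label": node.label,
                "is_tip": node.is_tip,
                "x": classical.x[node],
                "y_classical": classical.y[node],
                "y_tidy": tidy.y[node],
            }
        )
    return pd.DataFrame(
        rows, columns=["node_id", "label", "is_tip", "x", "y_classical", "y_tidy"]
    )
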