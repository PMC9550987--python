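"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phylotidy import (
    BirthDeathParams,
    LayoutCoordinates,
    PhyloNode,
    PhyloTree,
    Segment,
    TidyConfig,
    simulate_birth_death,
    subtree_segments,
)


def make_tree(seed: int, mu: float = 0.7, stop: int = 20, grace: str = "next-event") -> PhyloTree:
    """One reproducible birth-death tree."""
    return simulate_birth_death(
        BirthDeathParams(1.0, mu, stop, seed=seed), grace=grace
    )


def tree_batch(base_seed: int, n: int, mu: float = 0.7, stop: int = 20, **kw) -> list[PhyloTree]:
    return [make_tree(base_seed + i, mu=mu, stop=stop, **kw) for i in range(n)]


def generic_lengths_tree(seed: int, stop: int = 30, mu: float = 0.6) -> PhyloTree:
    """Random topology with fresh continuous branch lengths (no x ties)."""
    tree = make_tree(seed, mu=mu, stop=stop)
    rng = np.random.default_rng(seed + 777)
    for node in tree.postorder():
        if node.parent is not None:
            node.branch_length = float(rng.exponential(1.0))
    return tree


def trees_equal(a: PhyloTree, b: PhyloTree, rel: float = 1e-12) -> bool:
    """Structural equality: topology, child order, labels, branch lengths."""

    def eq(x: PhyloNode, y: PhyloNode) -> bool:
        if x.label != y.label or len(x.children) != len(y.children):
            return False
        if (x.branch_length is None) != (y.branch_length is None):
            return False
        if x.branch_length is not None:
            scale = max(abs(x.branch_length), abs(y.branch_length), 1.0)
            if abs(x.branch_length - y.branch_length) > rel * scale:
                return False
        return all(eq(cx, cy) for cx, cy in zip(x.children, y.children))

    return eq(a.root, b.root)


def brute_envelope(segments: list[Segment], x: float, side: str):
    """Pointwise envelope value at a generic x by scanning every segment."""
    pick = max if side == "top" else min
    vals = []
    for s in segments:
        if s.orientation == "h" and s.span[0] <= x <= s.span[1]:
            vals.append(s.level)
        elif s.orientation == "v" and s.level == x:
            vals.append(pick(s.span))
    return pick(vals) if vals else None


def brute_piecewise_gap(lower_top, upper_bottom):
    """All-pairs piece oracle: min difference over positive-length overlaps."""
    best = None
    for a1, b1, tv in lower_top.pieces:
        if tv is None:
            continue
        for a2, b2, bv in upper_bottom.pieces:
            if bv is None:
                continue
            if min(b1, b2) > max(a1, a2):  # overlap of positive length
                gap = bv - tv
                if best is None or gap < best:
                    best = gap
    return best


def _relations(tree: PhyloTree):
    """Set of (ancestor, descendant) id pairs, including (v, v)."""
    related = set()
    for node in tree.postorder():
        v = node
        while v is not None:
            related.add((id(v), id(node)))
            related.add((id(node), id(v)))
            v = v.parent
    return related


def min_separation(tree: PhyloTree, coords: LayoutCoordinates, config: TidyConfig):
    """Brute-force minimum vertical distance between segments of disjoint
    subtrees over shared x of positive length (None if no such pair).

    Horizontal pairs are compared over overlapping open x-intervals; a
    vertical connector is compared against horizontals whose open span
    strictly contains its x.
    """
    segs = subtree_segments(tree.root, coords, config)
    related = _relations(tree)
    best = None

    def upd(dist):
        nonlocal best
        if best is None or dist < best:
            best = dist

    horiz = [s for s in segs if s.orientation == "h"]
    vert = [s for s in segs if s.orientation == "v"]
    for i, s in enumerate(horiz):
        for t in horiz[i + 1:]:
            if (id(s.owner), id(t.owner)) in related:
                continue
            if min(s.span[1], t.span[1]) > max(s.span[0], t.span[0]):
                upd(abs(s.level - t.level))
    for v in vert:
        for h in horiz:
            if (id(v.owner), id(h.owner)) in related:
                continue
            if h.span[0] < v.level < h.span[1]:
                lo, hi = v.span
                upd(max(lo - h.level, h.level - hi, 0.0))
    return best


@pytest.fixture(scope="session")
def mixed_trees() -> list[PhyloTree]:
    """A reusable batch spanning ultrametric and highly non-ultrametric shapes."""
    out = []
    for i, mu in enumerate((0.0, 0.3, 0.6, 0.9)):
        out.extend(tree_batch(1000 + 100 * i, 4, mu=mu, stop=12 + 4 * i))
    return out
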