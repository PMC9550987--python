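"""Layout geometry: classical phylogram, contours, and the tidy pass."""

import math
import subprocess
import sys
import tempfile
from pathlib import Path

import numpy as np
import pytest

from conftest import (
    brute_envelope,
    brute_piecewise_gap,
    generic_lengths_tree,
    make_tree,
    min_separation,
    tree_batch,
    trees_equal,
)
from phylotidy import (
    PhyloNode,
    PhyloTree,
    Segment,
    TidyConfig,
    bottom_contour,
    classical_phylogram,
    contour_gap,
    merge_contour,
    parse_newick,
    subtree_segments,
    tidy_layout,
    top_contour,
    vertical_extent,
    write_newick,
)

EXAMPLE = "(A:4,(B:1,(C:1,D:3):1):1);"


def _hseg(y, x0, x1):
    return Segment("h", y, (x0, x1), PhyloNode())


class TestClassical:
    def test_two_tips(self):
        tree = parse_newick("(A:1,B:2);")
        coords = classical_phylogram(tree)
        a, b = tree.tips()
        assert (coords.y[a], coords.y[b], coords.y[tree.root]) == (0.0, 1.0, 0.5)
        assert (coords.x[a], coords.x[b], coords.x[tree.root]) == (1.0, 2.0, 0.0)

    def test_midpoint_recursion(self):
        tree = parse_newick(EXAMPLE)
        coords = classical_phylogram(tree)
        assert [coords.y[t] for t in tree.tips()] == [0.0, 1.0, 2.0, 3.0]
        internals = [n for n in tree.postorder() if not n.is_tip]
        assert [coords.y[n] for n in internals] == [2.5, 1.75, 0.875]

    def test_tip_extent_is_tip_count_minus_one(self):
        config = TidyConfig(tip_spacing=0.5)
        for i in range(200):
            tree = make_tree(40 + i, mu=0.5, stop=3 + i % 12)
            coords = classical_phylogram(tree, config)
            ys = [coords.y[t] for t in tree.tips()]
            assert max(ys) - min(ys) == pytest.approx(
                (tree.tip_count - 1) * config.tip_spacing
            )

    def test_x_is_cumulative_branch_length(self):
        tree = make_tree(3, mu=0.6, stop=25)
        coords = classical_phylogram(tree)
        for node in tree.preorder():
            if node.parent is not None:
                assert coords.x[node] == pytest.approx(
                    coords.x[node.parent] + node.branch_length
                )


class TestSegments:
    def test_single_tip_subtree(self):
        tree = parse_newick("(A:1,B:1);")
        coords = classical_phylogram(tree)
        segs = subtree_segments(tree.tips()[0], coords)
        assert len(segs) == 1 and segs[0].orientation == "h"
        assert segs[0].span == (0.0, 1.0)

    def test_cherry_subtree_counts(self):
        tree = parse_newick("((A:1,B:1):1,C:3);")
        coords = classical_phylogram(tree)
        segs = subtree_segments(tree.root.children[0], coords)
        horiz = [s for s in segs if s.orientation == "h"]
        vert = [s for s in segs if s.orientation == "v"]
        assert len(horiz) == 3 and len(vert) == 1
        # the cherry's stem starts at its attachment (the root's x)
        assert min(s.span[0] for s in horiz) == 0.0

    def test_structural_count_on_random_trees(self):
        for tree in tree_batch(70, 25, mu=0.7, stop=15):
            coords = classical_phylogram(tree)
            segs = subtree_segments(tree.root, coords)
            internal = tree.node_count - tree.tip_count
            assert len(segs) == tree.node_count + internal

    def test_label_box_segments(self):
        tree = parse_newick("(A:1,B:1);")
        config = TidyConfig(label_widths={"A": 0.5}, label_height=0.4)
        coords = classical_phylogram(tree, config)
        segs = subtree_segments(tree.tips()[0], coords, config)
        assert len(segs) == 3  # widened branch + two box edges
        levels = sorted(s.level for s in segs)
        assert levels == [-0.2, 0.0, 0.2]


class TestContours:
    def test_single_segment(self):
        segs = [_hseg(2.0, 0.0, 3.0)]
        for x in (0.1, 1.5, 2.9):
            assert top_contour(segs).value_at(x) == 2.0
            assert bottom_contour(segs).value_at(x) == 2.0

    def test_two_step_case(self):
        segs = [_hseg(0.0, 0.0, 2.0), _hseg(1.0, 1.0, 3.0)]
        top, bottom = top_contour(segs), bottom_contour(segs)
        assert [top.value_at(x) for x in (0.5, 1.5, 2.5)] == [0.0, 1.0, 1.0]
        assert [bottom.value_at(x) for x in (0.5, 1.5, 2.5)] == [0.0, 0.0, 1.0]
        assert top.breakpoints[0] == 0.0 and top.breakpoints[-1] == 3.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            top_contour([])

    def test_pointwise_against_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = rng.integers(1, 21)
            segs = []
            for _ in range(n):
                a, b = np.sort(rng.uniform(0, 10, 2))
                segs.append(_hseg(float(rng.normal()), float(a), float(b)))
            top, bottom = top_contour(segs), bottom_contour(segs)
            for x in rng.uniform(-1, 11, 34):
                x = float(x)
                assert top.value_at(x) == brute_envelope(segs, x, "top")
                assert bottom.value_at(x) == brute_envelope(segs, x, "bottom")

    def test_top_never_below_bottom(self, mixed_trees):
        for tree in mixed_trees:
            coords = classical_phylogram(tree)
            segs = subtree_segments(tree.root, coords)
            top, bottom = top_contour(segs), bottom_contour(segs)
            for x in np.linspace(top.x_min, top.x_max, 57)[1:]:
                assert top.value_at(float(x)) >= bottom.value_at(float(x))


class TestContourGap:
    def test_constant_contours(self):
        lower = top_contour([_hseg(0.0, 0.0, 2.0)])
        upper = bottom_contour([_hseg(3.0, 0.0, 2.0)])
        assert contour_gap(lower, upper) == 3.0

    def test_min_over_two_intervals(self):
        lower = top_contour([_hseg(0.0, 0.0, 1.0), _hseg(1.0, 1.0, 2.0)])
        upper = bottom_contour([_hseg(1.5, 0.0, 2.0)])
        assert contour_gap(lower, upper) == 0.5

    def test_disjoint_domains(self):
        lower = top_contour([_hseg(0.0, 0.0, 1.0)])
        upper = bottom_contour([_hseg(5.0, 2.0, 3.0)])
        assert contour_gap(lower, upper) is None

    def test_random_pairs_match_all_pairs_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(1000):
            def rand_contour(side):
                segs = []
                for _ in range(int(rng.integers(1, 8))):
                    a, b = np.sort(rng.uniform(0, 10, 2))
                    segs.append(_hseg(float(rng.normal()), float(a), float(b)))
                return (top_contour if side == "top" else bottom_contour)(segs)

            lower, upper = rand_contour("top"), rand_contour("bottom")
            got = contour_gap(lower, upper)
            expected = brute_piecewise_gap(lower, upper)
            if expected is None:
                # domains may still touch at a point; no positive overlap
                assert got is None or min(lower.x_max, upper.x_max) == max(
                    lower.x_min, upper.x_min
                )
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestMergeContour:
    def test_idempotent(self):
        c = top_contour([_hseg(0.0, 0.0, 2.0), _hseg(1.0, 1.0, 3.0)])
        assert merge_contour(c, c).pieces == c.pieces

    def test_disjoint_concatenation_keeps_hole(self):
        a = top_contour([_hseg(1.0, 0.0, 1.0)])
        b = top_contour([_hseg(2.0, 3.0, 4.0)])
        merged = merge_contour(a, b)
        assert merged.x_min == 0.0 and merged.x_max == 4.0
        assert merged.value_at(0.5) == 1.0
        assert merged.value_at(2.0) is None
        assert merged.value_at(3.5) == 2.0

    def test_random_pairs_pointwise(self):
        rng = np.random.default_rng(37)
        for _ in range(200):
            def rand(side):
                segs = [
                    _hseg(float(rng.normal()), *map(float, np.sort(rng.uniform(0, 10, 2))))
                    for _ in range(int(rng.integers(1, 10)))
                ]
                return (top_contour if side == "top" else bottom_contour)(segs)

            for side, pick in (("top", max), ("bottom", min)):
                a, b = rand(side), rand(side)
                merged = merge_contour(a, b)
                for x in rng.uniform(0, 10, 23):
                    va, vb = a.value_at(float(x)), b.value_at(float(x))
                    want = (
                        None if va is None and vb is None
                        else vb if va is None
                        else va if vb is None
                        else pick(va, vb)
                    )
                    assert merged.value_at(float(x)) == want


class TestTidyLayout:
    def test_ultrametric_cherry_is_unchanged(self):
        tree = parse_newick("(A:1,B:1);")
        classical = classical_phylogram(tree)
        tidy = tidy_layout(tree)
        assert all(tidy.y[n] == classical.y[n] for n in tree.postorder())

    def test_worked_example(self):
        """Sliding the inner subtree halves two gaps; extent 3 -> 2.5."""
        tree = parse_newick(EXAMPLE)
        tidy = tidy_layout(tree)
        assert [tidy.y[t] for t in tree.tips()] == [0.0, 1.0, 1.5, 2.5]
        internals = [n for n in tree.postorder() if not n.is_tip]
        assert [tidy.y[n] for n in internals] == [2.0, 1.5, 0.75]
        assert vertical_extent(tidy, tree) == 2.5

    def test_single_tip_tree(self):
        tree = parse_newick("A:1;")
        tidy = tidy_layout(tree)
        assert tidy.y[tree.root] == 0.0

    def test_x_coordinates_are_preserved(self, mixed_trees):
        for tree in mixed_trees:
            classical = classical_phylogram(tree)
            tidy = tidy_layout(tree)
            assert all(tidy.x[n] == classical.x[n] for n in tree.postorder())

    def test_sibling_y_order_is_preserved(self, mixed_trees):
        for tree in mixed_trees:
            classical = classical_phylogram(tree)
            tidy = tidy_layout(tree)
            for node in tree.postorder():
                cl = [classical.y[c] for c in node.children]
                td = [tidy.y[c] for c in node.children]
                assert np.argsort(cl).tolist() == np.argsort(td).tolist()

    def test_exact_gap_between_placed_siblings(self, mixed_trees):
        """After tidying, every accumulated-block/next-child contour gap
        equals d, recomputed independently from the full segment sets."""
        config = TidyConfig(d=1.0)
        for tree in mixed_trees:
            tidy = tidy_layout(tree, config)
            assert_exact_gaps(tree, tidy, config)

    def test_global_separation_brute_force(self):
        config = TidyConfig()
        checked = 0
        for tree in tree_batch(210, 12, mu=0.8, stop=25):
            if tree.node_count > 200:
                continue
            checked += 1
            tidy = tidy_layout(tree, config)
            sep = min_separation(tree, tidy, config)
            assert sep is None or sep >= config.d - 1e-9
        assert checked >= 5

    def test_subtree_geometry_is_context_independent(self):
        """Rigidity: a placed subtree's internal geometry equals the tidy
        layout of that subtree extracted as a stand-alone tree."""
        for seed in (61, 62, 63):
            tree = make_tree(seed, mu=0.8, stop=18)
            tidy = tidy_layout(tree)
            for node in tree.postorder():
                if node.is_tip or node is tree.root:
                    continue
                sub = PhyloTree(_copy_subtree(node))
                sub_tidy = tidy_layout(sub)
                ours = [tidy.y[v] - tidy.y[node] for v in node.iter_preorder()]
                theirs = [
                    sub_tidy.y[v] - sub_tidy.y[sub.root]
                    for v in sub.root.iter_preorder()
                ]
                assert ours == pytest.approx(theirs, abs=1e-9)

    def test_compression_is_nonnegative_when_d_at_most_spacing(self, mixed_trees):
        config = TidyConfig(d=0.8, tip_spacing=1.0)
        for tree in mixed_trees:
            classical = classical_phylogram(tree, config)
            tidy = tidy_layout(tree, config)
            assert vertical_extent(tidy, tree) <= vertical_extent(classical, tree) + 1e-9

    def test_ultrametric_trees_are_fixed_points(self):
        for tree in tree_batch(300, 10, mu=0.0, stop=20):
            classical = classical_phylogram(tree)
            tidy = tidy_layout(tree)
            assert all(tidy.y[n] == classical.y[n] for n in tree.postorder())

    def test_idempotence(self, mixed_trees):
        for tree in mixed_trees:
            tidy = tidy_layout(tree)
            again = tidy_layout(tree, start=tidy)
            assert all(again.y[n] == pytest.approx(tidy.y[n], abs=1e-9) for n in tree.postorder())

    def test_label_width_monotonicity(self):
        tree = make_tree(77, mu=0.8, stop=20)
        rng = np.random.default_rng(78)
        widths = {t.label: float(rng.uniform(0, 2)) for t in tree.tips()}
        base = vertical_extent(tidy_layout(tree, TidyConfig(label_widths=widths)), tree)
        for t in tree.tips()[::3]:
            bigger = dict(widths)
            bigger[t.label] = widths[t.label] + 1.5
            ext = vertical_extent(
                tidy_layout(tree, TidyConfig(label_widths=bigger)), tree
            )
            assert ext >= base - 1e-9

    def test_widening_when_d_exceeds_tip_spacing(self):
        tree = parse_newick("(A:1,B:1);")
        config = TidyConfig(d=2.0, tip_spacing=1.0)
        tidy = tidy_layout(tree, config)
        a, b = tree.tips()
        assert tidy.y[b] - tidy.y[a] == pytest.approx(2.0)

    def test_zero_length_branches_are_handled(self):
        for tree in tree_batch(400, 5, mu=0.6, stop=12, grace="none"):
            config = TidyConfig()
            tidy = tidy_layout(tree, config)
            assert_exact_gaps(tree, tidy, config)
            sep = min_separation(tree, tidy, config)
            assert sep is None or sep >= config.d - 1e-9

    def test_multifurcating_tree_separation(self):
        tree = parse_newick("((A:3,B:1,C:4):1,(D:1,E:1,F:1):2,G:6);")
        config = TidyConfig()
        tidy = tidy_layout(tree, config)
        assert_exact_gaps(tree, tidy, config)
        sep = min_separation(tree, tidy, config)
        assert sep is None or sep >= config.d - 1e-9


def _copy_subtree(node):
    clone = PhyloNode(node.label, node.branch_length)
    for child in node.children:
        clone.add_child(_copy_subtree(child))
    return clone


def assert_exact_gaps(tree, coords, config):
    """Recompute every accumulated-block/next-child gap from scratch."""
    for node in tree.postorder():
        if len(node.children) < 2:
            continue
        block = top_contour(subtree_segments(node.children[0], coords, config))
        for child in node.children[1:]:
            segs = subtree_segments(child, coords, config)
            gap = contour_gap(block, bottom_contour(segs))
            assert gap == pytest.approx(config.d, abs=1e-9)
            block = merge_contour(block, top_contour(segs))


R_SNIPPET = """
library(ape)
phy <- reorder(read.tree(commandArgs(TRUE)[1]), "cladewise")
n <- Ntip(phy); m <- phy$Nnode
xx <- node.depth.edgelength(phy)
yy <- numeric(n + m); yy[1:n] <- 0:(n-1)
po <- reorder(phy, "postorder")$edge
kids <- split(phy$edge[,2], phy$edge[,1])
for (nd in unique(po[,1])) {
  ch <- kids[[as.character(nd)]]
  yy[nd] <- (yy[ch[1]] + yy[ch[length(ch)]]) / 2
}
yynew <- ape:::tidy.xy(phy$edge, n, m, xx, yy)
out <- data.frame(label = phy$tip.label, y = yynew[1:n] - min(yynew[1:n]))
write.table(out, commandArgs(TRUE)[2], sep = "\\t", row.names = FALSE,
            col.names = FALSE, quote = FALSE)
"""


def test_tidy_matches_independent_r_implementation(tmp_path):
    """Tip coordinates must agree with the independently written tidy
    layout available in R's ape, on bifurcating trees without x ties."""
    script = tmp_path / "tidy.R"
    script.write_text(R_SNIPPET)
    for seed in (81, 82, 83):
        tree = generic_lengths_tree(seed, stop=30, mu=0.6)
        nwk = tmp_path / f"t{seed}.nwk"
        nwk.write_text(write_newick(tree) + "\n")
        out = tmp_path / f"y{seed}.tsv"
        subprocess.run(
            ["Rscript", "--vanilla", str(script), str(nwk), str(out)],
            check=True, capture_output=True,
        )
        theirs = {}
        for line in out.read_text().splitlines():
            label, y = line.split("\t")
            theirs[label] = float(y)
        tidy = tidy_layout(tree)
        base = min(tidy.y[t] for t in tree.tips())
        for t in tree.tips():
            assert tidy.y[t] - base == pytest.approx(theirs[t.label], abs=1e-8)
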