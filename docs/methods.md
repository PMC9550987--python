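# Methods

## Layout model

Both layouts assign coordinates in two unit systems: x in branch-length
units (root at x = 0, every node at its parent's x plus its branch
length), y in tip-spacing units. The **classical rectangular phylogram**
places tips at y = 0, s, 2s, … (s = `tip_spacing`) in traversal order and
every internal node midway between its first and last child. The **tidy
layout** starts from those coordinates and only translates subtrees
vertically; x coordinates are never modified, so the two layouts are
directly comparable and their vertical extents share units.

A subtree's drawing is the set of axis-parallel segments: one horizontal
branch per node (from the parent's x to the node's x, extended by the
label width for tips) and one vertical connector per internal node
(spanning its children's y at the node's x). The **top/bottom contour** of
a subtree is the pointwise max/min of its segments as a function of x,
a piecewise-constant step function.

### Interval semantics

A horizontal segment from x₁ to x₂ covers the half-open interval
(x₁, x₂]. Consequently a branch that *ends* exactly where another
*begins* does not constrain the layout — the two subtrees may approach
closer than d at that single shared x. This is a deliberate convention:
it is what makes short subtrees slide fully underneath longer sibling
branches whose tips happen to align with an internal node, and it matches
the behaviour of the independent R implementation in `ape`, against which
the test suite validates tip coordinates to 1e−8. Vertical connectors
never alter contours (their extremes coincide with the adjacent extreme
branches), with one exception: an isolated point contribution — a
zero-length terminal branch — is retained as a degenerate contour piece
so that point-tips still keep their distance from each other.

### The compression pass

Nodes are visited children-before-parent (plain postorder). This is
equivalent to a sweep by decreasing x when branch lengths are positive,
and remains well defined when zero-length branches make x coincide. At
each internal node:

1. the first (lowest-y) child subtree stays fixed and seeds the *block*;
2. each subsequent child, in y order, is rigidly translated by
   d − gap, where gap is the minimum of (child bottom contour − block top
   contour) over shared x, computed by a merge scan over the contour
   pieces (whichever piece ends first is advanced). Children further than
   d are pulled closer; children nearer than d (possible when d exceeds
   the tip spacing) are pushed apart;
3. the child's contours, translated with it, are merged pointwise into
   the block's;
4. the node's y is re-set to the midpoint of its first and last child.

Midpoint centering (rather than the mean of all children) keeps
ultrametric trees exact fixed points and makes the full-drawing vertical
extent coincide with the tips-only extent. Multifurcations are handled
against the accumulated block contour, which guarantees that *every*
earlier sibling — not just the adjacent one — stays at least d away.

Per-subtree contours are maintained incrementally (built once per node
from its own segments and merged upward), giving O(n·h) work for n nodes
and height h; a 1000-tip birth–death tree lays out in ~0.1 s. The test
suite independently recomputes every block/child gap from the full
segment sets and checks it equals d to 1e−9, and brute-forces all segment
pairs of disjoint subtrees on trees up to 200 nodes.

### Tip labels

A label is modelled as a widening of the terminal branch by
`label_widths[tip]` branch-length units before compression (the CLI
estimates widths as character count × `--width-per-char`, a monospace
approximation; font metrics are out of scope). Optionally a label box of
height `label_height` (two extra horizontal segments at y ± h/2 over the
label span) can be enabled; it is off by default, so labels only widen
branches. Wider labels make trees less compressible; the suite checks
that growing any label never shrinks the tidy extent. Tip dots in the SVG
output are decoration only and never enter the contours.

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| `d` | tip-spacings | 1.0 | minimum contour separation; with d ≤ tip_spacing tidying can only shrink the drawing |
| `tip_spacing` | tip-spacings | 1.0 | classical inter-tip distance |
| `label_widths` | branch-length units | {} | added to terminal branches |
| `label_height` | tip-spacings | 0 | optional label box |
| `speciation_rate` λ | events/lineage/time | 1.0 | birth–death simulator |
| `extinction_rate` μ | events/lineage/time | 0.0 | extinct lineages retained as tips |
| `n_extant_stop` | lineages | 100 | stop when this many are simultaneously extant |

## Synthetic data

The birth–death generator is a Gillespie simulation from a single
lineage: with k extant lineages the next event arrives after
Exp((λ+μ)k) time and is a speciation with probability λ/(λ+μ). Extinct
lineages are kept as tips ending before the final time — this is exactly
what makes the trees non-ultrametric and compressible. Runs that die out
are discarded and re-run on the same random stream (survival
conditioning); the returned tree is rooted at the first speciation
(`include_stem=True` keeps the stem).

The simulation ends at the time the first event *after* reaching the stop
count would occur, i.e. the tree is observed during the window in which
the extant count stands at the stop value. Ending at the instant of the
final speciation itself would leave that pair of tips with zero-length
branches — a drawing artifact no empirical tree has, which would also
make extinction-free trees compress slightly instead of being exact fixed
points. That instant-stop variant remains available (`grace="none"`) and
is exercised by the tests for the degenerate-geometry path.

Default conditions for the compression experiment: λ = 1, stop at 100
extant taxa, 50 replicates per extinction rate, d = tip_spacing = 1, no
labels; mean compression rises from exactly 0 at μ = 0 to slightly above
0.5 at μ = 0.8.

What the generator does **not** emulate: incomplete taxon sampling,
fossilization/sampling-through-time, rate variation across lineages, and
measurement noise in branch lengths. Passing tests therefore show the
layout is correct and that compression behaves as expected for fully
observed birth–death histories; compressibility of real trees (e.g.
heterochronous virus phylogenies) will vary with how non-ultrametric
they are and how long their labels render.

## Numerical choices

* Gap equalities are asserted to 1e−9 absolute in y units; the
  translation itself is exact (delta = d − gap in one subtraction).
* Newick branch lengths are written with `repr`, so parse→write→parse is
  bit-lossless; missing lengths default to 1.0 (strict mode rejects
  them), negative lengths are a parse error naming the character offset.
* Ultrametric trees are exact fixed points (their gaps evaluate to
  exactly d in binary arithmetic for dyadic tip spacings), so the
  zero-compression tests use equality, not tolerances.
* Single-tip trees have zero extent in both layouts; their compression is
  0 by convention.
* Contour-domain holes (possible only when merging contours of disjoint
  segment sets through the public API) carry a None value and are skipped
  by the gap scan; sibling subtrees always share their parent's x, so the
  tidy pass itself can never see disjoint domains.
* Degenerate contour pieces from zero-length branches participate in the
  gap scan, keeping coincident point-tips d apart.

## Known limitations

* The contour comparison is the straightforward O(n·h) merge; the
  strictly linear-time bookkeeping described for non-layered tidy trees
  is not implemented (unnecessary at the tree sizes targeted here).
* Compression is reported from tip-only extents (identical to
  full-drawing extents under midpoint centering with zero label height;
  both definitions are exposed).
* Child order is taken as given: no subtree-rotation search for the most
  compressible ordering.
* Newick only (no NEXUS/PhyloXML); rooted trees only.
* SVG label placement assumes monospace text and does not measure fonts.
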