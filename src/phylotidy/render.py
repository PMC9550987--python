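"""Deterministic SVG rendering of tree layouts.

Each non-root node contributes one horizontal branch line, each internal
node one vertical connector, and the root an optional short stem; tips
optionally carry a dot and a text label.  Data coordinates are mapped
linearly onto the viewport.  Output is plain SVG 1.1 text with fixed
number formatting, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .layout import LayoutCoordinates, TidyConfig
from .tree import PhyloTree

__all__ = ["RenderOptions", "render_svg", "label_widths_from_tree"]

_FMT = "{:.3f}".format


@dataclass
class RenderOptions:
    """Rendering parameters; all pixel dimensions must be positive.

    ``width_per_character`` converts a tip label's character count into a
    width in branch-length units, feeding :class:`~phylotidy.layout.TidyConfig`
    label widths (a monospace approximation; real font metrics are out of
    scope).
    """

    width: float = 800.0
    height: float = 600.0
    margin: float = 20.0
    stroke_width: float = 1.0
    show_labels: bool = True
    font_size: float = 10.0
    width_per_character: float = 0.0
    layout: str = "tidy"
    flip_y: bool = False
    root_stem: bool = True
    root_stem_px: float = 10.0
    tip_dots: bool = True
    tip_dot_radius: float = 2.0

    def __post_init__(self) -> None:
        for name in ("width", "height", "stroke_width", "font_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.width_per_character < 0:
            raise ValueError("width_per_character must be >= 0")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


def label_widths_from_tree(tree: PhyloTree, width_per_character: float) -> dict[str, float]:
    """Tip label -> width in branch-length units (monospace model)."""
    return {
        t.label: len(t.label) * width_per_character
        for t in tree.tips()
        if t.label
    }


def _escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def render_svg(
    tree: PhyloTree,
    coords: LayoutCoordinates,
    options: Optional[RenderOptions] = None,
    out=None,
) -> str:
    """Render a laid-out tree to an SVG string (and optionally a file).

    Raises ``ValueError`` for an empty tree; a single-tip tree renders as
    one horizontal line.
    """
    options = options or RenderOptions()
    nodes = tree.postorder()
    if not nodes:
        raise ValueError("cannot render an empty tree")

    xs = [coords.x[n] for n in nodes]
    ys = [coords.y[n] for n in nodes]
    x_lo, x_hi = min(xs), max(xs)
    y_lo, y_hi = min(ys), max(ys)
    x_span = (x_hi - x_lo) or 1.0
    y_span = (y_hi - y_lo) or 1.0
    inner_w = options.width - 2 * options.margin
    inner_h = options.height - 2 * options.margin

    def px(x: float) -> float:
        return options.margin + (x - x_lo) / x_span * inner_w

    def py(y: float) -> float:
        frac = (y - y_lo) / y_span
        if options.flip_y:
            frac = 1.0 - frac
        return options.margin + frac * inner_h

    sw = _FMT(options.stroke_width)
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>\n',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_FMT(options.width)}" height="{_FMT(options.height)}" '
        f'viewBox="0 0 {_FMT(options.width)} {_FMT(options.height)}">\n',
        f'<g stroke="black" stroke-width="{sw}" fill="none">\n',
    ]

    def line(x1: float, y1: float, x2: float, y2: float) -> None:
        parts.append(
            f'<line x1="{_FMT(x1)}" y1="{_FMT(y1)}" '
            f'x2="{_FMT(x2)}" y2="{_FMT(y2)}"/>\n'
        )

    for node in nodes:
        y = py(coords.y[node])
        if node.parent is not None:
            line(px(coords.x[node.parent]), y, px(coords.x[node]), y)
        elif options.root_stem:
            x = px(coords.x[node])
            line(x - options.root_stem_px, y, x, y)
        if node.children:
            child_ys = [py(coords.y[c]) for c in node.children]
            x = px(coords.x[node])
            line(x, min(child_ys), x, max(child_ys))
    parts.append("</g>\n")

    if options.tip_dots:
        parts.append('<g fill="black">\n')
        for t in tree.tips():
            parts.append(
                f'<circle cx="{_FMT(px(coords.x[t]))}" '
                f'cy="{_FMT(py(coords.y[t]))}" r="{_FMT(options.tip_dot_radius)}"/>\n'
            )
        parts.append("</g>\n")

    if options.show_labels:
        parts.append(
            f'<g font-family="monospace" font-size="{_FMT(options.font_size)}" '
            f'fill="black">\n'
        )
        for t in tree.tips():
            if not t.label:
                continue
            parts.append(
                f'<text x="{_FMT(px(coords.x[t]) + 4.0)}" '
                f'y="{_FMT(py(coords.y[t]) + options.font_size * 0.35)}">'
                f"{_escape(t.label)}</text>\n"
            )
        parts.append("</g>\n")

    parts.append("</svg>\n")
    svg = "".join(parts)
    if out is not None:
        with open(out, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(svg)
    return svg
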