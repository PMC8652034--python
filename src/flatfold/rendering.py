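"""Deterministic SVG rendering of per-domain diagrams and the family overlay.

Helices are rounded rectangles, strands arrows pointing N to C; consecutive
elements in sequence order are joined by light polyline connectors.  The family
("multiple") diagram overlays one averaged glyph per family-wide label, with
fill opacity equal to the label's occurrence frequency, so elements present in
every member are opaque and rare ones fade out.  Output is plain SVG 1.1 text;
repeated calls with identical inputs are byte-identical.

Layout coordinates are mathematical (y up); the y axis is flipped once at
render time since SVG's y grows downward.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from xml.sax.saxutils import escape

import numpy as np

from .family_stats import FamilyStats
from .layout_engine import (
    DomainDiagram,
    rot2,
    sse_endpoints,
    sse_glyph_geometry,
    wrap_angle,
)
from .sse_annotation import HELIX, STRAND

#: Display units per residue when lengths come from residue counts
#: (family overlay): the axial rise of each element type in Angstrom.
RISE_PER_RESIDUE = {HELIX: 1.5, STRAND: 3.3}

_HEX_RE = re.compile(r"^#[0-9a-fA-F]{6}$")


@dataclass
class RenderStyle:
    helix_fill: str = "#d1495b"
    strand_fill: str = "#30638e"
    helix_width: float = 3.0
    strand_width: float = 2.2
    connector_color: str = "#8d8d8d"
    connector_width: float = 0.5
    text_color: str = "#222222"
    font_size: float = 3.0
    scale: float = 8.0  # px per layout unit
    padding: float = 30.0  # px
    opacity_floor: float = 0.0  # optional legibility floor for the overlay

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        for color in (self.helix_fill, self.strand_fill, self.connector_color):
            if not _HEX_RE.match(color):
                raise ValueError(f"invalid CSS hex color {color!r}")


@dataclass
class FamilyDiagram:
    """Frequency-weighted overlay of one family's averaged SSE glyphs."""

    family_id: str
    per_label: dict[str, dict] = field(default_factory=dict)
    # per label: center (2,), angle (rad, circular mean), length, frequency, type


def _fmt(v: float) -> str:
    return f"{v:.2f}"


class _Canvas:
    """Collects glyphs in layout coordinates, then emits pixel-space SVG."""

    def __init__(self, style: RenderStyle):
        self.style = style
        self.points: list[np.ndarray] = []
        self.body: list[str] = []

    def track(self, *pts: np.ndarray):
        self.points.extend(np.asarray(p, dtype=float) for p in pts)

    def to_px(self, p: np.ndarray) -> tuple[float, float]:
        s, pad = self.style.scale, self.style.padding
        x = (p[0] - self._minx) * s + pad
        y = (self._maxy - p[1]) * s + pad  # y flip
        return x, y

    def freeze(self) -> None:
        """Fix the bounding box; no further track() calls may extend it."""
        if self.points:
            pts = np.array(self.points)
            self._minx, self._maxy = pts[:, 0].min(), pts[:, 1].max()
            self._w = (pts[:, 0].max() - self._minx) * self.style.scale + 2 * self.style.padding
            self._h = (self._maxy - pts[:, 1].min()) * self.style.scale + 2 * self.style.padding
        else:
            self._minx = self._maxy = 0.0
            self._w = self._h = 2 * self.style.padding

    def finish(self) -> str:
        w, h = self._w, self._h
        head = (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{_fmt(w)}" height="{_fmt(h)}" '
            f'viewBox="0 0 {_fmt(w)} {_fmt(h)}">\n'
        )
        return head + "".join(self.body) + "</svg>\n"


def _corner_points(center, angle, length, width):
    r = rot2(angle)
    half = np.array([length / 2.0, width / 2.0])
    return [
        center + r @ (half * np.array(s))
        for s in ((1, 1), (1, -1), (-1, 1), (-1, -1))
    ]


def _glyph_svg(
    canvas: _Canvas,
    label: str,
    sse_type: str,
    center: np.ndarray,
    angle: float,
    length: float,
    opacity: float | None = None,
) -> str:
    """One glyph group: shape + text label, id = label."""
    style = canvas.style
    width = style.helix_width if sse_type == HELIX else style.strand_width
    fill = style.helix_fill if sse_type == HELIX else style.strand_fill
    cx, cy = canvas.to_px(center)
    deg = -math.degrees(angle)  # y flip reverses the rotation sense
    lpx = length * style.scale
    wpx = width * style.scale
    op = "" if opacity is None else f' fill-opacity="{opacity:g}"'
    parts = [
        f'<g id="{escape(label)}" class="glyph {sse_type}" '
        f'data-angle-deg="{_fmt(math.degrees(wrap_angle(angle)))}" '
        f'transform="translate({_fmt(cx)},{_fmt(cy)}) rotate({_fmt(deg)})">'
    ]
    if sse_type == HELIX:
        parts.append(
            f'<rect x="{_fmt(-lpx / 2)}" y="{_fmt(-wpx / 2)}" width="{_fmt(lpx)}" '
            f'height="{_fmt(wpx)}" rx="{_fmt(wpx / 2)}" fill="{fill}"{op}/>'
        )
    else:
        head = min(0.35 * lpx, 1.6 * wpx)
        shaft = wpx * 0.55
        pts = [
            (-lpx / 2, -shaft / 2),
            (lpx / 2 - head, -shaft / 2),
            (lpx / 2 - head, -wpx / 2),
            (lpx / 2, 0.0),
            (lpx / 2 - head, wpx / 2),
            (lpx / 2 - head, shaft / 2),
            (-lpx / 2, shaft / 2),
        ]
        path = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts)
        parts.append(f'<polygon points="{path}" fill="{fill}"{op}/>')
    parts.append(
        f'<text x="0" y="0" text-anchor="middle" dominant-baseline="middle" '
        f'font-size="{_fmt(canvas.style.font_size * canvas.style.scale / 2)}" '
        f'fill="{canvas.style.text_color}">{escape(label)}</text>'
    )
    parts.append("</g>\n")
    return "".join(parts)


def render_domain_svg(diagram: DomainDiagram, style: RenderStyle | None = None) -> str:
    """Render one domain diagram: a glyph per SSE plus sequence connectors."""
    style = style or RenderStyle()
    canvas = _Canvas(style)
    glyphs = sse_glyph_geometry(diagram)
    for label, (center, angle, length, sse_type) in sorted(glyphs.items()):
        width = style.helix_width if sse_type == HELIX else style.strand_width
        canvas.track(*_corner_points(center, angle, length, width))

    connector_parts = []
    ends = sse_endpoints(diagram)
    seq = [l for l in diagram.sequence_order if l in ends]
    for a, b in zip(seq, seq[1:]):
        p0 = ends[a][1]  # C-terminus of the earlier element
        p1 = ends[b][0]  # N-terminus of the later element
        mid = 0.5 * (p0 + p1)
        seg = p1 - p0
        norm = np.linalg.norm(seg)
        if norm > 1e-9:
            perp = np.array([-seg[1], seg[0]]) / norm
            mid = mid + 1.2 * perp  # single fixed midpoint offset
        canvas.track(p0, mid, p1)
        connector_parts.append((p0, mid, p1))

    canvas.freeze()
    # connectors under glyphs
    for p0, mid, p1 in connector_parts:
        pts = " ".join(
            f"{_fmt(x)},{_fmt(y)}" for x, y in (canvas.to_px(p) for p in (p0, mid, p1))
        )
        canvas.body.append(
            f'<polyline points="{pts}" fill="none" stroke="{style.connector_color}" '
            f'stroke-width="{_fmt(style.connector_width * style.scale)}"/>\n'
        )
    for label, (center, angle, length, sse_type) in sorted(glyphs.items()):
        canvas.body.append(_glyph_svg(canvas, label, sse_type, center, angle, length))
    return canvas.finish()


def compute_family_diagram(
    diagrams: dict[str, DomainDiagram], stats: FamilyStats
) -> FamilyDiagram:
    """Average each label's glyph over the members containing it.

    Centers use the arithmetic mean, angles the circular mean (so -170 and
    +170 degrees average to 180, not 0); display length comes from the family
    average residue length scaled by the type's axial rise; frequency is copied
    from the family statistics.
    """
    accum: dict[str, list] = {}
    for dom_id in sorted(diagrams):
        for label, (center, angle, _, sse_type) in sse_glyph_geometry(
            diagrams[dom_id]
        ).items():
            accum.setdefault(label, []).append((center, angle, sse_type))
    fam = FamilyDiagram(family_id=stats.family_id)
    for label in sorted(accum):
        entries = accum[label]
        sse_type = entries[0][2]
        centers = np.array([c for c, _, _ in entries])
        sines = np.mean([math.sin(a) for _, a, _ in entries])
        cosines = np.mean([math.cos(a) for _, a, _ in entries])
        mean_angle = wrap_angle(math.atan2(sines, cosines))
        ls = stats.per_label.get(label)
        if ls is None:
            continue
        fam.per_label[label] = {
            "center": centers.mean(axis=0),
            "angle": mean_angle,
            "length": ls.avg_length * RISE_PER_RESIDUE[sse_type],
            "frequency": ls.frequency,
            "type": sse_type,
        }
    return fam


def render_family_svg(fam: FamilyDiagram, style: RenderStyle | None = None) -> str:
    """Render the multiple 2D diagram: averaged glyphs, opacity = frequency.

    No connectors are drawn: members may order shared elements differently, so
    an averaged topology would be ambiguous.
    """
    style = style or RenderStyle()
    canvas = _Canvas(style)
    for label in sorted(fam.per_label):
        e = fam.per_label[label]
        width = style.helix_width if e["type"] == HELIX else style.strand_width
        canvas.track(*_corner_points(e["center"], e["angle"], e["length"], width))
    canvas.freeze()
    for label in sorted(fam.per_label):
        e = fam.per_label[label]
        opacity = max(e["frequency"], style.opacity_floor)
        canvas.body.append(
            _glyph_svg(
                canvas, label, e["type"], e["center"], e["angle"], e["length"], opacity
            )
        )
    return canvas.finish()
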