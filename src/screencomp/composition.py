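"""The render tree: element types and the recursive compose pass.

A screen is described as a tree of *elements*.  Elements are pure
rendering instructions — they hold no pixels.  Three families exist:

layouts
    divide their area among any number of children
    (:class:`LinLayout`, :class:`GridLayout`, :class:`Overlay`).
wrappers
    take at most one child and modify its area or background
    (:class:`Padding`, :class:`Border`, :class:`Fill`,
    :class:`RectangleShaper`, :class:`ImageElement`, :class:`MouseArea`).
primitives
    take no children and draw into their full area
    (:class:`Text`, :class:`Circle`, :class:`Cross`, :class:`Line`;
    a childless :class:`Fill` is the filled-rectangle primitive).

:func:`compose` walks the tree, assigns every node an integer pixel
:class:`~screencomp.geometry.Rect`, draws through the
:class:`~screencomp.backend.Canvas` contract, and returns a
:class:`LayoutTrace` mapping node paths to the rect each received —
the headless test surface for all layout behavior.

Layouts and wrappers are callable: ``LinLayout("h")(a, b)`` returns the
layout with children attached, ``Border()(child)`` wraps a child.  This
keeps deeply nested screens readable as a single expression.

Raw numpy arrays are accepted anywhere an element is expected and are
wrapped in an :class:`ImageElement` automatically.  Raw strings are
*not* auto-wrapped into :class:`Text`; pass a ``Text`` element
explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .backend import Canvas, PixelBuffer
from .geometry import Rect, aspect_rect, fit_rect, inset_fractional, split_interval

__all__ = [
    "Color",
    "parse_color",
    "BLACK",
    "WHITE",
    "Element",
    "LinLayout",
    "LLItem",
    "GridLayout",
    "Overlay",
    "Padding",
    "Border",
    "Fill",
    "RectangleShaper",
    "ImageElement",
    "MouseArea",
    "Text",
    "Circle",
    "Cross",
    "Line",
    "TraceEntry",
    "LayoutTrace",
    "CompositionError",
    "normalize_child",
    "compose",
]

Color = tuple[int, int, int]

BLACK: Color = (0, 0, 0)
WHITE: Color = (255, 255, 255)


class CompositionError(ValueError):
    """An invalid tree was handed to :func:`compose`; names the node path."""


def parse_color(spec: Union[str, Sequence[int]]) -> Color:
    """Parse ``"#RRGGBB"`` (case-insensitive) or an (r, g, b) triple."""
    if isinstance(spec, str):
        s = spec.strip()
        if not s.startswith("#") or len(s) != 7:
            raise ValueError(f"expected '#RRGGBB' hex color, got {spec!r}")
        try:
            channels = tuple(int(s[i : i + 2], 16) for i in (1, 3, 5))
        except ValueError:
            raise ValueError(f"malformed hex color {spec!r}") from None
        return channels  # type: ignore[return-value]
    channels = tuple(spec)
    if len(channels) != 3:
        raise ValueError(f"color triple must have 3 channels, got {spec!r}")
    for c in channels:
        if not isinstance(c, (int, np.integer)) or isinstance(c, bool) or not 0 <= c <= 255:
            raise ValueError(f"color channel out of range in {spec!r}")
    return (int(channels[0]), int(channels[1]), int(channels[2]))


# ---------------------------------------------------------------------------
# element types
# ---------------------------------------------------------------------------


class Element:
    """Base class for all render-tree nodes."""

    kind: str = "element"

    def children(self) -> list[Optional["Element"]]:
        return []


class _Wrapper(Element):
    """Shared behavior for single-child nodes; ``wrapper(child)`` attaches."""

    def __init__(self, child: Optional[Element] = None):
        self.child = _coerce(child) if child is not None else None

    def __call__(self, child: "ElementLike") -> "_Wrapper":
        if self.child is not None:
            raise CompositionError(f"{self.kind} already has a child")
        self.child = _coerce(child)
        return self

    def children(self) -> list[Optional[Element]]:
        return [self.child] if self.child is not None else []


ElementLike = Union[Element, np.ndarray, PixelBuffer]


def _coerce(raw: ElementLike) -> Element:
    if isinstance(raw, Element):
        return raw
    if isinstance(raw, PixelBuffer):
        return ImageElement(raw.array)
    if isinstance(raw, np.ndarray):
        return ImageElement(raw)
    raise CompositionError(
        f"cannot use {type(raw).__name__!r} as a tree element; "
        "pass an Element or an image array"
    )


class LLItem(_Wrapper):
    """A linear-layout slot: relative size weight plus an optional child.

    A childless item is an empty spacer cell.
    """

    kind = "ll_item"

    def __init__(self, relative_size: float = 1, child: Optional[ElementLike] = None):
        if relative_size < 0:
            raise ValueError(f"relative_size must be >= 0, got {relative_size}")
        super().__init__(child)
        self.relative_size = relative_size


class LinLayout(Element):
    """Arrange children in a horizontal or vertical line.

    Space is split equally by default; wrap children in :class:`LLItem`
    to change proportions or insert empty cells.  Non-``LLItem``
    children are auto-wrapped with weight 1.
    """

    kind = "lin_layout"

    def __init__(self, orientation: str, *children: Optional[ElementLike]):
        if orientation not in ("h", "v", "horizontal", "vertical"):
            raise ValueError(f"orientation must be 'h' or 'v', got {orientation!r}")
        self.orientation = "h" if orientation.startswith("h") else "v"
        self._children: list[LLItem] = []
        if children:
            self(*children)

    def __call__(self, *children: Optional[ElementLike]) -> "LinLayout":
        for c in children:
            self._children.append(normalize_child(c, context="lin_layout"))
        return self

    def children(self) -> list[Optional[Element]]:
        return list(self._children)

    @property
    def items(self) -> list[LLItem]:
        return self._children


class GridLayout(Element):
    """Arrange children on a grid of rows.

    ``rows`` is a list of lists of optional elements; ``None`` marks an
    empty cell, and ragged rows are padded with empty cells on the
    right.  Row heights and column widths default to equal shares and
    can be overridden with ``row_proportions`` / ``col_proportions``.
    Row heights never depend on cell content.
    """

    kind = "grid_layout"

    def __init__(
        self,
        rows: Sequence[Sequence[Optional[ElementLike]]],
        row_proportions: Optional[Sequence[float]] = None,
        col_proportions: Optional[Sequence[float]] = None,
    ):
        self.rows: list[list[Optional[Element]]] = [
            [None if c is None else _coerce(c) for c in row] for row in rows
        ]
        self.n_cols = max((len(r) for r in self.rows), default=0)
        if row_proportions is not None and len(row_proportions) != len(self.rows):
            raise ValueError(
                f"row_proportions has {len(row_proportions)} entries "
                f"for {len(self.rows)} rows"
            )
        if col_proportions is not None and len(col_proportions) != self.n_cols:
            raise ValueError(
                f"col_proportions has {len(col_proportions)} entries "
                f"for {self.n_cols} columns"
            )
        self.row_proportions = list(row_proportions) if row_proportions else None
        self.col_proportions = list(col_proportions) if col_proportions else None

    def children(self) -> list[Optional[Element]]:
        return [c for row in self.rows for c in row]


class Overlay(Element):
    """Draw children on top of each other; later children draw on top."""

    kind = "overlay"

    def __init__(self, *children: ElementLike):
        self._children = [_coerce(c) for c in children]

    def __call__(self, *children: ElementLike) -> "Overlay":
        self._children.extend(_coerce(c) for c in children)
        return self

    def children(self) -> list[Optional[Element]]:
        return list(self._children)


class Padding(_Wrapper):
    """Inset the child's area by per-side fractions of the outer rect."""

    kind = "padding"

    def __init__(
        self,
        left: float = 0.0,
        right: float = 0.0,
        top: float = 0.0,
        bottom: float = 0.0,
        child: Optional[ElementLike] = None,
    ):
        for name, f in (("left", left), ("right", right), ("top", top), ("bottom", bottom)):
            if not 0 <= f < 1:
                raise ValueError(f"Padding.{name} must be in [0, 1), got {f}")
        if left + right >= 1 or top + bottom >= 1:
            raise ValueError("opposing paddings must sum to < 1")
        super().__init__(child)
        self.left, self.right, self.top, self.bottom = left, right, top, bottom

    @classmethod
    def from_scale(cls, scale: float, child: Optional[ElementLike] = None) -> "Padding":
        """Symmetric padding leaving ``scale`` of each dimension for the child."""
        if not 0 < scale <= 1:
            raise ValueError(f"scale must be in (0, 1], got {scale}")
        p = (1 - scale) / 2
        return cls(p, p, p, p, child)


class Border(_Wrapper):
    """Draw a stroke just inside the area edges, over the child.

    The child keeps the full area; the stroke is painted on top after
    the child renders, so a bordered box occupies exactly the rect it
    was assigned.
    """

    kind = "border"

    def __init__(self, color: Color = BLACK, width: int = 1, child: Optional[ElementLike] = None):
        if width < 1:
            raise ValueError(f"border width must be >= 1, got {width}")
        super().__init__(child)
        self.color = parse_color(color)
        self.width = width


class Fill(_Wrapper):
    """Fill the area with a color; childless, it is the rectangle primitive."""

    kind = "fill"

    def __init__(self, color: Union[str, Color], child: Optional[ElementLike] = None):
        super().__init__(child)
        self.color = parse_color(color)


class RectangleShaper(_Wrapper):
    """Reduce the area to the biggest rect with the given side proportions."""

    kind = "rectangle_shaper"

    def __init__(
        self, prop_w: float = 1, prop_h: float = 1, child: Optional[ElementLike] = None
    ):
        if prop_w <= 0 or prop_h <= 0:
            raise ValueError(f"proportions must be > 0, got {prop_w}:{prop_h}")
        super().__init__(child)
        self.prop_w = prop_w
        self.prop_h = prop_h


class ImageElement(Element):
    """A raster image stimulus.

    By default the image is scaled *down* to the biggest rect that fits
    the available space without distortion; if the space is larger than
    the image it is centered but not upscaled.  Scaling uses
    area-averaging unless ``smooth_scale`` is false (nearest-neighbor).
    """

    kind = "image"

    def __init__(
        self,
        pixels: Union[np.ndarray, PixelBuffer],
        allow_upscale: bool = False,
        smooth_scale: bool = True,
    ):
        arr = pixels.array if isinstance(pixels, PixelBuffer) else np.asarray(pixels)
        if arr.size == 0:
            raise ValueError("image must be non-empty")
        self.pixels = arr
        self.allow_upscale = allow_upscale
        self.smooth_scale = smooth_scale

    @property
    def content_size(self) -> tuple[int, int]:
        h, w = self.pixels.shape[:2]
        return (w, h)


class MouseArea(_Wrapper):
    """Give all space to the child and expose the assigned rect for mouse dispatch.

    ``callback(event, rect)`` is invoked by the events module when a
    mouse event falls inside the rect this node received during the
    last compose.  When areas overlap, the last-composed (topmost) one
    wins.
    """

    kind = "mouse_area"

    def __init__(self, callback: Callable, child: Optional[ElementLike] = None):
        super().__init__(child)
        self.callback = callback
        self.assigned_rect: Optional[Rect] = None


class Text(Element):
    """Multi-line text, rendered at a fixed size and clipped (never rescaled)."""

    kind = "text"

    def __init__(
        self,
        content: str,
        font_size: int = 32,
        bold: bool = False,
        color: Union[str, Color] = BLACK,
        align: str = "center",
    ):
        if font_size <= 0:
            raise ValueError(f"font_size must be > 0, got {font_size}")
        if align not in ("left", "center", "right"):
            raise ValueError(f"align must be left/center/right, got {align!r}")
        self.content = content
        self.font_size = font_size
        self.bold = bold
        self.color = parse_color(color)
        self.align = align


class Circle(Element):
    """Largest circle centered in the area; filled by default."""

    kind = "circle"

    def __init__(self, color: Union[str, Color] = BLACK, stroke: int = 1, filled: bool = True):
        if stroke < 1:
            raise ValueError(f"stroke must be >= 1, got {stroke}")
        self.color = parse_color(color)
        self.stroke = stroke
        self.filled = filled


class Cross(Element):
    """Two centered strokes spanning the full width and height."""

    kind = "cross"

    def __init__(self, color: Union[str, Color] = BLACK, stroke: int = 1):
        if stroke < 1:
            raise ValueError(f"stroke must be >= 1, got {stroke}")
        self.color = parse_color(color)
        self.stroke = stroke


class Line(Element):
    """A centered stroke spanning the area along one orientation."""

    kind = "line"

    def __init__(self, orientation: str, color: Union[str, Color] = BLACK, stroke: int = 1):
        if orientation not in ("h", "v", "horizontal", "vertical"):
            raise ValueError(f"orientation must be 'h' or 'v', got {orientation!r}")
        if stroke < 1:
            raise ValueError(f"stroke must be >= 1, got {stroke}")
        self.orientation = "h" if orientation.startswith("h") else "v"
        self.color = parse_color(color)
        self.stroke = stroke


# ---------------------------------------------------------------------------
# trace
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceEntry:
    path: str
    kind: str
    rect: Rect


@dataclass
class LayoutTrace:
    """Rect assigned to every composed node, in draw order.

    ``path`` strings are slash-separated child indices from the root
    (the root itself is ``"/"``).  ``mouse_areas`` lists the
    :class:`MouseArea` nodes with their rects in compose order, so the
    last entry is topmost.
    """

    entries: list[TraceEntry] = field(default_factory=list)
    mouse_areas: list[tuple[MouseArea, Rect]] = field(default_factory=list)

    def add(self, path: str, kind: str, rect: Rect) -> None:
        self.entries.append(TraceEntry(path, kind, rect))

    def rect_of(self, path: str) -> Rect:
        for e in self.entries:
            if e.path == path:
                return e.rect
        raise KeyError(f"no trace entry at path {path!r}")

    def find(self, kind: str) -> list[TraceEntry]:
        return [e for e in self.entries if e.kind == kind]

    def children_of(self, path: str) -> list[TraceEntry]:
        """Direct children of the node at ``path``, in draw order."""
        prefix = path.rstrip("/")
        return [
            e
            for e in self.entries
            if e.path != path
            and e.path.startswith(prefix + "/")
            and e.path[len(prefix) + 1 :]
            and "/" not in e.path[len(prefix) + 1 :]
        ]

    def to_json(self) -> str:
        return json.dumps(
            [
                {"path": e.path, "kind": e.kind, "rect": list(e.rect.as_tuple())}
                for e in self.entries
            ],
            indent=1,
        )


# ---------------------------------------------------------------------------
# normalization and compose
# ---------------------------------------------------------------------------


def normalize_child(
    raw: Optional[ElementLike], context: str = "generic"
) -> Optional[Element]:
    """Coerce a raw child into an Element per the context's rules.

    Images become :class:`ImageElement`; in a ``lin_layout`` context any
    non-``LLItem`` child (including ``None``) is wrapped in a weight-1
    :class:`LLItem`.  In other contexts ``None`` stays ``None`` (an
    empty cell).
    """
    if context == "lin_layout":
        if raw is None:
            return LLItem(1)
        el = _coerce(raw)
        return el if isinstance(el, LLItem) else LLItem(1, el)
    if raw is None:
        return None
    return _coerce(raw)


def _validate_tree(root: Element) -> None:
    seen: set[int] = set()

    def walk(node: Element, path: str) -> None:
        if id(node) in seen:
            raise CompositionError(f"node at {path!r} appears more than once in the tree")
        seen.add(id(node))
        for i, child in enumerate(node.children()):
            if child is not None:
                walk(child, f"{path.rstrip('/')}/{i}")

    walk(root, "/")


def compose(
    root: Optional[ElementLike], target: PixelBuffer | Canvas, area: Optional[Rect] = None
) -> LayoutTrace:
    """Render a tree into ``target`` and return the geometry trace.

    ``root`` may be an :class:`Element`, a raw image array (auto-wrapped),
    or ``None`` (nothing drawn, empty trace).  The root receives the full
    target rect (or ``area`` if given).  The pass is deterministic: the
    same tree composed at the same size produces identical pixels and an
    identical trace.
    """
    trace = LayoutTrace()
    if root is None:
        return trace
    element = _coerce(root)
    _validate_tree(element)
    w, h = target.size
    outer = area if area is not None else Rect(0, 0, w, h)
    if outer.w <= 0 or outer.h <= 0:
        raise ValueError("target area must be non-empty")
    _render(element, outer, "/", target, trace)
    return trace


def _render(node: Element, rect: Rect, path: str, canvas: Canvas, trace: LayoutTrace) -> None:
    trace.add(path, node.kind, rect)
    if rect.w == 0 or rect.h == 0:
        return

    def child_path(i: int) -> str:
        return f"{path.rstrip('/')}/{i}"

    if isinstance(node, LinLayout):
        items = node.items
        if not items:
            return
        weights = [it.relative_size for it in items]
        if sum(weights) <= 0:
            raise CompositionError(f"lin_layout at {path!r} has all-zero proportions")
        horizontal = node.orientation == "h"
        segments = split_interval(rect.w if horizontal else rect.h, weights)
        offset = rect.x if horizontal else rect.y
        for i, (item, seg) in enumerate(zip(items, segments)):
            cell = (
                Rect(offset, rect.y, seg, rect.h)
                if horizontal
                else Rect(rect.x, offset, rect.w, seg)
            )
            _render(item, cell, child_path(i), canvas, trace)
            offset += seg
    elif isinstance(node, GridLayout):
        if not node.rows or node.n_cols == 0:
            return
        row_w = node.row_proportions or [1] * len(node.rows)
        col_w = node.col_proportions or [1] * node.n_cols
        heights = split_interval(rect.h, row_w)
        widths = split_interval(rect.w, col_w)
        y = rect.y
        idx = 0
        for r, row in enumerate(node.rows):
            x = rect.x
            for c in range(node.n_cols):
                cell = row[c] if c < len(row) else None
                if cell is not None:
                    _render(
                        cell, Rect(x, y, widths[c], heights[r]), child_path(idx), canvas, trace
                    )
                x += widths[c]
                idx += 1
            y += heights[r]
    elif isinstance(node, Overlay):
        for i, child in enumerate(node.children()):
            _render(child, rect, child_path(i), canvas, trace)
    elif isinstance(node, LLItem):
        if node.child is not None:
            _render(node.child, rect, child_path(0), canvas, trace)
    elif isinstance(node, Padding):
        inner = inset_fractional(rect, node.left, node.right, node.top, node.bottom)
        if node.child is not None:
            _render(node.child, inner, child_path(0), canvas, trace)
    elif isinstance(node, RectangleShaper):
        inner = aspect_rect(node.prop_w, node.prop_h, rect)
        if node.child is not None:
            _render(node.child, inner, child_path(0), canvas, trace)
    elif isinstance(node, Border):
        if node.child is not None:
            _render(node.child, rect, child_path(0), canvas, trace)
        w = min(node.width, rect.w, rect.h)
        canvas.fill_rect(Rect(rect.x, rect.y, rect.w, w), node.color)
        canvas.fill_rect(Rect(rect.x, rect.bottom - w, rect.w, w), node.color)
        canvas.fill_rect(Rect(rect.x, rect.y, w, rect.h), node.color)
        canvas.fill_rect(Rect(rect.right - w, rect.y, w, rect.h), node.color)
    elif isinstance(node, Fill):
        canvas.fill_rect(rect, node.color)
        if node.child is not None:
            _render(node.child, rect, child_path(0), canvas, trace)
    elif isinstance(node, ImageElement):
        cw, ch = node.content_size
        dest = fit_rect(cw, ch, rect, allow_upscale=node.allow_upscale)
        if dest.w and dest.h:
            canvas.blit_scaled(node.pixels, dest, smooth=node.smooth_scale)
    elif isinstance(node, MouseArea):
        node.assigned_rect = rect
        trace.mouse_areas.append((node, rect))
        if node.child is not None:
            _render(node.child, rect, child_path(0), canvas, trace)
    elif isinstance(node, Text):
        _draw_text(node, rect, canvas)
    elif isinstance(node, Circle):
        radius = min(rect.w, rect.h) // 2
        cx = rect.x + rect.w // 2
        cy = rect.y + rect.h // 2
        canvas.draw_circle(cx, cy, radius, node.color, stroke=0 if node.filled else node.stroke)
    elif isinstance(node, Cross):
        _stroke_line(canvas, rect, "h", node.stroke, node.color)
        _stroke_line(canvas, rect, "v", node.stroke, node.color)
    elif isinstance(node, Line):
        _stroke_line(canvas, rect, node.orientation, node.stroke, node.color)
    else:
        raise CompositionError(f"unknown element kind {node.kind!r} at {path!r}")


def _stroke_line(canvas: Canvas, rect: Rect, orientation: str, stroke: int, color: Color) -> None:
    # stroke centering rounds half up: a 1 px line in an even-height area
    # sits on the lower-middle row
    if orientation == "h":
        s = min(stroke, rect.h)
        y = rect.y + (rect.h - s + 1) // 2
        canvas.fill_rect(Rect(rect.x, y, rect.w, s), color)
    else:
        s = min(stroke, rect.w)
        x = rect.x + (rect.w - s + 1) // 2
        canvas.fill_rect(Rect(x, rect.y, s, rect.h), color)


def _draw_text(node: Text, rect: Rect, canvas: Canvas) -> None:
    lines = node.content.split("\n")
    if node.content == "":
        return
    _, line_h = canvas.measure_text("", node.font_size, node.bold)
    block_h = line_h * len(lines)
    top = rect.y + (rect.h - block_h) // 2
    for i, line in enumerate(lines):
        line_w, _ = canvas.measure_text(line, node.font_size, node.bold)
        if node.align == "left":
            x = rect.x
        elif node.align == "right":
            x = rect.right - line_w
        else:
            x = rect.x + (rect.w - line_w) // 2
        canvas.draw_text_line(
            line, x, top + i * line_h, node.font_size, node.color, node.bold, clip=rect
        )
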