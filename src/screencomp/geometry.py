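"""Integer-pixel rectangle arithmetic.

Every layout decision in the composition pass reduces to one of the
operations in this module: splitting an interval proportionally,
insetting a rectangle by fractional margins, or fitting one rectangle
into another while preserving aspect ratio.  All results are integer
pixels; rectangles are half-open (a rect covers pixel columns
``[x, x + w)`` and rows ``[y, y + h)``) with the origin at the top-left
corner and y growing downwards.

Rounding rules
--------------
* Interval splitting uses cumulative-boundary rounding (round half up on
  the running boundary), which conserves the total length exactly;
  rounding each segment independently is deliberately not offered
  because it can create or lose pixels.
* Centering places any odd leftover pixel on the right/bottom side
  (offset = ``excess // 2``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

__all__ = [
    "Rect",
    "round_half_up",
    "split_interval",
    "inset_fractional",
    "fit_rect",
    "aspect_rect",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero towards +inf."""
    return math.floor(x + 0.5)


def center_offset(excess: int) -> int:
    """Offset that centers a span, leaving odd leftover on the far side."""
    return excess // 2


@dataclass(frozen=True, order=True)
class Rect:
    """Half-open integer pixel rectangle ``[x, x+w) x [y, y+h)``."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        for name in ("x", "y", "w", "h"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"Rect.{name} must be an int, got {v!r}")
        if self.w < 0 or self.h < 0:
            raise ValueError(f"Rect dimensions must be >= 0, got w={self.w} h={self.h}")

    @property
    def right(self) -> int:
        return self.x + self.w

    @property
    def bottom(self) -> int:
        return self.y + self.h

    @property
    def size(self) -> tuple[int, int]:
        return (self.w, self.h)

    @property
    def area(self) -> int:
        return self.w * self.h

    def contains_point(self, px: int, py: int) -> bool:
        """Half-open containment: the right/bottom edges are outside."""
        return self.x <= px < self.right and self.y <= py < self.bottom

    def contains_rect(self, other: "Rect") -> bool:
        return (
            self.x <= other.x
            and self.y <= other.y
            and other.right <= self.right
            and other.bottom <= self.bottom
        )

    def intersect(self, other: "Rect") -> "Rect":
        x = max(self.x, other.x)
        y = max(self.y, other.y)
        r = min(self.right, other.right)
        b = min(self.bottom, other.bottom)
        return Rect(x, y, max(0, r - x), max(0, b - y))

    def inset(self, amount: int) -> "Rect":
        """Shrink by ``amount`` integer pixels on every side (floor at 0)."""
        w = max(0, self.w - 2 * amount)
        h = max(0, self.h - 2 * amount)
        return Rect(self.x + amount, self.y + amount, w, h)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x, self.y, self.w, self.h)

    def __iter__(self) -> Iterator[int]:
        return iter(self.as_tuple())


def split_interval(length: int, weights: Sequence[float]) -> list[int]:
    """Divide ``length`` pixels into segments proportional to ``weights``.

    Boundary ``k`` is placed at ``round_half_up(length * sum(w[:k]) / sum(w))``;
    segment ``i`` is the difference of consecutive boundaries.  Segments
    always sum to ``length`` exactly and each is within one pixel of its
    exact proportional share.

    Raises
    ------
    ValueError
        If ``length`` is negative, any weight is negative, or all weights
        are zero.
    """
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    weights = list(weights)
    if not weights:
        raise ValueError("weights must be non-empty")
    if any(w < 0 for w in weights):
        raise ValueError(f"weights must be >= 0, got {weights}")
    total = sum(weights)
    if total <= 0:
        raise ValueError("at least one weight must be > 0")
    boundaries = [0]
    acc = 0.0
    for w in weights:
        acc += w
        boundaries.append(round_half_up(length * acc / total))
    # guard against float noise on the last boundary
    boundaries[-1] = length
    return [boundaries[i + 1] - boundaries[i] for i in range(len(weights))]


def inset_fractional(
    outer: Rect, left: float, right: float, top: float, bottom: float
) -> Rect:
    """Shrink ``outer`` by per-side fractions of its own size.

    The left offset is ``round_half_up(left * w)`` and the new width is
    ``round_half_up((1 - left - right) * w)``, clamped so the result
    stays inside ``outer``; vertically analogous.
    """
    for name, f in (("left", left), ("right", right), ("top", top), ("bottom", bottom)):
        if not (0 <= f < 1):
            raise ValueError(f"{name} fraction must be in [0, 1), got {f}")
    if left + right >= 1:
        raise ValueError(f"left + right must be < 1, got {left + right}")
    if top + bottom >= 1:
        raise ValueError(f"top + bottom must be < 1, got {top + bottom}")
    dx = round_half_up(left * outer.w)
    dy = round_half_up(top * outer.h)
    w = min(round_half_up((1 - left - right) * outer.w), outer.w - dx)
    h = min(round_half_up((1 - top - bottom) * outer.h), outer.h - dy)
    return Rect(outer.x + dx, outer.y + dy, w, h)


def fit_rect(content_w: int, content_h: int, outer: Rect, allow_upscale: bool = False) -> Rect:
    """Largest centered rect inside ``outer`` with the content's aspect ratio.

    The scale factor is ``min(outer.w / content_w, outer.h / content_h)``,
    additionally capped at 1 when ``allow_upscale`` is false, so content
    is shrunk to fit but never enlarged by default.
    """
    if content_w <= 0 or content_h <= 0:
        raise ValueError(
            f"content dimensions must be > 0, got {content_w}x{content_h}"
        )
    if outer.w == 0 or outer.h == 0:
        return Rect(outer.x, outer.y, 0, 0)
    s = min(outer.w / content_w, outer.h / content_h)
    if not allow_upscale:
        s = min(s, 1.0)
    w = min(round_half_up(s * content_w), outer.w)
    h = min(round_half_up(s * content_h), outer.h)
    return Rect(
        outer.x + center_offset(outer.w - w),
        outer.y + center_offset(outer.h - h),
        w,
        h,
    )


def aspect_rect(prop_w: float, prop_h: float, outer: Rect) -> Rect:
    """Largest centered rect in ``outer`` with side proportions ``prop_w:prop_h``."""
    if prop_w <= 0 or prop_h <= 0:
        raise ValueError(f"proportions must be > 0, got {prop_w}:{prop_h}")
    if outer.w == 0 or outer.h == 0:
        return Rect(outer.x, outer.y, 0, 0)
    s = min(outer.w / prop_w, outer.h / prop_h)
    w = min(round_half_up(s * prop_w), outer.w)
    h = min(round_half_up(s * prop_h), outer.h)
    return Rect(
        outer.x + center_offset(outer.w - w),
        outer.y + center_offset(outer.h - h),
        w,
        h,
    )
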