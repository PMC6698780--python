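"""Drawing backends.

The composition pass talks to an abstract canvas that exposes a handful
of raster operations: rectangle fill, scaled image blit, circle, and
glyph-run rendering plus text measurement.  Two implementations exist:

* :class:`PixelBuffer` — an off-screen numpy RGB raster.  Fully
  deterministic: the same draw calls always produce byte-identical
  pixels on every platform.  Text uses a synthetic fixed-advance font
  (glyph advance ``ceil(0.6 * font_size)``, line height
  ``round_half_up(1.2 * font_size)``) so geometry traces and rendered
  buffers are stable in tests.
* a windowed adapter (see :mod:`screencomp.runtime`) that forwards the
  same contract to a real window; it requires the optional ``pygame``
  dependency and is never used by the test suite.
"""

from __future__ import annotations

import hashlib
import math
from abc import ABC, abstractmethod
from typing import Sequence

import numpy as np
from PIL import Image

from .geometry import Rect, round_half_up

__all__ = ["Canvas", "PixelBuffer", "text_metrics"]

ColorTuple = tuple[int, int, int]


def text_metrics(text: str, font_size: int) -> tuple[int, int]:
    """(width, line height) of a single line under the synthetic font."""
    advance = math.ceil(0.6 * font_size)
    line_h = round_half_up(1.2 * font_size)
    return len(text) * advance, line_h


class Canvas(ABC):
    """Contract between the composition pass and a drawing surface."""

    @property
    @abstractmethod
    def size(self) -> tuple[int, int]:
        """(width, height) in pixels."""

    @abstractmethod
    def fill_rect(self, rect: Rect, color: ColorTuple) -> None: ...

    @abstractmethod
    def blit_scaled(self, image: np.ndarray, rect: Rect, smooth: bool = True) -> None: ...

    @abstractmethod
    def draw_circle(
        self, cx: int, cy: int, radius: int, color: ColorTuple, stroke: int = 0
    ) -> None:
        """Draw a circle centered at (cx, cy); ``stroke`` 0 means filled."""

    @abstractmethod
    def measure_text(self, text: str, font_size: int, bold: bool = False) -> tuple[int, int]: ...

    @abstractmethod
    def draw_text_line(
        self,
        text: str,
        x: int,
        y: int,
        font_size: int,
        color: ColorTuple,
        bold: bool = False,
        clip: Rect | None = None,
    ) -> None:
        """Render one line of text with its top-left corner at (x, y)."""


def _as_rgb_array(image: np.ndarray) -> np.ndarray:
    """Coerce an image array to HxWx3 uint8."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"expected HxW or HxWx3 image array, got shape {arr.shape}")
    return np.ascontiguousarray(arr[:, :, :3], dtype=np.uint8)


class PixelBuffer(Canvas):
    """Deterministic off-screen RGB raster backed by a numpy array."""

    def __init__(self, width: int, height: int, fill: ColorTuple = (255, 255, 255)):
        if width <= 0 or height <= 0:
            raise ValueError(f"buffer size must be positive, got {width}x{height}")
        self._array = np.empty((height, width, 3), dtype=np.uint8)
        self._array[:, :] = fill

    @classmethod
    def from_array(cls, image: np.ndarray) -> "PixelBuffer":
        arr = _as_rgb_array(image)
        buf = cls.__new__(cls)
        buf._array = arr.copy()
        return buf

    # -- inspection -------------------------------------------------------

    @property
    def array(self) -> np.ndarray:
        return self._array

    @property
    def size(self) -> tuple[int, int]:
        h, w = self._array.shape[:2]
        return (w, h)

    @property
    def width(self) -> int:
        return self._array.shape[1]

    @property
    def height(self) -> int:
        return self._array.shape[0]

    def digest(self) -> str:
        """SHA-256 of the raw pixel bytes; equal buffers hash equal."""
        return hashlib.sha256(self._array.tobytes()).hexdigest()

    def pixel(self, x: int, y: int) -> ColorTuple:
        r, g, b = self._array[y, x]
        return (int(r), int(g), int(b))

    def to_image(self) -> Image.Image:
        return Image.fromarray(self._array, mode="RGB")

    def save(self, path: str) -> None:
        self.to_image().save(path)

    def copy(self) -> "PixelBuffer":
        return PixelBuffer.from_array(self._array)

    # -- drawing ----------------------------------------------------------

    def _clip(self, rect: Rect) -> Rect:
        return rect.intersect(Rect(0, 0, self.width, self.height))

    def fill_rect(self, rect: Rect, color: ColorTuple) -> None:
        r = self._clip(rect)
        if r.w and r.h:
            self._array[r.y : r.bottom, r.x : r.right] = color

    def blit_scaled(self, image: np.ndarray, rect: Rect, smooth: bool = True) -> None:
        r = self._clip(rect)
        if not (r.w and r.h):
            return
        src = _as_rgb_array(image)
        if src.shape[:2] != (rect.h, rect.w):
            resample = Image.Resampling.BOX if smooth else Image.Resampling.NEAREST
            src = np.asarray(
                Image.fromarray(src, mode="RGB").resize((rect.w, rect.h), resample)
            )
        # crop the portion of the scaled source that survived clipping
        sx, sy = r.x - rect.x, r.y - rect.y
        self._array[r.y : r.bottom, r.x : r.right] = src[sy : sy + r.h, sx : sx + r.w]

    def draw_circle(
        self, cx: int, cy: int, radius: int, color: ColorTuple, stroke: int = 0
    ) -> None:
        if radius <= 0:
            return
        box = self._clip(Rect(cx - radius, cy - radius, 2 * radius, 2 * radius))
        if not (box.w and box.h):
            return
        yy, xx = np.mgrid[box.y : box.bottom, box.x : box.right]
        # sample at pixel centers so the disk is symmetric
        d2 = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2
        mask = d2 <= radius**2
        if stroke > 0:
            inner = max(0, radius - stroke)
            mask &= d2 >= inner**2
        self._array[box.y : box.bottom, box.x : box.right][mask] = color

    def measure_text(self, text: str, font_size: int, bold: bool = False) -> tuple[int, int]:
        return text_metrics(text, font_size)

    def draw_text_line(
        self,
        text: str,
        x: int,
        y: int,
        font_size: int,
        color: ColorTuple,
        bold: bool = False,
        clip: Rect | None = None,
    ) -> None:
        advance = math.ceil(0.6 * font_size)
        line_h = round_half_up(1.2 * font_size)
        glyph_h = max(1, round_half_up(0.7 * font_size))
        glyph_w = max(1, advance - max(1, advance // 5))
        if bold:
            glyph_w = min(advance, glyph_w + 1)
        top = y + (line_h - glyph_h) // 2
        for i, ch in enumerate(text):
            if ch.isspace():
                continue
            box = Rect(x + i * advance, top, glyph_w, glyph_h)
            if clip is not None:
                box = box.intersect(clip)
            self.fill_rect(box, color)
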