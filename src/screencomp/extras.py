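"""Render 2D numeric arrays as image stimuli.

Useful for browsing slices of volumetric data or for stimuli generated
from a formula: a 2D scalar field is min-max normalized and mapped cell
by cell through a 256-entry palette into an RGB raster, which can then
be placed in a render tree like any other image.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .backend import PixelBuffer
from .composition import Color, ImageElement, parse_color

__all__ = [
    "normalize_field",
    "grayscale_palette",
    "matplotlib_palette",
    "field_to_image",
    "field_element",
    "read_matrix",
]


def _validate_field(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"field must be a non-empty 2D array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("field contains non-finite values")
    return arr


def normalize_field(values) -> np.ndarray:
    """Min-max normalize a 2D field into [0, 1]; a constant field maps to 0."""
    arr = _validate_field(values)
    lo = arr.min()
    hi = arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def grayscale_palette() -> list[Color]:
    """The built-in default palette: 256 levels black→white."""
    return [(i, i, i) for i in range(256)]


def matplotlib_palette(name: str) -> list[Color]:
    """Sample a matplotlib colormap into a 256-entry palette (adapter)."""
    import matplotlib

    cmap = matplotlib.colormaps[name]
    return [
        tuple(int(round(c * 255)) for c in cmap(i / 255.0)[:3])  # type: ignore[misc]
        for i in range(256)
    ]


def field_to_image(values, palette: Optional[Sequence[Union[str, Color]]] = None) -> PixelBuffer:
    """Map a 2D field through a 256-entry palette, one pixel per cell.

    Row ``i`` of the field becomes pixel row ``i`` (row 0 at the top);
    normalized value ``v`` selects ``palette[round(v * 255)]``.
    """
    if palette is None:
        palette = grayscale_palette()
    palette = [parse_color(c) for c in palette]
    if len(palette) != 256:
        raise ValueError(f"palette must have exactly 256 entries, got {len(palette)}")
    norm = normalize_field(values)
    idx = np.round(norm * 255).astype(np.uint8)
    lut = np.asarray(palette, dtype=np.uint8)
    return PixelBuffer.from_array(lut[idx])


def field_element(
    values,
    palette: Optional[Sequence[Union[str, Color]]] = None,
    allow_upscale: bool = True,
    smooth_scale: bool = False,
) -> ImageElement:
    """A render-tree element showing a scalar field (upscaled blockily by default)."""
    return ImageElement(
        field_to_image(values, palette=palette).array,
        allow_upscale=allow_upscale,
        smooth_scale=smooth_scale,
    )


def read_matrix(path) -> np.ndarray:
    """Read a whitespace-separated plain-text matrix (CLI helper)."""
    arr = np.loadtxt(path, ndmin=2)
    return arr
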