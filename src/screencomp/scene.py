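"""JSON scene dialect.

A small declarative encoding of render trees for the CLI, 1:1 with the
element kinds::

    {"kind": "lin_layout", "orientation": "h", "children": [
        {"kind": "fill", "color": "#FF0000"},
        {"kind": "text", "content": "hello", "font_size": 40}
    ]}

Colors are ``"#RRGGBB"`` strings; images reference a PNG/BMP file via
``"path"``.  Errors name the offending node path.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
from PIL import Image

from .composition import (
    Border,
    Circle,
    Cross,
    Element,
    Fill,
    GridLayout,
    ImageElement,
    Line,
    LinLayout,
    LLItem,
    Overlay,
    Padding,
    RectangleShaper,
    Text,
)

__all__ = ["SceneError", "load_scene", "parse_scene"]


class SceneError(ValueError):
    """A malformed scene node; the message names the node path."""


def load_image(path: str) -> np.ndarray:
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def parse_scene(node: dict, path: str = "/") -> Element:
    """Turn a scene-dialect dict into an element tree."""
    if not isinstance(node, dict):
        raise SceneError(f"node at {path!r} must be an object, got {type(node).__name__}")
    kind = node.get("kind")
    children_raw = node.get("children", [])
    if not isinstance(children_raw, list):
        raise SceneError(f"'children' at {path!r} must be a list")
    children = [
        None if c is None else parse_scene(c, f"{path.rstrip('/')}/{i}")
        for i, c in enumerate(children_raw)
    ]

    def one_child(maximum: int = 1) -> Optional[Element]:
        if len(children) > maximum:
            raise SceneError(f"{kind} at {path!r} takes at most {maximum} child")
        return children[0] if children else None

    try:
        if kind == "lin_layout":
            return LinLayout(node.get("orientation", "h"), *children)
        if kind == "ll_item":
            return LLItem(node.get("relative_size", 1), one_child())
        if kind == "grid_layout":
            rows_spec = node.get("rows", [])
            rows = [
                [
                    None
                    if cell is None
                    else parse_scene(cell, f"{path.rstrip('/')}/{r}.{c}")
                    for c, cell in enumerate(row)
                ]
                for r, row in enumerate(rows_spec)
            ]
            return GridLayout(
                rows,
                row_proportions=node.get("row_proportions"),
                col_proportions=node.get("col_proportions"),
            )
        if kind == "overlay":
            return Overlay(*[c for c in children if c is not None])
        if kind == "padding":
            if "scale" in node:
                return Padding.from_scale(node["scale"], one_child())
            return Padding(
                node.get("left", 0.0),
                node.get("right", 0.0),
                node.get("top", 0.0),
                node.get("bottom", 0.0),
                one_child(),
            )
        if kind == "border":
            return Border(node.get("color", (0, 0, 0)), node.get("width", 1), one_child())
        if kind == "fill":
            return Fill(node["color"], one_child())
        if kind == "rectangle_shaper":
            return RectangleShaper(node.get("prop_w", 1), node.get("prop_h", 1), one_child())
        if kind == "image":
            return ImageElement(
                load_image(node["path"]),
                allow_upscale=node.get("allow_upscale", False),
                smooth_scale=node.get("smooth_scale", True),
            )
        if kind == "text":
            return Text(
                node["content"],
                font_size=node.get("font_size", 32),
                bold=node.get("bold", False),
                color=node.get("color", (0, 0, 0)),
                align=node.get("align", "center"),
            )
        if kind == "circle":
            return Circle(
                node.get("color", (0, 0, 0)),
                stroke=node.get("stroke", 1),
                filled=node.get("filled", True),
            )
        if kind == "cross":
            return Cross(node.get("color", (0, 0, 0)), stroke=node.get("stroke", 1))
        if kind == "line":
            return Line(
                node.get("orientation", "h"),
                node.get("color", (0, 0, 0)),
                stroke=node.get("stroke", 1),
            )
    except SceneError:
        raise
    except (KeyError, ValueError, TypeError, OSError) as exc:
        raise SceneError(f"invalid {kind} node at {path!r}: {exc}") from exc
    raise SceneError(f"unknown node kind {kind!r} at {path!r}")


def load_scene(path) -> Element:
    """Load a scene-dialect JSON file into an element tree."""
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SceneError(f"scene file is not valid JSON: {exc}") from exc
    return parse_scene(data)
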