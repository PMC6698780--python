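import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screencomp.backend import PixelBuffer
from screencomp.composition import (
    Border,
    Circle,
    CompositionError,
    Cross,
    Fill,
    GridLayout,
    ImageElement,
    Line,
    LinLayout,
    LLItem,
    MouseArea,
    Overlay,
    Padding,
    RectangleShaper,
    Text,
    compose,
    normalize_child,
    parse_color,
)
from screencomp.geometry import Rect

RED = (255, 0, 0)
GREEN = (0, 255, 0)
BLUE = (0, 0, 255)


def colored_mask(buf: PixelBuffer, color) -> np.ndarray:
    return np.all(buf.array == np.array(color, dtype=np.uint8), axis=-1)


class TestParseColor:
    @pytest.mark.parametrize(
        "spec,expected",
        [
            ("#FF0000", (255, 0, 0)),
            ("#ffffff", (255, 255, 255)),
            ("#00Ff7f", (0, 255, 127)),
            ((0, 128, 255), (0, 128, 255)),
        ],
    )
    def test_valid(self, spec, expected):
        assert parse_color(spec) == expected

    @pytest.mark.parametrize(
        "bad", ["FF0000", "#FF00", "#GGGGGG", (1, 2), (0, 0, 256), (0, 0, -1), (0.5, 0, 0)]
    )
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            parse_color(bad)


class TestNormalizeChild:
    def test_image_auto_wrapped_in_lin_layout(self):
        img = np.zeros((30, 30, 3), dtype=np.uint8)
        item = normalize_child(img, context="lin_layout")
        assert isinstance(item, LLItem)
        assert item.relative_size == 1
        assert isinstance(item.child, ImageElement)

    def test_ll_item_passes_through(self):
        item = LLItem(2, Text("x"))
        assert normalize_child(item, context="lin_layout") is item

    def test_absent_becomes_spacer(self):
        item = normalize_child(None, context="lin_layout")
        assert isinstance(item, LLItem)
        assert item.child is None

    def test_absent_grid_cell_stays_absent(self):
        assert normalize_child(None, context="grid") is None

    def test_unsupported_kind_rejected(self):
        with pytest.raises(CompositionError):
            normalize_child(42, context="lin_layout")

    def test_plain_string_not_auto_wrapped(self):
        with pytest.raises(CompositionError):
            normalize_child("hello", context="lin_layout")


class TestCompose:
    def test_equal_split_horizontal(self):
        buf = PixelBuffer(100, 50)
        trace = compose(LinLayout("h")(Fill(RED), Fill(BLUE)), buf)
        cells = [e.rect for e in trace.entries if e.kind == "ll_item"]
        assert cells == [Rect(0, 0, 50, 50), Rect(50, 0, 50, 50)]
        assert buf.pixel(0, 0) == RED
        assert buf.pixel(99, 49) == BLUE

    def test_childless_fill_is_rectangle_primitive(self):
        buf = PixelBuffer(10, 10, fill=(0, 0, 0))
        trace = compose(Fill((255, 255, 255)), buf)
        assert len(trace.entries) == 1
        assert colored_mask(buf, (255, 255, 255)).all()

    def test_none_root_draws_nothing(self):
        buf = PixelBuffer(10, 10, fill=RED)
        trace = compose(None, buf)
        assert trace.entries == []
        assert colored_mask(buf, RED).all()

    def test_raw_array_root_auto_wrapped(self):
        img = np.full((5, 5, 3), 7, dtype=np.uint8)
        buf = PixelBuffer(5, 5)
        trace = compose(img, buf)
        assert trace.entries[0].kind == "image"
        assert (buf.array == 7).all()

    def test_overlay_draw_order(self):
        buf = PixelBuffer(20, 20)
        compose(Overlay(Fill(RED), Fill(BLUE)), buf)
        assert colored_mask(buf, BLUE).all()

    def test_duplicate_node_rejected_with_path(self):
        shared = Fill(RED)
        with pytest.raises(CompositionError, match="/1"):
            compose(LinLayout("h")(shared, shared), PixelBuffer(10, 10))

    def test_wrapper_second_child_rejected(self):
        with pytest.raises(CompositionError):
            Border()(Fill(RED))(Fill(BLUE))

    def test_empty_target_area_rejected(self):
        buf = PixelBuffer(10, 10)
        with pytest.raises(ValueError):
            compose(Fill(RED), buf, area=Rect(0, 0, 0, 10))

    def test_determinism_byte_identical(self):
        def build():
            return LinLayout("v")(
                Text("Sample\ntext", font_size=20),
                LLItem(2, Overlay(Fill((10, 20, 30)), Circle(RED))),
                Border(width=3)(Cross(BLUE, stroke=2)),
            )

        a, b = PixelBuffer(131, 77), PixelBuffer(131, 77)
        ta = compose(build(), a)
        tb = compose(build(), b)
        assert a.digest() == b.digest()
        assert ta.entries == tb.entries

    def test_trace_json_export(self):
        import json

        trace = compose(LinLayout("h")(Fill(RED)), PixelBuffer(10, 10))
        data = json.loads(trace.to_json())
        assert data[0] == {"path": "/", "kind": "lin_layout", "rect": [0, 0, 10, 10]}
        assert all(set(d) == {"path", "kind", "rect"} for d in data)


class TestLinLayoutProportions:
    def test_llitem_weights(self):
        buf = PixelBuffer(900, 30)
        trace = compose(LinLayout("h")(LLItem(2, Fill(RED)), LLItem(1, Fill(BLUE))), buf)
        cells = [e.rect for e in trace.entries if e.kind == "ll_item"]
        assert cells[0].w == 600 and cells[1].w == 300

    def test_empty_spacer_leaves_background(self):
        buf = PixelBuffer(90, 30, fill=GREEN)
        compose(LinLayout("h")(Fill(RED), LLItem(1), Fill(RED)), buf)
        assert colored_mask(buf, GREEN)[:, 30:60].all()
        assert not colored_mask(buf, GREEN)[:, :30].any()

    def test_all_zero_weights_rejected(self):
        tree = LinLayout("h")(LLItem(0), LLItem(0))
        with pytest.raises(CompositionError):
            compose(tree, PixelBuffer(10, 10))

    @given(
        weights=st.lists(st.integers(1, 9), min_size=1, max_size=6),
        w=st.integers(1, 800),
        h=st.integers(1, 60),
        horizontal=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_tiling_and_proportionality(self, weights, w, h, horizontal):
        layout = LinLayout("h" if horizontal else "v")(*[LLItem(wt) for wt in weights])
        trace = compose(layout, PixelBuffer(w, h))
        cells = [e.rect for e in trace.entries if e.kind == "ll_item"]
        total = sum(weights)
        length = w if horizontal else h
        spans = [(c.x, c.w) if horizontal else (c.y, c.h) for c in cells]
        # tiling: disjoint, gap-free, conserving
        cursor = 0
        for start, span in spans:
            assert start == cursor
            cursor += span
        assert cursor == length
        # proportionality within one pixel
        for (_, span), wt in zip(spans, weights):
            assert abs(span - length * wt / total) <= 1


class TestGridLayout:
    def test_ragged_rows_padded_right(self):
        buf = PixelBuffer(60, 40, fill=GREEN)
        grid = GridLayout([[Fill(RED), Fill(BLUE)], [Fill(BLUE)]])
        trace = compose(grid, buf)
        rects = [e.rect for e in trace.entries if e.kind == "fill"]
        assert rects == [Rect(0, 0, 30, 20), Rect(30, 0, 30, 20), Rect(0, 20, 30, 20)]
        # missing bottom-right cell untouched
        assert colored_mask(buf, GREEN)[20:, 30:].all()

    def test_row_heights_independent_of_content(self):
        tall_text = Text("x\n" * 40)
        g1 = GridLayout([[tall_text], [None]])
        g2 = GridLayout([[Fill(RED)], [None]])
        t1 = compose(g1, PixelBuffer(50, 90))
        t2 = compose(g2, PixelBuffer(50, 90))
        assert t1.entries[1].rect == t2.entries[1].rect == Rect(0, 0, 50, 45)

    def test_row_and_col_proportions(self):
        grid = GridLayout(
            [[Fill(RED), Fill(BLUE)], [Fill(GREEN), Fill(RED)]],
            row_proportions=[3, 1],
            col_proportions=[1, 1],
        )
        trace = compose(grid, PixelBuffer(100, 100))
        rects = [e.rect for e in trace.entries if e.kind == "fill"]
        assert rects[0] == Rect(0, 0, 50, 75)
        assert rects[3] == Rect(50, 75, 50, 25)

    def test_proportion_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            GridLayout([[None, None]], col_proportions=[1])
        with pytest.raises(ValueError):
            GridLayout([[None], [None]], row_proportions=[1, 2, 3])


class TestWrappers:
    def test_padding_from_scale(self):
        trace = compose(Padding.from_scale(0.8)(Fill(RED)), PixelBuffer(1000, 500))
        assert trace.entries[1].rect == Rect(100, 50, 800, 400)

    def test_padding_without_child_draws_nothing(self):
        buf = PixelBuffer(20, 20, fill=GREEN)
        compose(Padding(0.1, 0.1, 0.1, 0.1), buf)
        assert colored_mask(buf, GREEN).all()

    def test_rectangle_shaper_square(self):
        trace = compose(RectangleShaper()(Fill(RED)), PixelBuffer(200, 100))
        assert trace.entries[1].rect == Rect(50, 0, 100, 100)

    def test_border_stroke_inside_edges_over_child(self):
        buf = PixelBuffer(50, 50)
        trace = compose(Border((0, 0, 0), 2)(Fill(RED)), buf)
        # child keeps the full rect; stroke painted on top just inside it
        assert trace.entries[1].rect == Rect(0, 0, 50, 50)
        black = colored_mask(buf, (0, 0, 0))
        assert black[:2, :].all() and black[-2:, :].all()
        assert black[:, :2].all() and black[:, -2:].all()
        assert colored_mask(buf, RED)[2:-2, 2:-2].all()

    def test_border_without_child_draws_stroke_only(self):
        buf = PixelBuffer(10, 10, fill=GREEN)
        compose(Border((0, 0, 0), 1), buf)
        assert colored_mask(buf, (0, 0, 0))[0, :].all()
        assert colored_mask(buf, GREEN)[1:-1, 1:-1].all()

    def test_fill_with_child_is_background(self):
        buf = PixelBuffer(100, 100)
        compose(Fill(GREEN)(Padding.from_scale(0.5)(Fill(RED))), buf)
        assert buf.pixel(0, 0) == GREEN
        assert buf.pixel(50, 50) == RED

    def test_mouse_area_registers_rect(self):
        area = MouseArea(lambda e, r: None, child=Fill(RED))
        trace = compose(LinLayout("h")(LLItem(1), area), PixelBuffer(100, 40))
        assert area.assigned_rect == Rect(50, 0, 50, 40)
        assert trace.mouse_areas == [(area, Rect(50, 0, 50, 40))]


class TestPrimitives:
    def test_circle_diameter_is_min_dimension(self):
        buf = PixelBuffer(100, 60)
        compose(Circle(RED), buf)
        mask = colored_mask(buf, RED)
        ys, xs = np.where(mask)
        assert ys.min() == 0 and ys.max() == 59
        assert xs.min() == 20 and xs.max() == 79
        assert mask[30, 50]
        assert not mask[0, 0]

    def test_circle_outline(self):
        buf = PixelBuffer(60, 60)
        compose(Circle(RED, stroke=3, filled=False), buf)
        mask = colored_mask(buf, RED)
        assert mask.any()
        assert not mask[30, 30]

    def test_line_horizontal_centered_row(self):
        # stroke centering rounds half up: row y = 10 in a 20-high area
        buf = PixelBuffer(100, 20)
        compose(Line("h", RED, stroke=1), buf)
        mask = colored_mask(buf, RED)
        assert mask[10, :].all()
        assert mask.sum() == 100

    def test_line_vertical(self):
        buf = PixelBuffer(21, 50)
        compose(Line("v", RED, stroke=1), buf)
        mask = colored_mask(buf, RED)
        assert mask[:, 10].all()
        assert mask.sum() == 50

    def test_cross_spans_both_dimensions(self):
        buf = PixelBuffer(30, 40)
        compose(Cross(RED, stroke=2), buf)
        mask = colored_mask(buf, RED)
        ys, xs = np.where(mask)
        assert xs.min() == 0 and xs.max() == 29
        assert ys.min() == 0 and ys.max() == 39

    def test_image_no_upscale_centered_exact(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, size=(30, 30, 3), dtype=np.uint8)
        buf = PixelBuffer(100, 100, fill=GREEN)
        compose(ImageElement(img, smooth_scale=False), buf)
        np.testing.assert_array_equal(buf.array[35:65, 35:65], img)
        assert colored_mask(buf, GREEN)[:35, :].all()

    def test_image_downscale_preserves_aspect(self):
        img = np.zeros((100, 200, 3), dtype=np.uint8)
        buf = PixelBuffer(100, 100, fill=GREEN)
        compose(ImageElement(img), buf)
        mask = colored_mask(buf, (0, 0, 0))
        ys, xs = np.where(mask)
        assert xs.min() == 0 and xs.max() == 99
        assert ys.min() == 25 and ys.max() == 74

    def test_image_upscale_allowed(self):
        img = np.full((10, 10, 3), 9, dtype=np.uint8)
        buf = PixelBuffer(40, 40)
        compose(ImageElement(img, allow_upscale=True, smooth_scale=False), buf)
        assert (buf.array == 9).all()


class TestText:
    def test_left_align_starts_at_left_edge(self):
        buf = PixelBuffer(200, 100)
        compose(Text("ab", font_size=32, align="left", color=RED), buf)
        ys, xs = np.where(colored_mask(buf, RED))
        assert xs.min() == 0

    def test_center_align_block_centered(self):
        buf = PixelBuffer(200, 100)
        compose(Text("ab", font_size=32, color=RED), buf)
        ys, xs = np.where(colored_mask(buf, RED))
        # advance ceil(0.6*32)=20 -> line width 40, left offset (200-40)//2
        assert xs.min() == 80
        # line height round(1.2*32)=38, block top (100-38)//2=31
        assert 31 <= ys.min() < 31 + 38

    def test_right_align_ends_at_right_edge(self):
        buf = PixelBuffer(200, 100)
        compose(Text("abc", font_size=30, align="right", color=RED), buf)
        ys, xs = np.where(colored_mask(buf, RED))
        # last glyph box ends advance - glyph_w before the right edge
        assert xs.max() >= 200 - 18

    def test_two_lines_stack(self):
        one = PixelBuffer(200, 200)
        two = PixelBuffer(200, 200)
        compose(Text("a", font_size=32, color=RED), one)
        compose(Text("a\na", font_size=32, color=RED), two)
        assert colored_mask(two, RED).sum() == 2 * colored_mask(one, RED).sum()

    def test_overflow_clipped_not_rescaled(self):
        buf = PixelBuffer(30, 10)
        compose(Text("wwwwwwwwww", font_size=32, color=RED), buf)
        # drawing stayed within the buffer and the area; nothing crashed
        assert colored_mask(buf, RED).sum() <= 30 * 10

    def test_empty_string_draws_nothing(self):
        buf = PixelBuffer(50, 50, fill=GREEN)
        compose(Text("", color=RED), buf)
        assert colored_mask(buf, GREEN).all()

    def test_spaces_leave_gaps(self):
        buf = PixelBuffer(200, 60)
        compose(Text("a a", font_size=32, align="left", color=RED), buf)
        mask = colored_mask(buf, RED)
        assert not mask[:, 20:40].any()


# ---------------------------------------------------------------------------
# randomized whole-tree properties
# ---------------------------------------------------------------------------


@st.composite
def element_trees(draw, depth=0):
    primitives = st.sampled_from(["fill", "text", "circle", "cross", "line"])
    choices = ["fill", "text", "circle", "cross", "line"]
    if depth < 3:
        choices += ["lin", "overlay", "padding", "border", "shaper", "grid"]
    kind = draw(st.sampled_from(choices))
    color = draw(st.tuples(*[st.integers(0, 255)] * 3))
    if kind == "fill":
        return Fill(color)
    if kind == "text":
        return Text("xy", font_size=draw(st.integers(6, 40)), color=color)
    if kind == "circle":
        return Circle(color)
    if kind == "cross":
        return Cross(color)
    if kind == "line":
        return Line(draw(st.sampled_from(["h", "v"])), color)
    if kind == "lin":
        n = draw(st.integers(1, 3))
        items = [
            LLItem(draw(st.integers(1, 4)), draw(element_trees(depth + 1)))
            for _ in range(n)
        ]
        return LinLayout(draw(st.sampled_from(["h", "v"])), *items)
    if kind == "overlay":
        n = draw(st.integers(1, 2))
        return Overlay(*[draw(element_trees(depth + 1)) for _ in range(n)])
    if kind == "padding":
        return Padding.from_scale(draw(st.floats(0.3, 1.0)), draw(element_trees(depth + 1)))
    if kind == "border":
        return Border(color, draw(st.integers(1, 4)), draw(element_trees(depth + 1)))
    if kind == "shaper":
        return RectangleShaper(
            draw(st.integers(1, 4)), draw(st.integers(1, 4)), draw(element_trees(depth + 1))
        )
    if kind == "grid":
        rows = [
            [draw(element_trees(depth + 1)), None] for _ in range(draw(st.integers(1, 2)))
        ]
        return GridLayout(rows)
    raise AssertionError(kind)


@given(tree=element_trees(), w=st.integers(8, 160), h=st.integers(8, 160))
@settings(max_examples=120, deadline=None)
def test_trace_containment_property(tree, w, h):
    trace = compose(tree, PixelBuffer(w, h))
    rects = {e.path: e.rect for e in trace.entries}
    outer = Rect(0, 0, w, h)
    for path, rect in rects.items():
        assert outer.contains_rect(rect)
        if path != "/":
            parent = path.rsplit("/", 1)[0] or "/"
            # grid cell paths have no explicit parent entry for the cell slot
            if parent in rects:
                assert rects[parent].contains_rect(rect)


@given(tree=element_trees(), w=st.integers(8, 120), h=st.integers(8, 120))
@settings(max_examples=60, deadline=None)
def test_compose_determinism_property(tree, w, h):
    a, b = PixelBuffer(w, h), PixelBuffer(w, h)
    ta = compose(tree, a)
    tb = compose(tree, b)
    assert a.digest() == b.digest()
    assert ta.entries == tb.entries
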