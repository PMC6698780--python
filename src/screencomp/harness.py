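"""Session skeleton: example screens, trial blocks, and results output.

The three bundled example screens exercise the full layout vocabulary:

1. an inter-temporal choice screen — two bordered offer boxes, each
   padded to 80% of its half of the screen, with a bold amount over a
   delay caption;
2. a symbol-matching screen — an instruction line over a spaced row of
   two symbols, shifted upward by a trailing empty slot;
3. a color/key training screen — three equal rows: caption, training
   stimulus, and a color→key mapping strip.

:func:`run_block` drives a list of trials against an injected listener
and clock: compose + present the stimulus, record its onset, wait for a
response, record the reaction time, then idle through the inter-trial
interval.  By convention the last trial's ITI is zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, TextIO, Union

from .backend import PixelBuffer
from .composition import (
    Border,
    Circle,
    Color,
    Cross,
    Element,
    Fill,
    LinLayout,
    LLItem,
    Padding,
    RectangleShaper,
    Text,
    compose,
    parse_color,
)
from .events import TIMEOUT, Clock, EventListener, UserAbort
from .runtime import DisplayContext, display, empty_surface

__all__ = [
    "TrialSpec",
    "TrialRecord",
    "build_example",
    "example_offer_box",
    "run_block",
    "write_results",
    "read_results",
    "NA",
]

logger = logging.getLogger(__name__)

NA = "NA"


@dataclass(frozen=True)
class TrialSpec:
    """One stimulus-response cycle: what to show, which keys count, then wait."""

    stimulus: Element
    valid_keys: frozenset[str]
    iti: float = 0.0
    timeout: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.valid_keys:
            raise ValueError("valid_keys must be non-empty")
        if self.iti < 0:
            raise ValueError(f"iti must be >= 0, got {self.iti}")


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one trial; ``rt`` is absent iff the trial timed out."""

    block: int
    trial: int
    onset: float
    response: Optional[str]
    rt: Optional[float]


# ---------------------------------------------------------------------------
# example screens
# ---------------------------------------------------------------------------


def example_offer_box(amount: str, delay: str) -> Border:
    """A bordered box with a bold amount over a delay caption (2:1 heights)."""
    return Border()(
        LinLayout("v")(
            LLItem(2, Text(amount, font_size=50, bold=True)),
            LLItem(1, Text(delay, font_size=50)),
        )
    )


def _intertemporal_choice(
    left_amount: str = "10€",
    left_delay: str = "now",
    right_amount: str = "20€",
    right_delay: str = "in 30 days",
) -> Element:
    # two-way horizontal split; each side scaled down to 80% and filled
    # with an offer box
    return LinLayout("h")(
        Padding.from_scale(0.8)(example_offer_box(left_amount, left_delay)),
        Padding.from_scale(0.8)(example_offer_box(right_amount, right_delay)),
    )


def _symbol(name: str) -> Element:
    if name == "circle":
        return Circle()
    if name == "cross":
        return Cross(stroke=5)
    if name == "square":
        return RectangleShaper()(Fill((0, 0, 0)))
    raise ValueError(f"unknown symbol {name!r}")


def _symbol_match(
    left: str = "circle",
    right: str = "cross",
    instruction: str = "Press F if the symbols match, J otherwise",
) -> Element:
    # instruction row, then the symbol row with three empty slots for
    # spacing, then one trailing empty slot to shift everything upward
    return LinLayout("v")(
        Text(instruction),
        LinLayout("h")(
            LLItem(1),
            _symbol(left),
            LLItem(1),
            _symbol(right),
            LLItem(1),
        ),
        LLItem(1),
    )


DEFAULT_COLOR_KEYS: tuple[tuple[str, str, str], ...] = (
    ("red", "#FF0000", "d"),
    ("green", "#00FF00", "f"),
    ("blue", "#0000FF", "j"),
    ("yellow", "#FFFF00", "k"),
)


def _make_train_stim(mode: str, color_name: str, color: Color) -> Element:
    if mode == "color":
        return Padding.from_scale(0.5)(RectangleShaper()(Fill(color)))
    if mode == "text":
        return Text(color_name, font_size=50)
    raise ValueError(f"mode must be 'color' or 'text', got {mode!r}")


def _make_color_mapping(mappings: Sequence[tuple[str, str, str]]) -> Element:
    # one inner horizontal layout per color, with two empty slots on its
    # outsides; adjacent mappings therefore sit two empty slots apart
    columns = []
    for _, hex_color, key in mappings:
        columns.append(
            LinLayout("h")(
                LLItem(1),
                Text(key, font_size=40),
                RectangleShaper()(Fill(hex_color)),
                LLItem(1),
            )
        )
    return LinLayout("h")(*columns)


def _color_training(
    mode: str = "color",
    target: str = "green",
    mappings: Sequence[tuple[str, str, str]] = DEFAULT_COLOR_KEYS,
) -> Element:
    by_name = {name: (name, hex_color, key) for name, hex_color, key in mappings}
    if target not in by_name:
        raise ValueError(f"target color {target!r} not in mappings")
    name, hex_color, _ = by_name[target]
    # three vertically aligned items of equal size
    return LinLayout("v")(
        Text("target color:"),
        _make_train_stim(mode, name, parse_color(hex_color)),
        _make_color_mapping(mappings),
    )


def build_example(example_id: int, **params) -> Element:
    """Build one of the bundled example screens (1, 2, or 3)."""
    builders = {1: _intertemporal_choice, 2: _symbol_match, 3: _color_training}
    try:
        builder = builders[example_id]
    except KeyError:
        raise ValueError(f"unknown example id {example_id!r}; choose 1, 2, or 3") from None
    return builder(**params)


# ---------------------------------------------------------------------------
# block execution
# ---------------------------------------------------------------------------


def run_block(
    trials: Sequence[TrialSpec],
    listener: EventListener,
    clock: Optional[Clock] = None,
    context: Optional[DisplayContext] = None,
    block: int = 0,
    session_start: Optional[float] = None,
    background: Union[str, Color] = (255, 255, 255),
) -> list[TrialRecord]:
    """Execute a block of trials and return their records in order.

    Per trial: the stimulus is composed onto a fresh background and
    presented, the onset (seconds since ``session_start``) is stored,
    the listener waits for one of the trial's valid keys, the reaction
    time is stored, and the inter-trial interval is waited out.  A
    timed-out trial records the sentinel response and no reaction time.
    :class:`UserAbort` propagates, but records of completed trials are
    attached to the exception as ``partial_records``.
    """
    from .runtime import get_context

    clock = clock if clock is not None else listener.clock
    ctx = context if context is not None else get_context()
    if trials and trials[-1].iti != 0:
        warnings.warn(
            "the last trial's inter-trial interval should be 0", stacklevel=2
        )
    if session_start is None:
        session_start = clock.now()
    records: list[TrialRecord] = []
    try:
        for i, trial in enumerate(trials):
            frame = empty_surface(background, ctx.resolution)
            compose(trial.stimulus, frame)
            display(frame)
            onset_abs = clock.now()
            # timestamps are microsecond-resolution; rounding the
            # differences to 6 places removes float subtraction noise
            onset = round(onset_abs - session_start, 6)
            response = listener.wait_for_keys(trial.valid_keys, timeout=trial.timeout)
            if response is TIMEOUT:
                record = TrialRecord(block, i, onset, None, None)
            else:
                rt = round(clock.now() - onset_abs, 6)
                record = TrialRecord(block, i, onset, str(response), rt)
            records.append(record)
            logger.debug("trial %d: %s", i, record)
            listener.wait_for_seconds(trial.iti)
    except UserAbort as abort:
        abort.partial_records = records  # type: ignore[attr-defined]
        raise
    return records


def write_results(records: Sequence[TrialRecord], subject: str, path) -> None:
    """Write trial records as TSV: subject, block, trial, onset, response, rt.

    Onsets and reaction times are decimal seconds with 6 places; missing
    responses and reaction times are written as ``NA``.
    """

    def fmt(value: Optional[float]) -> str:
        return NA if value is None else f"{value:.6f}"

    def emit(fh: TextIO) -> None:
        fh.write("subject\tblock\ttrial\tonset\tresponse\trt\n")
        for r in records:
            response = NA if r.response is None else r.response
            fh.write(
                f"{subject}\t{r.block}\t{r.trial}\t{fmt(r.onset)}\t{response}\t{fmt(r.rt)}\n"
            )

    if hasattr(path, "write"):
        emit(path)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            emit(fh)


def read_results(path) -> list[tuple[str, TrialRecord]]:
    """Parse a results TSV back into (subject, record) pairs."""
    out: list[tuple[str, TrialRecord]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["subject", "block", "trial", "onset", "response", "rt"]
        if header != expected:
            raise ValueError(f"unexpected results header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            subject, block, trial, onset, response, rt = line.rstrip("\n").split("\t")
            out.append(
                (
                    subject,
                    TrialRecord(
                        int(block),
                        int(trial),
                        float(onset),
                        None if response == NA else response,
                        None if rt == NA else float(rt),
                    ),
                )
            )
    return out
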