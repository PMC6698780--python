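"""Display and session helpers.

One display context exists per process.  The headless backend renders
into an off-screen :class:`~screencomp.backend.PixelBuffer` and keeps a
log of content digests for every presented frame, which is how session
flow is asserted in tests.  The windowed backend needs the optional
``pygame`` dependency and presents to a real window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

from .backend import PixelBuffer
from .composition import Color, parse_color
from .events import UserAbort

__all__ = [
    "DisplayContext",
    "init",
    "shutdown",
    "get_context",
    "display",
    "empty_surface",
    "slide_show",
    "edit_buffer",
    "BACKSPACE",
    "RETURN_CHARS",
]

BACKSPACE = "\x08"
RETURN_CHARS = ("\r", "\n")


@dataclass
class DisplayContext:
    resolution: tuple[int, int]
    fullscreen: bool
    backend: str
    frame_log: list[str] = field(default_factory=list)
    captured_frames: list[PixelBuffer] = field(default_factory=list)
    capture_frames: bool = False
    _window: object = None


_context: Optional[DisplayContext] = None


def init(
    resolution: tuple[int, int],
    fullscreen: bool = False,
    backend: str = "headless",
    capture_frames: bool = False,
) -> DisplayContext:
    """Create the process-wide display context.

    ``backend`` is ``"headless"`` (off-screen, deterministic) or
    ``"windowed"`` (requires pygame).  Initializing twice without
    :func:`shutdown` is an error.
    """
    global _context
    if _context is not None:
        raise RuntimeError("display already initialized; call shutdown() first")
    w, h = resolution
    if w <= 0 or h <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    if backend not in ("headless", "windowed"):
        raise ValueError(f"unknown backend {backend!r}")
    ctx = DisplayContext(
        resolution=(int(w), int(h)),
        fullscreen=fullscreen,
        backend=backend,
        capture_frames=capture_frames,
    )
    if backend == "windowed":
        ctx._window = _open_window(ctx)
    _context = ctx
    return ctx


def _open_window(ctx: DisplayContext):
    try:
        import pygame
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RuntimeError(
            "the windowed backend requires the optional 'pygame' dependency "
            "(pip install screencomp[windowed])"
        ) from exc
    pygame.init()
    flags = pygame.FULLSCREEN if ctx.fullscreen else 0
    return pygame.display.set_mode(ctx.resolution, flags)


def shutdown() -> None:
    """Tear down the display context (idempotent)."""
    global _context
    if _context is not None and _context.backend == "windowed":  # pragma: no cover
        import pygame

        pygame.quit()
    _context = None


def get_context() -> DisplayContext:
    if _context is None:
        raise RuntimeError("display not initialized; call init() first")
    return _context


def display(buffer: PixelBuffer) -> None:
    """Present a buffer; its size must equal the display resolution."""
    ctx = get_context()
    if buffer.size != ctx.resolution:
        raise ValueError(
            f"buffer size {buffer.size} does not match display resolution {ctx.resolution}"
        )
    if ctx.backend == "headless":
        ctx.frame_log.append(buffer.digest())
        if ctx.capture_frames:
            ctx.captured_frames.append(buffer.copy())
    else:  # pragma: no cover - needs a real window
        import pygame

        surf = pygame.surfarray.make_surface(buffer.array.swapaxes(0, 1))
        ctx._window.blit(surf, (0, 0))
        pygame.display.flip()


def empty_surface(
    color: Union[str, Color], size: Optional[tuple[int, int]] = None
) -> PixelBuffer:
    """A buffer uniformly filled with ``color``; defaults to display size."""
    rgb = parse_color(color)
    if size is None:
        if _context is None:
            raise RuntimeError("empty_surface() without a size requires init() first")
        size = _context.resolution
    return PixelBuffer(size[0], size[1], fill=rgb)


def slide_show(frames: Sequence[PixelBuffer], proceed: Callable[[], object]) -> None:
    """Present frames in order, calling ``proceed()`` once after each.

    ``proceed`` blocks until the subject advances (e.g. waits for the
    return key).  A :class:`~screencomp.events.UserAbort` raised by
    ``proceed`` stops the show after the current frame and propagates.
    """
    if not frames:
        raise ValueError("slide_show needs at least one frame")
    for frame in frames:
        display(frame)
        try:
            proceed()
        except UserAbort:
            raise


def edit_buffer(text: str, ch: str) -> tuple[str, bool]:
    """Apply one typed character to a text-entry buffer.

    Backspace removes the last character (no-op on empty); carriage
    return or newline finishes entry (``done=True``, text unchanged);
    any other printable character (or space) is appended; remaining
    control characters are ignored.
    """
    if ch == BACKSPACE:
        return text[:-1], False
    if ch in RETURN_CHARS:
        return text, True
    if ch == " " or ch.isprintable():
        return text + ch, False
    return text, False
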