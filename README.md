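# screencomp

Declarative screen composition and response capture for behavioral
experiments.

A screen is described as a tree of **layouts** (`LinLayout`,
`GridLayout`, `Overlay`), **wrappers** (`Padding`, `Border`, `Fill`,
`RectangleShaper`, `ImageElement`, `MouseArea`) and **primitives**
(`Text`, `Circle`, `Cross`, `Line`; a childless `Fill` is a filled
rectangle). A deterministic compose pass assigns every node an integer
pixel rectangle, renders it, and records a *geometry trace* — so every
layout decision is testable headlessly, without a window.

```python
from screencomp import (
    LinLayout, LLItem, Padding, Border, Text, PixelBuffer, compose,
)

def offer(amount, delay):
    return Padding.from_scale(0.8)(
        Border()(
            LinLayout("v")(
                LLItem(2, Text(amount, font_size=50, bold=True)),
                LLItem(1, Text(delay, font_size=50)),
            )
        )
    )

buf = PixelBuffer(1000, 1000)
trace = compose(LinLayout("h")(offer("10€", "now"), offer("20€", "in 30 days")), buf)
buf.save("choice.png")
print(trace.find("border")[0].rect)   # Rect(x=50, y=100, w=400, h=800)
```

Companion modules:

* `screencomp.geometry` — integer-pixel interval splitting (exact
  conservation via cumulative-boundary rounding), fractional insetting,
  aspect-preserving fitting (images are scaled down, never up, by
  default).
* `screencomp.events` — poll-based input: `EventListener` with
  handler chains, `wait_for_keys` / `wait_for_unicode_char` /
  `wait_for_seconds`, timeouts, and mouse-area dispatch. Clock and
  event source are injected; `SimulatedClock` + `ScriptedEventSource`
  make every timing path deterministic.
* `screencomp.runtime` — display context (`init`, `display`,
  `empty_surface`, `slide_show`) and text-entry buffer editing. The
  headless backend logs a digest of every presented frame.
* `screencomp.extras` — 2D numeric arrays as images (min-max
  normalization through a 256-entry palette).
* `screencomp.harness` — three example screens, `run_block` (onsets,
  reaction times, inter-trial intervals), and TSV results output.

The optional *windowed* backend presents to a real window and needs
`pygame` (`pip install screencomp[windowed]`); nothing else requires it.

## CLI

```sh
# compose an example (1-3) or a JSON scene headlessly
screencomp render --example 1 --size 1000x1000 --out screen.png --trace trace.json
screencomp render --scene scene.json --size 800x600 --out screen.png

# replay a scripted event stream through a trial block -> results TSV
screencomp simulate-block --events events.jsonl --out results.tsv --trials 2 --iti 1.0

# windowed preview (requires pygame)
screencomp demo --example 3
```

Scene files are JSON: `{"kind": "lin_layout", "orientation": "v",
"children": [...]}` with colors as `"#RRGGBB"`. Scripted events are
JSON lines: `{"t": 0.25, "kind": "key_down", "key": "f"}`.

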