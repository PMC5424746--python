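"""Gesture vocabulary of the hand controller.

The controller recognises four hand gestures: open hand, power grasp
(closed hand), point index and precision grasp.  The open hand doubles as
the mechanical *reset* position every other gesture must start from, which
is why the control strategy can optionally drop it from the trained model
(REDUCED mode) and treat any contraction after an executed gesture as a
reset command.
"""

from __future__ import annotations

import enum


class Gesture(enum.IntEnum):
    """The four recognised hand gestures.

    Integer values are the class ids used in trained models; they also
    define the controller output codes (see :data:`output_code`): positive
    codes for gestures, -1 reserved for the reset / open-hand position.
    """

    OPEN_HAND = 0
    POWER_GRASP = 1
    POINT_INDEX = 2
    PRECISION_GRASP = 3

    @property
    def is_reset(self) -> bool:
        return self is Gesture.OPEN_HAND


#: Marker for the relaxed (no-gesture) state in labeled streams.  REST is
#: deliberately not a member of :class:`Gesture`: it is never classified and
#: never actuated.
REST = "REST"

#: Controller output codes (trace encoding): -1 is the reset position,
#: positive integers encode actuated gestures.
OUTPUT_CODES = {
    Gesture.OPEN_HAND: -1,
    Gesture.POWER_GRASP: 1,
    Gesture.POINT_INDEX: 2,
    Gesture.PRECISION_GRASP: 3,
}


def output_code(gesture: Gesture) -> int:
    """Trace code of an actuated gesture (-1 = reset/open)."""
    return OUTPUT_CODES[Gesture(gesture)]


def parse_label(text: str) -> "Gesture | str":
    """Parse a CSV label field into a :class:`Gesture` or :data:`REST`."""
    text = text.strip()
    if text == REST:
        return REST
    try:
        return Gesture[text]
    except KeyError:
        raise ValueError(f"unknown gesture label {text!r}") from None


MODE_COMPLETE = "COMPLETE"
MODE_REDUCED = "REDUCED"
MODES = (MODE_COMPLETE, MODE_REDUCED)


def validate_mode(mode: str) -> str:
    mode = str(mode).upper()
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    return mode
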