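"""Adaptive five-stage QRS detector operating on the scale-8 CWT stream.

A QRS complex appears in the CWT as a pair of opposite-polarity lobes with
a zero-crossing between them at the R (or S) peak.  The machine walks five
stages per beat:

1. wait for the first lobe: the input exceeding the positive threshold
   memory flags a possible negative-polarity QRS (``qrs_n = 1``); dropping
   below the negative memory keeps ``qrs_n = 0``;
2. track the first lobe with the 0.75 rule (the memory follows
   ``0.75 * w`` whenever that is more extreme) and detect the
   zero-crossing, which is the R event: the RR counter value is emitted
   and both the RR and RT counters restart;
3. wait for the opposite lobe to exceed its memory;
4. track it with the 0.75 rule and detect the second zero-crossing;
5. hold for 40 ms before handing control to the T-end search.

Both threshold memories start at zero, so the first minutes of a recording
are spent learning the signal's lobe amplitudes; events in the first 60 s
are emitted but flagged unreliable.  If the machine waits more than 3 s for
a lobe (e.g. after a noise spike inflated the memories), the memories are
halved once per further second and the machine returns to stage 1, so a
drying electrode or a transient artifact can never lock the detector out
permanently.

All durations are configurable and converted to samples via the sampling
rate.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["QRSDetector", "REvent", "update_threshold"]


@dataclass(frozen=True)
class REvent:
    """One detected R (or S) peak."""

    sample_index: int
    rr_samples: int
    polarity: str  # "positive" or "negative"
    reliable: bool


def update_threshold(mem: float, w: float, direction: str) -> float:
    """Apply the 0.75 adaptation rule to one threshold memory.

    For ``direction="max"`` returns ``max(mem, 0.75*w)``; for ``"min"``
    the mirror image.  The memory therefore tracks three quarters of the
    most extreme lobe value seen, which is what makes the detector immune
    to slow amplitude drift.
    """
    if direction == "max":
        return max(mem, 0.75 * w)
    if direction == "min":
        return min(mem, 0.75 * w)
    raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")


def _crossed(prev: float, w: float) -> bool:
    """Discrete zero-crossing: sign(prev) != sign(w) with prev nonzero.

    An exact zero sample counts as the crossing itself (sign 0 differs from
    both signs), so crossings that land on a sample resolve to that sample.
    """
    if prev == 0.0:
        return False
    return (prev < 0.0) != (w < 0.0) or w == 0.0


class QRSDetector:
    """Stages 1-5 of the delineator; one :meth:`step` call per CWT sample.

    Parameters
    ----------
    fs_hz:
        Sampling rate of the CWT stream.
    te_handoff_ms:
        Stage-5 delay before the T-end search opens (default 40 ms).
    protection_timeout_s / protection_halving_s:
        Stall time before the threshold memories start halving, and the
        cadence of subsequent halvings.
    learning_s:
        Events earlier than this are flagged ``reliable=False``.
    """

    def __init__(
        self,
        fs_hz: float = 1000.0,
        te_handoff_ms: float = 40.0,
        protection_timeout_s: float = 3.0,
        protection_halving_s: float = 1.0,
        learning_s: float = 60.0,
    ):
        if fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        self.fs_hz = fs_hz
        self.handoff_samples = int(round(te_handoff_ms * fs_hz / 1000.0))
        self.protection_samples = int(round(protection_timeout_s * fs_hz))
        self.halving_samples = max(1, int(round(protection_halving_s * fs_hz)))
        self.learning_samples = int(round(learning_s * fs_hz))
        self.reset()

    def reset(self) -> None:
        self.stage = 1
        self.mem_pmax = 0.0
        self.mem_pmin = 0.0
        self.qrs_n = 0
        self.rr_counter = 0
        self.stall_timer = 0
        self._halvings_done = 0
        self._prev_w = 0.0
        self._handoff_left = 0
        self.last_event: REvent | None = None

    # ------------------------------------------------------------------

    def _protection_decay(self) -> bool:
        """Halve both memories once per second after a >3 s stall.

        Returns True when a halving occurred (the machine then re-enters
        stage 1).  The first halving happens strictly after the timeout.
        """
        if self.stall_timer <= self.protection_samples:
            return False
        overdue = self.stall_timer - self.protection_samples - 1
        due = 1 + overdue // self.halving_samples
        if due > self._halvings_done:
            self.mem_pmax /= 2.0
            self.mem_pmin /= 2.0
            self._halvings_done = due
            return True
        return False

    def step(self, w: float, k: int) -> REvent | None:
        """Advance the machine by one CWT sample ``w`` at stream index ``k``.

        Returns an :class:`REvent` exactly at the stage-2 zero-crossing,
        otherwise ``None``.  The caller owns the hand-off to the T-end
        machine: :attr:`handoff_done` turns True once the stage-5 delay has
        elapsed.
        """
        self.rr_counter += 1
        event = None

        if self.stage == 1:
            self.stall_timer += 1
            if self._protection_decay():
                pass  # already in stage 1; memories relaxed
            if w > self.mem_pmax:
                self.qrs_n = 1
                self._enter(2)
            elif w < self.mem_pmin:
                self.qrs_n = 0
                self._enter(2)

        elif self.stage == 2:
            if self.qrs_n:
                self.mem_pmax = update_threshold(self.mem_pmax, w, "max")
            else:
                self.mem_pmin = update_threshold(self.mem_pmin, w, "min")
            if _crossed(self._prev_w, w):
                event = REvent(
                    sample_index=k,
                    rr_samples=self.rr_counter,
                    polarity="negative" if self.qrs_n else "positive",
                    reliable=k >= self.learning_samples,
                )
                self.last_event = event
                self.rr_counter = 0
                self._enter(3)

        elif self.stage == 3:
            self.stall_timer += 1
            if self._protection_decay():
                self.stage = 1
            elif self.qrs_n:
                if w < self.mem_pmin:
                    self._enter(4)
            else:
                if w > self.mem_pmax:
                    self._enter(4)

        elif self.stage == 4:
            if self.qrs_n:
                self.mem_pmin = update_threshold(self.mem_pmin, w, "min")
            else:
                self.mem_pmax = update_threshold(self.mem_pmax, w, "max")
            if _crossed(self._prev_w, w):
                self._enter(5)
                self._handoff_left = self.handoff_samples

        elif self.stage == 5:
            self._handoff_left -= 1

        self._prev_w = w
        return event

    def _enter(self, stage: int) -> None:
        self.stage = stage
        self.stall_timer = 0
        self._halvings_done = 0

    @property
    def handoff_done(self) -> bool:
        """True while in stage 5 with the 40 ms delay fully elapsed."""
        return self.stage == 5 and self._handoff_left <= 0

    def tick(self) -> None:
        """Advance the RR counter without processing a sample.

        Called once per sample while the T-end machine owns the stream, so
        that the RR interval spans the full beat.
        """
        self.rr_counter += 1

    def to_stage_one(self) -> None:
        """Return to stage 1 (called when the T-end search concludes)."""
        self._enter(1)
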