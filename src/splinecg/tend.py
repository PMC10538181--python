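"""T-wave end detector: stages 6-10 of the delineation state machine.

After every QRS the machine searches, inside a window that adapts to the
heart rate, for the T wave's two CWT lobes.  Unlike the QRS case the sought
fiducial is not the crossing *between* the lobes (that is the T peak, Tp)
but the second zero-crossing, where the descending limb of the T wave
flattens back into the baseline: the T-wave end, Te.

Stage semantics:

6.  arm the search window -- 140 ms when the preceding RR exceeded 700 ms,
    100 ms otherwise -- and wait for the first lobe to exceed its threshold
    memory (entering through the positive memory sets ``t_n = 1``);
7.  track the first lobe with the 0.75 rule and find the first
    zero-crossing (Tp);
8.  wait for the opposite lobe;
9.  track it with the 0.75 rule, find the second zero-crossing (Te), emit
    the RT counter value and reset it;
10. rebalance: whenever a T-wave memory has grown beyond the corresponding
    QRS memory it is halved, so the T thresholds can never capture QRS
    lobes.

The window bounds the stage-6 first-lobe search; once a lobe has been
found, stages 7-9 may run past it but are bounded by an overall RT search
timeout (default 500 ms after the R peak), beyond which the beat is
recorded without an RT value.  A window timeout likewise ends the search
and returns control to QRS stage 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .qrs import QRSDetector, _crossed, update_threshold

__all__ = ["TEndDetector", "TeEvent", "select_search_window"]


@dataclass(frozen=True)
class TeEvent:
    """One detected T-wave end with its intermediate T peak."""

    te_index: int
    tp_index: int
    rt_samples: int
    t_polarity: str  # "positive", "negative" or "biphasic-resolved"


def select_search_window(rr_ms: float) -> float:
    """Length in ms of the first-lobe search window.

    140 ms when the last RR interval exceeded 700 ms, else 100 ms; the
    700 ms boundary itself takes the short window.
    """
    if rr_ms <= 0:
        raise ValueError(f"rr_ms must be positive, got {rr_ms}")
    return 140.0 if rr_ms > 700.0 else 100.0


class TEndDetector:
    """Stages 6-10; armed once per beat, stepped once per CWT sample."""

    def __init__(
        self,
        fs_hz: float = 1000.0,
        rt_timeout_ms: float = 500.0,
        protection_timeout_s: float = 3.0,
        protection_halving_s: float = 1.0,
    ):
        if fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        self.fs_hz = fs_hz
        self.rt_timeout_samples = int(round(rt_timeout_ms * fs_hz / 1000.0))
        self.protection_samples = int(round(protection_timeout_s * fs_hz))
        self.halving_samples = max(1, int(round(protection_halving_s * fs_hz)))
        self.mem_pmax_t = 0.0
        self.mem_pmin_t = 0.0
        self.stall_timer = 0
        self._halvings_done = 0
        self.reset_beat()

    def reset_beat(self) -> None:
        """Clear per-beat state (threshold memories persist across beats)."""
        self.stage = 0  # 0 = idle, else 6..10
        self.t_n = 0
        self.rt_counter = 0
        self.window_samples = 0
        self.window_deadline = -1
        self._rt_deadline = -1
        self._prev_w = 0.0
        self._tp_index: int | None = None

    def reset(self) -> None:
        """Full reset including the learned threshold memories."""
        self.mem_pmax_t = 0.0
        self.mem_pmin_t = 0.0
        self.stall_timer = 0
        self._halvings_done = 0
        self.reset_beat()

    def protection_tick(self) -> None:
        """Per-sample stall protection for the T threshold memories.

        The 0.75 rule only ever raises the memories and the stage-10
        rebalancing stops once the QRS memories have grown past them, so a
        transient that ratcheted the T memories above T-lobe amplitude
        would otherwise suppress Te detection permanently.  Mirroring the
        QRS protection, 3 s without a detected Te starts halving both T
        memories once per further second.
        """
        self.stall_timer += 1
        if self.stall_timer <= self.protection_samples:
            return
        overdue = self.stall_timer - self.protection_samples - 1
        due = 1 + overdue // self.halving_samples
        if due > self._halvings_done:
            self.mem_pmax_t /= 2.0
            self.mem_pmin_t /= 2.0
            self._halvings_done = due

    # ------------------------------------------------------------------

    def arm(self, r_index: int, rr_samples: int, search_start: int, prev_w: float = 0.0) -> None:
        """Open the search for the beat whose R peak is at ``r_index``.

        ``search_start`` is the stream index of the first sample handed to
        :meth:`step` (R index + the stage-5 delay); the window deadline is
        ``search_start + window_samples``.
        """
        rr_ms = rr_samples * 1000.0 / self.fs_hz
        win_ms = select_search_window(rr_ms)
        self.window_samples = int(round(win_ms * self.fs_hz / 1000.0))
        self.window_deadline = search_start + self.window_samples
        self._rt_deadline = r_index + self.rt_timeout_samples
        self._r_index = r_index
        # pre-set so that after the increment in step(k) it equals k - r_index
        self.rt_counter = search_start - r_index - 1
        self.stage = 6
        self.t_n = 0
        self._prev_w = prev_w
        self._tp_index = None

    def step(self, w: float, k: int) -> TeEvent | str | None:
        """Advance by one sample.

        Returns a :class:`TeEvent` at the Te crossing, the string
        ``"timeout"`` when the search is abandoned, otherwise ``None``.
        The caller returns the combined machine to QRS stage 1 on either
        outcome (stage-10 rebalancing is a separate call so the caller can
        pass in the QRS memories).
        """
        if self.stage == 0:
            return None
        self.rt_counter += 1
        result: TeEvent | str | None = None

        if self.stage == 6:
            if w > self.mem_pmax_t:
                self.t_n = 1
                self.stage = 7
            elif w < self.mem_pmin_t:
                self.t_n = 0
                self.stage = 7
            elif k >= self.window_deadline:
                result = "timeout"
                self.stage = 0

        elif self.stage == 7:
            if self.t_n:
                self.mem_pmax_t = update_threshold(self.mem_pmax_t, w, "max")
            else:
                self.mem_pmin_t = update_threshold(self.mem_pmin_t, w, "min")
            if _crossed(self._prev_w, w):
                self._tp_index = k
                self.stage = 8

        elif self.stage == 8:
            if self.t_n:
                if w < self.mem_pmin_t:
                    self.stage = 9
            else:
                if w > self.mem_pmax_t:
                    self.stage = 9

        elif self.stage == 9:
            if self.t_n:
                self.mem_pmin_t = update_threshold(self.mem_pmin_t, w, "min")
            else:
                self.mem_pmax_t = update_threshold(self.mem_pmax_t, w, "max")
            if _crossed(self._prev_w, w):
                result = TeEvent(
                    te_index=k,
                    tp_index=int(self._tp_index),
                    rt_samples=self.rt_counter,
                    t_polarity="negative" if self.t_n else "positive",
                )
                self.rt_counter = 0
                self.stall_timer = 0
                self._halvings_done = 0
                self.stage = 10

        if self.stage in (7, 8, 9) and result is None and k >= self._rt_deadline:
            result = "timeout"
            self.stage = 0

        self._prev_w = w
        return result

    def rebalance(self, qrs: QRSDetector) -> None:
        """Stage 10: halve any T memory that outgrew its QRS counterpart."""
        if self.mem_pmax_t > qrs.mem_pmax:
            self.mem_pmax_t /= 2.0
        if self.mem_pmin_t < qrs.mem_pmin:
            self.mem_pmin_t /= 2.0
        self.stage = 0
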