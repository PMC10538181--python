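"""End-to-end delineation and beat-to-beat metrics.

Chains the acquisition low-pass, the streaming CWT and the two state
machines over a record, producing one row per beat: R index, Te index, RR
and RT intervals in ms, heart rate in bpm and a reliability flag (False
during the initial learning window).  Also implements the storage encoding
in which RT values ride along inside heart-rate records as zero markers,
and the across-lead RT dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cwt import CWTConfig, CWTProcessor
from .qrs import QRSDetector
from .tend import TEndDetector

__all__ = [
    "BeatAnnotation",
    "Delineator",
    "delineate_record",
    "heart_rate_from_rr",
    "encode_marker_stream",
    "decode_marker_stream",
    "rt_dispersion",
]


@dataclass
class BeatAnnotation:
    """One delineated beat."""

    r_index: int
    te_index: int | None
    rr_ms: float  # NaN for the first beat of a record
    rt_ms: float  # NaN when no Te was found
    hr_bpm: float
    reliable: bool
    polarity: str
    valid: bool = True


def heart_rate_from_rr(rr_ms: float) -> float:
    """Instantaneous heart rate in bpm from an RR interval in ms."""
    if rr_ms <= 0:
        raise ValueError(f"rr_ms must be positive, got {rr_ms}")
    return 60000.0 / rr_ms


class Delineator:
    """Streaming CWT + QRS machine + T-end machine over one lead.

    One instance per lead; leads are processed independently, as in the
    three parallel hardware chains of the reference design.
    """

    def __init__(
        self,
        config: CWTConfig | None = None,
        learning_s: float = 60.0,
        rt_timeout_ms: float = 500.0,
    ):
        self.config = config or CWTConfig()
        fs = self.config.fs_hz
        self.cwt = CWTProcessor(self.config)
        self.qrs = QRSDetector(fs_hz=fs, learning_s=learning_s)
        self.tend = TEndDetector(fs_hz=fs, rt_timeout_ms=rt_timeout_ms)
        self._phase = "qrs"
        self._pending = None  # REvent awaiting its Te
        self._last_w = 0.0
        self._w_range = 0.0
        self.events: list[tuple] = []  # ("R"|"Te", event)

    def step(self, x) -> None:
        """Consume one raw sample."""
        w = self.cwt.step(x)
        # The reference hardware computes the CWT in 24-bit integers, so a
        # decayed lobe reaches an exact zero state that the crossing
        # detectors recognize.  Emulate that resolution: magnitudes below
        # one part in 2**24 of the dynamic range seen so far are sub-LSB
        # and flushed to zero before detection.
        aw = abs(w)
        if aw > self._w_range:
            self._w_range = aw
        elif aw < self._w_range * 2.0**-24:
            w = 0.0
        k = self.cwt.sample_index - 1  # index of the sample just consumed
        self.tend.protection_tick()

        if self._phase == "qrs":
            ev = self.qrs.step(w, k)
            if ev is not None:
                self.events.append(("R", ev))
                self._pending = ev
            if self.qrs.handoff_done:
                # The Te search is anchored on trusted R detections, so it
                # only arms once the learning window is over; during
                # learning the QRS machine keeps the whole stream, which is
                # what lets its thresholds ratchet up to true QRS amplitude.
                if (
                    self._pending is not None
                    and k >= self.qrs.learning_samples
                ):
                    self.tend.arm(
                        r_index=self._pending.sample_index,
                        rr_samples=self._pending.rr_samples,
                        search_start=k + 1,
                        prev_w=w,
                    )
                    self._phase = "tend"
                else:
                    self._finish_beat(None)
        else:
            self.qrs.tick()
            out = self.tend.step(w, k)
            if out == "timeout":
                # stage-10 rebalancing runs at every beat conclusion: it is
                # the only mechanism that lets a T threshold that once
                # captured QRS lobes decay back below T-wave amplitude
                self.tend.rebalance(self.qrs)
                self._finish_beat(None)
            elif out is not None:
                self.events.append(("Te", out))
                self.tend.rebalance(self.qrs)
                self._finish_beat(out)
        self._last_w = w

    def _finish_beat(self, te_event) -> None:
        self._phase = "qrs"
        self._pending = None
        self.tend.reset_beat()
        self.qrs.to_stage_one()

    def process(self, signal) -> None:
        for x in np.asarray(signal):
            self.step(x)

    def annotations(self, compensate_delay: bool = True, extra_delay: int = 0) -> pd.DataFrame:
        """Assemble the beat table from the collected events.

        ``compensate_delay`` subtracts the constant pipeline delay (the
        composed kernel's linear-phase center plus any acquisition-filter
        delay) from every index, which is how the fiducials are reported
        offline; the delay never affects RR or RT since both ends shift
        equally.
        """
        delay = (self.config.group_delay + extra_delay) if compensate_delay else 0
        fs = self.config.fs_hz
        rows = []
        r_events = [(i, e) for i, (kind, e) in enumerate(self.events) if kind == "R"]
        for n, (pos, ev) in enumerate(r_events):
            te = None
            nxt = r_events[n + 1][0] if n + 1 < len(r_events) else len(self.events)
            for kind, e in self.events[pos + 1 : nxt]:
                if kind == "Te":
                    te = e
                    break
            if n == 0:
                rr_ms = float("nan")
                hr = float("nan")
            else:
                rr_samples = ev.sample_index - r_events[n - 1][1].sample_index
                rr_ms = rr_samples * 1000.0 / fs
                hr = heart_rate_from_rr(rr_ms)
            rt_ms = te.rt_samples * 1000.0 / fs if te is not None else float("nan")
            r_idx = ev.sample_index - delay
            te_idx = (te.te_index - delay) if te is not None else None
            valid = te is None or te_idx != r_idx
            rows.append(
                {
                    "r_index": r_idx,
                    "te_index": te_idx,
                    "rr_ms": rr_ms,
                    "rt_ms": rt_ms,
                    "hr_bpm": hr,
                    "reliable": ev.reliable,
                    "polarity": ev.polarity,
                    "valid": valid,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "r_index", "te_index", "rr_ms", "rt_ms",
                "hr_bpm", "reliable", "polarity", "valid",
            ],
        )


def delineate_record(
    signal,
    config: CWTConfig | None = None,
    fs_hz: float | None = None,
    apply_lowpass: bool = True,
    compensate_delay: bool = True,
    learning_s: float = 60.0,
    rt_timeout_ms: float = 500.0,
) -> pd.DataFrame:
    """Delineate one lead; returns the beat table.

    The 200 Hz acquisition low-pass is applied first (disable it for
    signals that are already band-limited or for latency measurements);
    its group delay is included in the compensation.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    if config is None:
        config = CWTConfig(fs_hz=fs_hz or 1000.0)
    elif fs_hz is not None and fs_hz != config.fs_hz:
        raise ValueError("fs_hz disagrees with config.fs_hz")

    extra_delay = 0
    if apply_lowpass:
        from .io import lowpass_filter, LOWPASS_NUMTAPS

        signal = lowpass_filter(signal, config.fs_hz)
        extra_delay = (LOWPASS_NUMTAPS - 1) // 2

    d = Delineator(config, learning_s=learning_s, rt_timeout_ms=rt_timeout_ms)
    d.process(signal)
    return d.annotations(compensate_delay=compensate_delay, extra_delay=extra_delay)


def encode_marker_stream(annotations: pd.DataFrame, length: int) -> np.ndarray:
    """Storage encoding: zeros at every R and Te sample, HR elsewhere.

    Before the first beat the stream is zero; after each beat it holds that
    beat's heart rate, so the RT interval is recoverable offline as the
    spacing between paired zero markers inside an otherwise constant run.
    When R and Te would share a sample only one zero is stored and the
    annotation is flagged invalid.
    """
    events = []
    for _, row in annotations.iterrows():
        events.append((int(row["r_index"]), row["hr_bpm"]))
        if row["te_index"] is not None and not pd.isna(row["te_index"]):
            events.append((int(row["te_index"]), None))
    if any(not 0 <= idx < length for idx, _ in events):
        raise ValueError("annotation index out of range for the requested length")

    stream = np.zeros(length)
    events.sort(key=lambda t: t[0])
    hr = 0.0
    pos = 0
    for idx, new_hr in events:
        stream[pos:idx] = hr
        stream[idx] = 0.0
        if new_hr is not None and not pd.isna(new_hr):
            hr = float(new_hr)
        pos = idx + 1
    stream[pos:] = hr
    return stream


def decode_marker_stream(stream):
    """Inverse of :func:`encode_marker_stream`.

    Returns ``(event_indices, hr_series)``: the positions of the zero
    markers occurring after the first nonzero sample, and the stream itself
    as the heart-rate series.
    """
    stream = np.asarray(stream, dtype=float)
    nonzero = np.flatnonzero(stream)
    if len(nonzero) == 0:
        return np.empty(0, dtype=int), stream
    first = nonzero[0]
    events = np.flatnonzero(stream[first:] == 0.0) + first
    # the marker that started the first HR run is the last leading zero
    if first > 0:
        events = np.concatenate([[first - 1], events])
    return events.astype(int), stream


def rt_dispersion(rt_by_lead) -> float:
    """Max minus min RT across simultaneously recorded leads.

    Missing (NaN/None) leads are ignored; raises when no lead has a value.
    An across-lead spread in RT reflects repolarization heterogeneity, so
    changes in T-wave morphology show up here even without re-delineation.
    """
    vals = [v for v in rt_by_lead if v is not None and not np.isnan(v)]
    if not vals:
        raise ValueError("no lead provided an RT value")
    return float(max(vals) - min(vals))
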