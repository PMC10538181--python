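"""Synthetic 1 kHz ECG records with exact ground-truth R and Te indices.

Each beat is a sum of Gaussian bumps (P, Q, R, S, T) placed on a global
time axis, so every detector property is testable without downloading any
database.  The generator emulates the signal classes the delineator must
handle -- both QRS polarities; positive, negative and biphasic T waves;
fixed, ramped or jittered RR schedules; baseline wander; additive noise;
and the slow amplitude decay of a drying electrode -- while declaring the
truth it buries: the exact R-peak sample of every beat and a Te convention
(T center + 2 sigma_T, the point where a Gaussian T has fallen to ~13.5 %
of its peak).

The T wave is placed by a Bazett-type rate adaptation,
``RT = rtc_ms * sqrt(RR in s)``, so that repolarization shortens at fast
rates the way a real RT/QT interval does; the T center is then
``R + RT - 2 sigma_T``.  Default morphology follows textbook surface-ECG
values (amplitudes in mV, times in ms): R 1.0/sigma 10; Q -0.1/sigma 8 at
-40; S -0.15/sigma 8 at +40; P 0.15/sigma 25 at -160; T amplitude
0.3·R with sigma 55.

What the generator does *not* emulate: asymmetric T waves, ectopic beats,
muscle or mains artifacts, and the morphology changes of real pathology.
Passing the recovery tests therefore shows the state machines track the
paper's signal model, not that they are field-validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SyntheticECGSpec", "make_beat_template", "synthesize_record", "mv_to_counts"]

# (name, amplitude mV, center ms relative to R, sigma ms)
_WAVES = (
    ("P", 0.15, -160.0, 25.0),
    ("Q", -0.10, -40.0, 8.0),
    ("R", 1.00, 0.0, 10.0),
    ("S", -0.15, 40.0, 8.0),
)


@dataclass(frozen=True)
class SyntheticECGSpec:
    """Parameters of one synthetic record.

    ``rr_ms`` may be a scalar (fixed schedule), a ``(start, stop)`` tuple
    (linear ramp across the record) or an explicit per-beat sequence;
    ``rr_jitter_sd_ms`` adds seeded Gaussian jitter on top.  Identical
    seeds produce bit-identical records.
    """

    fs_hz: float = 1000.0
    n_beats: int = 30
    rr_ms: object = 800.0
    rr_jitter_sd_ms: float = 0.0
    qrs_polarity: str = "positive"
    t_morphology: str = "positive"
    t_amplitude_ratio: float = 0.3
    t_sigma_ms: float = 55.0
    rtc_ms: float = 340.0  # rate-corrected R-to-Te used to place the T wave
    noise_sd_mv: float = 0.0
    drift_per_min: float = 0.0  # fractional amplitude decay per minute
    baseline_wander_mv: float = 0.0
    baseline_wander_hz: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.n_beats < 0:
            raise ValueError("n_beats must be >= 0")
        if self.qrs_polarity not in ("positive", "negative"):
            raise ValueError(f"unknown qrs_polarity {self.qrs_polarity!r}")
        if self.t_morphology not in ("positive", "negative", "biphasic"):
            raise ValueError(f"unknown t_morphology {self.t_morphology!r}")
        if not np.isfinite(self.t_amplitude_ratio):
            raise ValueError("t_amplitude_ratio must be finite")

    def rr_schedule(self) -> np.ndarray:
        """Per-beat RR intervals in ms (seeded jitter applied)."""
        if self.n_beats == 0:
            return np.empty(0)
        if np.isscalar(self.rr_ms):
            rr = np.full(self.n_beats, float(self.rr_ms))
        elif isinstance(self.rr_ms, tuple) and len(self.rr_ms) == 2:
            rr = np.linspace(self.rr_ms[0], self.rr_ms[1], self.n_beats)
        else:
            rr = np.asarray(self.rr_ms, dtype=float)
            if len(rr) != self.n_beats:
                raise ValueError("explicit rr_ms sequence must have n_beats entries")
        if self.rr_jitter_sd_ms > 0:
            rng = np.random.default_rng(self.seed + 1)
            rr = rr + rng.normal(0.0, self.rr_jitter_sd_ms, self.n_beats)
        if np.any(rr <= 300.0) or np.any(rr >= 2000.0):
            raise ValueError("RR intervals must lie within (300, 2000) ms")
        return rr


def _t_waves(spec: SyntheticECGSpec, rr_ms: float):
    """T-wave components and the truth RT for one beat.

    Returns ``(components, rt_ms)`` where each component is
    ``(amplitude_mv, center_ms, sigma_ms)`` relative to the R peak.  Unlike
    the P/QRS bumps, T components are raised-cosine lobes with compact
    support ``center ± 2*sigma``: a real T wave *ends*, and the end is the
    fiducial the delineator must find, so the generator's T returns to
    baseline exactly at the declared truth ``Te = center + 2*sigma`` (a
    Gaussian never would, leaving Te undefined on noise-free records).
    """
    rt = spec.rtc_ms * np.sqrt(rr_ms / 1000.0)
    amp = spec.t_amplitude_ratio * 1.0
    sig = spec.t_sigma_ms
    center = rt - 2.0 * sig
    if spec.t_morphology == "positive":
        comps = [(amp, center, sig)]
    elif spec.t_morphology == "negative":
        comps = [(-amp, center, sig)]
    else:  # biphasic: opposite half-amplitude lobes, joint support ends at Te
        comps = [
            (-amp / 2.0, center - sig, sig / 2.0),
            (amp / 2.0, center + sig / 2.0, 3.0 * sig / 4.0),
        ]
    return comps, rt


def _cos_bump(t_ms, amp, center, sigma):
    """Raised-cosine bump: amp*cos^2(pi*(t-c)/(8*sigma)) on |t-c| <= 2*sigma."""
    u = (t_ms - center) / (2.0 * sigma)
    out = np.where(np.abs(u) <= 1.0, amp * np.cos(0.5 * np.pi * u) ** 2, 0.0)
    return out


def make_beat_template(spec: SyntheticECGSpec, rr_ms: float | None = None):
    """One beat's waveform with its declared fiducials.

    Returns ``(waveform, r_offset, te_offset)`` where the offsets are
    sample indices into the waveform; the template spans 400 ms before the
    R peak to ``rr_ms`` after it.
    """
    rr = float(rr_ms if rr_ms is not None else np.atleast_1d(
        np.asarray(spec.rr_ms, dtype=float).ravel())[0])
    fs = spec.fs_hz
    pre_ms = 400.0
    n = int(round((pre_ms + rr) * fs / 1000.0))
    t_ms = np.arange(n) * 1000.0 / fs - pre_ms
    wave = np.zeros(n)
    qrs_sign = -1.0 if spec.qrs_polarity == "negative" else 1.0
    for name, amp, c, s in _WAVES:
        a = amp * qrs_sign if name in ("Q", "R", "S") else amp
        wave += a * np.exp(-0.5 * ((t_ms - c) / s) ** 2)
    comps, rt = _t_waves(spec, rr)
    for a, c, s in comps:
        wave += _cos_bump(t_ms, a, c, s)
    r_offset = int(round(pre_ms * fs / 1000.0))
    te_offset = r_offset + int(round(rt * fs / 1000.0))
    if not 0 < te_offset - r_offset < n:
        raise ValueError("Te fiducial falls outside the beat template")
    return wave, r_offset, te_offset


def synthesize_record(spec: SyntheticECGSpec):
    """Full record with ground truth.

    Returns ``(signal, truth)``: a float mV signal and a DataFrame with one
    row per beat (``beat``, ``r_index``, ``te_index``, ``rr_ms``).
    """
    fs = spec.fs_hz
    rr = spec.rr_schedule()
    if spec.n_beats == 0:
        return np.empty(0), pd.DataFrame(columns=["beat", "r_index", "te_index", "rr_ms"])

    lead_in_ms = 500.0
    r_times_ms = lead_in_ms + np.concatenate([[0.0], np.cumsum(rr[:-1])])
    total_ms = lead_in_ms + np.sum(rr) + 400.0
    n = int(round(total_ms * fs / 1000.0))
    t_ms = np.arange(n) * 1000.0 / fs
    signal = np.zeros(n)

    qrs_sign = -1.0 if spec.qrs_polarity == "negative" else 1.0
    rows = []
    for i, (r_ms, rr_i) in enumerate(zip(r_times_ms, rr)):
        for name, amp, c, s in _WAVES:
            a = amp * qrs_sign if name in ("Q", "R", "S") else amp
            signal += a * np.exp(-0.5 * ((t_ms - r_ms - c) / s) ** 2)
        comps, rt = _t_waves(spec, rr_i)
        for a, c, s in comps:
            signal += _cos_bump(t_ms, a, r_ms + c, s)
        r_idx = int(round(r_ms * fs / 1000.0))
        rows.append(
            {
                "beat": i,
                "r_index": r_idx,
                "te_index": r_idx + int(round(rt * fs / 1000.0)),
                "rr_ms": rr_i,
            }
        )

    if spec.drift_per_min != 0.0:
        decay = 1.0 - spec.drift_per_min * (t_ms / 60000.0)
        signal *= np.clip(decay, 0.1, None)
    if spec.baseline_wander_mv != 0.0:
        signal += spec.baseline_wander_mv * np.sin(
            2.0 * np.pi * spec.baseline_wander_hz * t_ms / 1000.0
        )
    if spec.noise_sd_mv > 0.0:
        rng = np.random.default_rng(spec.seed)
        signal += rng.normal(0.0, spec.noise_sd_mv, n)

    return signal, pd.DataFrame(rows)


def mv_to_counts(signal_mv, bits: int = 24, vref_v: float = 2.4, gain: float = 1.0):
    """Map a millivolt signal to integer ADC counts.

    Emulates a 24-bit converter with a ±``vref_v`` reference at the given
    analog gain (the unity-gain default maps 1 mV to ~3495 counts), which
    is the scale at which the fixed-point register budgets of the hardware
    emulation hold.
    """
    lsb_mv = 2.0 * vref_v * 1000.0 / (gain * 2.0**bits)
    return np.round(np.asarray(signal_mv, dtype=float) / lsb_mv).astype(np.int64)
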