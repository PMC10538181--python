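"""Record I/O, the acquisition low-pass and annotation matching.

CSV records are two columns (``time_s``, ``amplitude``); beat tables are
plain CSV.  A minimal reader for PhysioNet/MIT (WFDB) records -- text
header, 16-bit and 212-packed signal formats, and MIT annotation files --
is included so externally annotated databases (QTDB and the like) can be
evaluated when their files are supplied; only the subset of the format
needed for that is implemented.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import firwin, lfilter

__all__ = [
    "LOWPASS_NUMTAPS",
    "lowpass_filter",
    "read_record_csv",
    "write_record_csv",
    "read_wfdb_record",
    "MatchReport",
    "match_annotations",
]

#: Tap count of the acquisition FIR (odd: exactly linear phase, integer
#: group delay of 20 samples at any rate).
LOWPASS_NUMTAPS = 41


def lowpass_filter(signal, fs_hz: float, cutoff_hz: float = 200.0):
    """Band-limit a lead before delineation.

    Linear-phase windowed (Hamming) FIR, 41 taps, -6 dB point placed at
    ``cutoff_hz + 25`` so the passband holds to ~200 Hz and the stopband
    reaches >40 dB by 350 Hz at fs = 1 kHz.  DC gain is exactly 1.
    """
    signal = np.asarray(signal, dtype=float)
    if fs_hz <= 2 * cutoff_hz:
        raise ValueError(f"fs_hz={fs_hz} too low for a {cutoff_hz} Hz cutoff")
    taps = firwin(LOWPASS_NUMTAPS, (cutoff_hz + 25.0) / (fs_hz / 2.0))
    return lfilter(taps, [1.0], signal)


# ---------------------------------------------------------------------------
# CSV records


def write_record_csv(path, signal, fs_hz: float) -> None:
    t = np.arange(len(signal)) / fs_hz
    pd.DataFrame({"time_s": t, "amplitude": np.asarray(signal)}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_record_csv(path):
    """Returns ``(signal, fs_hz)`` from a two-column record CSV."""
    df = pd.read_csv(path)
    if not {"time_s", "amplitude"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, amplitude")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: record too short to infer a sampling rate")
    fs = 1.0 / np.median(np.diff(t))
    return df["amplitude"].to_numpy(dtype=float), float(round(fs, 6))


# ---------------------------------------------------------------------------
# Minimal WFDB (MIT-format) reading


def _parse_gain(field: str):
    """Parse a 'gain(baseline)/units' signal-spec field."""
    units = "adu"
    if "/" in field:
        field, units = field.split("/", 1)
    baseline = None
    if "(" in field:
        field, rest = field.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(field) if field else 200.0
    if gain == 0:
        gain = 200.0
    return gain, baseline, units


def read_wfdb_record(path):
    """Read an MIT/WFDB record.

    ``path`` is the record path without extension.  Returns
    ``(signals, fs_hz, annotations)`` -- a list of per-lead float arrays in
    physical units, the sampling rate, and a DataFrame of annotations
    (``sample``, ``code``) from a ``.atr`` file when present (or ``None``).
    Formats 16 and 212 are supported, all leads in one signal file.
    """
    hea = path + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(f"missing header file {hea}")
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    rec = lines[0].split()
    if len(rec) < 4:
        raise ValueError(f"{hea}: malformed record line {lines[0]!r}")
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0])
    n_samples = int(rec[3])
    specs = []
    for ln in lines[1 : 1 + n_sig]:
        f = ln.split()
        fmt = int(f[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, _units = _parse_gain(f[2]) if len(f) > 2 else (200.0, None, "adu")
        adc_zero = int(f[4]) if len(f) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        specs.append({"file": f[0], "fmt": fmt, "gain": gain, "baseline": baseline})

    dat = os.path.join(os.path.dirname(path), specs[0]["file"])
    if not os.path.exists(dat):
        raise FileNotFoundError(f"missing signal file {dat}")
    raw = np.fromfile(dat, dtype=np.uint8)
    fmt = specs[0]["fmt"]
    if fmt == 16:
        flat = raw.view("<i2").astype(np.int64)
    elif fmt == 212:
        usable = (len(raw) // 3) * 3
        b = raw[:usable].reshape(-1, 3).astype(np.int64)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s0[s0 > 2047] -= 4096
        s1[s1 > 2047] -= 4096
        flat = np.empty(2 * len(b), dtype=np.int64)
        flat[0::2], flat[1::2] = s0, s1
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    flat = flat[: n_samples * n_sig]
    frames = flat.reshape(-1, n_sig)
    signals = [
        (frames[:, i] - specs[i]["baseline"]) / specs[i]["gain"] for i in range(n_sig)
    ]

    ann = None
    atr = path + ".atr"
    if os.path.exists(atr):
        ann = read_wfdb_annotations(atr)
    return signals, fs, ann


def read_wfdb_annotations(path) -> pd.DataFrame:
    """Decode an MIT annotation file into (sample, code) rows.

    Handles the SKIP, NUM, SUB, CHN and AUX pseudo-annotations of the
    format; beat/wave codes are returned as the raw integer code.
    """
    raw = np.fromfile(path, dtype=np.uint8)
    out = []
    t = 0
    i = 0
    n = len(raw)
    while i + 1 < n:
        a = int(raw[i]) | (int(raw[i + 1]) << 8)
        i += 2
        code = a >> 10
        delta = a & 0x3FF
        if code == 0 and delta == 0:  # end of file
            break
        if code == 59:  # SKIP: next 4 bytes = long interval, high word first
            if i + 3 >= n:
                break
            high = int(raw[i]) | (int(raw[i + 1]) << 8)
            low = int(raw[i + 2]) | (int(raw[i + 3]) << 8)
            t += (high << 16) | low
            i += 4
        elif code == 63:  # AUX: delta bytes of free text (padded to even)
            i += delta + (delta & 1)
        elif code in (60, 61, 62):  # NUM / SUB / CHN: modify state, no time
            pass
        else:
            t += delta
            out.append({"sample": t, "code": code})
    return pd.DataFrame(out, columns=["sample", "code"])


# ---------------------------------------------------------------------------
# Annotation matching


@dataclass(frozen=True)
class MatchReport:
    """Agreement between a truth and a detected event sequence."""

    n_truth: int
    n_detected: int
    n_matched: int
    sensitivity: float
    ppv: float
    ppv_defined: bool
    te_error_mean_ms: float
    te_error_sd_ms: float


def match_annotations(truth, detected, tolerance_ms: float = 50.0, fs_hz: float = 1000.0):
    """Greedy nearest-neighbour matching of two sorted index sequences.

    Candidate pairs within the tolerance are taken in order of increasing
    absolute error, each event matched at most once.  Sensitivity is
    matched/truth, positive predictivity matched/detected; errors are
    signed (detected - truth) in ms over the matched pairs.  With no
    detections the PPV is reported as 0 with ``ppv_defined=False``.
    """
    truth = np.asarray(truth, dtype=int)
    detected = np.asarray(detected, dtype=int)
    tol = tolerance_ms * fs_hz / 1000.0
    pairs = []
    for ti, tv in enumerate(truth):
        lo = np.searchsorted(detected, tv - tol)
        hi = np.searchsorted(detected, tv + tol, side="right")
        for di in range(lo, hi):
            pairs.append((abs(int(detected[di]) - int(tv)), ti, di))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    errors = []
    for _, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        errors.append((int(detected[di]) - int(truth[ti])) * 1000.0 / fs_hz)
    n_matched = len(errors)
    sens = n_matched / len(truth) if len(truth) else 0.0
    ppv_defined = len(detected) > 0
    ppv = n_matched / len(detected) if ppv_defined else 0.0
    err = np.asarray(errors)
    return MatchReport(
        n_truth=len(truth),
        n_detected=len(detected),
        n_matched=n_matched,
        sensitivity=sens,
        ppv=ppv,
        ppv_defined=ppv_defined,
        te_error_mean_ms=float(err.mean()) if n_matched else float("nan"),
        te_error_sd_ms=float(err.std()) if n_matched else float("nan"),
    )
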