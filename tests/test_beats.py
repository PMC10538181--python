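"""Beat metrics: HR, marker stream, dispersion, end-to-end delineation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import splinecg as sc
from splinecg.beats import (
    decode_marker_stream,
    delineate_record,
    encode_marker_stream,
    heart_rate_from_rr,
    rt_dispersion,
)


class TestHeartRate:
    @pytest.mark.parametrize("rr,hr", [(1000.0, 60.0), (500.0, 120.0), (750.0, 80.0)])
    def test_known_rates(self, rr, hr):
        assert heart_rate_from_rr(rr) == pytest.approx(hr)

    @given(st.floats(20.0, 240.0))
    def test_reciprocity(self, h):
        assert heart_rate_from_rr(60000.0 / h) == pytest.approx(h, rel=1e-12)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            heart_rate_from_rr(0.0)


def _ann(rows):
    return pd.DataFrame(rows, columns=["r_index", "te_index", "hr_bpm"])


class TestMarkerStream:
    def test_no_annotations_gives_all_zero(self):
        stream = encode_marker_stream(_ann([]), 100)
        assert not stream.any()
        idx, _ = decode_marker_stream(stream)
        assert len(idx) == 0

    def test_single_beat_encoding(self):
        stream = encode_marker_stream(
            _ann([{"r_index": 100, "te_index": 400, "hr_bpm": 60.0}]), 1000
        )
        assert stream[100] == 0.0 and stream[400] == 0.0
        assert (stream[:100] == 0.0).all()
        assert (stream[101:400] == 60.0).all() and (stream[401:] == 60.0).all()

    def test_round_trip_recovers_events_and_rt(self):
        ann = _ann([{"r_index": 100, "te_index": 400, "hr_bpm": 60.0}])
        idx, hr = decode_marker_stream(encode_marker_stream(ann, 1000))
        assert idx.tolist() == [100, 400]
        assert idx[1] - idx[0] == 300  # RT in samples at 1 kHz

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            encode_marker_stream(
                _ann([{"r_index": 100, "te_index": 2000, "hr_bpm": 60.0}]), 1000
            )

    @given(
        st.lists(st.integers(2, 30), min_size=1, max_size=15),
    )
    def test_round_trip_lossless_for_separated_indices(self, gaps):
        # markers separated by at least one HR sample, as real beats are
        r_list = list(np.cumsum(gaps))
        rows = [
            {"r_index": r, "te_index": 500 + r, "hr_bpm": 60.0 + i}
            for i, r in enumerate(r_list)
        ]
        stream = encode_marker_stream(_ann(rows), 1100)
        idx, _ = decode_marker_stream(stream)
        want = sorted(r_list + [500 + r for r in r_list])
        assert idx.tolist() == want


class TestDispersion:
    @pytest.mark.parametrize(
        "leads,want", [((300, 300, 300), 0.0), ((280, 300, 310), 30.0), ((300,), 0.0)]
    )
    def test_max_minus_min(self, leads, want):
        assert rt_dispersion(leads) == want

    def test_missing_leads_ignored(self):
        assert rt_dispersion([np.nan, 280.0, 310.0]) == 30.0

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            rt_dispersion([np.nan, None])


class TestDelineateRecord:
    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            delineate_record(np.empty(0))

    def test_flat_record_yields_no_beats(self):
        beats = delineate_record(np.zeros(5000))
        assert len(beats) == 0

    def test_clean_record_annotates_every_beat(self, clean_record):
        _, signal, truth = clean_record
        beats = delineate_record(signal, learning_s=10.0)
        post_truth = truth[truth["r_index"] > 15000]
        det = beats["r_index"].to_numpy()
        for t in post_truth["r_index"]:
            assert np.abs(det - t).min() == 0  # compensated indices exact
        rr = beats.loc[beats["r_index"] > 15000, "rr_ms"]
        assert np.abs(rr - 800.0).max() <= 1.0

    def test_polarity_inverted_record_same_rr_series(self, clean_record):
        _, signal, _ = clean_record
        a = delineate_record(signal, apply_lowpass=False, learning_s=10.0)
        b = delineate_record(-signal, apply_lowpass=False, learning_s=10.0)
        pd.testing.assert_series_equal(a["rr_ms"], b["rr_ms"])

    def test_uncompensated_offset_is_group_delay_plus_filter(self, clean_record):
        _, signal, truth = clean_record
        raw = delineate_record(
            signal, apply_lowpass=False, compensate_delay=False, learning_s=10.0
        )
        det = raw["r_index"].to_numpy()
        offs = {
            int(np.abs(det - t).min() * np.sign(det[np.argmin(np.abs(det - t))] - t))
            for t in truth[truth["r_index"] > 15000]["r_index"]
        }
        assert offs == {40}  # composed kernel center 5*m

    def test_rt_below_rr_when_present(self, clean_record):
        _, signal, _ = clean_record
        beats = delineate_record(signal, learning_s=10.0)
        both = beats.dropna(subset=["rt_ms", "rr_ms"])
        assert (both["rt_ms"] < both["rr_ms"]).all()

    def test_hr_matches_rr(self, clean_record):
        _, signal, _ = clean_record
        beats = delineate_record(signal, learning_s=10.0).dropna(subset=["rr_ms"])
        np.testing.assert_allclose(
            beats["hr_bpm"], 60000.0 / beats["rr_ms"], rtol=1e-12
        )
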