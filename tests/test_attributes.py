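import math

import numpy as np
import pytest

import fluvialnet as fn
from fluvialnet.attributes import (
    DEFAULT_STREAM_SPEED_TABLE,
    DO_NOT_APPLY,
    DOWNSTREAM,
    UNRESTRICTED,
    UPSTREAM,
    validate_stream_speed_table,
)

from conftest import records_for


def river(length_km, stream_cls=1, discharge=5.0):
    return fn.RiverSegment(1, 0, [(0.0, 0.0), (0.2, 0.0)], length_km,
                           discharge, "medium", stream_cls)


class TestEffectiveSpeed:
    @pytest.mark.parametrize("direction", [DOWNSTREAM, UPSTREAM])
    def test_zero_stream_identity(self, direction):
        # no current: the boat makes its cruising speed either way
        assert fn.effective_speed(fn.BoatProfile(), 0.0, direction) == 18.52

    def test_stream_adds_and_subtracts(self):
        p = fn.BoatProfile()
        assert fn.effective_speed(p, 3.0, DOWNSTREAM) == pytest.approx(21.52)
        assert fn.effective_speed(p, 3.0, UPSTREAM) == pytest.approx(15.52)

    def test_upstream_floored_against_strong_current(self):
        assert fn.effective_speed(fn.BoatProfile(), 20.0, UPSTREAM) == 1.0

    def test_negative_stream_rejected(self):
        with pytest.raises(ValueError):
            fn.effective_speed(fn.BoatProfile(), -1.0, DOWNSTREAM)

    def test_profile_invariant_enforced(self):
        with pytest.raises(ValueError):
            fn.BoatProfile(avg_speed_kmh=40.0, max_speed_kmh=37.0)


class TestSegmentTravelTimes:
    def test_hour_long_segment_identity(self):
        tt = fn.segment_travel_times(river(18.52), table={1: 0.0})
        assert tt == (pytest.approx(1.0), pytest.approx(1.0))

    def test_downstream_hour_with_stream(self):
        tt_down, tt_up = fn.segment_travel_times(river(21.52), table={1: 3.0})
        assert tt_down == pytest.approx(1.0)
        assert tt_up == pytest.approx(21.52 / 15.52)

    def test_unmapped_stream_class_errors(self):
        with pytest.raises(fn.ValidationError, match="stream speed class"):
            fn.segment_travel_times(river(1.0, stream_cls=9))

    @pytest.mark.parametrize("seed", range(10))
    def test_downstream_never_slower(self, seed):
        for seg in fn.random_tree(seed, 40):
            tt_down, tt_up = fn.segment_travel_times(seg)
            stream = DEFAULT_STREAM_SPEED_TABLE[seg.stream_speed_class]
            assert tt_down > 0 and math.isfinite(tt_up)
            if stream > 0:
                assert tt_down < tt_up


class TestFlowRegime:
    def test_default_mapping(self):
        assert fn.classify_flow_regime(1) == "low"
        assert fn.classify_flow_regime("medium") == "medium"

    def test_unknown_code_named_in_error(self):
        with pytest.raises(fn.ValidationError, match="'glacial'"):
            fn.classify_flow_regime("glacial")

    def test_sampled_shares_match_configured_probabilities(self):
        # the generator draws regimes at 5% / 86% / 9%; at n = 10,000 the
        # observed shares must sit within one percentage point of that
        rng = np.random.default_rng(42)
        draws = rng.choice(["low", "medium", "high"], size=10_000,
                           p=[0.05, 0.86, 0.09])
        levels = [fn.classify_flow_regime(d) for d in draws]
        shares = {lv: levels.count(lv) / len(levels) for lv in ("low", "medium", "high")}
        assert shares["low"] == pytest.approx(0.05, abs=0.01)
        assert shares["medium"] == pytest.approx(0.86, abs=0.01)
        assert shares["high"] == pytest.approx(0.09, abs=0.01)


class TestNavigabilityFilter:
    def test_zero_threshold_keeps_all(self):
        segs = fn.random_tree(0, 20)
        assert fn.navigability_filter(segs, 0.0) == segs

    def test_threshold_selects_by_discharge(self):
        segs = [river(1.0, discharge=d) for d in (1.0, 5.0, 10.0)]
        for i, s in enumerate(segs):
            s.seg_id = i + 1
        assert len(fn.navigability_filter(segs, 5.0)) == 2

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            fn.navigability_filter([], -1.0)

    def test_monotone_in_threshold(self):
        segs = fn.random_tree(3, 60)
        sizes = [len(fn.navigability_filter(segs, q)) for q in (0, 2, 5, 10, 50, 1e6)]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[0] == 60


class TestRecordEmission:
    def test_y_network_sentinels_and_speeds(self, y_records):
        assert len(y_records) == 3
        for rec in y_records:
            assert rec.bridge == rec.tunnel == rec.lanes == rec.electricity == DO_NOT_APPLY
            assert rec.width_limit == rec.weight_limit == rec.height_limit == UNRESTRICTED
            assert rec.avgspeed_kmh == 18.52
            assert rec.maxspeed_kmh == 37.0
            assert rec.oneway == "both"
            assert rec.foot_access is False

    def test_travel_times_rederivable_from_stored_fields(self, y_records):
        for rec in y_records:
            down = rec.length_km / (rec.avgspeed_kmh + rec.stream_speed_kmh)
            up = rec.length_km / max(rec.avgspeed_kmh - rec.stream_speed_kmh, 1.0)
            assert rec.tt_down_h == pytest.approx(down, rel=1e-12)
            assert rec.tt_up_h == pytest.approx(up, rel=1e-12)

    def test_below_threshold_segments_flagged_not_deleted(self, y_segments):
        records = records_for(y_segments, min_discharge_cms=4.0)
        assert len(records) == 3  # nothing deleted
        flags = {r.seg_id: r.navigable for r in records}
        assert flags == {1: True, 2: True, 3: False}

    @pytest.mark.parametrize("seed", range(10))
    def test_one_record_per_segment(self, seed):
        segs = fn.random_tree(seed, 30)
        assert len(records_for(segs)) == 30

    def test_block_mode_marks_upstream_impassable(self):
        rec = fn.to_osm_records([river(5.0)], {1: (0, 1)}, table={1: 30.0},
                                upstream_mode="block")[0]
        assert math.isinf(rec.tt_up_h)
        assert rec.tt_down_h == pytest.approx(5.0 / 48.52)

    def test_stream_speed_column_emitted_even_when_not_applied(self):
        rec = fn.to_osm_records([river(10.0, stream_cls=3)], {1: (0, 1)},
                                apply_stream_speed=False)[0]
        assert rec.stream_speed_kmh == 3.0  # column kept for end users
        assert rec.tt_down_h == rec.tt_up_h == pytest.approx(10.0 / 18.52)


def test_stream_table_must_be_monotone():
    with pytest.raises(ValueError):
        validate_stream_speed_table({1: 2.0, 2: 1.0})
    validate_stream_speed_table(DEFAULT_STREAM_SPEED_TABLE)


class TestSpeedProperties:
    """Property checks of the plus/minus speed mechanism."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(avg=st.floats(2.0, 36.0), stream=st.floats(0.0, 50.0))
    @settings(max_examples=200, derandomize=True)
    def test_downstream_dominates_and_cap_holds(self, avg, stream):
        p = fn.BoatProfile(avg_speed_kmh=avg, max_speed_kmh=37.0,
                           min_effective_speed_kmh=1.0)
        down = fn.effective_speed(p, stream, DOWNSTREAM)
        up = fn.effective_speed(p, stream, UPSTREAM)
        assert down == avg + stream
        assert up >= 1.0
        assert down >= up
        assert down <= p.max_speed_kmh + stream

    @given(length=st.floats(0.1, 500.0), stream=st.floats(0.01, 50.0))
    @settings(max_examples=200, derandomize=True)
    def test_travel_time_asymmetry_for_any_segment(self, length, stream):
        seg = river(length)
        tt_down, tt_up = fn.segment_travel_times(seg, table={1: stream})
        assert 0 < tt_down < tt_up
        assert math.isfinite(tt_up)
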