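import math
import warnings

import numpy as np
import pytest

from trailbells.engine import (
    EngineConfig,
    EngineError,
    StylusSample,
    _current_radii,
    classify_hit,
    finalize,
    ingest_declaration,
    ingest_sample,
    run_trace,
    start_session,
)


def tap(t, x, y):
    return StylusSample(t, x, y, True)


def lift(t):
    return StylusSample(t, None, None, False)


def tap_target(layout, t, target_id):
    s = layout.symbol(target_id)
    return tap(t, s.x_mm, s.y_mm)


def tap_sequence(layout, ids, t0=0.0, dt=1.0):
    """Pen taps at target centres with lifts in between (segment breaks)."""
    out = []
    t = t0
    for tid in ids:
        out.append(tap_target(layout, t, tid))
        out.append(lift(t + dt / 2))
        t += dt
    return out


class TestStartRules:
    def test_tmt_waits_for_first_target(self, tmt_a):
        state = start_session(tmt_a)
        # wander far from every target (canvas corner, then a lift)
        for s in [tap(0.0, 0.5, 0.5), tap(0.5, 1.0, 1.0), lift(1.0)]:
            assert ingest_sample(state, s) == []
        assert not state.started and state.events == []

    def test_tmt_starts_on_first_target_entry(self, tmt_a):
        state = start_session(tmt_a)
        evs = ingest_sample(state, tap_target(tmt_a, 3.25, "t01"))
        assert [e.event_type for e in evs] == ["session_start", "target_tmt"]
        assert evs[0].t == evs[1].t == 3.25
        assert state.t_start == 3.25

    def test_pre_start_contact_with_other_targets_ignored(self, tmt_a):
        state = start_session(tmt_a)
        assert ingest_sample(state, tap_target(tmt_a, 0.0, "t05")) == []
        assert not state.started

    def test_bells_starts_at_first_sample(self, bells):
        state = start_session(bells)
        evs = ingest_sample(state, lift(2.0))
        assert [e.event_type for e in evs] == ["session_start"]
        assert state.t_start == 2.0


class TestClassification:
    def test_in_order_sweep_gives_target_events(self, tmt_a):
        state = start_session(tmt_a)
        events = []
        for s in tap_sequence(tmt_a, ["t01", "t02", "t03"]):
            events += ingest_sample(state, s)
        kinds = [e.event_type for e in events]
        assert kinds == ["session_start", "target_tmt", "target_tmt", "target_tmt"]
        assert state.expected_order_index == 4

    def test_order_violation_is_error_and_expected_stays(self, tmt_a):
        state = start_session(tmt_a)
        for s in tap_sequence(tmt_a, ["t01", "t02"]):
            ingest_sample(state, s)
        evs = ingest_sample(state, tap_target(tmt_a, 5.0, "t04"))
        assert [e.event_type for e in evs] == ["error_tmt"]
        assert state.expected_order_index == 3  # resume from last correct target

    def test_rehit_is_repetition(self, tmt_a):
        state = start_session(tmt_a)
        for s in tap_sequence(tmt_a, ["t01", "t02"]):
            ingest_sample(state, s)
        evs = ingest_sample(state, tap_target(tmt_a, 5.0, "t01"))
        assert [e.event_type for e in evs] == ["repetition_tmt"]

    def test_classify_hit_pure(self, tmt_a):
        state = start_session(tmt_a)
        state.expected_order_index = 3
        state.correctly_connected = ["t01", "t02"]
        assert classify_hit(state, "t03") == "target_tmt"
        assert classify_hit(state, "t07") == "error_tmt"
        assert classify_hit(state, "t02") == "repetition_tmt"
        with pytest.raises(KeyError):
            classify_hit(state, "nope")

    def test_bells_rehit_not_logged_again(self, bells):
        state = start_session(bells)
        bid = bells.targets[0].id
        ingest_sample(state, tap_target(bells, 0.0, bid))
        ingest_sample(state, lift(0.5))
        evs = ingest_sample(state, tap_target(bells, 1.0, bid))
        assert evs == []
        assert len(state.found_bells) == 1

    def test_bells_distractor_is_error_once(self, bells):
        state = start_session(bells)
        did = bells.distractors[0].id
        evs = ingest_sample(state, tap_target(bells, 0.0, did))
        assert [e.event_type for e in evs] == ["session_start", "error_bells"]
        ingest_sample(state, lift(0.5))
        assert ingest_sample(state, tap_target(bells, 1.0, did)) == []


class TestDebounceAndGeometry:
    def test_dwell_inside_target_emits_once(self, tmt_a):
        state = start_session(tmt_a)
        s = tmt_a.symbol("t01")
        evs = ingest_sample(state, tap(0.0, s.x_mm, s.y_mm))
        evs += ingest_sample(state, tap(0.033, s.x_mm + 0.1, s.y_mm))
        assert [e.event_type for e in evs] == ["session_start", "target_tmt"]

    def test_exit_and_reentry_is_a_new_hit(self, tmt_a):
        state = start_session(tmt_a)
        s = tmt_a.symbol("t01")
        far = (s.x_mm + 3 * s.active_radius_mm, s.y_mm)
        ingest_sample(state, tap(0.0, s.x_mm, s.y_mm))
        ingest_sample(state, tap(0.5, *far))  # exit
        evs = ingest_sample(state, tap(1.0, s.x_mm, s.y_mm))
        assert [e.event_type for e in evs] == ["repetition_tmt"]

    def test_fast_stroke_cannot_tunnel(self, tmt_a):
        # one segment passing straight through target 1 without a sample inside
        state = start_session(tmt_a)
        s = tmt_a.symbol("t01")
        r = s.active_radius_mm
        evs = ingest_sample(state, tap(0.0, s.x_mm - 5 * r, s.y_mm))
        evs += ingest_sample(state, tap(0.1, s.x_mm + 5 * r, s.y_mm))
        assert [e.event_type for e in evs] == ["session_start", "target_tmt"]
        # entry time interpolated on the segment: crossing at 4r of 10r travelled
        assert evs[0].t == pytest.approx(0.04, abs=1e-9)

    def test_pen_lift_breaks_segments(self, tmt_a):
        state = start_session(tmt_a)
        s = tmt_a.symbol("t01")
        r = s.active_radius_mm
        ingest_sample(state, tap(0.0, s.x_mm - 5 * r, s.y_mm))
        ingest_sample(state, lift(0.05))
        evs = ingest_sample(state, tap(0.1, s.x_mm + 5 * r, s.y_mm))
        assert evs == []  # jumped over the circle while lifted

    def test_final_target_area_enlarged_only_when_next(self, tmt_a):
        state = start_session(tmt_a)
        base = state.radii[-1]
        assert _current_radii(state)[-1] == base
        state.expected_order_index = 20
        assert _current_radii(state)[-1] == pytest.approx(base * math.sqrt(1.2))
        assert (_current_radii(state)[-1] / base) ** 2 == pytest.approx(1.2, abs=1e-9)


class TestTermination:
    def test_completion_at_20th_target_timestamp(self, tmt_a):
        state = start_session(tmt_a)
        ids = [t.id for t in tmt_a.targets]
        events = []
        for s in tap_sequence(tmt_a, ids, dt=2.0):
            events += ingest_sample(state, s)
        assert state.ended and state.end_reason == "completed"
        assert events[-1].event_type == "session_end"
        assert events[-1].t == events[-2].t  # ends at the final hit

    def test_timeout_at_exactly_300s(self, tmt_a):
        state = start_session(tmt_a)
        ingest_sample(state, tap_target(tmt_a, 0.0, "t01"))
        ingest_sample(state, lift(1.0))
        evs = ingest_sample(state, lift(301.0))
        assert [e.event_type for e in evs] == ["timeout", "session_end"]
        assert evs[0].t == 300.0 and state.end_reason == "timeout"

    def test_declaration_terminates_bells(self, bells):
        state = start_session(bells)
        ingest_sample(state, tap_target(bells, 0.0, bells.targets[0].id))
        evs = ingest_declaration(state, 120.0)
        assert [e.event_type for e in evs] == ["declaration_finished", "session_end"]
        assert state.end_reason == "declared"
        log = finalize(state)
        assert log.end_reason == "declared" and log.t_end == 120.0

    def test_bells_inactivity_prompt_after_45s(self, bells):
        state = start_session(bells, EngineConfig())
        ingest_sample(state, lift(0.0))
        assert ingest_sample(state, lift(44.0)) == []
        evs = ingest_sample(state, lift(46.0))
        assert [e.event_type for e in evs] == ["inactivity_prompt"]
        assert evs[0].t == 45.0
        # not re-armed until a new bell is found
        assert ingest_sample(state, lift(95.0)) == []
        ingest_sample(state, tap_target(bells, 100.0, bells.targets[0].id))
        ingest_sample(state, lift(100.5))
        evs = ingest_sample(state, lift(146.0))
        assert [e.event_type for e in evs] == ["inactivity_prompt"]
        assert evs[0].t == 145.0

    def test_finalize_requires_termination(self, tmt_a):
        state = start_session(tmt_a)
        with pytest.raises(EngineError, match="terminated"):
            finalize(state)


class TestProtocol:
    def test_out_of_order_timestamps_rejected(self, tmt_a):
        state = start_session(tmt_a)
        ingest_sample(state, tap(1.0, 1.0, 1.0))
        with pytest.raises(EngineError, match="out-of-order"):
            ingest_sample(state, tap(0.5, 1.0, 1.0))

    def test_samples_after_end_warn_and_ignore(self, bells):
        state = start_session(bells)
        ingest_sample(state, tap(0.0, 1.0, 1.0))
        ingest_declaration(state, 1.0)
        with pytest.warns(UserWarning, match="after session end"):
            assert ingest_sample(state, tap(2.0, 1.0, 1.0)) == []

    def test_invalid_layout_rejected(self, tmt_a):
        from trailbells.layout import TestLayout

        bad = TestLayout(test_kind="TMT_A", language="it", canvas=tmt_a.canvas,
                         targets=tmt_a.targets[:10])
        with pytest.raises(EngineError, match="invalid layout"):
            start_session(bad)


def _brute_force_crossings(layout, samples):
    """Independent oracle: count entry crossings of base active circles
    along the pen-down polyline, with lifts breaking segments."""
    circles = [(t.x_mm, t.y_mm, t.active_radius_mm) for t in layout.symbols]
    inside = [False] * len(circles)
    prev = None
    count = 0
    for s in samples:
        if not s.pen_down:
            prev = None
            inside = [False] * len(circles)
            continue
        for k, (cx, cy, r) in enumerate(circles):
            now_in = math.hypot(s.x - cx, s.y - cy) <= r
            crossed = False
            if prev is not None and not inside[k]:
                # sample the chord densely: robust, assumption-free
                for u in np.linspace(0.0, 1.0, 60):
                    px = prev.x + u * (s.x - prev.x)
                    py = prev.y + u * (s.y - prev.y)
                    if math.hypot(px - cx, py - cy) <= r:
                        crossed = True
                        break
            if (prev is None and now_in and not inside[k]) or crossed:
                count += 1
                inside[k] = True
            elif not now_in:
                inside[k] = False
            if crossed and not now_in:
                inside[k] = False
        prev = s
    return count


def test_event_conservation_matches_crossing_oracle(tmt_a):
    """Every active-area entry crossing yields exactly one classified event.

    Run with the final-target enlargement disabled so the oracle can use
    the static base radii without replicating engine state.
    """
    from trailbells.simulator import SimProfile, simulate_tmt

    config = EngineConfig(area_expansion=0.0)
    res = simulate_tmt(
        tmt_a, SimProfile(error_prob=0.15, repetition_prob=0.1, seed=21), config=config
    )
    log = run_trace(tmt_a, res.samples, config=config)
    hits = log.events_of("target_tmt", "error_tmt", "repetition_tmt")
    assert len(hits) == _brute_force_crossings(log.layout, log.raw_trace)


def test_target_events_strictly_increasing_order(tmt_session):
    _, log = tmt_session
    orders = [log.layout.symbol(e.target_id).order_index
              for e in log.events_of("target_tmt")]
    assert orders == list(range(1, len(orders) + 1))


def test_streaming_equals_batch(tmt_session):
    res, log = tmt_session
    state = start_session(log.layout, log.config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in res.samples:
            ingest_sample(state, s)
    streamed = finalize(state)
    assert streamed.events == log.events
    assert streamed.end_reason == log.end_reason
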