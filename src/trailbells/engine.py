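"""Stylus-stream session engine: collision detection, event classification,
start/termination logic.

The engine consumes timestamped pen samples against a :class:`TestLayout`
and emits classified :class:`TestEvent` records:

* a target is *reached* when the stylus trace hits its circular active
  area — tested with continuous segment/circle intersection between
  consecutive pen-down samples, so fast strokes cannot tunnel through a
  circle between samples; the entry time is linearly interpolated on the
  segment;
* TMT hits are classified as correct (respecting the order), repetition
  (previously connected) or error (violating the order); the expected
  target does not advance on an error, so execution resumes from the last
  correctly connected target;
* Bells hits on a bell are correct, on a distractor an error; re-marks of
  an already-marked symbol produce no new event;
* the TMT clock starts when the first target is entered, the Bells clock
  at the first ingested sample; sessions end on completion, on a user
  declaration, or at the 300 s timeout; the Bells engine prompts after
  more than 45 s without a newly found bell;
* the final TMT target's active area grows by 20% while it is the next
  to be reached.

Pen lifts break segments: no collision is detected across a lift, and a
circle re-entered after an exit counts as a new hit (hits are crossings,
not dwell samples).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .layout import TestLayout, validate_layout

__all__ = [
    "StylusSample",
    "TestEvent",
    "EngineConfig",
    "SessionState",
    "SessionLog",
    "EngineError",
    "EVENT_TYPES",
    "start_session",
    "ingest_sample",
    "ingest_declaration",
    "classify_hit",
    "finalize",
    "run_trace",
]

EVENT_TYPES = (
    "session_start",
    "target_tmt",
    "error_tmt",
    "repetition_tmt",
    "target_bells",
    "error_bells",
    "timeout",
    "inactivity_prompt",
    "error_notification",
    "declaration_finished",
    "session_end",
)

END_REASONS = ("completed", "declared", "timeout")


class EngineError(RuntimeError):
    """Raised on protocol violations (bad samples, illegal finalize...)."""


@dataclass(frozen=True)
class StylusSample:
    """One pen sample: time (s), position (mm) and contact state."""

    t: float
    x: float | None
    y: float | None
    pen_down: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise EngineError("sample time must be finite")
        if self.pen_down and (self.x is None or self.y is None):
            raise EngineError("pen-down sample requires coordinates")


@dataclass(frozen=True)
class TestEvent:
    """One classified occurrence in a session."""

    event_type: str
    t: float
    target_id: str | None = None
    x: float | None = None
    y: float | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise EngineError(f"unknown event type {self.event_type!r}")


@dataclass(frozen=True)
class EngineConfig:
    """Engine constants; defaults are the platform's published values."""

    timeout_s: float = 300.0  # 5-min session timeout
    inactivity_s: float = 45.0  # Bells: prompt after >45 s without a new bell
    max_notifications: int = 3  # at most 3 spoken error notifications
    area_expansion: float = 0.2  # final TMT target active-area growth
    sample_rate_hz: float = 30.0

    def to_dict(self) -> dict:
        return {
            "timeout_s": self.timeout_s,
            "inactivity_s": self.inactivity_s,
            "max_notifications": self.max_notifications,
            "area_expansion": self.area_expansion,
            "sample_rate_hz": self.sample_rate_hz,
        }


@dataclass
class SessionState:
    """Mutable state of a running session."""

    layout: TestLayout
    config: EngineConfig
    is_tmt: bool
    centers: np.ndarray  # (n, 2) symbol centres
    radii: np.ndarray  # (n,) active radii
    ids: list[str]
    expected_order_index: int = 1
    correctly_connected: list[str] = field(default_factory=list)
    found_bells: list[str] = field(default_factory=list)
    marked_errors: set = field(default_factory=set)
    started: bool = False
    ended: bool = False
    end_reason: str | None = None
    t_start: float | None = None
    t_end: float | None = None
    last_bell_t: float | None = None
    prompt_armed: bool = True
    inside_ids: set = field(default_factory=set)
    prev: StylusSample | None = None
    clock: float | None = None
    trace: list[StylusSample] = field(default_factory=list)
    events: list[TestEvent] = field(default_factory=list)
    declarations: list[float] = field(default_factory=list)

    @property
    def n_targets(self) -> int:
        return len(self.layout.targets)


def start_session(layout: TestLayout, config: EngineConfig | None = None) -> SessionState:
    """Initialise a session for a valid layout."""
    report = validate_layout(layout)
    if not report.ok:
        raise EngineError(f"invalid layout: {report.findings}")
    config = config or EngineConfig()
    syms = layout.symbols
    return SessionState(
        layout=layout,
        config=config,
        is_tmt=layout.test_kind in ("TMT_A", "TMT_B"),
        centers=np.array([[t.x_mm, t.y_mm] for t in syms]),
        radii=np.array([t.active_radius_mm for t in syms]),
        ids=[t.id for t in syms],
    )


def _current_radii(state: SessionState) -> np.ndarray:
    """Active radii, with the final TMT target enlarged by +20% area when
    it is the next expected one."""
    r = state.radii
    if state.is_tmt and state.expected_order_index == state.n_targets:
        r = r.copy()
        r[state.n_targets - 1] *= math.sqrt(1.0 + state.config.area_expansion)
    return r


def _segment_entries(
    p0: np.ndarray | None,
    p1: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
) -> list[tuple[int, float]]:
    """Circles the motion enters, as ``(index, s)`` with entry fraction
    ``s`` in [0, 1] along ``p0 -> p1`` (``s = 0`` when starting inside).

    With ``p0 is None`` the motion degenerates to the point ``p1``.
    """
    if p0 is None or (abs(p0[0] - p1[0]) < 1e-12 and abs(p0[1] - p1[1]) < 1e-12):
        inside = np.hypot(*(centers - p1).T) <= radii
        return [(int(i), 0.0) for i in np.nonzero(inside)[0]]
    d = p1 - p0
    a = float(d @ d)
    f = p0 - centers  # (n, 2)
    b = 2.0 * f @ d
    c = np.einsum("ij,ij->i", f, f) - radii**2
    start_inside = c <= 0.0
    disc = b**2 - 4.0 * a * c
    out: list[tuple[int, float]] = []
    with np.errstate(invalid="ignore"):
        sqrt_disc = np.sqrt(np.where(disc >= 0.0, disc, np.nan))
        s_in = (-b - sqrt_disc) / (2.0 * a)
    enters = (~start_inside) & (disc >= 0.0) & (s_in >= 0.0) & (s_in <= 1.0)
    for i in np.nonzero(start_inside)[0]:
        out.append((int(i), 0.0))
    for i in np.nonzero(enters)[0]:
        out.append((int(i), float(s_in[i])))
    out.sort(key=lambda e: e[1])
    return out


def classify_hit(state: SessionState, target_id: str) -> str | None:
    """Classify a hit on ``target_id`` per the connection-order rules.

    Returns the event type, or ``None`` for Bells re-marks, which are not
    logged again.  Does not mutate state.
    """
    spec = state.layout.symbol(target_id)  # KeyError on unknown id
    if state.is_tmt:
        if spec.order_index == state.expected_order_index:
            return "target_tmt"
        if target_id in state.correctly_connected:
            return "repetition_tmt"
        return "error_tmt"
    if spec.role == "bell_target":
        return None if target_id in state.found_bells else "target_bells"
    return None if target_id in state.marked_errors else "error_bells"


def _apply_hit(state: SessionState, target_id: str, t: float, xy: tuple[float, float]) -> list[TestEvent]:
    etype = classify_hit(state, target_id)
    if etype is None:
        return []
    ev = TestEvent(etype, t, target_id, xy[0], xy[1])
    state.events.append(ev)
    out = [ev]
    if etype == "target_tmt":
        state.correctly_connected.append(target_id)
        state.expected_order_index += 1
        if state.expected_order_index > state.n_targets:
            out.append(_end(state, "completed", t))
    elif etype == "target_bells":
        state.found_bells.append(target_id)
        state.last_bell_t = t
        state.prompt_armed = True
        if len(state.found_bells) == state.n_targets:
            out.append(_end(state, "completed", t))
    elif etype == "error_bells":
        state.marked_errors.add(target_id)
    return out


def _end(state: SessionState, reason: str, t: float) -> TestEvent:
    state.ended = True
    state.end_reason = reason
    state.t_end = t
    ev = TestEvent("session_end", t, detail=reason)
    state.events.append(ev)
    return ev


def _start(state: SessionState, t: float) -> TestEvent:
    state.started = True
    state.t_start = t
    state.last_bell_t = t
    ev = TestEvent("session_start", t)
    state.events.append(ev)
    return ev


def ingest_sample(state: SessionState, s: StylusSample) -> list[TestEvent]:
    """Process one sample; returns the events it triggered (often none)."""
    if state.ended:
        warnings.warn("sample after session end ignored", stacklevel=2)
        return []
    if state.clock is not None and s.t < state.clock:
        raise EngineError(f"out-of-order sample: t={s.t} < {state.clock}")
    state.clock = s.t
    state.trace.append(s)

    emitted: list[TestEvent] = []

    # Bells clock runs from canvas presentation: the first ingested sample.
    if not state.started and not state.is_tmt:
        emitted.append(_start(state, s.t))

    # motion for collision purposes: pen lifts break segments
    p1 = None
    p0 = None
    if s.pen_down:
        p1 = np.array([s.x, s.y], dtype=float)
        if state.prev is not None and state.prev.pen_down:
            p0 = np.array([state.prev.x, state.prev.y], dtype=float)
    t_prev = state.prev.t if (state.prev is not None and state.prev.pen_down) else s.t

    entries: list[tuple[int, float]] = []
    entries_all: list[tuple[int, float]] = []
    known_inside: set[int] = set()
    if p1 is not None:
        radii = _current_radii(state)
        known_inside = {state.ids.index(i) for i in state.inside_ids}
        entries_all = _segment_entries(p0, p1, state.centers, radii)
        entries = [(i, frac) for i, frac in entries_all if i not in known_inside]

    deadline = None if state.t_start is None else state.t_start + state.config.timeout_s

    for i, frac in entries:
        t_hit = t_prev + frac * (s.t - t_prev)
        if p0 is None:
            xy = (float(p1[0]), float(p1[1]))
        else:
            pt = p0 + frac * (p1 - p0)
            xy = (float(pt[0]), float(pt[1]))
        if not state.started:
            # TMT starts only when the first target is entered;
            # pre-start contacts elsewhere are not logged.
            spec = state.layout.symbol(state.ids[i])
            if spec.order_index == 1:
                emitted.append(_start(state, t_hit))
                deadline = state.t_start + state.config.timeout_s
                emitted.extend(_apply_hit(state, state.ids[i], t_hit, xy))
            continue
        if deadline is not None and t_hit >= deadline:
            break
        # Bells inactivity prompt due before this hit?
        emitted.extend(_maybe_prompt(state, t_hit))
        if state.ended:
            break
        emitted.extend(_apply_hit(state, state.ids[i], t_hit, xy))
        if state.ended:
            break

    if not state.ended:
        emitted.extend(_maybe_prompt(state, s.t))
    if not state.ended and deadline is not None and s.t >= deadline:
        state.events.append(TestEvent("timeout", deadline, detail="5-min timeout"))
        emitted.append(state.events[-1])
        emitted.append(_end(state, "timeout", deadline))

    # membership at the end of the motion, for enter-once debouncing: a
    # circle counts as occupied only if a crossing was detected (or it was
    # already occupied) AND the endpoint still lies within it — keeping
    # membership consistent with entry detection at boundary samples
    if state.ended or p1 is None:
        state.inside_ids = set()
    else:
        candidates = known_inside | {i for i, _ in entries_all}
        # tiny tolerance: an entry detected exactly at the boundary must
        # leave the circle marked occupied, or the next segment would
        # re-detect the same crossing
        still = np.hypot(*(state.centers - p1).T) <= _current_radii(state) + 1e-9
        state.inside_ids = {state.ids[i] for i in candidates if still[i]}
    state.prev = s
    return emitted


def _maybe_prompt(state: SessionState, now: float) -> list[TestEvent]:
    """Emit the Bells inactivity prompt when >45 s passed without a new bell."""
    if state.is_tmt or not state.started or not state.prompt_armed:
        return []
    due = state.last_bell_t + state.config.inactivity_s
    if now > due:
        state.prompt_armed = False
        ev = TestEvent("inactivity_prompt", due, detail="no new bells for 45 s")
        state.events.append(ev)
        return [ev]
    return []


def ingest_declaration(state: SessionState, t: float) -> list[TestEvent]:
    """The user declares the test finished; terminates with reason ``declared``."""
    if state.ended:
        warnings.warn("declaration after session end ignored", stacklevel=2)
        return []
    if not state.started:
        raise EngineError("declaration before session start")
    state.declarations.append(t)
    ev = TestEvent("declaration_finished", t)
    state.events.append(ev)
    return [ev, _end(state, "declared", t)]


@dataclass(frozen=True)
class SessionLog:
    """Immutable record of a finished session: the replay and indicator
    substrate.  ``events`` are reproducible from ``raw_trace`` (plus
    ``declarations``) and the embedded layout."""

    layout: TestLayout
    layout_hash: str
    config: EngineConfig
    raw_trace: tuple[StylusSample, ...]
    events: tuple[TestEvent, ...]
    end_reason: str
    declarations: tuple[float, ...] = ()
    metadata: dict = field(default_factory=dict)

    @property
    def test_kind(self) -> str:
        return self.layout.test_kind

    @property
    def t_start(self) -> float:
        for e in self.events:
            if e.event_type == "session_start":
                return e.t
        raise EngineError("log has no session_start event")

    @property
    def t_end(self) -> float:
        return self.events[-1].t

    def events_of(self, *types: str) -> list[TestEvent]:
        return [e for e in self.events if e.event_type in types]


def finalize(state: SessionState, metadata: dict | None = None) -> SessionLog:
    """Package a terminated session into an immutable :class:`SessionLog`.

    Rejects non-terminal states: termination must have occurred through
    completion, declaration or timeout.
    """
    if not state.ended or state.end_reason not in END_REASONS:
        raise EngineError("finalize requires a terminated session")
    return SessionLog(
        layout=state.layout,
        layout_hash=state.layout.layout_hash(),
        config=state.config,
        raw_trace=tuple(state.trace),
        events=tuple(state.events),
        end_reason=state.end_reason,
        declarations=tuple(state.declarations),
        metadata=dict(metadata or {}),
    )


def run_trace(
    layout: TestLayout,
    samples: Iterable[StylusSample],
    config: EngineConfig | None = None,
    declarations: Sequence[float] = (),
    metadata: dict | None = None,
) -> SessionLog:
    """Batch-process a full trace (with optional declaration times) and
    return the finalized log.  Equivalent to streaming ingestion."""
    state = start_session(layout, config)
    decls = sorted(declarations)
    di = 0
    for s in samples:
        while di < len(decls) and state.started and not state.ended and decls[di] <= s.t:
            ingest_declaration(state, decls[di])
            di += 1
        if state.ended:
            break
        ingest_sample(state, s)
    while di < len(decls) and state.started and not state.ended:
        ingest_declaration(state, decls[di])
        di += 1
    if not state.ended:
        raise EngineError(
            "trace ended before session termination "
            f"(started={state.started}, reason candidates exhausted)"
        )
    return finalize(state, metadata)
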