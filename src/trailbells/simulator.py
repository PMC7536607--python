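"""Synthetic stylus-trace simulator.

Generates 30 Hz pen traces over a test layout together with the
ground-truth event list, so the whole pipeline (engine → supervision →
indicators → replay) can be exercised and cross-validated without
clinical data.  Profiles control the qualitative features that separate
diagnostic groups in practice: mean inter-target interval and its
variability, error and repetition rates, scanning regularity, fatigue,
and early-declaration behaviour.

Kinematics are deliberately simple: constant-speed straight segments
between waypoints.  Inter-target intervals are log-normal (positive and
right-skewed, like human response times).  For the TMT the pen stays
down and detours around other active circles, so the only circle
crossings are the intended ones; for the Bells Test the pen travels
lifted and taps each symbol at its centroid, which likewise guarantees
that detected events match the intended ones exactly.

Group presets ("normal", "MCI", "dementia") anchor the mean inter-target
interval to published group medians per test and increase error rate and
scan irregularity with diagnostic severity.  They are a qualitative
emulation, not a fitted patient model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import EngineConfig, StylusSample, TestEvent, _segment_entries
from .layout import TestLayout

__all__ = [
    "SimProfile",
    "SimResult",
    "SimulationError",
    "simulate_tmt",
    "simulate_bells",
    "simulate",
    "make_group_presets",
    "GROUP_MEANS",
]


class SimulationError(RuntimeError):
    """Raised for infeasible profiles or unroutable layouts."""


#: Cap on simulated pen speed.  Bursts much beyond this are implausible
#: for elderly test-takers, and the cap keeps 30 Hz inter-sample chords
#: short relative to the active-area radii.  Intervals drawn too short
#: for the required travel are stretched to the feasible minimum.
MAX_PEN_SPEED_MM_S = 150.0

#: Clearance (mm) that routed legs must keep from circles they are not
#: meant to enter, over and above the active radius; absorbs the chord
#: corner-cutting of 30 Hz sampling at the speed cap.
ROUTE_VERIFY_MARGIN_MM = 0.75


@dataclass(frozen=True)
class SimProfile:
    """Cognitive-profile parameters of a simulated participant."""

    inter_target_mean_s: float = 2.0
    inter_target_cv: float = 0.3
    error_prob: float = 0.0
    repetition_prob: float = 0.0
    scan_pattern: str = "raster_lr"  # raster_lr | raster_tb | random_walk
    scan_irregularity: float = 0.0
    fatigue_slope: float = 0.0  # relative interval growth per target
    declare_early_prob: float = 0.0  # Bells: stop and declare before finishing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inter_target_mean_s <= 0:
            raise SimulationError("inter_target_mean_s must be positive")
        for name in ("error_prob", "repetition_prob", "scan_irregularity", "declare_early_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.scan_pattern not in ("raster_lr", "raster_tb", "random_walk"):
            raise SimulationError(f"unknown scan_pattern {self.scan_pattern!r}")


@dataclass(frozen=True)
class SimResult:
    """A simulated session: trace, expected events, declaration times."""

    samples: tuple[StylusSample, ...]
    ground_truth: tuple[TestEvent, ...]
    declarations: tuple[float, ...]
    profile: SimProfile
    layout: TestLayout


# published per-test group medians of the mean inter-target interval (s)
GROUP_MEANS = {
    "tmt_a": {"normal": 1.67, "mci": 2.10, "dementia": 2.55},
    "tmt_b": {"normal": 3.66, "mci": 6.10, "dementia": 10.07},
    "bells": {"normal": 4.46, "mci": 5.88, "dementia": 6.59},
}

_GROUP_SHAPE = {
    # (cv, error_prob, repetition_prob, scan_irregularity)
    "normal": (0.25, 0.02, 0.01, 0.05),
    "mci": (0.35, 0.06, 0.02, 0.30),
    "dementia": (0.45, 0.12, 0.04, 0.60),
}


def make_group_presets(test: str = "tmt_a", seed: int = 0) -> dict[str, SimProfile]:
    """Profiles for the three diagnostic groups on one test.

    Mean inter-target intervals carry the published group medians for the
    chosen test; variability, error rate and scan irregularity grow with
    diagnostic severity.
    """
    if test not in GROUP_MEANS:
        raise SimulationError(f"unknown test {test!r}; use tmt_a, tmt_b or bells")
    out = {}
    for group, mean in GROUP_MEANS[test].items():
        cv, ep, rp, irr = _GROUP_SHAPE[group]
        out[group] = SimProfile(
            inter_target_mean_s=mean,
            inter_target_cv=cv,
            error_prob=ep,
            repetition_prob=rp,
            scan_irregularity=irr,
            declare_early_prob=0.0,
            seed=seed,
        )
    return out


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Log-normal draws with the given arithmetic mean and CV."""
    if cv <= 0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


# ---------------------------------------------------------------------------
# obstacle-avoiding polylines (TMT pen-down strokes)


def _entries_on_polyline(pts: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> list[int]:
    """Indices of circles entered along a polyline, in order, counting a
    circle the start point lies in only once (as the segment origin)."""
    inside = set()
    if len(centers) == 0:
        return []
    d0 = np.hypot(*(centers - pts[0]).T)
    inside |= {int(i) for i in np.nonzero(d0 <= radii)[0]}
    hits: list[int] = []
    for a, b in zip(pts[:-1], pts[1:]):
        for i, _s in _segment_entries(a, b, centers, radii):
            if i not in inside:
                hits.append(i)
        dist = np.hypot(*(centers - b).T)
        inside = {int(i) for i in np.nonzero(dist <= radii)[0]}
    return hits


def _plan_leg(
    p0: np.ndarray,
    p1: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    bounds: tuple[float, float],
    clearance: float = 1.5,
    depth: int = 10,
) -> np.ndarray:
    """Polyline from p0 to p1 avoiding the given circles (inflated by
    ``clearance``).  Recursive bypass around the first blocking circle,
    trying both sides; waypoints are clamped to the canvas."""
    infl = radii + clearance
    entries = [(i, s) for i, s in _segment_entries(p0, p1, centers, infl) if s > 0.0]
    if not entries:
        return np.vstack([p0, p1])
    if depth == 0:
        raise SimulationError("path planning recursion limit reached")
    i, _s = entries[0]
    c, r = centers[i], infl[i] * 1.5
    d = p1 - p0
    norm = np.array([-d[1], d[0]])
    nn = np.linalg.norm(norm)
    if nn == 0:
        raise SimulationError("degenerate leg")
    norm /= nn
    last_err: Exception | None = None
    for side in (1.0, -1.0):
        w = c + side * norm * r
        w = np.clip(w, [1.0, 1.0], [bounds[0] - 1.0, bounds[1] - 1.0])
        try:
            left = _plan_leg(p0, w, centers, radii, bounds, clearance, depth - 1)
            right = _plan_leg(w, p1, centers, radii, bounds, clearance, depth - 1)
            return np.vstack([left, right[1:]])
        except SimulationError as exc:
            last_err = exc
    raise SimulationError(f"cannot route around circle {i}: {last_err}")


#: Route memo: layouts are immutable, so collision-free legs between two
#: fixed endpoints can be reused across simulated sessions.
_ROUTE_CACHE: dict[tuple, np.ndarray] = {}


def _route(
    p0: np.ndarray,
    p1: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    dest: int,
    bounds: tuple[float, float],
    cache_key: tuple | None = None,
) -> np.ndarray:
    """Obstacle-avoiding polyline where only the ``dest`` circle may be
    entered; verified post hoc against the full circle set.

    The origin circle (the one ``p0`` lies in, if any) stays an obstacle:
    its start-inside contact does not count as an entry, but looping back
    into it after the exit is rejected — a re-entry would be classified
    as a spurious hit.
    """
    if cache_key is not None and cache_key in _ROUTE_CACHE:
        return _ROUTE_CACHE[cache_key]
    keep = np.array([k for k in range(len(centers)) if k != dest], dtype=int)
    for clearance in (2.5, 1.5, 0.9):
        try:
            pts = _plan_leg(p0, p1, centers[keep], radii[keep], bounds, clearance)
        except SimulationError:
            continue
        hits = _entries_on_polyline(pts, centers, radii + ROUTE_VERIFY_MARGIN_MM)
        if hits == [dest]:  # exactly one entry, into the destination only
            if cache_key is not None:
                _ROUTE_CACHE[cache_key] = pts
            return pts
    raise SimulationError("unable to route a collision-free leg")


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sum(np.hypot(*(np.diff(pts, axis=0)).T)))


# ---------------------------------------------------------------------------
# TMT


def simulate_tmt(
    layout: TestLayout,
    profile: SimProfile,
    fs: float = 30.0,
    config: EngineConfig | None = None,
) -> SimResult:
    """Simulate a continuous-pen TMT execution.

    With probability ``error_prob`` the pen detours through a wrong
    (unconnected, out-of-order) target on the way to the next correct
    one; with ``repetition_prob`` it re-enters an already connected
    target.  The drawn log-normal interval covers the whole transition,
    detour included, so the mean interval between correct targets equals
    ``inter_target_mean_s`` (times the fatigue factor).
    """
    if layout.test_kind not in ("TMT_A", "TMT_B"):
        raise SimulationError("simulate_tmt requires a TMT layout")
    config = config or EngineConfig()
    rng = np.random.default_rng(profile.seed)
    targets = layout.targets
    n = len(targets)
    centers = np.array([[t.x_mm, t.y_mm] for t in targets])
    # plan against the largest radius each area can take (final target may grow)
    radii = np.array([t.active_radius_mm for t in targets])
    radii_max = radii.copy()
    radii_max[-1] *= math.sqrt(1.0 + config.area_expansion)
    bounds = (layout.canvas.width_mm, layout.canvas.height_mm)

    intervals = _lognormal(rng, profile.inter_target_mean_s, profile.inter_target_cv, n - 1)
    intervals *= 1.0 + profile.fatigue_slope * np.arange(n - 1)
    total = float(np.sum(intervals)) + 2.0
    if total > 0.95 * config.timeout_s:
        raise SimulationError(
            f"profile infeasible: scheduled duration {total:.0f}s approaches the "
            f"{config.timeout_s:.0f}s timeout"
        )

    # visit plan: (kind, index) per transition
    transitions: list[list[tuple[str, int]]] = []
    connected: list[int] = [0]
    for k in range(1, n):
        visits: list[tuple[str, int]] = []
        wrong_pool = [j for j in range(n) if j != k and j not in connected]
        if wrong_pool and rng.random() < profile.error_prob:
            tgt = centers[k]
            j = min(wrong_pool, key=lambda q: float(np.hypot(*(centers[q] - tgt))))
            visits.append(("error_tmt", j))
        if len(connected) > 1 and rng.random() < profile.repetition_prob:
            visits.append(("repetition_tmt", int(rng.choice(connected[:-1]))))
        visits.append(("target_tmt", k))
        transitions.append(visits)
        connected.append(k)

    # geometry: start just outside target 1, then leg-by-leg routed polylines
    c0 = centers[0]
    toward = np.array([bounds[0] / 2.0, bounds[1] / 2.0]) - c0
    tn = np.linalg.norm(toward)
    toward = toward / tn if tn > 0 else np.array([1.0, 0.0])
    start = c0 + toward * (radii[0] + 8.0)

    t_pts: list[float] = [0.0]
    x_pts: list[float] = [float(start[0])]
    y_pts: list[float] = [float(start[1])]
    truth: list[TestEvent] = []

    def entry_arclen(pts: np.ndarray, center: np.ndarray, radius: float) -> float:
        """Arc length along ``pts`` at which the circle is first entered."""
        acc = 0.0
        for a, b in zip(pts[:-1], pts[1:]):
            seg = float(np.hypot(*(b - a)))
            hit = _segment_entries(a, b, center[None, :], np.array([radius]))
            if hit:
                return acc + hit[0][1] * seg
            acc += seg
        raise SimulationError("polyline never enters the destination circle")

    max_traverse_s = 0.25  # cap on post-entry crawl to the centroid
    v_cap = MAX_PEN_SPEED_MM_S
    visit_dwell = 2.0 / fs  # brief pause when touching a target

    def append_at_speed(pts: np.ndarray, v: float) -> float:
        """Append a polyline moved at constant speed; returns arrival time."""
        seglen = np.hypot(*(np.diff(pts, axis=0)).T)
        t0 = t_pts[-1]
        acc = 0.0
        for (px, py), sl in zip(pts[1:], seglen):
            acc += sl
            t_pts.append(t0 + acc / v)
            x_pts.append(float(px))
            y_pts.append(float(py))
        return t_pts[-1]

    def pause(duration: float) -> None:
        t_pts.append(t_pts[-1] + duration)
        x_pts.append(x_pts[-1])
        y_pts.append(y_pts[-1])

    def append_final_leg(pts: np.ndarray, t_entry: float, L_e: float) -> None:
        """Append the leg into the transition's correct target: constant
        speed crossing the active-area boundary exactly at ``t_entry``,
        then a (capped) traverse to the centroid with an explicit
        breakpoint at the entry point when the speed changes."""
        t0 = t_pts[-1]
        v1 = L_e / (t_entry - t0) if L_e > 0 else 0.0
        seglen = np.hypot(*(np.diff(pts, axis=0)).T)
        remaining = float(np.sum(seglen)) - L_e
        slow = v1 > 0 and remaining / v1 > max_traverse_s
        v2 = remaining / max_traverse_s if slow else v1
        acc = 0.0
        for (px, py), sl in zip(pts[1:], seglen):
            prev_acc = acc
            acc += sl
            if slow and prev_acc < L_e < acc:
                frac = (L_e - prev_acc) / sl
                t_pts.append(t_entry)
                x_pts.append(x_pts[-1] + frac * (float(px) - x_pts[-1]))
                y_pts.append(y_pts[-1] + frac * (float(py) - y_pts[-1]))
            if acc <= L_e or v1 <= 0:
                t_pts.append(t0 + (acc / v1 if v1 > 0 else 0.0))
            else:
                t_pts.append(t_entry + (acc - L_e) / v2)
            x_pts.append(float(px))
            y_pts.append(float(py))

    lkey = (layout.layout_hash(), round(config.area_expansion, 6))

    def transition_legs(frm: int, visits: list[tuple[str, int]]) -> list[np.ndarray]:
        legs = []
        for _kind, j in visits:
            legs.append(_route(centers[frm], centers[j], centers, radii_max,
                               dest=j, bounds=bounds, cache_key=(lkey, frm, j)))
            frm = j
        return legs

    # lead-in: entry into target 1 at t = 1.0 s (or as soon as the speed
    # cap allows)
    lead_in = _route(start, c0, centers, radii_max, dest=0, bounds=bounds,
                     cache_key=(lkey, "lead", round(float(start[0]), 3), round(float(start[1]), 3)))
    L_e0 = entry_arclen(lead_in, c0, radii[0])
    t_first = max(1.0, L_e0 / v_cap)
    append_final_leg(lead_in, t_first, L_e0)
    pause(visit_dwell)
    truth.append(TestEvent("session_start", t_first))
    truth.append(TestEvent("target_tmt", t_first, targets[0].id))

    prev_entry = t_first
    cur = 0
    for k, visits in enumerate(transitions, start=1):
        legs = transition_legs(cur, visits)
        dest = visits[-1][1]
        dest_radius = radii_max[dest] if dest == n - 1 else radii[dest]
        lens = [_polyline_length(p) for p in legs]
        L_e = entry_arclen(legs[-1], centers[dest], dest_radius)
        move_len = sum(lens[:-1]) + L_e
        n_pauses = len(visits) - 1
        departure = t_pts[-1]
        # scheduled entry, stretched if the pen cannot physically make it
        t_entry = max(prev_entry + float(intervals[k - 1]),
                      departure + move_len / v_cap + n_pauses * visit_dwell)
        v = move_len / (t_entry - departure - n_pauses * visit_dwell)
        for (kind, j), leg in zip(visits[:-1], legs[:-1]):
            arrival = append_at_speed(leg, v)
            truth.append(TestEvent(kind, arrival, targets[j].id))
            pause(visit_dwell)
        append_final_leg(legs[-1], t_entry, L_e)
        truth.append(TestEvent("target_tmt", t_entry, targets[dest].id))
        pause(visit_dwell)
        prev_entry = t_entry
        cur = dest
    truth.append(TestEvent("session_end", prev_entry, detail="completed"))

    # trailing dwell so the final entry is fully sampled
    pause(0.3)

    samples = _sample_grid(np.array(t_pts), np.array(x_pts), np.array(y_pts), fs)
    return SimResult(tuple(samples), tuple(truth), (), profile, layout)


def _sample_grid(t: np.ndarray, x: np.ndarray, y: np.ndarray, fs: float) -> list[StylusSample]:
    """Sample the piecewise-linear motion on the nominal grid plus the
    motion breakpoints themselves, so the sampled chords reproduce the
    planned polyline exactly (real tablets jitter; the engine does not
    assume uniform spacing)."""
    grid = np.arange(0.0, t[-1] + 1.0 / fs, 1.0 / fs)
    all_t = np.unique(np.concatenate([grid, t]))
    xs = np.interp(all_t, t, x)
    ys = np.interp(all_t, t, y)
    return [StylusSample(float(g), float(a), float(b), True) for g, a, b in zip(all_t, xs, ys)]


# ---------------------------------------------------------------------------
# Bells


def _scan_order(layout: TestLayout, profile: SimProfile, rng: np.random.Generator) -> list[int]:
    centers = np.array([[t.x_mm, t.y_mm] for t in layout.targets])
    if profile.scan_pattern == "raster_lr":
        order = list(np.lexsort((centers[:, 1], centers[:, 0])))  # by x, then y
    elif profile.scan_pattern == "raster_tb":
        order = list(np.lexsort((centers[:, 0], centers[:, 1])))  # by y, then x
    else:
        order = list(rng.permutation(len(centers)))
    n_swaps = round(profile.scan_irregularity * len(order))
    for _ in range(n_swaps):
        i, j = rng.integers(0, len(order), 2)
        order[i], order[j] = order[j], order[i]
    return [int(i) for i in order]


def simulate_bells(
    layout: TestLayout,
    profile: SimProfile,
    fs: float = 30.0,
    config: EngineConfig | None = None,
    stop_after: int | None = None,
) -> SimResult:
    """Simulate a Bells execution: lifted-pen travel, centroid taps.

    Bells are visited in ``scan_pattern`` order perturbed by
    ``scan_irregularity`` (a fraction of random transpositions); with
    ``error_prob`` per transition a distractor near the path is marked.
    With ``declare_early_prob`` (or an explicit ``stop_after``) the
    participant stops early, pauses, and declares the test finished.
    """
    if layout.test_kind != "BELLS":
        raise SimulationError("simulate_bells requires a Bells layout")
    config = config or EngineConfig()
    rng = np.random.default_rng(profile.seed)
    bells = layout.targets
    distractors = layout.distractors
    b_centers = np.array([[t.x_mm, t.y_mm] for t in bells])
    d_centers = np.array([[t.x_mm, t.y_mm] for t in distractors])

    order = _scan_order(layout, profile, rng)
    n_found = len(order)
    declares = stop_after is not None or rng.random() < profile.declare_early_prob
    if stop_after is not None:
        n_found = min(stop_after, n_found)
    elif declares:
        n_found = int(rng.integers(max(1, len(order) // 2), len(order)))
    order = order[:n_found]

    intervals = _lognormal(rng, profile.inter_target_mean_s, profile.inter_target_cv, len(order))
    intervals *= 1.0 + profile.fatigue_slope * np.arange(len(order))
    if float(np.sum(intervals)) + 5.0 > 0.95 * config.timeout_s:
        raise SimulationError("profile infeasible: scheduled duration approaches the timeout")

    dwell = 0.15
    used_distractors: set[int] = set()
    # build taps: (time_of_dwell_start, point, event_type, id)
    taps: list[tuple[float, np.ndarray, str, str]] = []
    t = 0.0
    prev_pt = np.array([2.0, 2.0])
    for step, (bi, iv) in enumerate(zip(order, intervals)):
        tgt = b_centers[bi]
        seg_t = max(iv, dwell * 3)
        if len(distractors) and rng.random() < profile.error_prob:
            mid = (prev_pt + tgt) / 2.0
            free = [q for q in range(len(distractors)) if q not in used_distractors]
            if free:
                q = min(free, key=lambda i: float(np.hypot(*(d_centers[i] - mid))))
                used_distractors.add(q)
                taps.append((t + seg_t * 0.5, d_centers[q], "error_bells", distractors[q].id))
        t += seg_t
        taps.append((t, tgt, "target_bells", bells[bi].id))
        prev_pt = tgt
    taps.sort(key=lambda e: e[0])

    # lay out motion pieces: pen-up travel, pen-down dwell at each tap
    t_pts = [0.0]
    x_pts = [2.0]
    y_pts = [2.0]
    pen = []  # pen state per piece (between consecutive breakpoints)
    cursor = np.array([2.0, 2.0])
    now = 0.0
    events: list[TestEvent] = []

    def add_piece(t1: float, pt: np.ndarray, down: bool) -> None:
        nonlocal now, cursor
        t_pts.append(t1)
        x_pts.append(float(pt[0]))
        y_pts.append(float(pt[1]))
        pen.append(down)
        now, cursor = t1, pt

    for tap_t, pt, etype, tid in taps:
        travel_end = max(tap_t, now + 1.0 / fs)
        add_piece(travel_end, pt, down=False)  # lifted travel
        # dwell: pen down at the centroid; detection at the first grid sample
        t_event = math.ceil(travel_end * fs - 1e-9) / fs
        add_piece(travel_end + dwell, pt, down=True)
        events.append(TestEvent(etype, t_event, tid, float(pt[0]), float(pt[1])))

    declarations: tuple[float, ...] = ()
    if declares and n_found < len(bells):
        t_decl = now + 3.0
        add_piece(t_decl + 0.2, cursor + np.array([5.0, 5.0]), down=False)
        declarations = (t_decl,)

    # ground truth incl. start, inactivity prompts, termination
    truth: list[TestEvent] = [TestEvent("session_start", 0.0)]
    last_bell_t = 0.0
    armed = True
    for ev in events:
        if armed and ev.t > last_bell_t + config.inactivity_s:
            truth.append(
                TestEvent("inactivity_prompt", last_bell_t + config.inactivity_s,
                          detail="no new bells for 45 s")
            )
            armed = False
        truth.append(ev)
        if ev.event_type == "target_bells":
            last_bell_t = ev.t
            armed = True
    if declarations:
        t_decl = declarations[0]
        if armed and t_decl > last_bell_t + config.inactivity_s:
            truth.append(
                TestEvent("inactivity_prompt", last_bell_t + config.inactivity_s,
                          detail="no new bells for 45 s")
            )
        truth.append(TestEvent("declaration_finished", t_decl))
        truth.append(TestEvent("session_end", t_decl, detail="declared"))
    else:
        truth.append(TestEvent("session_end", events[-1].t, detail="completed"))

    samples = _sample_bells(np.array(t_pts), np.array(x_pts), np.array(y_pts), pen, fs)
    return SimResult(tuple(samples), tuple(truth), declarations, profile, layout)


def _sample_bells(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, pen: list[bool], fs: float
) -> list[StylusSample]:
    grid = np.arange(0.0, t[-1] + 1.0 / fs, 1.0 / fs)
    xs = np.interp(grid, t, x)
    ys = np.interp(grid, t, y)
    # piece index for each grid time: pen state of the piece it falls in
    idx = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, len(pen) - 1)
    return [
        StylusSample(float(g), float(a), float(b), bool(pen[i]))
        for g, a, b, i in zip(grid, xs, ys, idx)
    ]


def simulate(
    layout: TestLayout,
    profile: SimProfile,
    fs: float = 30.0,
    config: EngineConfig | None = None,
    **kwargs,
) -> SimResult:
    """Dispatch to :func:`simulate_tmt` or :func:`simulate_bells`."""
    if layout.test_kind == "BELLS":
        return simulate_bells(layout, profile, fs, config, **kwargs)
    return simulate_tmt(layout, profile, fs, config)
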