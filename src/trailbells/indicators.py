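"""Digital evaluation indicators computed from a finished session log.

For the TMT: completion Time, Targets, Errors, Errors/targets, the mean
inter-target interval ΔT and its trailing-window variants ΔT_n (the mean
interval among the last ``21 - n`` correct-target events, 1 ≤ n ≤ 20).
For the Bells Test: Targets, ΔT, ΔT_n (last ``36 - n`` events), NIDmin
(the minimum, over the horizontal and vertical components, of the number
of inversions in direction of the smoothed scanning trace through the
first 25 detected bells) and 1Bell (the 3x3 canvas subarea containing the
first detected bell).

The trailing window of ΔT_n counts *events*: an m-event window yields
m - 1 intervals, so the single-event window (n = N) is undefined and
reported as absent.  Sessions that terminated early simply truncate the
window to the events actually observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import SessionLog
from .layout import CanvasGeometry, subarea_of

__all__ = [
    "IndicatorSet",
    "ScanningTrace",
    "compute_indicators",
    "delta_t_n",
    "nid_min",
    "first_bell",
    "tmt_ba",
    "moving_average3",
    "count_inversions",
    "SCAN_TRACE_MAX_BELLS",
]

#: The scanning trace uses at most the first 25 detected bells.
SCAN_TRACE_MAX_BELLS = 25

#: Smoothing span for the scanning-trace moving average.
SMOOTH_SPAN = 3

_TARGET_EVENTS = ("target_tmt", "target_bells")


@dataclass(frozen=True)
class IndicatorSet:
    """The digital indicators of one session."""

    test_kind: str
    time_s: float
    targets: int
    errors: int
    errors_over_targets: float | None
    delta_t_s: float | None
    delta_t_series: dict[int, float | None]
    repetitions: int | None = None  # TMT only
    nid_min: int | None = None  # Bells only
    nid_x: int | None = None
    nid_y: int | None = None
    nid_truncated: bool | None = None
    first_bell_subarea: str | None = None  # Bells only
    end_reason: str = ""

    def to_dict(self) -> dict:
        d = {
            "test_kind": self.test_kind,
            "time_s": self.time_s,
            "targets": self.targets,
            "errors": self.errors,
            "errors_over_targets": self.errors_over_targets,
            "delta_t_s": self.delta_t_s,
            "end_reason": self.end_reason,
        }
        if self.repetitions is not None:
            d["repetitions"] = self.repetitions
        if self.test_kind == "BELLS":
            d.update(
                nid_min=self.nid_min,
                nid_x=self.nid_x,
                nid_y=self.nid_y,
                nid_truncated=self.nid_truncated,
                first_bell_subarea=self.first_bell_subarea,
            )
        d["delta_t_series"] = {str(n): v for n, v in self.delta_t_series.items()}
        return d


@dataclass(frozen=True)
class ScanningTrace:
    """Polyline through the first detected bells, in detection order."""

    x: np.ndarray
    y: np.ndarray
    truncated: bool  # fewer than 25 bells were available

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("x and y components differ in length")
        if len(self.x) > SCAN_TRACE_MAX_BELLS:
            raise ValueError("scanning trace limited to the first 25 bells")


def _target_times(log: SessionLog) -> np.ndarray:
    return np.array([e.t for e in log.events_of(*_TARGET_EVENTS)])


def _n_max(log: SessionLog) -> int:
    return len(log.layout.targets)  # 20 for TMT, 35 for Bells


def delta_t_n(log: SessionLog, n: int) -> float | None:
    """Mean inter-target interval over the trailing event window starting
    at target ``n``; ``None`` when fewer than 2 events fall in it."""
    n_max = _n_max(log)
    if not 1 <= n <= n_max:
        raise ValueError(f"n must be in [1, {n_max}], got {n}")
    times = _target_times(log)
    window = n_max - n + 1
    tail = times[-window:] if window <= len(times) else times
    if len(tail) < 2:
        return None
    return float(np.mean(np.diff(tail)))


def moving_average3(values: np.ndarray) -> np.ndarray:
    """Centred moving average over a span of 3 elements; the edge windows
    shrink to the 2 available points."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return v.copy()
    out = np.empty_like(v)
    out[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    out[0] = (v[0] + v[1]) / 2.0
    out[-1] = (v[-2] + v[-1]) / 2.0
    return out


def count_inversions(values: np.ndarray) -> int:
    """Number of inversions in direction of a 1-D series: sign changes of
    the first difference of the span-3 smoothed series.  Zero differences
    (plateaus) are skipped rather than counted."""
    sm = moving_average3(np.asarray(values, dtype=float))
    d = np.diff(sm)
    nz = d[d != 0.0]
    if len(nz) < 2:
        return 0
    return int(np.sum(nz[1:] * nz[:-1] < 0.0))


def scanning_trace(log: SessionLog) -> ScanningTrace:
    """Coordinates of the first (up to 25) detected bells in order."""
    bells = log.events_of("target_bells")[:SCAN_TRACE_MAX_BELLS]
    return ScanningTrace(
        x=np.array([e.x for e in bells], dtype=float),
        y=np.array([e.y for e in bells], dtype=float),
        truncated=len(bells) < SCAN_TRACE_MAX_BELLS,
    )


def nid_min(log: SessionLog) -> tuple[int, int, int, bool] | None:
    """NIDmin of a Bells log: ``(nid_min, nid_x, nid_y, truncated)``.

    Scanning strategies can be organised horizontally or vertically, so
    the smaller of the two directional counts is retained.  ``None`` when
    fewer than 3 bells were found (no direction is defined).
    """
    if log.test_kind != "BELLS":
        raise ValueError("NIDmin is defined for Bells logs only")
    tr = scanning_trace(log)
    if len(tr.x) < 3:
        return None
    nx = count_inversions(tr.x)
    ny = count_inversions(tr.y)
    return (min(nx, ny), nx, ny, tr.truncated)


def first_bell(log: SessionLog, canvas: CanvasGeometry | None = None) -> str | None:
    """Subarea ("A1".."C3") of the first detected bell; None when no bell
    was found.  Uses the logged pen coordinate of the hit."""
    bells = log.events_of("target_bells")
    if not bells:
        return None
    return subarea_of((bells[0].x, bells[0].y), canvas or log.layout.canvas)


def tmt_ba(time_a: float | None, time_b: float | None) -> float | None:
    """Derived set-shifting cost: TMT-B time minus TMT-A time."""
    if time_a is None or time_b is None:
        return None
    return time_b - time_a


def compute_indicators(log: SessionLog) -> IndicatorSet:
    """All indicators of a finalized session log."""
    if log.metadata.get("tutorial"):
        raise ValueError("tutorial sessions are not scored")
    times = _target_times(log)
    targets = len(times)
    errors = len(log.events_of("error_tmt", "error_bells"))
    n_max = _n_max(log)
    series = {n: delta_t_n(log, n) for n in range(1, n_max + 1)}
    is_tmt = log.test_kind in ("TMT_A", "TMT_B")
    nid = None if is_tmt else nid_min(log)
    return IndicatorSet(
        test_kind=log.test_kind,
        time_s=log.t_end - log.t_start,
        targets=targets,
        errors=errors,
        errors_over_targets=(errors / targets) if targets else None,
        delta_t_s=float(np.mean(np.diff(times))) if targets >= 2 else None,
        delta_t_series=series,
        repetitions=len(log.events_of("repetition_tmt")) if is_tmt else None,
        nid_min=nid[0] if nid else None,
        nid_x=nid[1] if nid else None,
        nid_y=nid[2] if nid else None,
        nid_truncated=nid[3] if nid else None,
        first_bell_subarea=None if is_tmt else first_bell(log),
        end_reason=log.end_reason,
    )
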