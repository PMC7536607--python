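"""Session persistence and deferred replay.

A session is stored as JSON Lines: a header record (format version,
embedded layout, engine config, pseudonymous metadata, end reason,
declaration times), one record per raw stylus sample, and one record per
classified event.  The stored events are by construction reproducible
from the raw trace plus the layout, which :func:`verify_replay` checks by
re-running the engine and reporting any divergence — the automated
analogue of a clinician re-scoring a session from its replay.

:func:`replay` reconstructs the session frame by frame at a chosen rate;
:func:`export_svg` renders the final annotated frame (targets, pen path,
event markers) for visual inspection.  Subject identifiers are opaque
caller-supplied tokens; the library never stores names.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .engine import (
    EngineConfig,
    EngineError,
    EVENT_TYPES,
    SessionLog,
    StylusSample,
    TestEvent,
    run_trace,
)
from .layout import TestLayout

__all__ = [
    "SCHEMA_VERSION",
    "LogFormatError",
    "ReplayFrame",
    "ConsistencyReport",
    "write_log",
    "read_log",
    "replay",
    "export_svg",
    "verify_replay",
]

SCHEMA_VERSION = 1


class LogFormatError(ValueError):
    """Malformed or version-incompatible session file."""


def write_log(log: SessionLog, path: str | Path) -> None:
    """Serialize a finalized session to JSONL (lossless round trip)."""
    def num(v):
        return None if v is None else float(v)

    with open(path, "w") as fh:
        header = {
            "record": "header",
            "version": SCHEMA_VERSION,
            "layout_hash": log.layout_hash,
            "layout": log.layout.to_dict(),
            "config": log.config.to_dict(),
            "end_reason": log.end_reason,
            "declarations": [float(t) for t in log.declarations],
            "metadata": log.metadata,
        }
        fh.write(json.dumps(header) + "\n")
        for s in log.raw_trace:
            fh.write(
                json.dumps(
                    {"record": "sample", "t_s": s.t, "x_mm": num(s.x),
                     "y_mm": num(s.y), "pen_down": s.pen_down}
                )
                + "\n"
            )
        for e in log.events:
            fh.write(
                json.dumps(
                    {"record": "event", "event_type": e.event_type,
                     "target_id": e.target_id, "t_s": e.t,
                     "x_mm": num(e.x), "y_mm": num(e.y), "detail": e.detail}
                )
                + "\n"
            )


def read_log(path: str | Path) -> SessionLog:
    """Parse and validate a session JSONL file.

    Raises :class:`LogFormatError` naming the offending line on schema
    violations (unknown records or event types, missing header,
    truncated JSON, bad version).
    """
    header = None
    samples: list[StylusSample] = []
    events: list[TestEvent] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise LogFormatError(f"{path}:{ln}: invalid JSON ({exc})") from exc
            kind = rec.get("record")
            if ln == 1:
                if kind != "header":
                    raise LogFormatError(f"{path}:1: first record must be the header")
                if rec.get("version") != SCHEMA_VERSION:
                    raise LogFormatError(
                        f"{path}:1: unsupported version {rec.get('version')!r}"
                    )
                header = rec
                continue
            if kind == "sample":
                try:
                    samples.append(
                        StylusSample(
                            t=float(rec["t_s"]),
                            x=None if rec["x_mm"] is None else float(rec["x_mm"]),
                            y=None if rec["y_mm"] is None else float(rec["y_mm"]),
                            pen_down=bool(rec["pen_down"]),
                        )
                    )
                except (KeyError, TypeError, ValueError, EngineError) as exc:
                    raise LogFormatError(f"{path}:{ln}: bad sample ({exc})") from exc
            elif kind == "event":
                etype = rec.get("event_type")
                if etype not in EVENT_TYPES:
                    raise LogFormatError(f"{path}:{ln}: unknown event_type {etype!r}")
                try:
                    events.append(
                        TestEvent(
                            event_type=etype,
                            t=float(rec["t_s"]),
                            target_id=rec.get("target_id"),
                            x=None if rec.get("x_mm") is None else float(rec["x_mm"]),
                            y=None if rec.get("y_mm") is None else float(rec["y_mm"]),
                            detail=rec.get("detail", ""),
                        )
                    )
                except (KeyError, TypeError, ValueError) as exc:
                    raise LogFormatError(f"{path}:{ln}: bad event ({exc})") from exc
            else:
                raise LogFormatError(f"{path}:{ln}: unknown record kind {kind!r}")
    if header is None:
        raise LogFormatError(f"{path}: empty file, header missing")
    if not events or events[-1].event_type != "session_end":
        raise LogFormatError(f"{path}: truncated log, no session_end event")
    layout = TestLayout.from_dict(header["layout"])
    return SessionLog(
        layout=layout,
        layout_hash=header["layout_hash"],
        config=EngineConfig(**header["config"]),
        raw_trace=tuple(samples),
        events=tuple(events),
        end_reason=header["end_reason"],
        declarations=tuple(header.get("declarations", [])),
        metadata=header.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# replay


@dataclass(frozen=True)
class ReplayFrame:
    """Session state at time ``t``: pen path so far and highlighted events."""

    t: float
    path: tuple[StylusSample, ...]
    events: tuple[TestEvent, ...]


def replay(log: SessionLog, fps: float = 2.0) -> list[ReplayFrame]:
    """Frame-by-frame reconstruction from t=0 to the end of the trace.

    A ``D``-second session at rate ``fps`` yields ``floor(D * fps) + 1``
    frames; the final frame shows every logged event exactly once.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    trace = log.raw_trace
    if not trace:
        import warnings

        warnings.warn("empty trace: replay is a single empty frame", stacklevel=2)
        return [ReplayFrame(0.0, (), tuple(log.events))]
    t0 = trace[0].t
    duration = trace[-1].t - t0
    n_frames = math.floor(duration * fps + 1e-9) + 1
    frames = []
    for i in range(n_frames):
        ft = t0 + i / fps
        frames.append(
            ReplayFrame(
                t=ft,
                path=tuple(s for s in trace if s.t <= ft + 1e-12),
                events=tuple(e for e in log.events if e.t <= ft + 1e-12),
            )
        )
    if frames[-1].t < trace[-1].t:
        frames.append(ReplayFrame(trace[-1].t, trace, tuple(log.events)))
    else:
        frames[-1] = ReplayFrame(frames[-1].t, trace, tuple(log.events))
    return frames


_MARKERS = {
    "target_tmt": ("circle", "#2a9d2a"),
    "target_bells": ("circle", "#2a9d2a"),
    "error_tmt": ("cross", "#d62728"),
    "error_bells": ("cross", "#d62728"),
    "repetition_tmt": ("diamond", "#ff7f0e"),
    "session_start": ("tick", "#1f77b4"),
    "session_end": ("tick", "#1f77b4"),
    "timeout": ("tick", "#7f7f7f"),
    "inactivity_prompt": ("tick", "#7f7f7f"),
    "error_notification": ("tick", "#7f7f7f"),
    "declaration_finished": ("tick", "#1f77b4"),
}


def _strokes(path: tuple[StylusSample, ...]) -> Iterator[list[StylusSample]]:
    cur: list[StylusSample] = []
    for s in path:
        if s.pen_down:
            cur.append(s)
        elif cur:
            yield cur
            cur = []
    if cur:
        yield cur


def export_svg(log: SessionLog, path: str | Path, frame: ReplayFrame | None = None) -> None:
    """Render the final (or given) annotated frame to an SVG file:
    canvas, target circles, pen-down strokes, one marker per event."""
    frame = frame or replay(log, fps=1.0)[-1]
    c = log.layout.canvas
    svg = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=f"{c.width_mm}mm",
        height=f"{c.height_mm}mm",
        viewBox=f"0 0 {c.width_mm} {c.height_mm}",
    )
    ET.SubElement(svg, "rect", x="0", y="0", width=str(c.width_mm),
                  height=str(c.height_mm), fill="white", stroke="black",
                  attrib={"stroke-width": "0.5"})
    for t in log.layout.symbols:
        ET.SubElement(
            svg, "circle", cx=str(t.x_mm), cy=str(t.y_mm),
            r=str(t.active_radius_mm),
            fill="none" if t.role != "distractor" else "#eeeeee",
            stroke="#999999", attrib={"stroke-width": "0.2"},
        )
    for stroke in _strokes(frame.path):
        pts = " ".join(f"{s.x},{s.y}" for s in stroke)
        ET.SubElement(svg, "polyline", points=pts, fill="none", stroke="#1f77b4",
                      attrib={"stroke-width": "0.4", "class": "pen-path"})
    for e in frame.events:
        shape, color = _MARKERS[e.event_type]
        ex = e.x if e.x is not None else 2.0
        ey = e.y if e.y is not None else 2.0
        g = ET.SubElement(svg, "g", attrib={"class": f"event {e.event_type}"})
        if shape == "circle":
            ET.SubElement(g, "circle", cx=str(ex), cy=str(ey), r="1.5",
                          fill="none", stroke=color, attrib={"stroke-width": "0.5"})
        elif shape == "cross":
            for dx, dy in ((1, 1), (1, -1)):
                ET.SubElement(g, "line", x1=str(ex - dx), y1=str(ey - dy),
                              x2=str(ex + dx), y2=str(ey + dy), stroke=color,
                              attrib={"stroke-width": "0.5"})
        elif shape == "diamond":
            pts = f"{ex},{ey - 1.5} {ex + 1.5},{ey} {ex},{ey + 1.5} {ex - 1.5},{ey}"
            ET.SubElement(g, "polygon", points=pts, fill="none", stroke=color,
                          attrib={"stroke-width": "0.5"})
        else:  # tick
            ET.SubElement(g, "line", x1=str(ex), y1=str(ey - 1.5), x2=str(ex),
                          y2=str(ey + 1.5), stroke=color,
                          attrib={"stroke-width": "0.5"})
    ET.ElementTree(svg).write(path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# consistency


@dataclass
class ConsistencyReport:
    """Divergences between stored and recomputed session records."""

    divergences: list[str]

    @property
    def ok(self) -> bool:
        return not self.divergences


def verify_replay(log: SessionLog, atol: float = 1e-9) -> ConsistencyReport:
    """Re-run the engine over the stored raw trace and compare with the
    stored events; an empty report means the log is self-consistent."""
    if log.layout is None:
        raise EngineError("log has no layout to verify against")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        redone = run_trace(log.layout, log.raw_trace, log.config, log.declarations)
    div: list[str] = []
    if redone.end_reason != log.end_reason:
        div.append(f"end_reason: stored {log.end_reason!r}, recomputed {redone.end_reason!r}")
    n = max(len(redone.events), len(log.events))
    for i in range(n):
        if i >= len(log.events):
            e = redone.events[i]
            div.append(f"event {i}: missing from stored log ({e.event_type} {e.target_id})")
            continue
        if i >= len(redone.events):
            e = log.events[i]
            div.append(f"event {i}: stored but not recomputed ({e.event_type} {e.target_id})")
            continue
        a, b = log.events[i], redone.events[i]
        same = (
            a.event_type == b.event_type
            and a.target_id == b.target_id
            and abs(a.t - b.t) <= atol
            and (a.x is None) == (b.x is None)
            and (a.x is None or abs(a.x - b.x) <= atol)
            and (a.y is None or abs(a.y - b.y) <= atol)
        )
        if not same:
            div.append(
                f"event {i}: stored ({a.event_type}, {a.target_id}, t={a.t:.6f}) "
                f"!= recomputed ({b.event_type}, {b.target_id}, t={b.t:.6f})"
            )
    return ConsistencyReport(div)
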