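"""Test layouts for the digitized Trail Making Test (TMT) and Bells Test.

A layout is a tablet-sized canvas (millimetres, origin at the top-left
corner, x rightward, y downward) plus a set of circular *active areas*:
the regions within which a stylus crossing counts as a hit.

* TMT-A: 20 sequence targets labelled ``1``..``20``.
* TMT-B: 20 sequence targets alternating number/letter (Italian
  ``1,A..10,L`` — the Italian alphabet has no J or K — or English
  ``1,A..10,J``).
* Bells: 35 bell targets among 280 distractors, the classic cancellation
  sheet scaled to the tablet.  Each symbol's active circle is centred on
  the symbol centroid with an area 20% larger than the symbol surface
  (modelled as a circle of radius ``symbol_radius_mm``), i.e. an active
  radius of ``r * sqrt(1.2)``.

Since the canonical paper-sheet coordinates are not published, layouts
are placed by seeded rejection sampling with a minimum centre separation;
canonical coordinates can be loaded from JSON instead and are affinely
scaled to the canvas.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np

__all__ = [
    "CanvasGeometry",
    "TargetSpec",
    "TestLayout",
    "LayoutReport",
    "LayoutError",
    "TMT_CANVAS",
    "BELLS_CANVAS",
    "ACTIVE_AREA_EXCESS",
    "make_tmt_layout",
    "make_bells_layout",
    "subarea_of",
    "validate_layout",
    "load_layout",
    "save_layout",
]

#: Fractional area excess of an active circle over the symbol surface.
ACTIVE_AREA_EXCESS = 0.2

#: Default TMT target radius (mm); the circle drawn on screen is the active area.
DEFAULT_TMT_RADIUS_MM = 4.5

#: Default Bells symbol radius (mm); the symbol surface is modelled as this circle.
DEFAULT_SYMBOL_RADIUS_MM = 3.0

ITALIAN_LETTERS = ["A", "B", "C", "D", "E", "F", "G", "H", "I", "L"]
ENGLISH_LETTERS = ["A", "B", "C", "D", "E", "F", "G", "H", "I", "J"]


class LayoutError(ValueError):
    """Raised when a layout cannot be built or parsed."""


@dataclass(frozen=True)
class CanvasGeometry:
    """Drawable canvas in millimetres."""

    width_mm: float
    height_mm: float
    orientation: str = "portrait"

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise LayoutError("canvas dimensions must be positive")
        if self.orientation not in ("portrait", "landscape"):
            raise LayoutError(f"unknown orientation {self.orientation!r}")

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.width_mm and 0.0 <= y <= self.height_mm


#: Tablet canvas used for the TMT (portrait) and Bells Test (landscape).
TMT_CANVAS = CanvasGeometry(148.0, 210.0, "portrait")
BELLS_CANVAS = CanvasGeometry(210.0, 148.0, "landscape")


@dataclass(frozen=True)
class TargetSpec:
    """One symbol on the canvas with its circular active area."""

    id: str
    label: str
    x_mm: float
    y_mm: float
    base_radius_mm: float
    active_radius_mm: float
    role: str  # sequence_target | bell_target | distractor
    order_index: int | None = None

    def __post_init__(self) -> None:
        if self.base_radius_mm <= 0 or self.active_radius_mm <= 0:
            raise LayoutError(f"target {self.id}: radii must be positive")
        if self.role not in ("sequence_target", "bell_target", "distractor"):
            raise LayoutError(f"target {self.id}: unknown role {self.role!r}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x_mm, self.y_mm)


@dataclass(frozen=True)
class TestLayout:
    """A complete test sheet: canvas plus targets and distractors."""

    test_kind: str  # TMT_A | TMT_B | BELLS
    language: str  # it | en
    canvas: CanvasGeometry
    targets: tuple[TargetSpec, ...]
    distractors: tuple[TargetSpec, ...] = ()
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def symbols(self) -> tuple[TargetSpec, ...]:
        return self.targets + self.distractors

    def symbol(self, target_id: str) -> TargetSpec:
        for t in self.symbols:
            if t.id == target_id:
                return t
        raise KeyError(target_id)

    def to_dict(self) -> dict:
        def enc(t: TargetSpec) -> dict:
            d = {
                "id": t.id,
                "label": t.label,
                "x_mm": t.x_mm,
                "y_mm": t.y_mm,
                "base_radius_mm": t.base_radius_mm,
                "active_radius_mm": t.active_radius_mm,
                "role": t.role,
            }
            if t.order_index is not None:
                d["order_index"] = t.order_index
            return d

        return {
            "test_kind": self.test_kind,
            "language": self.language,
            "canvas": asdict(self.canvas),
            "targets": [enc(t) for t in self.targets],
            "distractors": [enc(t) for t in self.distractors],
            "seed": self.seed,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TestLayout":
        try:
            canvas = CanvasGeometry(**d["canvas"])

            def dec(e: dict) -> TargetSpec:
                return TargetSpec(
                    id=str(e["id"]),
                    label=str(e["label"]),
                    x_mm=float(e["x_mm"]),
                    y_mm=float(e["y_mm"]),
                    base_radius_mm=float(e["base_radius_mm"]),
                    active_radius_mm=float(e["active_radius_mm"]),
                    role=str(e["role"]),
                    order_index=e.get("order_index"),
                )

            return cls(
                test_kind=d["test_kind"],
                language=d.get("language", "it"),
                canvas=canvas,
                targets=tuple(dec(e) for e in d["targets"]),
                distractors=tuple(dec(e) for e in d.get("distractors", [])),
                seed=d.get("seed"),
                metadata=d.get("metadata", {}),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise LayoutError(f"malformed layout: {exc}") from exc

    def layout_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def save_layout(layout: TestLayout, path: str | Path) -> None:
    Path(path).write_text(json.dumps(layout.to_dict(), indent=1) + "\n")


def load_layout(path: str | Path) -> TestLayout:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise LayoutError(f"{path}: not valid JSON ({exc})") from exc
    return TestLayout.from_dict(d)


# ---------------------------------------------------------------------------
# placement


def _place_centers(
    rng: np.random.Generator,
    n: int,
    canvas: CanvasGeometry,
    margin: float,
    min_sep: float,
    max_tries: int = 200_000,
) -> np.ndarray:
    """Seeded rejection sampling of ``n`` centres with pairwise separation.

    Raises :class:`LayoutError` when the constraint cannot be satisfied
    within the try budget (layout-infeasible).
    """
    lo = np.array([margin, margin])
    hi = np.array([canvas.width_mm - margin, canvas.height_mm - margin])
    if np.any(hi <= lo):
        raise LayoutError("canvas too small for the requested margin")
    placed = np.empty((0, 2))
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise LayoutError(
                f"placement infeasible: {len(placed)}/{n} symbols placed with "
                f"min separation {min_sep:.2f} mm on "
                f"{canvas.width_mm:.0f}x{canvas.height_mm:.0f} mm canvas"
            )
        cand = lo + rng.random(2) * (hi - lo)
        if len(placed) and np.min(np.hypot(*(placed - cand).T)) < min_sep:
            continue
        placed = np.vstack([placed, cand])
    return placed


def tmt_labels(variant: str, language: str) -> list[str]:
    """Ordered label sequence for a 20-target TMT sheet."""
    if variant == "A":
        return [str(i) for i in range(1, 21)]
    if variant != "B":
        raise LayoutError(f"unknown TMT variant {variant!r}")
    letters = ITALIAN_LETTERS if language == "it" else ENGLISH_LETTERS
    out: list[str] = []
    for i in range(10):
        out.append(str(i + 1))
        out.append(letters[i])
    return out


def make_tmt_layout(
    variant: str = "A",
    language: str = "it",
    canvas: CanvasGeometry | None = None,
    seed: int = 0,
    base_radius_mm: float = DEFAULT_TMT_RADIUS_MM,
    min_sep_factor: float = 2.5,
) -> TestLayout:
    """Generate a 20-target TMT layout (variant ``A`` or ``B``).

    Placement is deterministic given ``seed``.  The first and last targets
    carry start/end annotations in their metadata, mirroring the written
    signs on the sheet.
    """
    if language not in ("it", "en"):
        raise LayoutError(f"unknown language {language!r}")
    canvas = canvas or TMT_CANVAS
    labels = tmt_labels(variant, language)
    rng = np.random.default_rng(seed)
    # separation keeps even the enlarged final-target area clear of neighbours
    centers = _place_centers(
        rng,
        len(labels),
        canvas,
        margin=base_radius_mm * 2.0,
        min_sep=base_radius_mm * min_sep_factor,
    )
    targets = tuple(
        TargetSpec(
            id=f"t{i + 1:02d}",
            label=lab,
            x_mm=float(c[0]),
            y_mm=float(c[1]),
            base_radius_mm=base_radius_mm,
            active_radius_mm=base_radius_mm,
            role="sequence_target",
            order_index=i + 1,
        )
        for i, (lab, c) in enumerate(zip(labels, centers))
    )
    return TestLayout(
        test_kind="TMT_A" if variant == "A" else "TMT_B",
        language=language,
        canvas=canvas,
        targets=targets,
        seed=seed,
        metadata={
            "placement": "seeded",
            "start_label": labels[0],
            "end_label": labels[-1],
        },
    )


N_BELLS = 35
N_DISTRACTORS = 280


def make_bells_layout(
    canvas: CanvasGeometry | None = None,
    seed: int = 0,
    coords_file: str | Path | None = None,
    symbol_radius_mm: float = DEFAULT_SYMBOL_RADIUS_MM,
) -> TestLayout:
    """Generate the Bells cancellation sheet: 35 bells, 280 distractors.

    Every symbol's active circle is centred on the symbol and covers
    1 + :data:`ACTIVE_AREA_EXCESS` times the symbol surface.  With
    ``coords_file`` (JSON list of ``{x, y, role}``, 315 entries), the given
    coordinates are affinely scaled to the canvas instead of sampled.
    """
    canvas = canvas or BELLS_CANVAS
    active_radius = symbol_radius_mm * math.sqrt(1.0 + ACTIVE_AREA_EXCESS)
    if coords_file is not None:
        entries = json.loads(Path(coords_file).read_text())
        bells = [e for e in entries if e.get("role") == "bell_target"]
        distr = [e for e in entries if e.get("role") == "distractor"]
        if len(bells) != N_BELLS or len(distr) != N_DISTRACTORS:
            raise LayoutError(
                f"coords_file must list {N_BELLS} bells and {N_DISTRACTORS} "
                f"distractors; observed {len(bells)} and {len(distr)}"
            )
        pts = np.array([[e["x"], e["y"]] for e in entries], dtype=float)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        m = symbol_radius_mm * 2.0
        scale = np.array([canvas.width_mm - 2 * m, canvas.height_mm - 2 * m]) / span
        pts = m + (pts - lo) * scale  # monotone affine map per axis
        roles = [e["role"] for e in entries]
        placement = "scaled_from_file"
    else:
        rng = np.random.default_rng(seed)
        pts = _place_centers(
            rng,
            N_BELLS + N_DISTRACTORS,
            canvas,
            margin=symbol_radius_mm * 2.0,
            min_sep=2.0 * active_radius + 0.5,
        )
        roles = ["bell_target"] * N_BELLS + ["distractor"] * N_DISTRACTORS
        placement = "seeded"

    targets, distractors = [], []
    for i, (p, role) in enumerate(zip(pts, roles)):
        spec = TargetSpec(
            id=(f"b{len(targets) + 1:02d}" if role == "bell_target" else f"d{len(distractors) + 1:03d}"),
            label="bell" if role == "bell_target" else "distractor",
            x_mm=float(p[0]),
            y_mm=float(p[1]),
            base_radius_mm=symbol_radius_mm,
            active_radius_mm=active_radius,
            role=role,
        )
        (targets if role == "bell_target" else distractors).append(spec)
    return TestLayout(
        test_kind="BELLS",
        language="it",
        canvas=canvas,
        targets=tuple(targets),
        distractors=tuple(distractors),
        seed=None if coords_file else seed,
        metadata={"placement": placement},
    )


# ---------------------------------------------------------------------------
# subareas

_COLS = "ABC"


def subarea_of(point: tuple[float, float], canvas: CanvasGeometry) -> str:
    """3x3 subarea label of a canvas point, e.g. ``"A1"`` (top-left).

    Columns A,B,C run left to right; rows 1,2,3 top to bottom.  Cells are
    half-open ``[lo, hi)`` except the last row/column, which is closed, so
    every in-canvas point maps to exactly one cell.
    """
    x, y = point
    if not canvas.contains(x, y):
        raise LayoutError(f"point ({x:.1f}, {y:.1f}) outside canvas")
    col = min(int(x / (canvas.width_mm / 3.0)), 2)
    row = min(int(y / (canvas.height_mm / 3.0)), 2)
    return f"{_COLS[col]}{row + 1}"


# ---------------------------------------------------------------------------
# validation


@dataclass
class LayoutReport:
    """Findings from :func:`validate_layout`; empty findings mean valid."""

    findings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, msg: str) -> None:
        self.findings.append(msg)


_EXPECTED_COUNTS = {"TMT_A": (20, 0), "TMT_B": (20, 0), "BELLS": (N_BELLS, N_DISTRACTORS)}


def validate_layout(layout: TestLayout) -> LayoutReport:
    """Check counts, label sequences, id uniqueness, canvas bounds and
    pairwise active-area overlap."""
    rep = LayoutReport()
    exp = _EXPECTED_COUNTS.get(layout.test_kind)
    if exp is None:
        rep.add(f"unknown test_kind {layout.test_kind!r}")
        return rep
    tutorial = bool(layout.metadata.get("tutorial"))
    n_t, n_d = exp
    if not tutorial:
        if len(layout.targets) != n_t:
            rep.add(f"expected {n_t} targets, found {len(layout.targets)}")
        if len(layout.distractors) != n_d:
            rep.add(f"expected {n_d} distractors, found {len(layout.distractors)}")

    ids = [t.id for t in layout.symbols]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        rep.add(f"duplicate ids: {dupes}")

    if layout.test_kind in ("TMT_A", "TMT_B"):
        order = [t.order_index for t in layout.targets]
        if order != list(range(1, len(layout.targets) + 1)):
            rep.add("sequence targets must have consecutive order_index 1..N")
        want = tmt_labels("A" if layout.test_kind == "TMT_A" else "B", layout.language)
        got = [t.label for t in layout.targets]
        if tutorial:
            want = want[: len(got)]
        if len(got) == len(want) and got != want:
            rep.add(f"label sequence mismatch: expected {want}, found {got}")

    for t in layout.symbols:
        if not layout.canvas.contains(t.x_mm, t.y_mm):
            rep.add(f"{t.id}: centre outside canvas")
    syms = layout.symbols
    if syms:
        pts = np.array([[t.x_mm, t.y_mm] for t in syms])
        rad = np.array([t.active_radius_mm for t in syms])
        d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
        lim = rad[:, None] + rad[None, :]
        ii, jj = np.where(np.triu(d < lim, k=1))
        for i, j in zip(ii, jj):
            rep.add(f"active areas overlap: {syms[i].id} and {syms[j].id}")
    return rep
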