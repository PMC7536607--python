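# Methods

`trailbells` implements the scoring core of a tablet-based, vocally
supervised administration of two classic neuropsychological tests: the
Trail Making Test (TMT, parts A and B) and the Bells cancellation test.
This note documents the models, rules and numerical choices the package
makes, and what its synthetic-data experiments do and do not show.

## Test model

**Canvas and layouts.** Coordinates are millimetres with the origin at
the top-left corner, x rightward, y downward. The TMT canvas is
portrait 148×210 mm, the Bells canvas landscape 210×148 mm — a 10.1"
tablet drawing surface. Because the sheet is smaller than the A4
originals, the digitized TMT uses 20 targets (TMT-A labelled 1–20;
TMT-B alternating number/letter, Italian `1,A…10,L` because the Italian
alphabet lacks J and K, English `1,A…10,J`). The Bells sheet keeps the
classic configuration of 35 bells among 280 distractors, scaled to the
canvas. The canonical symbol coordinates of the source sheets are not
publicly available, so layouts are placed by seeded rejection sampling
under a minimum-separation constraint (2.5× the target radius for the
TMT; twice the active radius plus 0.5 mm for Bells); canonical
coordinates can be supplied as JSON and are scaled affinely per axis.
`validate_layout` checks counts, label sequences, id uniqueness, canvas
bounds and pairwise active-area overlap; generators only emit layouts
that validate cleanly.

**Active areas.** A symbol is *hit* when the stylus trace touches its
circular active area. For the TMT the drawn circle is the active area
(default radius 4.5 mm, configurable). For Bells symbols the icon
surface is modelled as a circle of radius 3 mm and the active circle is
centred on the centroid with area exactly 1.2× the symbol surface
(radius ×√1.2). While the final TMT target is the next one to be
reached, its active area grows by the same 20% factor — a robustness
measure for trailing strokes that approach the last circle without
entering it.

## Event detection and classification

Collision testing is continuous: each pair of consecutive pen-down
samples forms a segment that is intersected with every active circle,
so a fast stroke cannot tunnel through a target between 30 Hz samples;
the entry time is interpolated linearly on the segment. Pen lifts break
segments. A circle stays "occupied" until the pen exits it, so dwelling
inside produces one event and a re-entry after an exit is a new hit
(hits are crossings, not dwell samples). Occupancy is derived from the
detected crossings intersected with endpoint containment (with a 10⁻⁹ mm
hysteresis), which keeps membership and entry detection consistent when
a sample lands exactly on a circle boundary.

TMT hits are classified against the expected order: the expected target
is correct (`target_tmt`, order advances); an already-connected target
is a repetition; anything else is an error, after which execution
resumes from the last correctly connected target (the expected index
does not advance). Bells hits on an unfound bell are `target_bells`, on
a distractor `error_bells`; re-marks of an already-marked symbol are not
logged again (the conservative reading — the original log format does
not address repeats).

**Clocks and termination.** The TMT session starts when the first
target is entered; pre-start contacts elsewhere are not logged. The
Bells clock starts at the first ingested sample (a proxy for canvas
presentation). Sessions end on completion (20th target connected in
order / all 35 bells found), on the user's declaration, or at the 300 s
timeout (closed bound: exactly 300 s triggers it, events timestamped at
the deadline). In the Bells test, if more than 45 s pass without a new
bell the engine emits an inactivity prompt, re-armed only by the next
found bell.

## Supervision dialogue

The vocal assistant is re-implemented at the text level as a finite
state machine (phases: explanation → tutorial demo → tutorial practice
→ testing ⇄ awaiting-confirmation → closing). Utterance understanding
is keyword clustering: within a listening context, dictionaries map
case-insensitive substrings onto semantic inputs, first matching
dictionary wins (negated forms are listed before their positive
counterparts so "not finished" is not swallowed by "finished").
Unmatched input triggers one repetition request, then a re-prompt.
Error notifications are capped at three per session — further errors
are still logged, only the utterance is suppressed; repetitions never
notify. The inactivity prompt moves the dialogue to a confirmation
question whose answers either resume the search or terminate the
session as *declared*. Every session, whatever its outcome, closes with
the same accomplishment remark. The full transition table is
`trailbells.supervision.TRANSITIONS`; the spoken texts of the original
system are not published, so the utterance catalog carries intent-level
placeholder strings per language. Tutorials run on a reduced sub-layout
(TMT: 6 targets, 3 demonstrated; Bells: 5 bells among a proportional
distractor slice) flagged `tutorial`, and tutorial sessions are refused
by the indicator computation.

## Indicators

From a finalized session log:

- **Time** — `t(session_end) − t(session_start)`, seconds.
- **Targets / Errors / Repetitions** — event counts; **Errors/targets**
  is their ratio, undefined (absent) when no target was hit.
- **ΔT** — mean of the inter-arrival intervals between consecutive
  correct-target events.
- **ΔT_n** (1 ≤ n ≤ N, N = 20 or 35) — mean interval within the trailing
  window of the last `N − n + 1` target events. The window counts
  *events*, so an m-event window holds m−1 intervals and the one-event
  window (n = N) is reported absent; sessions that ended early truncate
  the window to the events observed. The alternative reading
  ("N − n intervals") differs by one count and is noted as ambiguous;
  the event-window convention is used throughout.
- **NIDmin** (Bells) — the scanning trace connects the first
  min(25, found) bell coordinates in detection order; each component is
  smoothed with a span-3 centred moving average (edge windows shrink to
  two points); the number of inversions in direction per axis is the
  count of strict sign changes between consecutive *nonzero* first
  differences (exact-zero differences are skipped, making the count
  plateau-robust); NIDmin is the minimum of the two axis counts, since a
  scan may be organised horizontally or vertically. Fewer than 3 bells
  → absent; fewer than 25 → computed on all found bells with a
  `truncated` flag.
- **1Bell** (Bells) — the 3×3 subarea (columns A–C left→right, rows 1–3
  top→bottom; half-open cells, far edges closed) containing the pen
  coordinate of the first detected bell. The pen coordinate is the
  logged field; the symbol centroid is available via the layout.
- **TMT-BA** — TMT-B time minus TMT-A time; negative values are
  returned as-is.

## Synthetic traces

The simulator generates 30 Hz traces plus the intended ("ground-truth")
event list, so the engine can be cross-validated end to end. It is a
kinematic sketch, not a biomechanical model: constant-speed straight
segments between waypoints, log-normal inter-target intervals
(positive, right-skewed response times parameterised by mean and CV), a
fatigue slope that inflates successive intervals, and per-transition
error/repetition probabilities.

TMT traces keep the pen down. Legs between targets are routed around
all other active circles by recursive bypass with verified clearance —
a route is accepted only if it enters exactly one circle, the
destination, once; the origin circle may not be re-entered after the
exit. Error detours visit the unconnected out-of-order target closest
to the intended one (plausible, not uniform); repetitions re-visit a
random already-connected target. Leg speeds are set so the active-area
boundary is crossed exactly at the scheduled entry time; the pen then
proceeds to the centroid (crawl capped at 0.25 s) and pauses two sample
periods, as a person decelerating to touch a target does. Pen speed is
capped at 150 mm/s — a fast but plausible stroke for this population —
and intervals drawn shorter than the feasible travel are stretched to
the cap, which also keeps inter-sample chords short relative to the
circle radii. Sample streams contain the nominal 30 Hz grid plus the
motion breakpoints themselves (real tablets jitter; the engine makes no
uniform-rate assumption), so the sampled chords reproduce the planned
polyline exactly. Profiles whose schedule would approach the 300 s
timeout are rejected as infeasible rather than silently truncated.

Bells traces travel pen-up and tap each symbol at its centroid for a
short pen-down dwell, so event coordinates are exact centroids and
event times land on the sample grid. Scan order is `raster_lr`
(globally x-sorted — a left-to-right sweep), `raster_tb` (y-sorted) or
a random permutation, perturbed by `scan_irregularity`: that fraction of
the order length in random transpositions. NID responds strongly to
the first few transpositions and saturates once the order is
effectively scrambled (≈30% swaps), so the dose–response is monotone
but plateaus at high irregularity. Early stopping (`declare_early_prob`
or an explicit stop count) truncates the visit list, pauses 3 s and
issues the declaration.

**Group presets.** `make_group_presets(test)` returns "normal", "MCI"
and "dementia" profiles whose mean inter-target intervals are the
published group medians for that test (TMT-A 1.67/2.10/2.55 s, TMT-B
3.66/6.10/10.07 s, Bells 4.46/5.88/6.59 s) with CV, error rate and scan
irregularity increasing with severity. These are qualitative anchors
for exercising the pipeline, not a fitted patient model; in particular
the presets set the fatigue slope to zero so that ΔT recovery is an
unbiased check of the interval machinery.

**What the simulations show.** Passing the agreement, recovery and
trend suites demonstrates that the engine classifies exactly the events
the generator intended, that the indicator pipeline recovers the
parameters that generated the data, and that the indicators move in the
directions the profile parameters encode. They do not validate the
instrument clinically: real stylus traces have curvature, tremor,
hesitations, palm contacts and hardware noise that the generator does
not emulate, and the preset anchors are group medians, not individual
trajectories.

## Persistence and replay

Sessions are stored as JSON Lines (header with format version, embedded
layout, config, declaration times and pseudonymous metadata; then one
record per raw sample and per event). Reading validates the schema and
reports the offending line. `replay` reconstructs frames at a chosen
rate (`floor(duration·fps)+1` frames; the final frame carries every
event); `export_svg` renders the annotated final frame (target circles,
pen-down strokes, type-specific event markers). `verify_replay` re-runs
the engine over the stored raw trace and reports any divergence from
the stored events — the automated analogue of re-scoring a session from
its replay; engine-produced logs round-trip bit-identically. Subject
identifiers are caller-supplied opaque tokens only.

## Numerical and design notes

- Subarea boundaries are half-open with the far row/column closed, so
  the nine cells partition the canvas with no double assignment.
- The segment/circle entry parameter is the smaller quadratic root
  clipped to the segment; a stroke starting inside a circle (after a
  lift) counts as an entry at the first sample.
- Timeout and prompt deadlines are evaluated against interpolated event
  times, so a hit occurring before the deadline within the same segment
  is logged before the timeout.
- Layout placement failure after a bounded retry budget raises a
  layout-infeasible error naming the violated constraint rather than
  looping forever.
- Default engine constants: 300 s timeout, 45 s inactivity prompt,
  3 notifications, 20% area expansion, 30 Hz nominal sampling; all
  overridable per run and snapshotted into the session log.
- Problem sizes used by the acceptance suites (500 agreement sessions,
  1000 oracle traces, 100 replay round-trips, 200 sessions per preset
  for recovery, 4×50 for the irregularity trend) were chosen to give
  stable statistics at interactive runtimes on a single CPU.

## Known limitations

- Layout coordinates are synthetic stand-ins for the unpublished
  canonical sheets; indicator *values* on real sheets would differ even
  for identical behaviour (1Bell in particular depends on where bells
  actually sit).
- The dialogue manager is text-level; recognition errors, latency and
  prosody of a deployed voice assistant are out of scope.
- The simulator's straight-line kinematics understate path length and
  overstate regularity relative to human strokes; NID values from
  simulated *pen paths* are meaningful only through the bell-order
  scanning trace, which is what the indicator uses.
- Whether the original implementation stops the TMT clock at the final
  target's entry or at pen lift is unspecified; entry time is used.
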