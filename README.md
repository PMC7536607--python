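# trailbells

Digitized, vocally supervised **Trail Making Test** (A/B) and **Bells
cancellation test** for tablet-based cognitive screening — the scoring
engine behind the tests, as a reusable Python library and CLI.

Paper-and-pencil TMT and Bells administrations yield a handful of
numbers (completion time, targets found, error counts). A stylus on a
tablet records the whole trajectory, which makes finer *digital
indicators* computable:

- **Time, Targets, Errors, Errors/targets** — the classic outcomes,
  derived from automatically classified stylus events;
- **ΔT** — the mean time between consecutive correct-target events, a
  per-step processing-speed measure;
- **ΔT_n** — ΔT over the trailing window starting at target *n*
  (the mean interval among the last `N − n + 1` target events),
  sensitive to fatigue and end-of-task slowing;
- **NIDmin** (Bells) — number of inversions in direction: sign changes
  of the first difference of the span-3-smoothed scanning trace through
  the first 25 detected bells, minimised over the horizontal and
  vertical components — a visuo-attentional scan-regularity measure;
- **1Bell** (Bells) — the 3×3 canvas subarea (A–C × 1–3) of the first
  detected bell, the scan starting point;
- **TMT-BA** — TMT-B time minus TMT-A time, the set-shifting cost.

The package provides, per module:

| module | contents |
| --- | --- |
| `trailbells.layout` | canvas + layout generation (TMT-A/B, Bells: 35 bells, 280 distractors), active-area geometry, 3×3 subareas, validation, JSON I/O |
| `trailbells.engine` | stylus-stream session engine: segment/circle collision detection, order-based event classification, start/timeout/declaration logic |
| `trailbells.supervision` | the virtual supervisor: keyword→semantic-input matching, dialogue FSM (error notifications capped at 3, 45 s inactivity confirmation, closing remark), tutorial scripts |
| `trailbells.indicators` | all indicators above from a finalized session log |
| `trailbells.replay` | JSONL session persistence, frame-by-frame replay, SVG export, stored-vs-recomputed consistency checking |
| `trailbells.simulator` | synthetic stylus traces with cognitive-profile parameters and diagnostic-group presets, plus ground-truth event lists |
| `trailbells.cli` | `trailbells` command: `layout`, `simulate`, `run`, `indicators`, `replay`, `dialogue`, `verify` |

## Worked example

Simulate a TMT-A execution with the "MCI" profile (mean inter-target
interval anchored at the published group median of 2.10 s), run the
engine over the raw trace, and score it:

```python
import trailbells as tb
from trailbells.simulator import make_group_presets, SimProfile, simulate_tmt
from trailbells.engine import run_trace
from trailbells.indicators import compute_indicators

layout = tb.make_tmt_layout("A", "it", seed=7)
profile = make_group_presets("tmt_a")["mci"]
profile = SimProfile(**{**profile.__dict__, "seed": 42})

sim = simulate_tmt(layout, profile)          # 30 Hz trace + ground truth
log = run_trace(layout, sim.samples)         # classified session log
ind = compute_indicators(log)

print(f"time_s              {ind.time_s:.2f}")
print(f"targets             {ind.targets}")
print(f"errors              {ind.errors}")
print(f"repetitions         {ind.repetitions}")
print(f"delta_t_s           {ind.delta_t_s:.3f}")
print(f"delta_t_n[15]       {ind.delta_t_series[15]:.3f}")
print(f"end_reason          {ind.end_reason}")
```

prints

```
time_s              38.82
targets             20
errors              0
repetitions         1
delta_t_s           2.043
delta_t_n[15]       2.031
end_reason          completed
```

The simulated participant connected all 20 targets in 38.8 s with one
repeated target and no order errors; the mean inter-target interval of
2.04 s sits near the profile's 2.10 s anchor (one session's mean
scatters around it), and the trailing-window ΔT_15 shows no end-of-task
slowing, as expected with the preset's zero fatigue slope.

The same pipeline from the shell:

```sh
trailbells simulate --test tmt-a --profile mci --seed 42 \
    --out trace.csv --layout-out layout.json
trailbells run --layout layout.json --trace trace.csv --out session.jsonl
trailbells indicators compute --session session.jsonl
trailbells replay --session session.jsonl --fps 2 --out replay.svg
trailbells verify --session session.jsonl
```

## Scope

The package covers layout generation, event detection, supervision
logic, indicators, persistence/replay and simulation. Speech
recognition/synthesis, network transport, the tablet GUI, and clinical
cohort statistics are out of scope; see `docs/methods.md` for the full
model description, design decisions and limitations.
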