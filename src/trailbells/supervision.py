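"""Virtual-supervisor dialogue manager.

A deterministic, text-level re-implementation of the vocal assistant that
accompanies the digitized tests: a finite-state machine whose stimuli are
engine events and *semantic inputs* — utterance classes obtained by
keyword matching, so that different phrasings with the same meaning
("Yes, I understood", "I have understood", "I understand") collapse onto
one token ("understood").

Supervision behaviour:

* on a TMT error the supervisor notifies the user and asks to resume from
  the last correctly connected target, for at most 3 errors — further
  errors are still logged by the engine but produce no utterance;
* repetitions trigger no notification;
* in the Bells Test, after the engine's 45 s inactivity prompt the
  supervisor asks whether all bells have been found and either resumes
  or terminates on the user's answer;
* every session closes with an accomplishment remark regardless of the
  actual score.

Speech recognition and synthesis are out of scope: strings go in,
utterance tokens come out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .engine import TestEvent
from .layout import TestLayout

__all__ = [
    "SemanticDictionary",
    "DialogueState",
    "ProtocolError",
    "TutorialScript",
    "PHASES",
    "TRANSITIONS",
    "DEFAULT_CONTEXTS",
    "UTTERANCES",
    "match_semantic",
    "step_dialogue",
    "run_tutorial",
    "load_dictionaries",
]

PHASES = (
    "explanation",
    "tutorial_demo",
    "tutorial_practice",
    "testing",
    "awaiting_confirmation",
    "closing",
)

MAX_NOTIFICATIONS = 3


class ProtocolError(RuntimeError):
    """Stimulus illegal in the current dialogue phase."""


@dataclass(frozen=True)
class SemanticDictionary:
    """One semantic input and the keywords that map onto it."""

    semantic_input: str
    keywords: tuple[str, ...]


def _ctx(*pairs: tuple[str, Sequence[str]]) -> tuple[SemanticDictionary, ...]:
    seen: set[str] = set()
    dicts = []
    for token, kws in pairs:
        low = {k.lower() for k in kws}
        if low & seen:
            raise ValueError(f"keyword sets overlap at {token!r}")
        seen |= low
        dicts.append(SemanticDictionary(token, tuple(kws)))
    return tuple(dicts)


#: Listening contexts.  Dictionary order matters: within a context the
#: first dictionary containing a matched keyword wins, so negations are
#: listed before their positive counterparts ("not finished" would
#: otherwise substring-match "finished").
DEFAULT_CONTEXTS: dict[str, tuple[SemanticDictionary, ...]] = {
    "comprehension": _ctx(
        ("not_understood", ("not understood", "did not understand", "repeat", "again", "pardon")),
        ("understood", ("understood", "understand", "clear", "yes", "ok")),
    ),
    "found_all": _ctx(
        ("not_finished", ("not finished", "not yet", "still", "no", "keep going")),
        ("finished", ("finished", "done", "all of them", "yes", "that's all")),
    ),
}


def match_semantic(text: str, context: Sequence[SemanticDictionary]) -> str | None:
    """Case-insensitive keyword scan of ``text`` against a listening
    context; returns the semantic input of the first dictionary with a
    matching keyword, or None (caller should request a repetition)."""
    if not context:
        raise ValueError("listening context must hold at least one dictionary")
    low = text.lower()
    for d in context:
        for kw in d.keywords:
            if kw.lower() in low:
                return d.semantic_input
    return None


def load_dictionaries(path: str | Path) -> tuple[SemanticDictionary, ...]:
    """Load a listening context from JSON: [{semantic_input, keywords}]."""
    entries = json.loads(Path(path).read_text())
    return _ctx(*((e["semantic_input"], e["keywords"]) for e in entries))


#: Utterance catalog.  The original spoken texts are not published;
#: these placeholders carry the documented intent per language.
UTTERANCES: dict[str, dict[str, str]] = {
    "explanation_intro": {
        "en": "I will now explain the test.",
        "it": "Ora le spiego il test.",
    },
    "explanation_repeat": {
        "en": "Let me explain it once more.",
        "it": "Glielo spiego di nuovo.",
    },
    "tutorial_demo_intro": {
        "en": "Watch the demonstration on the first targets.",
        "it": "Osservi la dimostrazione sui primi simboli.",
    },
    "practice_prompt": {
        "en": "Now practice with the remaining targets.",
        "it": "Ora si eserciti con i simboli rimanenti.",
    },
    "test_start": {
        "en": "The tutorial is over; the actual test starts now.",
        "it": "Il tutorial è finito; ora inizia il test vero e proprio.",
    },
    "error_notification": {
        "en": "An error was made; please resume from the last correct target.",
        "it": "C'è stato un errore; riprenda dall'ultimo simbolo corretto.",
    },
    "ask_found_all": {
        "en": "Do you believe you have found all the bells?",
        "it": "Crede di aver trovato tutte le campanelle?",
    },
    "resume_test": {
        "en": "Please continue searching.",
        "it": "Continui pure a cercare.",
    },
    "please_repeat": {
        "en": "I did not catch that; could you repeat?",
        "it": "Non ho capito; può ripetere?",
    },
    "closing_remark": {
        "en": "Thank you for taking part in this test.",
        "it": "Grazie per aver partecipato a questo test.",
    },
}

#: FSM command token: not an utterance — tells the engine to terminate
#: the session with reason "declared".
DECLARE_FINISHED = "declare_finished"


@dataclass(frozen=True)
class DialogueState:
    """Immutable dialogue-manager state."""

    phase: str = "explanation"
    notification_count: int = 0
    last_utterance: str | None = None
    repeat_requests: int = 0

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ProtocolError(f"unknown phase {self.phase!r}")
        if not 0 <= self.notification_count <= MAX_NOTIFICATIONS:
            raise ProtocolError("notification_count out of range")


#: Transition table: (phase, stimulus) -> (next phase, action).  Actions
#: are utterance tokens, the engine command `declare_finished`, or None
#: for legal no-ops.  Stimuli are engine event types or semantic inputs.
TRANSITIONS: dict[tuple[str, str], tuple[str, str | None]] = {
    ("explanation", "understood"): ("tutorial_demo", "tutorial_demo_intro"),
    ("explanation", "not_understood"): ("explanation", "explanation_repeat"),
    ("tutorial_demo", "demo_done"): ("tutorial_practice", "practice_prompt"),
    ("tutorial_practice", "practice_done"): ("testing", "test_start"),
    ("testing", "target_tmt"): ("testing", None),
    ("testing", "target_bells"): ("testing", None),
    ("testing", "repetition_tmt"): ("testing", None),
    ("testing", "error_bells"): ("testing", None),
    ("testing", "error_tmt"): ("testing", "error_notification"),  # capped at 3
    ("testing", "inactivity_prompt"): ("awaiting_confirmation", "ask_found_all"),
    ("testing", "timeout"): ("testing", None),
    ("testing", "declaration_finished"): ("testing", None),
    ("testing", "session_end"): ("closing", "closing_remark"),
    ("awaiting_confirmation", "finished"): ("testing", DECLARE_FINISHED),
    ("awaiting_confirmation", "not_finished"): ("testing", "resume_test"),
    ("awaiting_confirmation", "target_bells"): ("testing", None),
    ("awaiting_confirmation", "session_end"): ("closing", "closing_remark"),
    ("awaiting_confirmation", "declaration_finished"): ("awaiting_confirmation", None),
}


def step_dialogue(
    state: DialogueState, stimulus: TestEvent | str
) -> tuple[DialogueState, str | None]:
    """Advance the FSM on an engine event or a semantic input.

    Returns the new state and an action: an utterance token, the command
    ``declare_finished``, or None.  Unknown (unmatched) semantic input is
    represented by the empty token ``""`` and triggers a repetition
    request.  Illegal transitions raise :class:`ProtocolError`.
    """
    token = stimulus.event_type if isinstance(stimulus, TestEvent) else stimulus
    if token == "":
        # unmatched utterance: ask once for a repetition, then re-prompt
        utt = "please_repeat" if state.repeat_requests == 0 else state.last_utterance
        return replace(state, repeat_requests=state.repeat_requests + 1), utt
    key = (state.phase, token)
    if key not in TRANSITIONS:
        raise ProtocolError(f"stimulus {token!r} illegal in phase {state.phase!r}")
    next_phase, action = TRANSITIONS[key]
    count = state.notification_count
    if action == "error_notification":
        if count >= MAX_NOTIFICATIONS:
            action = None  # errors beyond the third pass silently
        else:
            count += 1
    new = DialogueState(
        phase=next_phase,
        notification_count=count,
        last_utterance=action if action in UTTERANCES else state.last_utterance,
        repeat_requests=0,
    )
    return new, action


@dataclass(frozen=True)
class TutorialScript:
    """Deterministic tutorial: demo highlights then a practice subset.

    Practice runs through the engine in tutorial mode; its events carry
    ``tutorial=True`` metadata and are never scored.
    """

    demo_ids: tuple[str, ...]
    practice_ids: tuple[str, ...]
    practice_layout: TestLayout


def run_tutorial(
    layout: TestLayout, subset_size: int | None = None, demo_size: int | None = None
) -> TutorialScript:
    """Build the tutorial script for a layout.

    A small subset of targets is shown; the app demonstrates the first
    ``demo_size`` of them and the user practices with the remainder.
    Defaults: TMT 6 targets (3 demonstrated), Bells 5 bells (2
    demonstrated) among a proportional slice of distractors.
    """
    is_tmt = layout.test_kind in ("TMT_A", "TMT_B")
    subset_size = subset_size or (6 if is_tmt else 5)
    demo_size = demo_size if demo_size is not None else (3 if is_tmt else 2)
    if not 0 < demo_size < subset_size <= len(layout.targets):
        raise ValueError("need 0 < demo_size < subset_size <= number of targets")
    subset = layout.targets[:subset_size]
    if is_tmt:
        practice = subset
        distractors = ()
    else:
        practice = subset
        k = round(len(layout.distractors) * subset_size / len(layout.targets))
        distractors = layout.distractors[:k]
    practice_layout = TestLayout(
        test_kind=layout.test_kind,
        language=layout.language,
        canvas=layout.canvas,
        targets=practice,
        distractors=distractors,
        seed=layout.seed,
        metadata={**layout.metadata, "tutorial": True},
    )
    return TutorialScript(
        demo_ids=tuple(t.id for t in subset[:demo_size]),
        practice_ids=tuple(t.id for t in subset[demo_size:]),
        practice_layout=practice_layout,
    )
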