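"""The six adaptive training exercises and the per-session scheduler.

One session = six 3-minute exercise blocks (18 active minutes) played in a
seeded random order.  Difficulty persists across sessions through a
:class:`SessionState` dict.  Adaptation rules per exercise:

* ``stop``: anticipated-response stop exercise; SSD staircase, -50 ms after
  a failed stop, +50 ms after a successful stop, clamped to [300, 700].
* ``flanker``: difficulty level raises the distractor count and the target
  onset delay; level +1 after 8 consecutive correct, -1 after 2 consecutive
  errors.
* ``vspan`` / ``dspan``: list length +1 after two consecutive correct
  recalls, -1 after two consecutive failures (floor 2).
* ``switching``: levels move from one-dimension to two-dimension rules;
  at advanced levels (>= 4) windstorm events temporarily reverse the rule.
* ``matching``: the sorting dimension changes after a run of consecutive
  correct responses whose required length steps down the 12 -> 8 -> 6 -> 4
  ladder as each rung is achieved.

Trial budgets per block are simulation parameters (default 40); the
exercises are specified in minutes, not trial counts, so the budget is a
documented stand-in for a typical 3-minute pace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ..policies import ResponderPolicy
from .records import SessionLog, TrialLog, TrialRecord
from .staircase import StaircaseState

EXERCISES = ("stop", "flanker", "vspan", "dspan", "switching", "matching")
MATCHING_LADDER = (12, 8, 6, 4)

#: exercise id -> cognitive domain whose policy drives it
EXERCISE_DOMAINS = {
    "stop": "response_inhibition",
    "flanker": "interference_control",
    "vspan": "verbal_wm",
    "dspan": "visuospatial_wm",
    "switching": "switching",
    "matching": "matching",
}


@dataclass
class SessionState:
    """Per-exercise difficulty carried from one session to the next."""

    ssd: float = 500.0
    flanker_level: int = 1
    vspan_length: int = 2
    dspan_length: int = 2
    switching_level: int = 1
    matching_rung: int = 0          # index into MATCHING_LADDER
    extras: dict[str, Any] = field(default_factory=dict)

    def snapshot(self) -> dict[str, Any]:
        return {
            "ssd": self.ssd, "flanker_level": self.flanker_level,
            "vspan_length": self.vspan_length, "dspan_length": self.dspan_length,
            "switching_level": self.switching_level, "matching_rung": self.matching_rung,
        }


def _p_correct_flanker(policy: ResponderPolicy, level: int) -> float:
    # more distractors / later target onset -> harder
    edge = (policy["base_rt"] - 550.0) / 200.0  # slower base RT = weaker child
    return float(np.clip(0.95 - 0.05 * (level - 1) - 0.1 * edge, 0.05, 0.99))


def _run_stop_block(policy, state: SessionState, rng, budget: int) -> TrialLog:
    stair = StaircaseState(current_value=state.ssd)
    log = TrialLog(task="train_stop")
    for i in range(budget):
        if rng.random() < 0.25:
            ssd = stair.current_value
            lift = max(0.0, rng.normal(policy["go_mean"], policy["go_sd"]))
            stopped = ssd + policy["ssrt_true"] <= lift
            stair.update(stopped)
            log.append(TrialRecord("train_stop", "block", i, "stop", correct=bool(stopped), ssd=ssd))
        else:
            rt = max(0.0, rng.normal(policy["go_mean"], policy["go_sd"]))
            log.append(TrialRecord("train_stop", "block", i, "go", response="lift", rt=rt))
    state.ssd = stair.current_value
    return log


def _run_flanker_block(policy, state: SessionState, rng, budget: int) -> TrialLog:
    log = TrialLog(task="train_flanker")
    streak_ok = streak_err = 0
    for i in range(budget):
        level = state.flanker_level
        ok = rng.random() < _p_correct_flanker(policy, level)
        log.append(TrialRecord("train_flanker", "block", i, "flanker", correct=bool(ok),
                               stimulus={"level": level, "n_distractors": 2 + level,
                                         "onset_delay_ms": 50 * (level - 1)}))
        if ok:
            streak_ok, streak_err = streak_ok + 1, 0
            if streak_ok == 8:
                state.flanker_level += 1
                streak_ok = 0
        else:
            streak_err, streak_ok = streak_err + 1, 0
            if streak_err == 2 and state.flanker_level > 1:
                state.flanker_level -= 1
                streak_err = 0
    return log


def _run_span_block(policy, state: SessionState, rng, budget: int, attr: str, task: str) -> TrialLog:
    log = TrialLog(task=task)
    streak_ok = streak_err = 0
    for i in range(budget):
        length = getattr(state, attr)
        ok = length <= policy["capacity"] and rng.random() >= policy["lapse"]
        log.append(TrialRecord(task, "block", i, f"len{length}", correct=bool(ok),
                               stimulus={"length": length}))
        if ok:
            streak_ok, streak_err = streak_ok + 1, 0
            if streak_ok == 2:
                setattr(state, attr, length + 1)
                streak_ok = 0
        else:
            streak_err, streak_ok = streak_err + 1, 0
            if streak_err == 2 and length > 2:
                setattr(state, attr, length - 1)
                streak_err = 0
    return log


def _run_switching_block(policy, state: SessionState, rng, budget: int) -> TrialLog:
    log = TrialLog(task="train_switching")
    streak_ok = streak_err = 0
    reversed_rule = False
    for i in range(budget):
        level = state.switching_level
        two_dim = level >= 2
        if level >= 4 and rng.random() < 0.1:
            reversed_rule = not reversed_rule  # windstorm event
        base = 1.0 - policy["slip_prob"]
        p = float(np.clip(base - (0.10 if two_dim else 0.0)
                          - (0.5 * policy["perseveration_prob"] if reversed_rule else 0.0)
                          - 0.02 * max(0, level - 2), 0.05, 0.99))
        ok = rng.random() < p
        log.append(TrialRecord("train_switching", "block", i, "switch", correct=bool(ok),
                               stimulus={"level": level, "two_dimension": two_dim,
                                         "reversed": reversed_rule}))
        if ok:
            streak_ok, streak_err = streak_ok + 1, 0
            if streak_ok == 6:
                state.switching_level += 1
                streak_ok = 0
        else:
            streak_err, streak_ok = streak_err + 1, 0
            if streak_err == 2 and state.switching_level > 1:
                state.switching_level -= 1
                streak_err = 0
    return log


def _run_matching_block(policy, state: SessionState, rng, budget: int) -> TrialLog:
    log = TrialLog(task="train_matching")
    streak = 0
    for i in range(budget):
        rung = min(state.matching_rung, len(MATCHING_LADDER) - 1)
        need = MATCHING_LADDER[rung]
        ok = rng.random() < policy["acc_advanced"]
        log.append(TrialRecord("train_matching", "block", i, "match", correct=bool(ok),
                               stimulus={"change_after": need}))
        if ok:
            streak += 1
            if streak == need:          # dimension changes; ladder steps down
                if state.matching_rung < len(MATCHING_LADDER) - 1:
                    state.matching_rung += 1
                streak = 0
        else:
            streak = 0
    return log


_RUNNERS = {
    "stop": _run_stop_block,
    "flanker": _run_flanker_block,
    "vspan": lambda p, s, r, b: _run_span_block(p, s, r, b, "vspan_length", "train_vspan"),
    "dspan": lambda p, s, r, b: _run_span_block(p, s, r, b, "dspan_length", "train_dspan"),
    "switching": _run_switching_block,
    "matching": _run_matching_block,
}


def run_training_session(
    policy_set: dict[str, ResponderPolicy],
    session_state: SessionState,
    seed: int | np.random.Generator,
    participant_id: str = "p0",
    session_index: int = 1,
    trial_budget: int = 40,
) -> SessionLog:
    """Play one full session (six exercises, seeded random order)."""
    for ex in EXERCISES:
        if ex not in policy_set:
            raise KeyError(f"policy_set missing exercise {ex!r}")
    unknown = set(policy_set) - set(EXERCISES)
    if unknown:
        raise KeyError(f"unknown exercise id(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = list(EXERCISES)
    rng.shuffle(order)
    start = session_state.snapshot()
    blocks = {}
    for ex in order:
        blocks[ex] = _RUNNERS[ex](policy_set[ex], session_state, rng, trial_budget)
    return SessionLog(
        participant_id=participant_id, session_index=session_index,
        exercise_order=order, blocks=blocks,
        difficulty_start=start, difficulty_end=session_state.snapshot(),
    )
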