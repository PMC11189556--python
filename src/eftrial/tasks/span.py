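"""Serial span tasks: backwards digit span and spatial block tapping.

Both tasks ascend from a span of two.  A responder recalls a sequence
correctly iff the span does not exceed its (continuous) capacity and no
attention lapse occurs on that trial.

Digit span: two trials per span, advance when at least one of the two is
correct, end when both trials at a span fail.

Block tapping (Corsi): advancement requires two *consecutive* correct
recalls of the current length; the task discontinues once two trials at a
length have been failed.  A length resolved 1-of-2 is re-presented once
more (hard cap of three trials per length); with at least two of three
correct the length is passed, otherwise the task ends.  Spans run 2..9.
"""

from __future__ import annotations

import numpy as np

from ..policies import ResponderPolicy
from .records import TrialLog, TrialRecord


def _recall_ok(policy: ResponderPolicy, span: int, rng: np.random.Generator) -> bool:
    if span > policy["capacity"]:
        return False
    return rng.random() >= policy["lapse"]


def run_digit_span(
    policy: ResponderPolicy,
    seed: int | np.random.Generator = 0,
    start_span: int = 2,
    max_span: int = 9,
) -> TrialLog:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    log = TrialLog(task="digit_span", meta={"direction": "backwards"})
    idx = 0
    for span in range(start_span, max_span + 1):
        outcomes = []
        for _ in range(2):
            ok = _recall_ok(policy, span, rng)
            log.append(TrialRecord("digit_span", f"span_{span}", idx, f"span{span}",
                                   response="recall", correct=ok, stimulus={"span": span}))
            outcomes.append(ok)
            idx += 1
        if not any(outcomes):
            break
    return log


def run_corsi(
    policy: ResponderPolicy,
    seed: int | np.random.Generator = 0,
    start_span: int = 2,
    max_span: int = 9,
    max_trials_per_span: int = 3,
) -> TrialLog:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    log = TrialLog(task="corsi")
    idx = 0
    for span in range(start_span, max_span + 1):
        outcomes: list[bool] = []
        advanced = False
        while len(outcomes) < max_trials_per_span:
            ok = _recall_ok(policy, span, rng)
            log.append(TrialRecord("corsi", f"span_{span}", idx, f"span{span}",
                                   response="recall", correct=ok, stimulus={"span": span}))
            outcomes.append(ok)
            idx += 1
            if len(outcomes) >= 2 and outcomes[-1] and outcomes[-2]:
                advanced = True          # two consecutive correct
                break
            if outcomes.count(False) >= 2:
                break                    # two failures at this length
        if not advanced and len(outcomes) == max_trials_per_span:
            advanced = outcomes.count(True) >= 2
        if not advanced:
            break
    return log
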