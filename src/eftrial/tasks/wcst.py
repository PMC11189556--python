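"""Modified card-sorting task (48 non-ambiguous cards, feedback-driven).

The active sorting criterion cycles colour -> shape -> number and changes,
unannounced, after 6 consecutive correct sorts.  The responder maintains a
believed criterion: it keeps it after positive feedback; after negative
feedback it either perseverates (repeats the now-wrong criterion, with the
policy's perseveration probability) or moves deterministically to the next
dimension in the cycle.  Independently, an attention slip replaces the
intended sort with a uniformly random different dimension.

Each trial logs the active criterion and the responded dimension, which is
all the scorer needs to classify errors as perseverative (matching the
immediately preceding criterion, once a switch has occurred) or not.
"""

from __future__ import annotations

import numpy as np

from ..policies import ResponderPolicy
from .records import TrialLog, TrialRecord

DIMENSIONS = ("colour", "shape", "number")
N_TRIALS = 48
RUN_LENGTH = 6


def run_wcst(
    policy: ResponderPolicy,
    seed: int | np.random.Generator = 0,
    criterion_order: tuple[str, ...] = DIMENSIONS,
    initial_belief: str = "colour",
    strategy: str = "learner",
) -> TrialLog:
    """Administer 48 sorting trials.

    ``strategy``: "learner" (feedback-driven, default), "omniscient" (always
    sorts by the active criterion; a ceiling probe) or "fixed:<dimension>"
    (ignores feedback entirely; a perseveration probe).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    log = TrialLog(task="wcst", meta={"criterion_order": list(criterion_order)})
    crit_idx = 0
    previous_criterion: str | None = None
    belief = initial_belief
    run = 0
    n_switches = 0
    for i in range(N_TRIALS):
        criterion = criterion_order[crit_idx % len(criterion_order)]
        if strategy == "omniscient":
            response = criterion
        elif strategy.startswith("fixed:"):
            response = strategy.split(":", 1)[1]
        else:
            response = belief
            if rng.random() < policy["slip_prob"]:
                others = [d for d in DIMENSIONS if d != belief]
                response = others[rng.integers(len(others))]
        correct = response == criterion
        log.append(TrialRecord(
            "wcst", "main", i, "sort", response=response, correct=correct,
            stimulus={"criterion": criterion, "previous_criterion": previous_criterion},
        ))
        if correct:
            belief = response       # positive feedback confirms the dimension
            run += 1
            if run == RUN_LENGTH:
                previous_criterion = criterion
                crit_idx += 1
                n_switches += 1
                run = 0
        else:
            run = 0
            if strategy == "learner" and rng.random() >= policy["perseveration_prob"]:
                nxt = (DIMENSIONS.index(belief) + 1) % len(DIMENSIONS)
                belief = DIMENSIONS[nxt]
            # else: perseverate, keep the same belief
    log.meta["n_criterion_changes"] = n_switches
    return log
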