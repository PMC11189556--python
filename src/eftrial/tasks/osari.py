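"""Anticipated-response stop-signal task (bar-filling paradigm).

The child holds a key while a bar fills over 1000 ms and must lift at the
800 ms target.  On stop trials the bar freezes at the stop-signal delay
(SSD) and the lift must be withheld.  Behaviour follows the independent
race model: a planned lift time is drawn from the go distribution and races
the stop process, which finishes at SSD + true SSRT.  The stop process wins
ties.  SSD tracks performance with a 50 ms one-up/one-down staircase
clamped to [300, 700] ms.

Schedule: 10 practice go trials, 20 mixed practice trials (15 go / 5 stop),
then three test blocks of 60 trials each at 75% go / 25% stop, randomly
ordered within block (135 go and 45 stop test trials in total).
"""

from __future__ import annotations

import numpy as np

from ..policies import ResponderPolicy
from .records import TrialLog, TrialRecord
from .staircase import StaircaseState

GO_TARGET_MS = 800.0
BAR_FULL_MS = 1000.0
TEST_BLOCKS = 3
TRIALS_PER_BLOCK = 60
STOP_FRACTION = 0.25


def run_osari(
    policy: ResponderPolicy,
    seed: int | np.random.Generator,
    staircase: StaircaseState | None = None,
) -> TrialLog:
    for name in ("go_mean", "go_sd", "ssrt_true", "omission_rate"):
        if name not in policy.params:
            raise ValueError(f"policy missing parameter {name!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    stair = staircase or StaircaseState()
    log = TrialLog(task="osari", meta={"go_target_ms": GO_TARGET_MS})

    def planned_lift() -> float:
        return max(0.0, rng.normal(policy["go_mean"], policy["go_sd"]))

    def go_trial(block: str, index: int) -> TrialRecord:
        if rng.random() < policy["omission_rate"]:
            return TrialRecord("osari", block, index, "go", response=None, rt=None)
        rt = planned_lift()
        return TrialRecord("osari", block, index, "go", response="lift", rt=rt)

    def stop_trial(block: str, index: int) -> TrialRecord:
        ssd = stair.current_value
        lift = planned_lift()
        omitted = rng.random() < policy["omission_rate"]
        stop_finish = ssd + policy["ssrt_true"]
        # stop wins on a tie; an omission is trivially a successful stop
        stopped = omitted or stop_finish <= lift
        stair.update(stopped)
        if stopped:
            return TrialRecord("osari", block, index, "stop", response=None, rt=None,
                               correct=True, ssd=ssd)
        return TrialRecord("osari", block, index, "stop", response="lift", rt=lift,
                           correct=False, ssd=ssd)

    idx = 0
    for _ in range(10):
        log.append(go_trial("practice_go", idx)); idx += 1
    mixed = ["go"] * 15 + ["stop"] * 5
    rng.shuffle(mixed)
    for kind in mixed:
        log.append(go_trial("practice_mixed", idx) if kind == "go" else stop_trial("practice_mixed", idx))
        idx += 1
    n_stop = int(TRIALS_PER_BLOCK * STOP_FRACTION)
    for b in range(TEST_BLOCKS):
        kinds = ["go"] * (TRIALS_PER_BLOCK - n_stop) + ["stop"] * n_stop
        rng.shuffle(kinds)
        block = f"test_{b + 1}"
        for kind in kinds:
            log.append(go_trial(block, idx) if kind == "go" else stop_trial(block, idx))
            idx += 1
    log.meta["final_ssd"] = stair.current_value
    return log
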