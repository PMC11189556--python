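"""Child flanker task with alerting/orienting cues (attention-network paradigm).

A central fish points left or right; flanking fish are congruent or
incongruent.  One of four cues (none, centre, double, spatial) precedes the
target.  Reaction times are generated additively: base RT, plus the
congruency cost on incongruent trials, minus an alerting benefit on any
informative cue, minus an additional orienting benefit on spatial cues,
plus Gaussian noise.  The three standard subtraction scores then recover
the generative benefits/cost in expectation.

Schedule: one practice block of 24 trials (12 target-only, 12 flankered;
excluded from scoring) and three experimental blocks of 48 trials, each
balanced over 2 congruency x 4 cue cells.
"""

from __future__ import annotations

import numpy as np

from ..policies import ResponderPolicy
from .records import TrialLog, TrialRecord

CUES = ("no", "centre", "double", "spatial")
EXPERIMENTAL_BLOCKS = 3
TRIALS_PER_BLOCK = 48


def run_ant(policy: ResponderPolicy, seed: int | np.random.Generator) -> TrialLog:
    for name in ("base_rt", "congruency_cost", "alerting_benefit", "orienting_benefit", "noise_sd"):
        if name not in policy.params:
            raise ValueError(f"policy missing parameter {name!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    log = TrialLog(task="ant")
    idx = 0

    def emit(block: str, congruency: str, cue: str) -> None:
        nonlocal idx
        fixation = rng.uniform(400.0, 1600.0)
        stim = {"cue": cue, "fixation_ms": fixation, "direction": "left" if rng.random() < 0.5 else "right"}
        if rng.random() < policy["omission_rate"]:
            log.append(TrialRecord("ant", block, idx, congruency, response=None, rt=None,
                                   correct=False, stimulus=stim))
            idx += 1
            return
        rt = policy["base_rt"] + rng.normal(0.0, policy["noise_sd"])
        if congruency == "incongruent":
            rt += policy["congruency_cost"]
        if cue != "no":
            rt -= policy["alerting_benefit"]
        if cue == "spatial":
            rt -= policy["orienting_benefit"]
        if rng.random() < policy["anticipation_rate"]:
            rt = rng.uniform(0.0, 99.0)  # fast guess, excluded by the <100 ms rule
        rt = max(0.0, rt)
        log.append(TrialRecord("ant", block, idx, congruency, response=stim["direction"],
                               rt=rt, correct=True, stimulus=stim))
        idx += 1

    practice = ["target_only"] * 12 + ["flanker"] * 12
    rng.shuffle(practice)
    for kind in practice:
        congruency = "congruent" if kind == "target_only" else ("congruent" if rng.random() < 0.5 else "incongruent")
        emit("practice", congruency, "no")
    for b in range(EXPERIMENTAL_BLOCKS):
        cells = [(c, q) for c in ("congruent", "incongruent") for q in CUES] * (TRIALS_PER_BLOCK // 8)
        rng.shuffle(cells)
        for congruency, cue in cells:
            emit(f"exp_{b + 1}", congruency, cue)
    return log
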