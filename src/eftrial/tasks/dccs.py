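"""Dimensional card sort: pre-switch, post-switch and advanced phases.

Six trials under the first sorting rule (pre-switch), six after the rule
changes (post-switch; the rule to apply is announced each trial, so memory
load is minimal).  With at least five of six post-switch trials correct the
child progresses to a 12-trial advanced phase in which the rule is verbally
cued trial-by-trial.  The responder applies the announced rule with a
per-phase accuracy from its policy.

The pre-switch pass criterion is not part of the published task description
(only post-switch and advanced criteria are); it is set to the same 5-of-6
rule by analogy and is configurable.
"""

from __future__ import annotations

import numpy as np

from ..policies import ResponderPolicy
from .records import TrialLog, TrialRecord

PHASE_TRIALS = {"pre_switch": 6, "post_switch": 6, "advanced": 12}
PASS_THRESHOLDS = {"pre_switch": 5, "post_switch": 5, "advanced": 9}


def run_dccs(policy: ResponderPolicy, seed: int | np.random.Generator = 0) -> TrialLog:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    log = TrialLog(task="dccs", meta={"pass_thresholds": dict(PASS_THRESHOLDS)})
    acc = {"pre_switch": policy["acc_pre"], "post_switch": policy["acc_post"],
           "advanced": policy["acc_advanced"]}
    idx = 0
    n_correct = {}
    for phase in ("pre_switch", "post_switch"):
        n_correct[phase] = 0
        for t in range(PHASE_TRIALS[phase]):
            rule = "colour" if phase == "pre_switch" else "shape"
            ok = rng.random() < acc[phase]
            n_correct[phase] += ok
            log.append(TrialRecord("dccs", phase, idx, phase, response="sort",
                                   correct=bool(ok), stimulus={"rule": rule}))
            idx += 1
    if n_correct["post_switch"] >= PASS_THRESHOLDS["post_switch"]:
        for t in range(PHASE_TRIALS["advanced"]):
            rule = "colour" if rng.random() < 0.5 else "shape"  # cued per trial
            ok = rng.random() < acc["advanced"]
            log.append(TrialRecord("dccs", "advanced", idx, "advanced", response="sort",
                                   correct=bool(ok), stimulus={"rule": rule}))
            idx += 1
    return log
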