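"""Link between latent executive-function ability and generative task behaviour.

Each cognitive domain has a documented population-default parameterisation
(the behaviour of a child at the latent mean, z = 0) and a linear link that
makes behaviour strictly better as z increases: shorter true stopping
latency, smaller flanker interference cost, larger memory span, lower
perseveration probability, higher rule-application accuracy.  The link
coefficients live in :data:`POLICY_LINKS` and are configurable; every task
engine consumes a :class:`ResponderPolicy` and nothing else, so the mapping
is the single place where "ability" acquires behavioural meaning.

Sign conventions: RT-like parameters (ms) and error probabilities decrease
in z, spans and accuracies increase in z.  All parameters are clipped to
their physical ranges after the linear link is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

DOMAINS = (
    "response_inhibition",
    "interference_control",
    "verbal_wm",
    "visuospatial_wm",
    "switching",
    "matching",
    "everyday_ef",
    "sewb",
)

#: domain -> parameter -> (intercept at z=0, slope per z, lower clip, upper clip)
POLICY_LINKS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "response_inhibition": {
        # anticipated-response stop task: timed lift toward an 800 ms target
        "ssrt_true": (350.0, -40.0, 80.0, 650.0),
        "go_mean": (800.0, 0.0, 500.0, 1000.0),
        "go_sd": (60.0, -10.0, 15.0, 200.0),
        "omission_rate": (0.05, -0.02, 0.0, 0.4),
    },
    "interference_control": {
        "base_rt": (750.0, -60.0, 300.0, 1500.0),
        "congruency_cost": (100.0, -25.0, 5.0, 400.0),
        "alerting_benefit": (40.0, 0.0, 0.0, 200.0),
        "orienting_benefit": (40.0, 0.0, 0.0, 200.0),
        "noise_sd": (120.0, 0.0, 0.0, 500.0),
        "omission_rate": (0.03, -0.01, 0.0, 0.4),
        "anticipation_rate": (0.01, -0.004, 0.0, 0.2),
    },
    "verbal_wm": {
        # backwards digit span; capacity is continuous, a span succeeds iff
        # span <= capacity (and no lapse)
        "capacity": (3.8, 1.0, 0.0, 12.0),
        "lapse": (0.08, -0.03, 0.005, 0.6),
    },
    "visuospatial_wm": {
        "capacity": (4.3, 1.0, 0.0, 12.0),
        "lapse": (0.08, -0.03, 0.005, 0.6),
    },
    "switching": {
        # card-sorting behaviour: after negative feedback the child either
        # perseverates on the old criterion or moves on; slips are attention
        # failures on otherwise-known rules
        "perseveration_prob": (0.45, -0.15, 0.02, 0.9),
        "slip_prob": (0.15, -0.05, 0.01, 0.5),
    },
    "matching": {
        "acc_pre": (0.95, 0.02, 0.05, 1.0),
        "acc_post": (0.86, 0.05, 0.05, 1.0),
        "acc_advanced": (0.78, 0.08, 0.05, 1.0),
    },
    "everyday_ef": {
        # parent-rated executive dysfunction composite (raw scale, higher = worse)
        "gec_mean": (105.0, -10.0, 63.0, 189.0),
        "gec_sd": (9.0, 0.0, 1.0, 30.0),
    },
    "sewb": {
        # strengths-and-difficulties total (0-40, higher = more problems)
        "sdq_mean": (9.0, -2.5, 0.0, 40.0),
        "sdq_sd": (4.0, 0.0, 0.5, 15.0),
    },
}

#: parameters for which *larger* is better (all others improve by shrinking)
_INCREASING = {"capacity", "acc_pre", "acc_post", "acc_advanced", "go_mean"}


@dataclass
class ResponderPolicy:
    """Generative behavioural parameters for one domain at one timepoint."""

    domain: str
    params: dict[str, float] = field(default_factory=dict)
    z: float = 0.0

    def __post_init__(self) -> None:
        if self.domain not in POLICY_LINKS:
            raise KeyError(f"unknown domain: {self.domain!r}")
        for name, value in self.params.items():
            if name.endswith(("_rate", "prob", "lapse")) or name.startswith("acc_"):
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"{name} must be a probability, got {value}")
            if name in ("ssrt_true", "go_mean", "go_sd", "base_rt", "noise_sd") and value <= 0:
                raise ValueError(f"{name} must be > 0")
            if name == "capacity" and value < 0:
                raise ValueError("capacity must be >= 0")

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def make_policy(domain: str, z: float, links: dict | None = None) -> ResponderPolicy:
    """Build the :class:`ResponderPolicy` implied by latent ability ``z``.

    At z = 0 the policy sits exactly at the documented population defaults;
    the link is linear in z with clipping at physical bounds, so higher z is
    never worse on any parameter.
    """
    table = (links or POLICY_LINKS).get(domain)
    if table is None:
        raise KeyError(f"unknown domain: {domain!r}")
    params = {}
    for name, (b0, b1, lo, hi) in table.items():
        params[name] = min(hi, max(lo, b0 + b1 * z))
    return ResponderPolicy(domain=domain, params=params, z=z)


def policy_improves(a: ResponderPolicy, b: ResponderPolicy) -> bool:
    """True when ``a`` is at least as good as ``b`` on every parameter and
    strictly better on at least one (ignoring pure nuisance scales)."""
    if a.domain != b.domain:
        raise ValueError("policies from different domains are not comparable")
    strictly = False
    for name in a.params:
        pa, pb = a.params[name], b.params[name]
        better = pa >= pb if name in _INCREASING else pa <= pb
        if not better and not math.isclose(pa, pb):
            return False
        if not math.isclose(pa, pb):
            strictly = True
    return strictly
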