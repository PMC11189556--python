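"""Synthetic cohort generator for the two-arm school trial.

Simulated children carry latent executive-function abilities (z-scores) for
eight domains at three timepoints.  Baseline abilities are multivariate
normal with a configurable cross-domain correlation and a classroom random
intercept that induces the requested intra-class correlation; abilities at
later timepoints follow an AR(1) in the individual component, so the
marginal variance and the classroom ICC are stable over time.  The
intervention effect enters as a mean shift of ``effect_sizes[domain]``
standard deviations on the intervention arm at the post-intervention
occasion, retained at a configurable fraction at follow-up.  Because the
latent scale is unit-variance, the injected shift *is* the standardized
group difference in latent ability.

Demographics (age, IQ, gender, motivation, family functioning) are drawn
from distributions matched to the trial's baseline table; the continuous
``ses_index`` is a synthetic stand-in (the source reports only categorical
caregiver education) and is used solely as an imputation auxiliary and
compliance covariate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .policies import DOMAINS, ResponderPolicy, make_policy

TIMEPOINTS = ("T1", "T2", "T3")


@dataclass
class CohortConfig:
    n_control: int = 60
    n_intervention: int = 55
    n_classrooms: int = 6
    age_range: tuple[float, float] = (6.0, 9.0)   # children aged 6-8 years
    age_mean: float = 7.46
    age_sd: float = 0.61
    iq_mean: float = 104.75
    iq_sd: float = 14.22
    iq_floor: float = 70.0
    effect_sizes: dict[str, float] = field(default_factory=dict)
    retention: float = 1.0          # fraction of the T2 effect retained at T3
    classroom_icc: float = 0.1
    cross_domain_corr: float = 0.3
    stability: float = 0.7          # occasion-to-occasion latent autocorrelation
    drift: dict[str, float] = field(default_factory=dict)  # timepoint -> shift (both arms)
    adherence_beta: tuple[float, float] = (6.0, 4.0)  # mean 0.6 -> ~12/20 sessions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_intervention <= 0:
            raise ValueError("arm sizes must be positive")
        if self.n_classrooms <= 0:
            raise ValueError("n_classrooms must be positive")
        if not self.iq_floor < self.iq_mean:
            raise ValueError("iq_floor must be below iq_mean")
        if not 0.0 <= self.classroom_icc < 1.0:
            raise ValueError("classroom_icc must be in [0, 1)")
        if not -1.0 < self.stability < 1.0:
            raise ValueError("stability must be in (-1, 1)")
        for dom, d in self.effect_sizes.items():
            if dom not in DOMAINS:
                raise ValueError(f"unknown domain in effect_sizes: {dom!r}")
            if not np.isfinite(d):
                raise ValueError("effect sizes must be finite")


@dataclass
class ParticipantProfile:
    id: str
    arm: str                        # "intervention" | "control"
    classroom: str
    age: float
    iq: float
    gender: str
    ses_index: float
    motivation: float               # mastery-motivation persistence scale mean (1-5)
    family_functioning: float       # family-functioning scale mean (1-4)
    ability: dict[str, dict[str, float]]   # domain -> timepoint -> latent z
    adherence_propensity: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def generate_cohort(config: CohortConfig) -> list[ParticipantProfile]:
    """Deterministically generate the cohort implied by ``config``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_control + config.n_intervention
    arms = np.array(["control"] * config.n_control + ["intervention"] * config.n_intervention)
    rng.shuffle(arms)

    k = len(DOMAINS)
    corr = np.full((k, k), config.cross_domain_corr)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    icc = config.classroom_icc

    classrooms = rng.integers(config.n_classrooms, size=n)
    room_effect = rng.normal(size=config.n_classrooms)

    lo, hi = config.age_range
    profiles = []
    for i in range(n):
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), lo, hi - 1e-9))
        iq = rng.normal(config.iq_mean, config.iq_sd)
        while iq <= config.iq_floor:            # exclusion boundary: resample
            iq = rng.normal(config.iq_mean, config.iq_sd)
        x = chol @ rng.normal(size=k)           # individual baseline component
        base = np.sqrt(1.0 - icc) * x + np.sqrt(icc) * room_effect[classrooms[i]]
        ability: dict[str, dict[str, float]] = {d: {} for d in DOMAINS}
        indiv = x.copy()
        for t_idx, tp in enumerate(TIMEPOINTS):
            if t_idx > 0:
                innov = chol @ rng.normal(size=k)
                indiv = config.stability * indiv + np.sqrt(1 - config.stability ** 2) * innov
            vec = (np.sqrt(1.0 - icc) * indiv
                   + np.sqrt(icc) * room_effect[classrooms[i]]) if t_idx > 0 else base
            drift = config.drift.get(tp, 0.0)
            for j, dom in enumerate(DOMAINS):
                val = vec[j] + drift
                if arms[i] == "intervention":
                    d = config.effect_sizes.get(dom, 0.0)
                    if tp == "T2":
                        val += d
                    elif tp == "T3":
                        val += config.retention * d
                ability[dom][tp] = float(val)
        profiles.append(ParticipantProfile(
            id=f"p{i:04d}",
            arm=str(arms[i]),
            classroom=f"c{classrooms[i]:02d}",
            age=age,
            iq=float(iq),
            gender="male" if rng.random() < 0.55 else "female",
            ses_index=float(rng.normal()),
            motivation=float(np.clip(rng.normal(3.26, 0.89), 1.0, 5.0)),
            family_functioning=float(np.clip(rng.normal(1.44, 0.38), 1.0, 4.0)),
            ability=ability,
            adherence_propensity=float(rng.beta(*config.adherence_beta)),
        ))
    return profiles


def apply_intervention_effect(cohort: list[ParticipantProfile],
                              effect_sizes: dict[str, float],
                              retention: float = 1.0) -> None:
    """Shift intervention-arm latent abilities at T2 (and T3, scaled by the
    retention fraction) in place.  Used when arm labels come from an
    external allocator rather than from :func:`generate_cohort` (whose own
    shifts should then be disabled by passing empty ``effect_sizes``)."""
    for dom in effect_sizes:
        if dom not in DOMAINS:
            raise ValueError(f"unknown domain {dom!r}")
    for p in cohort:
        if p.arm != "intervention":
            continue
        for dom, d in effect_sizes.items():
            p.ability[dom]["T2"] += d
            p.ability[dom]["T3"] += retention * d


def make_responder(profile: ParticipantProfile, domain: str, timepoint: str,
                   links: dict | None = None) -> ResponderPolicy:
    """Behavioural policy implied by the participant's latent ability."""
    if domain not in profile.ability:
        raise KeyError(f"unknown domain: {domain!r}")
    if timepoint not in profile.ability[domain]:
        raise KeyError(f"no ability recorded at {timepoint!r}")
    return make_policy(domain, profile.ability[domain][timepoint], links=links)


def cohort_to_frame(cohort: list[ParticipantProfile]) -> pd.DataFrame:
    """Covariate view of the cohort (one row per participant)."""
    rows = []
    for p in cohort:
        rows.append({
            "participant_id": p.id, "arm": p.arm, "classroom": p.classroom,
            "age": p.age, "iq": p.iq, "gender": p.gender, "ses_index": p.ses_index,
            "motivation": p.motivation, "family_functioning": p.family_functioning,
            "adherence_propensity": p.adherence_propensity,
        })
    return pd.DataFrame(rows)


def save_cohort(cohort: list[ParticipantProfile], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(p) for p in cohort], fh)


def load_cohort(path: str) -> list[ParticipantProfile]:
    with open(path) as fh:
        raw = json.load(fh)
    return [ParticipantProfile(**d) for d in raw]


# --------------------------------------------------------------- missingness

@dataclass
class MissingnessSpec:
    """Per-measure, per-timepoint missing-data rates.

    ``rates`` maps measure -> rate, or measure -> {timepoint: rate}.  The
    default mechanism is missing-completely-at-random (what the trial's
    missing-values analysis concluded); a missing-at-random hook tilts the
    per-row probability by a logistic term in one covariate when
    ``mar_covariate`` is set.
    """

    rates: dict[str, float | dict[str, float]] = field(default_factory=dict)
    mechanism: str = "MCAR"
    mar_covariate: str | None = None
    mar_slope: float = 0.0
    seed: int = 0

    def rate_for(self, measure: str, timepoint: str) -> float:
        r = self.rates.get(measure, 0.0)
        if isinstance(r, dict):
            r = r.get(timepoint, 0.0)
        if not 0.0 <= r < 1.0:
            raise ValueError(f"missing rate for {measure}/{timepoint} must be in [0, 1)")
        return float(r)


#: rates emulating the trial's observed missingness: heavy on the caregiver
#: executive-function ratings (low response rates) and the stop task
#: (software corruption), light (<20%) elsewhere.
DEFAULT_MISSINGNESS = {
    "osari_ssrt": {"T1": 0.34, "T2": 0.45, "T3": 0.56},
    "brief_gec": {"T1": 0.27, "T2": 0.32, "T3": 0.38},
    "ant_conflict": 0.10, "ds_total": 0.10, "corsi_total": 0.10,
    "wcst_prop_err": 0.10, "dccs_adv": 0.10,
    "sdq_parent": 0.15, "sdq_teacher": 0.05,
}


def apply_missingness(
    table: pd.DataFrame,
    spec: MissingnessSpec,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Blank outcome values at the requested rates (identifiers untouched).

    Deterministic given ``spec.seed``.  Under the MAR hook the logistic tilt
    is centred so the marginal rate stays approximately the requested one.
    """
    rng = np.random.default_rng(spec.seed)
    out = table.copy()
    if spec.mechanism not in ("MCAR", "MAR"):
        raise ValueError("mechanism must be MCAR or MAR")
    tilt = None
    if spec.mechanism == "MAR" and spec.mar_covariate:
        if covariates is None:
            raise ValueError("MAR mechanism needs a covariate frame")
        cov = covariates.set_index("participant_id")[spec.mar_covariate]
        z = (cov - cov.mean()) / (cov.std() or 1.0)
        tilt = z.to_dict()
    for (measure, tp), idx in out.groupby(["measure", "timepoint"]).groups.items():
        rate = spec.rate_for(measure, tp)
        if rate == 0.0:
            continue
        rows = out.loc[idx]
        if tilt is None:
            mask = rng.random(len(rows)) < rate
        else:
            logit = np.log(rate / (1 - rate)) + spec.mar_slope * np.array(
                [tilt.get(pid, 0.0) for pid in rows["participant_id"]])
            mask = rng.random(len(rows)) < 1.0 / (1.0 + np.exp(-logit))
        out.loc[rows.index[mask], "value"] = np.nan
        out.loc[rows.index[mask], "missing"] = True
    return out
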