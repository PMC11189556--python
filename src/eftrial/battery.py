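"""Administer the full assessment battery to a cohort.

For each participant and timepoint the six performance tasks are run
through their engines and scored, and the two rating scales are generated
at subscale level (from the everyday-EF and wellbeing latents) and summed
by the rating scorer.  The result is the package's interchange format: a
long outcome table with one row per participant x timepoint x measure.

Outcome orientation follows the instruments: stop-signal RT, conflict
score, error proportion and both rating composites *decrease* with ability,
the span totals and advanced-sort count increase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ParticipantProfile, TIMEPOINTS, make_responder
from .scoring import (MEASURES, score_ant, score_dccs, score_osari, score_ratings,
                      score_span, score_wcst)
from .tasks import run_ant, run_corsi, run_dccs, run_digit_span, run_osari, run_wcst

TABLE_COLUMNS = ("participant_id", "arm", "classroom", "timepoint", "measure", "value", "missing")


def _ratings(profile: ParticipantProfile, timepoint: str, rng: np.random.Generator) -> dict[str, float]:
    gec_pol = make_responder(profile, "everyday_ef", timepoint)
    sdq_pol = make_responder(profile, "sewb", timepoint)
    # nine caregiver-rated EF subscales whose raw sum is the global composite
    brief = {f"scale_{i}": float(np.clip(
        rng.normal(gec_pol["gec_mean"] / 9.0, gec_pol["gec_sd"] / 3.0), 7.0, 21.0))
        for i in range(9)}

    def sdq_subscales() -> dict[str, float]:
        subs = {s: float(np.clip(rng.normal(sdq_pol["sdq_mean"] / 4.0, sdq_pol["sdq_sd"] / 2.0), 0, 10))
                for s in ("emotional", "conduct", "hyperactivity", "peer")}
        subs["prosocial"] = float(np.clip(rng.normal(7.0, 2.0), 0, 10))
        return subs

    parent = score_ratings(brief, sdq_subscales(), [profile.motivation], [profile.family_functioning])
    teacher = score_ratings(brief, sdq_subscales(), [profile.motivation], [profile.family_functioning])
    return {"brief_gec": parent.brief_gec_raw,
            "sdq_parent": parent.sdq_total,
            "sdq_teacher": teacher.sdq_total}


def administer_participant(
    profile: ParticipantProfile, timepoint: str, rng: np.random.Generator,
) -> dict[str, float]:
    """Run and score every measure for one participant at one timepoint.

    A stop-task administration failing its performance QC yields a missing
    stop-signal RT (mirroring the trial's exclusion rule).
    """
    values: dict[str, float] = {}
    osari = score_osari(run_osari(make_responder(profile, "response_inhibition", timepoint), rng))
    values["osari_ssrt"] = osari.ssrt if osari.qc_pass else np.nan
    values["ant_conflict"] = score_ant(
        run_ant(make_responder(profile, "interference_control", timepoint), rng)).conflict
    values["ds_total"] = score_span(
        run_digit_span(make_responder(profile, "verbal_wm", timepoint), rng)).total
    values["corsi_total"] = score_span(
        run_corsi(make_responder(profile, "visuospatial_wm", timepoint), rng)).total
    values["wcst_prop_err"] = score_wcst(
        run_wcst(make_responder(profile, "switching", timepoint), rng)).prop_total_errors
    values["dccs_adv"] = score_dccs(
        run_dccs(make_responder(profile, "matching", timepoint), rng)).advanced_total
    values.update(_ratings(profile, timepoint, rng))
    return values


def administer_battery(
    cohort: list[ParticipantProfile],
    timepoints: tuple[str, ...] = TIMEPOINTS,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Long outcome table for the whole cohort; deterministic given seed."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    for profile in cohort:
        for tp in timepoints:
            values = administer_participant(profile, tp, rng)
            for measure in MEASURES:
                if measure not in values:
                    continue
                v = values[measure]
                rows.append({
                    "participant_id": profile.id, "arm": profile.arm,
                    "classroom": profile.classroom, "timepoint": tp,
                    "measure": measure, "value": v, "missing": bool(np.isnan(v)),
                })
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def table_to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long table to participant rows with measure_timepoint columns."""
    wide = table.pivot_table(index="participant_id", columns=["measure", "timepoint"],
                             values="value", aggfunc="first", dropna=False)
    wide.columns = [f"{m}_{t}" for m, t in wide.columns]
    meta = table[["participant_id", "arm", "classroom"]].drop_duplicates("participant_id")
    return meta.merge(wide.reset_index(), on="participant_id")
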