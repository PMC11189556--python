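"""End-to-end orchestration and summary tables.

``run_pipeline`` chains every stage of the simulated trial — cohort,
randomised allocation, task administration at the three occasions,
scoring, missingness, imputation, the outcome summary table, the latent
change score ladder and the group-effect Bayes factor, plus the adherence
sensitivity analyses — with every stage seeded from a master seed through
``numpy.random.SeedSequence`` spawning, so any stage can be re-run in
isolation and two runs with the same seed are byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats as st

from . import trial_ops
from .battery import administer_battery, table_to_wide
from .cohort import (CohortConfig, DEFAULT_MISSINGNESS, MissingnessSpec,
                     apply_intervention_effect, apply_missingness, cohort_to_frame,
                     generate_cohort)
from .lcs import (LCSSpec, MCMCConfig, bayes_factor_group_effect, fit_ladder,
                  icc_by_cluster, sensitivity_suite)
from .scoring import MEASURES


# ------------------------------------------------------------ summary table

def tabulate_outcomes(table: pd.DataFrame) -> pd.DataFrame:
    """Per measure x arm x timepoint n/mean/SD, plus between-group
    differences in change (T1->T2 and T1->T3) with normal-theory 95% CIs.

    Change contrasts use complete pairs within arm; an empty cell yields an
    n = 0 row rather than an error.
    """
    rows = []
    for measure in table["measure"].unique():
        sub = table[table.measure == measure]
        cells = {}
        for arm in ("control", "intervention"):
            for tp in ("T1", "T2", "T3"):
                v = sub[(sub.arm == arm) & (sub.timepoint == tp)]["value"].dropna()
                cells[(arm, tp)] = v
                rows.append({"measure": measure, "arm": arm, "timepoint": tp,
                             "n": int(len(v)),
                             "mean": float(v.mean()) if len(v) else np.nan,
                             "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan})
        for t_end, label in (("T2", "T1-T2"), ("T3", "T1-T3")):
            diffs = {}
            for arm in ("control", "intervention"):
                wide = sub[sub.arm == arm].pivot_table(
                    index="participant_id", columns="timepoint", values="value", aggfunc="first")
                if "T1" in wide.columns and t_end in wide.columns:
                    ch = (wide[t_end] - wide["T1"]).dropna()
                    diffs[arm] = ch
            if len(diffs) == 2 and all(len(c) > 1 for c in diffs.values()):
                a, b = diffs["intervention"], diffs["control"]
                diff = float(a.mean() - b.mean())
                se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
                z = st.norm.ppf(0.975)
                rows.append({"measure": measure, "arm": "difference", "timepoint": label,
                             "n": int(len(a) + len(b)), "mean": diff, "sd": se,
                             "ci_low": diff - z * se, "ci_high": diff + z * se})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- CONSORT flow

@dataclass
class FlowCounts:
    assessed: int
    excluded: int
    enrolled: int
    randomised: dict[str, int]
    analysed: dict[str, int]
    withdrawn: dict[str, list[str]]

    def __post_init__(self) -> None:
        if self.enrolled != self.assessed - self.excluded:
            raise ValueError("flow conservation violated: enrolled != assessed - excluded")
        if self.enrolled != sum(self.randomised.values()):
            raise ValueError("flow conservation violated: enrolled != sum randomised")
        for arm, n in self.analysed.items():
            if n > self.randomised.get(arm, 0):
                raise ValueError(f"analysed > randomised in arm {arm}")

    def render(self) -> str:
        lines = [f"Assessed for eligibility: {self.assessed}",
                 f"  Excluded: {self.excluded}",
                 f"Enrolled and randomised: {self.enrolled}"]
        for arm in self.randomised:
            w = self.withdrawn.get(arm, [])
            lines.append(f"  {arm}: randomised {self.randomised[arm]}, "
                         f"withdrawn {len(w)}, analysed {self.analysed[arm]}")
        return "\n".join(lines)


def consort_flow(cohort, allocation: trial_ops.AllocationRecord,
                 withdrawals: dict[str, str] | None = None,
                 n_assessed: int | None = None) -> FlowCounts:
    """Participant accounting from screening through analysis."""
    withdrawals = withdrawals or {}
    ids = {p.id for p in cohort}
    orphans = set(allocation.assignments) - ids | set(withdrawals) - ids
    if orphans:
        raise ValueError(f"ids not in cohort: {sorted(orphans)}")
    randomised: dict[str, int] = {}
    for pid, arm in allocation.assignments.items():
        randomised[arm] = randomised.get(arm, 0) + 1
    withdrawn: dict[str, list[str]] = {arm: [] for arm in randomised}
    for pid, reason in withdrawals.items():
        withdrawn[allocation.assignments[pid]].append(f"{pid}: {reason}")
    analysed = {arm: randomised[arm] - len(withdrawn[arm]) for arm in randomised}
    assessed = n_assessed if n_assessed is not None else len(ids)
    return FlowCounts(assessed=assessed, excluded=assessed - len(ids),
                      enrolled=len(ids), randomised=randomised,
                      analysed=analysed, withdrawn=withdrawn)


# ---------------------------------------------------------------- pipeline

@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    families: tuple[str, ...] = ("inhibitory",)
    intervals: tuple[str, ...] = ("T1T2",)
    model_ids: tuple[int, ...] = (1, 2, 3, 4)
    covariates: tuple[str, ...] = ("iq", "age")
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    timepoints: tuple[str, ...] = ("T1", "T2", "T3")
    seed: int = 0


def _stage_seeds(master: int, stages: list[str]) -> dict[str, int]:
    seqs = np.random.SeedSequence(master).spawn(len(stages))
    return {name: int(s.generate_state(1)[0] % (2 ** 31)) for name, s in zip(stages, seqs)}


def run_pipeline(config: PipelineConfig, out_dir: str | None = None) -> dict:
    """Simulate, administer, score, impute, summarise, fit and report.

    Returns the artifact bundle as a dict; with ``out_dir`` set the
    serializable pieces (tables as CSV, summaries as JSON, the audit log)
    are also written to disk.
    """
    stages = ["cohort", "allocation", "battery", "missingness", "imputation",
              "sessions", "analysis"]
    seeds = _stage_seeds(config.seed, stages)
    audit = [{"stage": s, "seed": seeds[s]} for s in stages]

    # generate the cohort effect-free, allocate arms through the blinded
    # block randomiser, then inject the configured intervention effect
    base_cfg = asdict(config.cohort)
    effect_sizes = dict(base_cfg.pop("effect_sizes"))
    retention = base_cfg["retention"]
    cohort_cfg = CohortConfig(**{**base_cfg, "seed": seeds["cohort"], "effect_sizes": {}})
    cohort = generate_cohort(cohort_cfg)
    demo = cohort_to_frame(cohort)

    alloc = trial_ops.block_randomise([p.id for p in cohort], seed=seeds["allocation"])
    alloc = trial_ops.balance_check_and_rerandomise(alloc, demo, seed=seeds["allocation"])
    alloc.unblind("analysis stage of a simulated trial")
    for p in cohort:
        p.arm = alloc.assignments[p.id]
    apply_intervention_effect(cohort, effect_sizes, retention)
    demo = cohort_to_frame(cohort)

    table = administer_battery(cohort, config.timepoints, seed=seeds["battery"])
    spec = MissingnessSpec(rates=config.missingness, seed=seeds["missingness"])
    observed = apply_missingness(table, spec, covariates=demo)

    miss_summary = trial_ops.summarise_missingness(observed, covariates=demo)
    wide = table_to_wide(observed)
    completed = trial_ops.impute_chained(wide, auxiliaries=demo, n_imputations=1,
                                         seed=seeds["imputation"])[0]
    completed = completed.merge(demo[["participant_id", "iq", "age"]], on="participant_id")

    summary = tabulate_outcomes(observed)
    iccs = icc_by_cluster(observed)

    sessions = trial_ops.simulate_sessions(
        [p for p in cohort if p.arm == "intervention"], seed=seeds["sessions"])
    labels = trial_ops.classify_compliance(sessions)
    compliance = trial_ops.compliance_summary(labels)
    sensitivity = sensitivity_suite(
        observed[observed.arm == "intervention"], labels,
        demo[demo.arm == "intervention"], sessions)

    mcmc = MCMCConfig(n_walkers=config.mcmc.n_walkers, n_burn=config.mcmc.n_burn,
                      n_steps=config.mcmc.n_steps, thin=config.mcmc.thin,
                      seed=seeds["analysis"], progress=False)
    analyses = {}
    for family in config.families:
        for interval in config.intervals:
            ladder = fit_ladder(family, completed, interval=interval,
                                covariates=config.covariates, mcmc=mcmc,
                                model_ids=config.model_ids)
            bf_fit = ladder.fits.get(2)
            bf = bayes_factor_group_effect(
                LCSSpec(family=family, interval=interval, model_id=2,
                        covariates=config.covariates),
                completed, mcmc=mcmc, fit=bf_fit)
            analyses[f"{family}:{interval}"] = {"ladder": ladder, "bayes_factor": bf}

    flow = consort_flow(cohort, alloc, n_assessed=len(cohort) + 4)
    bundle = {
        "config": config, "cohort": cohort, "demographics": demo,
        "allocation": alloc, "outcomes_complete": table, "outcomes_observed": observed,
        "outcomes_imputed": completed, "summary_table": summary,
        "missingness": miss_summary, "icc": iccs, "sessions": sessions,
        "compliance": compliance, "sensitivity": sensitivity,
        "analyses": analyses, "consort": flow, "audit": audit,
    }
    if out_dir:
        _write_bundle(bundle, out_dir)
    return bundle


def render_report(bundle: dict) -> str:
    """Human-readable text report of the bundle's headline numbers."""
    lines = ["# Simulated trial report", "", bundle["consort"].render(), ""]
    comp = bundle["compliance"]
    lines.append(f"Adherence: mean {comp['mean_sessions']:.1f}/20 sessions, "
                 f"{comp['n_compliers']}/{comp['n']} compliers (>=16 sessions)")
    lines.append("")
    for key, res in bundle["analyses"].items():
        bf = res["bayes_factor"]
        verdict = ("evidence for a group effect (BF10 >= 3)" if bf.evidence_h1 else
                   "evidence for no group effect (BF01 >= 3)" if bf.evidence_h0 else
                   "inconclusive (neither BF >= 3)")
        lines.append(f"{key}: BF10 = {bf.bf10:.2f}, BF01 = {bf.bf01:.2f} -> {verdict}")
        ladder = res["ladder"]
        loos = ", ".join(f"M{m}: {f.looic:.1f}" for m, f in sorted(ladder.fits.items()))
        lines.append(f"  LOOIC {loos}; preferred: Model {ladder.preferred}")
    return "\n".join(lines)


def _write_bundle(bundle: dict, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    bundle["outcomes_observed"].to_csv(os.path.join(out_dir, "outcomes_observed.csv"), index=False)
    bundle["outcomes_imputed"].to_csv(os.path.join(out_dir, "outcomes_imputed.csv"), index=False)
    bundle["summary_table"].to_csv(os.path.join(out_dir, "summary_table.csv"), index=False)
    bundle["allocation"].to_frame().to_csv(os.path.join(out_dir, "allocation.csv"), index=False)
    with open(os.path.join(out_dir, "audit.jsonl"), "w") as fh:
        for entry in bundle["audit"]:
            fh.write(json.dumps(entry) + "\n")
    serializable = {
        "compliance": bundle["compliance"],
        "missingness": bundle["missingness"],
        "bayes_factors": {k: {"bf10": v["bayes_factor"].bf10, "bf01": v["bayes_factor"].bf01}
                          for k, v in bundle["analyses"].items()},
        "looic": {k: {m: f.looic for m, f in v["ladder"].fits.items()}
                  for k, v in bundle["analyses"].items()},
    }
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(serializable, fh, indent=2)
    with open(os.path.join(out_dir, "report.md"), "w") as fh:
        fh.write(render_report(bundle))
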