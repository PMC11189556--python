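"""Schedule, staircase and adaptation invariants of the task engines."""

import numpy as np
import pytest
from hypothesis import given, strategies as hst

from eftrial.policies import ResponderPolicy, make_policy, policy_improves
from eftrial.tasks import (SessionState, StaircaseState, run_ant, run_corsi,
                           run_dccs, run_digit_span, run_osari,
                           run_training_session, run_wcst)
from eftrial.tasks.training import EXERCISE_DOMAINS, MATCHING_LADDER


# ------------------------------------------------------------- staircase

@given(hst.lists(hst.booleans(), min_size=1, max_size=200))
def test_staircase_never_leaves_bounds(outcomes):
    stair = StaircaseState()
    for stopped in outcomes:
        v = stair.update(stopped)
        assert 300.0 <= v <= 700.0
    assert len(stair.history) == len(outcomes)


def test_staircase_rises_to_ceiling_under_constant_stopping():
    stair = StaircaseState()
    values = [stair.update(True) for _ in range(10)]
    assert values[:4] == [550.0, 600.0, 650.0, 700.0]
    assert all(v == 700.0 for v in values[4:])


def test_staircase_rejects_invalid_state():
    with pytest.raises(ValueError):
        StaircaseState(step=0.0)
    with pytest.raises(ValueError):
        StaircaseState(current_value=900.0)


# ------------------------------------------------------------------ OSARI

def test_osari_schedule_counts(stationary_stop_policy):
    log = run_osari(stationary_stop_policy, seed=0)
    test = [t for t in log.trials if t.block.startswith("test")]
    assert sum(t.trial_type == "go" for t in test) == 135
    assert sum(t.trial_type == "stop" for t in test) == 45
    practice_mixed = [t for t in log.trials if t.block == "practice_mixed"]
    assert sum(t.trial_type == "go" for t in practice_mixed) == 15
    assert sum(t.trial_type == "stop" for t in practice_mixed) == 5
    assert sum(t.block == "practice_go" for t in log.trials) == 10
    assert all(300.0 <= t.ssd <= 700.0 for t in log.trials if t.trial_type == "stop")


def test_osari_always_stopping_pins_ssd_at_ceiling():
    pol = ResponderPolicy("response_inhibition",
                          {"go_mean": 800.0, "go_sd": 0.001,
                           "ssrt_true": 80.0, "omission_rate": 0.0})
    log = run_osari(pol, seed=1)
    stops = [t for t in log.trials if t.trial_type == "stop"]
    assert all(t.correct for t in stops)
    ssds = [t.ssd for t in stops]
    # monotone +50 walk until pinned at the 700 ms bound
    for a, b in zip(ssds, ssds[1:]):
        assert b == min(700.0, a + 50.0)
    assert ssds[-1] == 700.0


def test_osari_staircase_converges_to_half_respond_rate(stationary_stop_policy):
    rates = []
    for s in range(200):
        log = run_osari(stationary_stop_policy, seed=s)
        stops = [t for t in log.trials if t.block.startswith("test") and t.trial_type == "stop"]
        rates.append(np.mean([t.rt is not None for t in stops[-30:]]))
    assert 0.45 <= np.mean(rates) <= 0.55


def test_osari_respond_probability_nondecreasing_in_ssd(stationary_stop_policy):
    # race model: longer delays leave less time for the stop process
    rng = np.random.default_rng(0)
    probs = []
    for ssd in (300.0, 450.0, 600.0, 700.0):
        lifts = rng.normal(800.0, 50.0, size=4000)
        probs.append(np.mean(lifts < ssd + 200.0))
    assert all(a <= b + 1e-12 for a, b in zip(probs, probs[1:]))


def test_osari_determinism(stationary_stop_policy):
    a = run_osari(stationary_stop_policy, seed=42)
    b = run_osari(stationary_stop_policy, seed=42)
    assert [(t.trial_type, t.rt, t.ssd) for t in a.trials] == \
           [(t.trial_type, t.rt, t.ssd) for t in b.trials]


def test_osari_missing_policy_parameter_raises():
    with pytest.raises(ValueError, match="missing parameter"):
        run_osari(ResponderPolicy("response_inhibition", {"go_mean": 800.0}), seed=0)


# -------------------------------------------------------------------- ANT

def test_ant_experimental_balance():
    log = run_ant(make_policy("interference_control", 0.0), seed=3)
    exp = [t for t in log.trials if t.block.startswith("exp")]
    assert len(exp) == 144
    assert sum(t.trial_type == "congruent" for t in exp) == 72
    assert sum(t.trial_type == "incongruent" for t in exp) == 72
    for cue in ("no", "centre", "double", "spatial"):
        assert sum(t.stimulus["cue"] == cue for t in exp) == 36
    assert sum(t.block == "practice" for t in log.trials) == 24


def test_ant_zero_cost_zero_noise_gives_identical_rts():
    pol = ResponderPolicy("interference_control",
                          {"base_rt": 700.0, "congruency_cost": 0.0,
                           "alerting_benefit": 0.0, "orienting_benefit": 0.0,
                           "noise_sd": 1e-9, "omission_rate": 0.0,
                           "anticipation_rate": 0.0})
    log = run_ant(pol, seed=0)
    rts = {round(t.rt, 6) for t in log.trials if t.block.startswith("exp")}
    assert rts == {700.0}


def test_ant_scored_conflict_recovers_generative_cost():
    pol = ResponderPolicy("interference_control",
                          {"base_rt": 700.0, "congruency_cost": 100.0,
                           "alerting_benefit": 40.0, "orienting_benefit": 40.0,
                           "noise_sd": 50.0, "omission_rate": 0.0,
                           "anticipation_rate": 0.0})
    from eftrial.scoring import score_ant
    conflicts = [score_ant(run_ant(pol, seed=s)).conflict for s in range(200)]
    assert abs(np.mean(conflicts) - 100.0) < 10.0


# ------------------------------------------------------------- span tasks

def test_digit_span_hand_trace_capacity_five():
    pol = ResponderPolicy("verbal_wm", {"capacity": 5.0, "lapse": 0.0})
    log = run_digit_span(pol, seed=0)
    correct = [t for t in log.trials if t.correct]
    assert len(correct) == 8                       # two each at spans 2-5
    assert max(t.stimulus["span"] for t in correct) == 5
    assert [t.correct for t in log.trials][-2:] == [False, False]   # both span-6 fail


def test_digit_span_zero_capacity():
    pol = ResponderPolicy("verbal_wm", {"capacity": 0.0, "lapse": 0.0})
    log = run_digit_span(pol, seed=0)
    assert len(log.trials) == 2 and not any(t.correct for t in log.trials)


def test_digit_span_ceiling():
    pol = ResponderPolicy("verbal_wm", {"capacity": 9.0, "lapse": 0.0})
    log = run_digit_span(pol, seed=0)
    assert all(t.correct for t in log.trials)
    assert max(t.stimulus["span"] for t in log.trials) == 9


def test_corsi_hand_trace_capacity_four():
    pol = ResponderPolicy("visuospatial_wm", {"capacity": 4.0, "lapse": 0.0})
    log = run_corsi(pol, seed=0)
    correct = [t for t in log.trials if t.correct]
    assert len(correct) == 6                       # two each at spans 2-4
    assert max(t.stimulus["span"] for t in correct) == 4


def test_corsi_ceiling_and_floor():
    hi = ResponderPolicy("visuospatial_wm", {"capacity": 9.0, "lapse": 0.0})
    log = run_corsi(hi, seed=0)
    assert max(t.stimulus["span"] for t in log.trials) == 9
    lo = ResponderPolicy("visuospatial_wm", {"capacity": 9.0, "lapse": 1.0})
    log = run_corsi(lo, seed=0)
    assert not any(t.correct for t in log.trials)
    assert {t.stimulus["span"] for t in log.trials} == {2}


# ------------------------------------------------------------ card sorting

def test_wcst_omniscient_ceiling():
    log = run_wcst(make_policy("switching", 0.0), seed=0, strategy="omniscient")
    assert len(log.trials) == 48
    assert all(t.correct for t in log.trials)
    assert log.meta["n_criterion_changes"] == 8


def test_wcst_colour_perseverator_errors_start_at_first_switch():
    log = run_wcst(make_policy("switching", 0.0), seed=0, strategy="fixed:colour")
    results = [t.correct for t in log.trials]
    assert all(results[:6])                        # colour active first
    assert not any(results[6:])                    # wrong forever after the switch


def test_wcst_deterministic_learner_matches_brute_force_trace():
    pol = ResponderPolicy("switching", {"perseveration_prob": 0.0, "slip_prob": 0.0})
    log = run_wcst(pol, seed=123)

    # independent trace of the same deterministic rules
    dims = ("colour", "shape", "number")
    belief, crit_idx, run, errors = "colour", 0, 0, 0
    for _ in range(48):
        criterion = dims[crit_idx % 3]
        if belief != criterion:
            errors += 1
            run = 0
            belief = dims[(dims.index(belief) + 1) % 3]
        else:
            run += 1
            if run == 6:
                crit_idx += 1
                run = 0
    from eftrial.scoring import score_wcst
    assert score_wcst(log).prop_total_errors == pytest.approx(errors / 48)


# -------------------------------------------------------------------- DCCS

def test_dccs_perfect_policy_reaches_advanced():
    pol = ResponderPolicy("matching", {"acc_pre": 1.0, "acc_post": 1.0, "acc_advanced": 1.0})
    log = run_dccs(pol, seed=0)
    assert len(log.trials) == 24
    assert sum(t.block == "advanced" and t.correct for t in log.trials) == 12


def test_dccs_gate_blocks_advanced_phase():
    pol = ResponderPolicy("matching", {"acc_pre": 1.0, "acc_post": 0.0, "acc_advanced": 1.0})
    log = run_dccs(pol, seed=0)
    assert len(log.trials) == 12
    assert not any(t.block == "advanced" for t in log.trials)


def test_dccs_gate_probability_matches_binomial_tail():
    import scipy.stats as st
    pol = ResponderPolicy("matching", {"acc_pre": 1.0, "acc_post": 0.9, "acc_advanced": 0.5})
    n = 2000
    administered = sum(
        any(t.block == "advanced" for t in run_dccs(pol, seed=s).trials) for s in range(n))
    expected = 1 - st.binom.cdf(4, 6, 0.9)         # P(X >= 5), X ~ Bin(6, .9)
    assert abs(administered / n - expected) < 3 * np.sqrt(expected * (1 - expected) / n)


# ---------------------------------------------------------------- training

def _policy_set(z=0.0):
    return {ex: make_policy(dom, z) for ex, dom in EXERCISE_DOMAINS.items()}


def test_training_session_structure_and_persistence():
    state = SessionState()
    logs = []
    for i in range(20):
        logs.append(run_training_session(_policy_set(), state, seed=i,
                                         session_index=i + 1))
    assert len(logs) == 20
    assert all(len(s.blocks) == 6 for s in logs)
    # difficulty carried across sessions
    assert logs[5].difficulty_start == logs[4].difficulty_end


def test_training_matching_ladder_steps_in_order():
    always = ResponderPolicy("matching", {"acc_pre": 1.0, "acc_post": 1.0, "acc_advanced": 1.0})
    pols = _policy_set()
    pols["matching"] = always
    state = SessionState()
    run_training_session(pols, state, seed=0, trial_budget=40)
    log = None
    # after 12 + 8 + 6 + 4 = 30 consecutive correct the ladder is exhausted
    assert state.matching_rung == len(MATCHING_LADDER) - 1


def test_training_span_difficulty_tracks_ability():
    weak, strong = SessionState(), SessionState()
    for i in range(5):
        run_training_session(_policy_set(-1.5), weak, seed=i)
        run_training_session(_policy_set(+1.5), strong, seed=i)
    assert strong.vspan_length > weak.vspan_length
    assert strong.dspan_length >= weak.dspan_length


def test_training_unknown_exercise_rejected():
    pols = _policy_set()
    pols["juggling"] = pols["stop"]
    with pytest.raises(KeyError):
        run_training_session(pols, SessionState(), seed=0)


def test_trial_log_jsonl_round_trip(tmp_path, stationary_stop_policy):
    log = run_osari(stationary_stop_policy, seed=3)
    path = tmp_path / "osari.jsonl"
    log.to_jsonl(str(path))
    from eftrial.tasks import TrialLog
    back = TrialLog.from_jsonl(str(path))
    assert back.task == "osari" and len(back) == len(log)
    assert [(t.trial_type, t.rt, t.ssd) for t in back.trials] == \
           [(t.trial_type, t.rt, t.ssd) for t in log.trials]


# ---------------------------------------------------------------- policies

def test_policy_monotone_in_ability():
    for dom in ("response_inhibition", "interference_control", "verbal_wm",
                "visuospatial_wm", "switching", "matching"):
        lo, mid, hi = (make_policy(dom, z) for z in (-1.0, 0.0, 1.0))
        assert policy_improves(hi, lo)
        assert policy_improves(hi, mid) or hi.params == mid.params


def test_policy_defaults_at_latent_mean():
    from eftrial.policies import POLICY_LINKS
    pol = make_policy("response_inhibition", 0.0)
    for name, (b0, *_rest) in POLICY_LINKS["response_inhibition"].items():
        assert pol[name] == pytest.approx(b0)


def test_unknown_domain_rejected():
    with pytest.raises(KeyError):
        make_policy("telepathy", 0.0)
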