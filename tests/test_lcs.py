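"""Latent change score models: ladder structure, recovery, LOO, Bayes
factors and the auxiliary analyses."""

import math

import numpy as np
import pandas as pd
import pytest

from eftrial.lcs import (DEFAULT_TRUE_PARAMS, LCSSpec, MCMCConfig,
                         bayes_factor_group_effect, build_lcs_model, compare_loo,
                         fit_lcs, fwer_adjust, icc_oneway, icc_by_cluster,
                         n_free_parameters, prepare_lcs_data, sensitivity_suite,
                         simulate_from_model, thorndike_case2)

FAST = MCMCConfig(n_burn=400, n_steps=1500, seed=0)


@pytest.fixture(scope="module")
def model1_fit():
    wide = simulate_from_model(n_per_group=150, seed=21)
    spec = LCSSpec(family="inhibitory", model_id=1)
    prep = prepare_lcs_data(wide, spec, standardize=False)
    return spec, prep, fit_lcs(spec, prep, FAST)


# ---------------------------------------------------------------- structure

def test_ladder_parameter_counts():
    base = n_free_parameters(LCSSpec(family="inhibitory", model_id=1))
    assert n_free_parameters(LCSSpec(family="inhibitory", model_id=2)) == base + 2
    assert n_free_parameters(LCSSpec(family="inhibitory", model_id=3)) == base + 6
    assert n_free_parameters(LCSSpec(family="inhibitory", model_id=4)) == base + 7
    with_cov = LCSSpec(family="inhibitory", model_id=1, covariates=("iq", "age"))
    assert n_free_parameters(with_cov) == base + 4


def test_model_definition_reports_arm_specific_parameters():
    m1 = build_lcs_model(LCSSpec(family="working_memory", model_id=1))
    m4 = build_lcs_model(LCSSpec(family="working_memory", model_id=4))
    assert m1["arm_specific"] == []
    assert "d_gamma" in m4["arm_specific"]
    assert m1["indicators"]["near"] == ("corsi_total", "ds_total")


def test_spec_validation():
    with pytest.raises(ValueError):
        LCSSpec(family="astrology")
    with pytest.raises(ValueError):
        LCSSpec(family="inhibitory", model_id=5)
    with pytest.raises(ValueError):
        LCSSpec(family="inhibitory", interval="T2T3")


def test_zero_variance_indicator_rejected():
    wide = simulate_from_model(n_per_group=30, seed=1)
    wide["ant_conflict_T1"] = 1.0
    wide["ant_conflict_T2"] = 1.0
    with pytest.raises(ValueError, match="zero-variance"):
        prepare_lcs_data(wide, LCSSpec(family="inhibitory"))


def test_missing_indicator_column_rejected():
    wide = simulate_from_model(n_per_group=30, seed=1).drop(columns=["osari_ssrt_T2"])
    with pytest.raises(ValueError, match="absent"):
        prepare_lcs_data(wide, LCSSpec(family="inhibitory"))


# ----------------------------------------------------------------- recovery

def test_model1_fit_recovers_generating_parameters(model1_fit):
    _, _, fit = model1_fit
    true = DEFAULT_TRUE_PARAMS
    checked = inside = 0
    for name, row in fit.params.iterrows():
        tv = np.arctanh(true["rho"]) if name == "zrho" else true.get(name)
        if tv is None:
            continue
        checked += 1
        inside += row["ci2.5"] <= tv <= row["ci97.5"]
    assert checked >= 20
    assert inside / checked >= 0.8        # single replicate; pooled study in acceptance
    assert fit.converged, fit.failure


def test_ppp_near_half_for_generating_model(model1_fit):
    _, _, fit = model1_fit
    assert 0.1 <= fit.ppp <= 0.9


def test_group_offset_recovered_under_model2():
    wide = simulate_from_model({"d_mu_dn": 0.5}, n_per_group=150, seed=22)
    spec = LCSSpec(family="inhibitory", model_id=2)
    fit = fit_lcs(spec, prepare_lcs_data(wide, spec, standardize=False), FAST)
    row = fit.params.loc["d_mu_dn"]
    assert row["ci2.5"] <= 0.5 <= row["ci97.5"]
    assert row["mean"] == pytest.approx(0.5, abs=0.25)


def test_single_indicator_option_recovers_group_offset():
    """The measurement-error-free single-indicator variant drops the second
    loadings/intercepts/residuals and still finds the arm offset."""
    from eftrial.lcs import n_free_parameters
    spec = LCSSpec(family="inhibitory", model_id=2, single_indicator=True)
    assert n_free_parameters(spec) == n_free_parameters(
        LCSSpec(family="inhibitory", model_id=2)) - 8
    wide = simulate_from_model({"d_mu_dn": 0.5}, n_per_group=150, seed=31)
    fit = fit_lcs(spec, prepare_lcs_data(wide, spec), FAST)
    row = fit.params.loc["d_mu_dn"]
    assert row["mean"] > 0.2
    assert "lam_near" not in fit.params.index


# ---------------------------------------------------------------------- LOO

def test_compare_loo_identities(model1_fit):
    spec, prep, fit1 = model1_fit
    assert compare_loo(fit1, fit1) == (0.0, 0.0)
    spec2 = LCSSpec(family="inhibitory", model_id=2)
    fit2 = fit_lcs(spec2, prep, FAST)
    d_ab, se_ab = compare_loo(fit1, fit2)
    d_ba, se_ba = compare_loo(fit2, fit1)
    assert d_ab == pytest.approx(-d_ba)
    assert se_ab == pytest.approx(se_ba)


def test_loo_prefers_generating_model_under_misspecification():
    wide = simulate_from_model({"d_mu_dn": 0.8}, n_per_group=150, seed=23)
    s2 = LCSSpec(family="inhibitory", model_id=2)
    prep = prepare_lcs_data(wide, s2, standardize=False)
    f2 = fit_lcs(s2, prep, FAST)
    f1 = fit_lcs(LCSSpec(family="inhibitory", model_id=1), prep, FAST)
    diff, se = compare_loo(f2, f1)
    assert diff < -2 * se                 # richer (true) model wins decisively


def test_compare_loo_rejects_mismatched_observations(model1_fit):
    spec, _, fit1 = model1_fit
    other = simulate_from_model(n_per_group=40, seed=9)
    fit_small = fit_lcs(spec, prepare_lcs_data(other, spec, standardize=False),
                        MCMCConfig(n_burn=200, n_steps=600, seed=1))
    with pytest.raises(ValueError):
        compare_loo(fit1, fit_small)


# -------------------------------------------------------------- Bayes factor

def test_bayes_factor_identity_and_null_evidence():
    wide = simulate_from_model(n_per_group=150, seed=24)
    spec = LCSSpec(family="inhibitory", model_id=2)
    bf = bayes_factor_group_effect(spec, prepare_lcs_data(wide, spec, standardize=False),
                                   FAST)
    assert bf.bf10 * bf.bf01 == pytest.approx(1.0)
    assert bf.bf01 >= 3.0                 # generated with zero arm effect
    assert bf.evidence_h0 and not bf.evidence_h1


def test_bayes_factor_detects_large_effect():
    wide = simulate_from_model({"d_mu_dn": 0.8}, n_per_group=150, seed=25)
    spec = LCSSpec(family="inhibitory", model_id=2)
    bf = bayes_factor_group_effect(spec, prepare_lcs_data(wide, spec, standardize=False),
                                   FAST)
    assert bf.bf10 >= 3.0 and bf.evidence_h1


# ----------------------------------------------------------------------- ICC

def test_icc_oneway_recovers_generated_values():
    rng = np.random.default_rng(0)
    for target, tol in ((0.0, 0.05), (0.2, 0.07)):
        rooms = np.repeat(np.arange(50), 20)
        u = rng.normal(0, math.sqrt(target), 50)[rooms]
        e = rng.normal(0, math.sqrt(1 - target), 1000)
        assert abs(icc_oneway(u + e, rooms) - target) <= tol


def test_icc_degenerate_and_invalid_inputs():
    assert math.isnan(icc_oneway(np.ones(20), np.repeat([0, 1], 10)))
    with pytest.raises(ValueError):
        icc_oneway(np.arange(5.0), np.zeros(5))


def test_icc_by_cluster_table_shape():
    rows = []
    rng = np.random.default_rng(1)
    for i in range(60):
        for tp in ("T1", "T2"):
            rows.append({"participant_id": f"p{i}", "arm": "control",
                         "classroom": f"c{i % 4}", "timepoint": tp,
                         "measure": "ds_total", "value": rng.normal(), "missing": False})
    out = icc_by_cluster(pd.DataFrame(rows))
    assert set(out.timepoint) == {"T1", "T2"}
    assert ((out.icc >= 0) | out.icc.isna()).all()


# ------------------------------------------------- FWER / range restriction

def test_holm_adjustment_closed_form():
    out = fwer_adjust({"a": 0.01, "b": 0.04})
    adj = dict(zip(out.test, out.p_adjusted))
    assert adj["a"] == pytest.approx(0.02)
    assert adj["b"] == pytest.approx(0.04)


def test_holm_single_test_unchanged_and_empty_rejected():
    out = fwer_adjust([0.03])
    assert out.p_adjusted.iloc[0] == pytest.approx(0.03)
    assert not fwer_adjust([1.0, 1.0, 1.0]).reject.any()
    with pytest.raises(ValueError):
        fwer_adjust([])


def test_thorndike_case2_values():
    assert thorndike_case2(0.5, 2.0) == pytest.approx(1 / math.sqrt(1.75), abs=1e-6)
    assert thorndike_case2(0.0, 3.0) == 0.0
    assert thorndike_case2(0.42, 1.0) == pytest.approx(0.42)
    with pytest.raises(ValueError):
        thorndike_case2(1.0, 2.0)
    with pytest.raises(ValueError):
        thorndike_case2(0.5, 0.0)


# --------------------------------------------------------------- sensitivity

def _sensitivity_inputs(n=55, n_missing_pairs=2, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"p{i}" for i in range(n)]
    sessions = {pid: int(rng.integers(2, 21)) for pid in ids}
    rows = []
    for pid in ids:
        t1 = rng.normal(400, 50)
        change = sessions[pid] * 2.0          # perfectly collinear with dose
        rows.append({"participant_id": pid, "arm": "intervention", "classroom": "c0",
                     "timepoint": "T1", "measure": "osari_ssrt", "value": t1,
                     "missing": False})
        rows.append({"participant_id": pid, "arm": "intervention", "classroom": "c0",
                     "timepoint": "T2", "measure": "osari_ssrt", "value": t1 + change,
                     "missing": False})
    table = pd.DataFrame(rows)
    for pid in ids[:n_missing_pairs]:
        table.loc[(table.participant_id == pid) & (table.timepoint == "T2"), "value"] = np.nan
    demo = pd.DataFrame({"participant_id": ids,
                         "gender": rng.choice(["male", "female"], n),
                         "iq": rng.normal(105, 14, n),
                         "motivation": rng.uniform(1, 5, n),
                         "ses_index": rng.normal(size=n),
                         "family_functioning": rng.uniform(1, 4, n)})
    from eftrial.trial_ops import classify_compliance
    labels = classify_compliance(sessions)
    return table, labels, demo, sessions


def test_sensitivity_collinear_dose_gives_unit_correlation():
    table, labels, demo, sessions = _sensitivity_inputs()
    out = sensitivity_suite(table, labels, demo, sessions)
    assert out["adherence_correlation"]["r"] == pytest.approx(1.0)


def test_sensitivity_df_uses_n_minus_two_convention():
    # 55 complete pairs -> df 53 (the printed-report convention); dropping
    # two pairs shrinks the df accordingly
    table, labels, demo, sessions = _sensitivity_inputs(n=55, n_missing_pairs=0)
    out = sensitivity_suite(table, labels, demo, sessions)
    assert out["adherence_correlation"]["df"] == 53
    table2, labels2, demo2, sessions2 = _sensitivity_inputs(n=55, n_missing_pairs=2)
    out2 = sensitivity_suite(table2, labels2, demo2, sessions2)
    assert out2["adherence_correlation"]["df"] == 51


def test_sensitivity_reports_comparisons_and_logit():
    table, labels, demo, sessions = _sensitivity_inputs(seed=3)
    out = sensitivity_suite(table, labels, demo, sessions)
    assert any(c["timepoint"] == "T1" for c in out["comparisons"])
    assert "compliance_logit" in out
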