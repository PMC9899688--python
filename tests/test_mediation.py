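"""Closed-form mediation estimator: fits, decomposition, identities."""

import math
from dataclasses import replace

import numpy as np
import pytest

from longmediate.errors import EstimationError
from longmediate.mediation import (
    AnalysisSpec,
    assemble_rows,
    build_outcome,
    estimate_from_rows,
    estimate_mediation,
    fit_least_squares,
    proportion_mediated,
    proportion_mediated_from_ratios,
    total_effect_check,
)
from longmediate.synthetic import GeneratorConfig, generate, true_effects
from longmediate.trial_data import analysis_set

from conftest import make_patient
from _oracles import mc_counterfactual


# ---------------------------------------------------------------- outcome


def test_build_outcome_log_ratio():
    p = make_patient(weeks=(0, 12), uacr=[100, 100])
    assert build_outcome(p, 12) == 0.0
    p2 = make_patient(weeks=(0, 12), uacr=[100, 38.5])
    assert build_outcome(p2, 12) == pytest.approx(math.log(0.385))
    p3 = make_patient(weeks=(0, 12), uacr=[200, 100])
    assert build_outcome(p3, 12) == pytest.approx(math.log(0.5))
    with pytest.raises(EstimationError):
        build_outcome(make_patient(weeks=(0, 12), uacr=[100, None]), 12)


# ---------------------------------------------------------------- OLS core


def test_ols_exact_fit_zero_residuals():
    x = np.arange(10.0)
    X = np.column_stack([np.ones(10), x])
    fit = fit_least_squares(3.0 + 2.0 * x, X, ["int", "x"])
    assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)
    assert fit["x"] == pytest.approx(2.0)


def test_ols_collinear_column_named():
    x = np.arange(10.0)
    X = np.column_stack([np.ones(10), x, x])
    with pytest.raises(EstimationError, match="x_copy|x_orig"):
        fit_least_squares(x, X, ["int", "x_orig", "x_copy"])


def test_ols_insufficient_rows():
    X = np.ones((3, 4))
    with pytest.raises(EstimationError, match="insufficient"):
        fit_least_squares(np.zeros(3), X, list("abcd"))


def test_ols_matches_normal_equations_and_statsmodels():
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(100), rng.normal(size=(100, 3))])
    y = rng.normal(size=100)
    fit = fit_least_squares(y, X, ["c0", "c1", "c2", "c3"])
    oracle = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(fit.coef, oracle, atol=1e-8)
    sm = pytest.importorskip("statsmodels.api")
    res = sm.OLS(y, X).fit()
    assert np.allclose(fit.coef, res.params, atol=1e-8)
    assert fit.residual_sd == pytest.approx(np.sqrt(res.mse_resid), rel=1e-8)


# ------------------------------------------------------- decomposition


def test_decomposition_identities_on_generated_data(endpoint_set, spec_joint_cum):
    est = estimate_mediation(endpoint_set, spec_joint_cum)
    assert est.te_log == pytest.approx(est.nde_log + est.nie_log, abs=1e-12)
    assert est.te_ratio == pytest.approx(est.nde_ratio * est.nie_ratio, abs=1e-10)
    assert est.pm_pct == pytest.approx(100 * est.nie_log / est.te_log, abs=1e-10)


def test_exact_null_mediator_path_gives_zero_nie():
    """No treatment->mediator path, no mediator->outcome path, no outcome
    noise: the outcome model is exact and NIE must vanish to float precision."""
    cfg = GeneratorConfig(
        n_patients=120, seed=2, missing_rate=0.0, sigma_y=0.0,
        alpha_sbp=0.0, alpha_egfr=0.0, gamma_sbp=0.0, gamma_egfr=0.0,
    )
    ds = analysis_set(generate(cfg), 52)
    est = estimate_mediation(
        ds, AnalysisSpec(mediators=(("sbp", "cumulative_mean"),
                                    ("egfr", "cumulative_mean")))
    )
    assert abs(est.nie_log) < 1e-8
    assert est.nie_ratio == pytest.approx(1.0, abs=1e-8)
    assert abs(est.pm_pct) < 1e-6


def test_full_mediation_limit_pm_100():
    """delta = 0 and tau = 0 with zero outcome noise: treatment coefficient
    and interactions fit exactly to zero, so PM = 100% to float precision."""
    cfg = GeneratorConfig(n_patients=150, seed=4, missing_rate=0.0,
                          sigma_y=0.0, delta=0.0)
    ds = analysis_set(generate(cfg), 52)
    est = estimate_mediation(
        ds, AnalysisSpec(mediators=(("sbp", "cumulative_mean"),
                                    ("egfr", "cumulative_mean")))
    )
    assert abs(est.nde_log) < 1e-10
    assert est.pm_pct == pytest.approx(100.0, abs=1e-6)


def test_counterfactual_simulation_oracle(spec_joint_cum):
    """Closed-form NDE/NIE equal brute-force counterfactual simulation from
    the same fitted models, within Monte-Carlo error."""
    ds = analysis_set(generate(GeneratorConfig(n_patients=400, seed=31)), 52)
    rows = assemble_rows(ds, spec_joint_cum)
    est = estimate_from_rows(rows, spec_joint_cum)
    nde_mc, nie_mc, se_nde, se_nie = mc_counterfactual(rows=rows, est=est,
                                                       n_draws=400_000, seed=8)
    assert abs(est.nde_log - nde_mc) < 3 * max(se_nde, 1e-12)
    assert abs(est.nie_log - nie_mc) < 3 * max(se_nie, 1e-12)


def test_estimator_consistent_at_large_n(spec_joint_cum):
    cfg = GeneratorConfig(n_patients=5000, seed=5, missing_rate=0.0)
    gt = true_effects(cfg)
    est = estimate_mediation(analysis_set(generate(cfg), 52), spec_joint_cum)
    # 3 Monte-Carlo SEs, with SEs scaled from the default-n bootstrap spread
    assert abs(est.nde_log - gt.nde_log) < 0.06
    assert abs(est.nie_log - gt.nie_log) < 0.06


# ------------------------------------------------------- model variants


def test_no_interaction_reduction_is_difference_method(endpoint_set):
    """Without exposure-mediator interaction, NIE equals the product of
    coefficients and matches the marginal-vs-adjusted difference exactly."""
    spec = AnalysisSpec(
        mediators=(("sbp", "cumulative_mean"), ("egfr", "cumulative_mean")),
        interactions=False,
    )
    rows = assemble_rows(endpoint_set, spec)
    est = estimate_from_rows(rows, spec)
    product = sum(
        est.outcome_fit[f"m[{lab}]"] * est.mediator_fits[lab]["arm"]
        for lab in rows.mediator_labels
    )
    assert est.nie_log == pytest.approx(product, abs=1e-12)
    check = total_effect_check(endpoint_set, spec)
    assert abs(check.gap) < 1e-8  # nested-OLS identity, exact
    # difference method: marginal TE minus adjusted treatment coefficient
    assert check.te_marginal - est.outcome_fit["arm"] == pytest.approx(
        product, abs=1e-8
    )


def test_interaction_model_te_gap_is_small_but_reported(endpoint_set, spec_joint_cum):
    check = total_effect_check(endpoint_set, spec_joint_cum)
    assert check.gap != 0.0  # diagnostic, not an identity, with interactions
    assert abs(check.gap) < 0.05


def test_arm_swap_negates_te_no_interaction(endpoint_set):
    spec = AnalysisSpec(mediators=(("sbp", "cumulative_mean"),), interactions=False)
    flipped = replace(
        endpoint_set,
        patients=[replace(p, arm=1 - p.arm) for p in endpoint_set.patients],
    )
    a = estimate_mediation(endpoint_set, spec)
    b = estimate_mediation(flipped, spec)
    assert b.te_log == pytest.approx(-a.te_log, abs=1e-10)
    assert b.nie_log == pytest.approx(-a.nie_log, abs=1e-10)


def test_covariate_centering_invariance(endpoint_set, spec_joint_cum):
    """Shifting every baseline covariate by a constant leaves all effects
    unchanged (treatment coefficient and mediator means shift compensatingly)."""
    rows = assemble_rows(endpoint_set, spec_joint_cum)
    est = estimate_from_rows(rows, spec_joint_cum)
    rows2 = type(rows)(
        rows.patient_ids, rows.a, rows.y, rows.m,
        rows.c + np.array([3.0, -25.0, 12.0]), rows.mediator_labels,
        rows.covariate_names,
    )
    est2 = estimate_from_rows(rows2, spec_joint_cum)
    assert est2.nde_log == pytest.approx(est.nde_log, abs=1e-9)
    assert est2.nie_log == pytest.approx(est.nie_log, abs=1e-9)
    assert est2.te_log == pytest.approx(est.te_log, abs=1e-9)


def test_single_mediator_is_k1_specialisation(endpoint_set):
    """The K=1 spec gives the same numbers whether the mediator tuple is
    built directly or sliced from a longer specification."""
    direct = estimate_mediation(
        endpoint_set, AnalysisSpec(mediators=(("sbp", "cumulative_mean"),))
    )
    sliced_spec = AnalysisSpec(
        mediators=tuple([("sbp", "cumulative_mean"), ("egfr", "cumulative_mean")][:1])
    )
    sliced = estimate_mediation(endpoint_set, sliced_spec)
    assert direct.quantities() == sliced.quantities()


def test_both_arms_required():
    ds = generate(GeneratorConfig(n_patients=30, seed=12, allocation=1.0))
    with pytest.raises(EstimationError, match="arms"):
        estimate_mediation(ds, AnalysisSpec(mediators=(("sbp", "cumulative_mean"),)))


# ------------------------------------------------------- proportion mediated


def test_proportion_mediated_values():
    assert proportion_mediated_from_ratios(0.911, 0.385) == pytest.approx(9.8, abs=0.05)
    assert proportion_mediated(0.0, math.log(0.4)) == 0.0
    assert proportion_mediated(math.log(0.4), math.log(0.4)) == pytest.approx(100.0)
    assert math.isnan(proportion_mediated(0.1, 0.0))


def test_analysis_spec_validation():
    with pytest.raises(ValueError):
        AnalysisSpec(mediators=())
    spec = AnalysisSpec(mediators=(("sbp", "cumulative_mean"), ("egfr", "achieved")))
    assert spec.resolved_covariates() == ("bl_log_uacr", "bl_sbp", "bl_egfr")
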