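import numpy as np
import pytest

from revlearn.fitting import (CohortSCR, DegenerateRegressorError, RescorlaWagnerSCR,
                              across_subjects_objective, compare_rho_groups, deviance,
                              ev_regressor_for_subject, fit_within_cohort,
                              fit_within_subject)
from revlearn.models import ModelParams
from revlearn.synth import simulate_cohort

from conftest import recovery_gen


def _noisy_cohort(orders, alpha=0.08, rho=0.7, n=8, noise=0.2, seed=11):
    return simulate_cohort(orders, recovery_gen(alpha, rho, seed=seed,
                                                n_subjects=n, noise_sd=noise))


# ---------------------------------------------------------------- regressor

def test_regressor_nesting_and_initialization(seq):
    fb = ev_regressor_for_subject(seq, ModelParams.feedback(0.1))
    nested = ev_regressor_for_subject(
        seq, ModelParams.instructed(0.1, 0.0, v0_cs_plus=0.5, v0_cs_minus=0.5))
    np.testing.assert_array_equal(fb, nested)
    # first analyzed value is V0 of the presented cue
    params = ModelParams.instructed(0.3, 0.8)
    reg = ev_regressor_for_subject(seq, params, analyze="all")
    first_cue = seq.events["cue"].iloc[0]
    expected = params.v0_cs_plus if first_cue == seq.config.cs_plus_cue(1) \
        else params.v0_cs_minus
    assert reg[0] == expected


def test_zero_learning_rate_regressor_constant_between_swaps(seq):
    reg = ev_regressor_for_subject(seq, ModelParams.instructed(0.0, 1.0), analyze="all")
    boundaries = set(seq.instructions["after_trial"].astype(int))
    phase_start = 0
    for b in sorted(boundaries) + [len(reg)]:
        assert np.ptp(reg[phase_start:b]) <= 2e-16 * 10 or \
            np.unique(np.round(reg[phase_start:b], 12)).size <= 2  # two cue values
        phase_start = b


# ---------------------------------------------------------------- objective

def test_objective_matches_per_subject_ols_oracle(orders):
    """Dual route: objective SSE equals lstsq residuals summed over subjects."""
    cohort = CohortSCR.from_cohort(_noisy_cohort(orders))
    params = ModelParams.instructed(0.1, 0.5)
    sse = across_subjects_objective(params, cohort)
    total = 0.0
    for y, o in zip(cohort.responses, cohort.orders):
        x = ev_regressor_for_subject(cohort.sequences[o], params)
        mask = cohort.sequences[o].events["us"].to_numpy() == 0
        X = np.column_stack([np.ones(mask.sum()), x])
        _, res, *_ = np.linalg.lstsq(X, np.asarray(y)[mask], rcond=None)
        total += float(res[0])
    assert sse == pytest.approx(total, rel=1e-10)


def test_objective_near_zero_for_noiseless_cohort(orders):
    gen = recovery_gen(0.08, 0.7, seed=2, n_subjects=4, noise_sd=0.0)
    cohort = CohortSCR.from_cohort(simulate_cohort(orders, gen))
    assert across_subjects_objective(ModelParams.instructed(0.08, 0.7), cohort) < 1e-20


def test_objective_raises_on_degenerate_regressor(orders):
    cohort = CohortSCR.from_cohort(_noisy_cohort(orders))
    with pytest.raises(DegenerateRegressorError):
        across_subjects_objective(ModelParams.feedback(0.0), cohort)


def test_objective_uniform_rescaling(orders):
    cohort = CohortSCR.from_cohort(_noisy_cohort(orders))
    params = ModelParams.instructed(0.12, 0.4)
    base = across_subjects_objective(params, cohort)
    scaled = CohortSCR(sequences=cohort.sequences,
                       responses=[3.0 * y + 1.7 for y in cohort.responses],
                       orders=cohort.orders)
    assert across_subjects_objective(params, scaled) == pytest.approx(9.0 * base, rel=1e-9)


# ---------------------------------------------------------------- estimators

def test_noiseless_self_fit_recovers_parameters(orders):
    gen = recovery_gen(0.08, 0.7, seed=5, n_subjects=4, noise_sd=0.0)
    est = RescorlaWagnerSCR(variant="instructed", n_restarts=4).fit(
        simulate_cohort(orders, gen))
    assert abs(est.alpha_ - 0.08) < 1e-3
    assert abs(est.rho_ - 0.7) < 1e-3
    assert est.degenerate_noiseless_
    assert est.deviance_ is None


def test_duplicating_subjects_preserves_argmin(orders):
    cohort = CohortSCR.from_cohort(_noisy_cohort(orders, n=6))
    est1 = RescorlaWagnerSCR(n_restarts=4).fit(cohort)
    doubled = CohortSCR(sequences=cohort.sequences,
                        responses=cohort.responses + cohort.responses,
                        orders=cohort.orders + cohort.orders)
    est2 = RescorlaWagnerSCR(n_restarts=4).fit(doubled)
    assert est2.alpha_ == pytest.approx(est1.alpha_, abs=2e-4)
    assert est2.rho_ == pytest.approx(est1.rho_, abs=2e-4)
    assert est2.sse_ == pytest.approx(2 * est1.sse_, rel=1e-4)


def test_restart_robustness(orders):
    cohort = CohortSCR.from_cohort(_noisy_cohort(orders, n=6))
    f1 = RescorlaWagnerSCR(n_restarts=10, restart_seed=0).fit(cohort).sse_
    f2 = RescorlaWagnerSCR(n_restarts=10, restart_seed=99).fit(cohort).sse_
    assert abs(f1 - f2) < 1e-6


def test_instructed_nests_feedback_sse(orders):
    """Adding rho as a free parameter can only improve the fit (matched V0)."""
    cohort = CohortSCR.from_cohort(_noisy_cohort(orders, rho=0.4, n=6))
    fb = RescorlaWagnerSCR(variant="feedback", n_restarts=6).fit(cohort)
    ins = RescorlaWagnerSCR(variant="instructed", v0_cs_plus=0.5, v0_cs_minus=0.5,
                            n_restarts=6).fit(cohort)
    assert ins.sse_ <= fb.sse_ + 1e-9


def test_flat_subject_excluded_with_warning(orders):
    cohort = CohortSCR.from_cohort(_noisy_cohort(orders, n=4))
    cohort.responses[2] = np.zeros_like(cohort.responses[2])
    with pytest.warns(UserWarning, match="constant SCR"):
        est = RescorlaWagnerSCR(n_restarts=3).fit(cohort)
    assert est.n_subjects_ == 3


def test_within_fit_structure(orders):
    cohort = CohortSCR.from_cohort(_noisy_cohort(orders, n=2))
    res = fit_within_subject(cohort.sequences[0], cohort.responses[0], n_restarts=4)
    assert res.per_subject.shape == (1, 2)
    assert res.fit_mode == "within"
    assert 0.0 <= res.rho <= 1.0  # within fits bounded by default


def test_get_set_params_round_trip():
    est = RescorlaWagnerSCR(variant="feedback", n_restarts=3)
    params = est.get_params()
    est2 = RescorlaWagnerSCR().set_params(**params)
    assert est2.get_params() == params
    with pytest.raises(ValueError):
        est.set_params(nonsense=1)


def test_predict_matches_sse(orders):
    cohort = CohortSCR.from_cohort(_noisy_cohort(orders, n=4))
    est = RescorlaWagnerSCR(n_restarts=4).fit(cohort)
    preds = est.predict(cohort)
    sse = 0.0
    for y, o, pred in zip(cohort.responses, cohort.orders, preds):
        mask = cohort.sequences[o].events["us"].to_numpy() == 0
        sse += float(np.sum((np.asarray(y)[mask] - pred) ** 2))
    assert sse == pytest.approx(est.sse_, rel=1e-9)


# ---------------------------------------------------------------- deviance

def test_deviance_identities():
    base = deviance(10.0, 64)
    assert deviance(30.0, 64) == pytest.approx(base + 64 * np.log(3.0))
    # duplicated data: direct formula check
    assert deviance(20.0, 128) == pytest.approx(128 * np.log(2 * np.pi * 20.0 / 128) + 128)
    with pytest.raises(ValueError):
        deviance(0.0, 64)


# ---------------------------------------------------------------- group test

def test_compare_rho_groups_null_and_df():
    a = np.array([0.1, 0.5, 0.9, 0.3] * 5)
    comp = compare_rho_groups(a, a.copy())
    assert comp.t_stat == pytest.approx(0.0, abs=1e-12)
    assert comp.df == 38
    assert comp.p_value == pytest.approx(1.0)
    with pytest.raises(ValueError):
        compare_rho_groups(np.array([0.5]), a)
    with pytest.raises(ValueError):
        compare_rho_groups(np.full(5, 0.2), np.full(5, 0.4))


def test_within_rho_separates_generating_variants(orders):
    """Within-subject rho estimates are higher for an instructed-generated
    cohort than for a feedback-driven one."""
    hi = simulate_cohort(orders, recovery_gen(0.06, 0.9, seed=21, n_subjects=8))
    lo = simulate_cohort(orders, recovery_gen(0.06, 0.0, seed=22, n_subjects=8))
    rho_hi = [f.rho for f in fit_within_cohort(hi, n_restarts=4)]
    rho_lo = [f.rho for f in fit_within_cohort(lo, n_restarts=4)]
    assert np.mean(rho_hi) > np.mean(rho_lo)
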