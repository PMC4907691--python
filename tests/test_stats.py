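import numpy as np
import pytest

from revlearn.models import ModelParams
from revlearn.stats import (build_first_level_design, fit_two_level,
                            instructed_reversal_contrast, mixedlm_crosscheck)
from revlearn.synth import simulate_cohort
from revlearn.task import CS_PLUS, instruction_windows

from conftest import recovery_gen

BETA = {"intercept": 0.25, "stimulus": 0.0, "reversal": 0.0,
        "interaction": 0.06, "time": -0.05}


def _synthetic_scores(design, beta, noise_sd, rng):
    """Scores over all 80 trials; analyzed trials follow the linear model."""
    y = np.zeros(80)
    X = design.matrix
    vals = X @ np.array([beta[k] for k in
                         ("intercept", "stimulus", "reversal", "interaction", "time")])
    y[design.trials - 1] = vals + rng.normal(0, noise_sd, size=len(vals))
    return y


# ------------------------------------------------------------------ design

def test_instructed_reversal_codes_flip_at_instructions(seq):
    d = build_first_level_design(seq, "instructed").frame.set_index("trial")
    for t in d.index:
        expected_phase = sum(t > b for b in (20, 40, 60))
        assert d.loc[t, "phase"] == expected_phase
        assert d.loc[t, "reversal"] == (0.5 if expected_phase % 2 == 0 else -0.5)


def test_uninstructed_reversal_codes_flip_at_first_new_csplus_shock(seq):
    d = build_first_level_design(seq, "uninstructed").frame.set_index("trial")
    ev = seq.events
    # within block 2, the phase flips at the first US (which lands on the
    # previous CS-, i.e. the new CS+); unreinforced trials before it keep phase 0
    block2 = ev[ev["block"] == 2]
    first_us = int(block2.loc[block2["us"] == 1, "trial"].iloc[0])
    pre = [t for t in d.index if 20 < t < first_us]
    post = [t for t in d.index if first_us < t <= 40]
    assert all(d.loc[t, "phase"] == 0 for t in pre)
    assert all(d.loc[t, "phase"] == 1 for t in post)


def test_interaction_codes_current_csplus(seq):
    """The interaction column is +1/2 on current CS+ and -1/2 on current CS-."""
    d = build_first_level_design(seq, "instructed").frame
    roles = seq.events.set_index("trial")["role"]
    for _, row in d.iterrows():
        expected = 0.5 if roles.loc[row["trial"]] == CS_PLUS else -0.5
        assert row["interaction"] == expected
        assert row["interaction"] == pytest.approx(2 * row["stimulus"] * row["reversal"])


def test_design_centered_and_time_standardized(seq):
    f = build_first_level_design(seq, "instructed").frame
    assert abs(f["time"].mean()) < 1e-12
    assert f["time"].std(ddof=0) == pytest.approx(1.0)
    assert set(f["stimulus"]) == {0.5, -0.5}


def test_subsets(seq):
    full = build_first_level_design(seq, "instructed", "all").frame
    post = build_first_level_design(seq, "instructed", "post_first_reversal").frame
    half = build_first_level_design(seq, "instructed", "second_half_of_each_run").frame
    assert post["trial"].min() > 20
    assert len(half) < len(full)
    with pytest.raises(ValueError):
        build_first_level_design(seq, "instructed", "bogus")


# ------------------------------------------------------------------ two-level

def test_injected_effects_recovered(orders):
    rng = np.random.default_rng(3)
    designs, responses = [], []
    for i in range(30):
        d = build_first_level_design(orders[i % 2], "instructed")
        designs.append(d)
        responses.append(_synthetic_scores(d, BETA, 0.08, rng))
    res = fit_two_level(designs, responses)
    within = res.second_level.query("level == 'within'").set_index("effect")
    assert within.loc["interaction", "estimate"] == pytest.approx(0.06, abs=0.02)
    assert within.loc["time", "estimate"] == pytest.approx(-0.05, abs=0.02)
    assert abs(within.loc["stimulus", "estimate"]) < 0.02
    assert within.loc["interaction", "p"] < 0.001


def test_identical_groups_have_zero_group_difference(orders):
    rng = np.random.default_rng(4)
    designs, responses, groups = [], [], []
    for i in range(10):
        d = build_first_level_design(orders[i % 2], "instructed")
        y = _synthetic_scores(d, BETA, 0.1, rng)
        for g in ("instructed", "uninstructed"):  # same data in both groups
            designs.append(d)
            responses.append(y)
            groups.append(g)
    res = fit_two_level(designs, responses, groups)
    diff = res.second_level.query("level == 'group_diff'")
    assert np.allclose(diff["estimate"], 0.0, atol=1e-12)


def test_two_stage_equals_pooled_ols_on_balanced_noiseless_data(orders):
    beta = dict(BETA, stimulus=0.02, reversal=-0.01)
    rng = np.random.default_rng(0)
    d = build_first_level_design(orders[0], "instructed")
    y = _synthetic_scores(d, beta, 0.0, rng)
    res = fit_two_level([d, d, d], [y, y, y])
    within = res.second_level.query("level == 'within'").set_index("effect")
    for effect, value in beta.items():
        assert within.loc[effect, "estimate"] == pytest.approx(value, abs=1e-10)


def test_mixed_model_crosscheck(orders):
    """Two-stage within-subject estimates agree with a joint random-intercept
    mixed model on balanced data."""
    rng = np.random.default_rng(8)
    designs, responses = [], []
    for i in range(12):
        d = build_first_level_design(orders[i % 2], "instructed")
        beta = dict(BETA, intercept=0.25 + rng.normal(0, 0.05))
        designs.append(d)
        responses.append(_synthetic_scores(d, beta, 0.06, rng))
    res = fit_two_level(designs, responses)
    mlm = mixedlm_crosscheck(designs, responses)
    within = res.second_level.query("level == 'within'").set_index("effect")
    assert within.loc["interaction", "estimate"] == pytest.approx(
        mlm.params["interaction"], abs=0.01)
    assert within.loc["time", "estimate"] == pytest.approx(mlm.params["time"], abs=0.01)


# ------------------------------------------------------------------ contrast

def test_reversal_contrast_df_and_full_reversal_sign(orders):
    cohort = simulate_cohort(orders, recovery_gen(0.06, 1.0, seed=9, n_subjects=20,
                                                  noise_sd=0.0))
    responses = [s.amplitudes for s in cohort.subjects]
    seqs = [cohort.sequences[s.order] for s in cohort.subjects]
    res = instructed_reversal_contrast(responses, seqs)
    assert res.df == 19
    assert res.estimate > 0
    # noiseless: per-subject effect = slope * (EV differential post - pre),
    # computable directly from the generating EV traces
    from revlearn.models import simulate_ev_trace
    expected = []
    for s in cohort.subjects:
        sq = cohort.sequences[s.order]
        ev = simulate_ev_trace(sq, cohort.gen.model).v_presented * s.truth["slope"]
        effs = []
        for w in instruction_windows(sq):
            plus, minus = w.new_cs_plus, ("B" if w.new_cs_plus == "A" else "A")
            post = ev[np.array(w.post_trials[plus]) - 1].mean() \
                - ev[np.array(w.post_trials[minus]) - 1].mean()
            pre = ev[np.array(w.pre_trials[plus]) - 1].mean() \
                - ev[np.array(w.pre_trials[minus]) - 1].mean()
            effs.append(post - pre)
        expected.append(np.mean(effs))
    assert res.estimate == pytest.approx(np.mean(expected), abs=1e-10)


def test_reversal_contrast_null_when_rho_zero(orders):
    cohort = simulate_cohort(orders, recovery_gen(0.06, 0.0, seed=10, n_subjects=40,
                                                  noise_sd=0.05))
    responses = [s.amplitudes for s in cohort.subjects]
    seqs = [cohort.sequences[s.order] for s in cohort.subjects]
    res = instructed_reversal_contrast(responses, seqs)
    assert abs(res.estimate) < 0.04  # pre/post differentials cancel


def test_contrast_input_validation(orders):
    with pytest.raises(ValueError):
        instructed_reversal_contrast([], [])
    with pytest.raises(ValueError):
        instructed_reversal_contrast([np.zeros(80)], [])
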