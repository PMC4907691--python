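import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revlearn.models import (ModelParams, closed_form_ev_constant_r, instructed_swap,
                             rw_update, simulate_ev_trace)
from revlearn.task import TaskConfig, generate_trial_sequence

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


@pytest.mark.parametrize("v, r, alpha, expected", [
    (0.5, 1, 0.061, (0.5305, 0.5)),       # direct substitution
    (0.5, 0, 0.0, (0.5, -0.5)),           # zero learning rate leaves EV unchanged
    (1.0, 1, 0.3, (1.0, 0.0)),            # fully predicted outcome, zero PE
])
def test_rw_update_examples(v, r, alpha, expected):
    v_next, delta = rw_update(v, r, alpha)
    assert v_next == pytest.approx(expected[0], abs=1e-12)
    assert delta == pytest.approx(expected[1], abs=1e-12)


@pytest.mark.parametrize("bad", [
    dict(v=-0.1, r=0, alpha=0.1), dict(v=0.5, r=0, alpha=1.2),
    dict(v=0.5, r=2, alpha=0.1),
])
def test_rw_update_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        rw_update(**bad)


@pytest.mark.parametrize("va, vb, rho, expected", [
    (0.8, 0.2, 1.0, (0.2, 0.8)),          # complete swap
    (0.8, 0.2, 0.0, (0.8, 0.2)),          # identity
    (0.8, 0.2, 0.943, (0.2342, 0.7658)),  # hand evaluation of the mixing equations
])
def test_instructed_swap_examples(va, vb, rho, expected):
    out = instructed_swap(va, vb, rho)
    assert out[0] == pytest.approx(expected[0], abs=1e-12)
    assert out[1] == pytest.approx(expected[1], abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(va=unit, vb=unit, rho=unit)
def test_swap_conserves_value_sum_and_stays_bounded(va, vb, rho):
    a, b = instructed_swap(va, vb, rho)
    assert a + b == pytest.approx(va + vb, abs=1e-12)
    assert -1e-12 <= a <= 1 + 1e-12 and -1e-12 <= b <= 1 + 1e-12


@settings(derandomize=True, max_examples=100)
@given(v0=unit, alpha=unit, r=st.integers(0, 1), n=st.integers(0, 1000))
def test_iterated_update_matches_closed_form(v0, alpha, r, n):
    """Geometric approach to the asymptote: analytic oracle for the recursion."""
    v = v0
    for _ in range(n):
        v, _ = rw_update(v, r, alpha)
    assert v == pytest.approx(closed_form_ev_constant_r(v0, alpha, r, n), abs=1e-9)


def test_closed_form_examples():
    assert closed_form_ev_constant_r(0.5, 0.061, 0, 0) == 0.5
    assert closed_form_ev_constant_r(0.25, 0.1, 0, 3) == pytest.approx(0.18225, abs=1e-12)
    assert closed_form_ev_constant_r(0.5, 0.3, 1, 10_000) == pytest.approx(1.0)


def test_v0_defaults_by_variant():
    fb = ModelParams.feedback(0.1)
    assert (fb.v0_cs_plus, fb.v0_cs_minus) == (0.5, 0.5)
    ins = ModelParams.instructed(0.1, 0.5)
    assert (ins.v0_cs_plus, ins.v0_cs_minus) == (0.75, 0.25)


def test_instructed_rho0_nests_feedback(seq):
    fb = simulate_ev_trace(seq, ModelParams.feedback(0.12))
    ins = simulate_ev_trace(seq, ModelParams.instructed(0.12, 0.0, v0_cs_plus=0.5,
                                                        v0_cs_minus=0.5))
    np.testing.assert_allclose(ins.table[["v_presented", "delta", "v_a", "v_b"]],
                               fb.table[["v_presented", "delta", "v_a", "v_b"]],
                               atol=0, rtol=0)


def test_full_swap_exchanges_values_at_instruction(seq):
    """At the first instruction (shared history), rho=1 hands each cue
    exactly the value the rho=0 model keeps for the other cue."""
    ins = simulate_ev_trace(seq, ModelParams.instructed(0.061, 1.0))
    fb = simulate_ev_trace(seq, ModelParams.instructed(0.061, 0.0, v0_cs_plus=0.75,
                                                       v0_cs_minus=0.25))
    first = int(seq.instructions["after_trial"].iloc[0])
    row_i = ins.table[ins.table["trial"] == first].iloc[0]
    row_f = fb.table[fb.table["trial"] == first].iloc[0]
    assert row_i["v_a"] == pytest.approx(row_f["v_b"], abs=1e-12)
    assert row_i["v_b"] == pytest.approx(row_f["v_a"], abs=1e-12)


def test_feedback_variant_ignores_instructions(seq):
    fb = simulate_ev_trace(seq, ModelParams.feedback(0.2))
    tbl = fb.table
    for after in seq.instructions["after_trial"].astype(int):
        before = tbl[tbl["trial"] == after].iloc[0]
        nxt = tbl[tbl["trial"] == after + 1].iloc[0]
        unpresented = "v_b" if nxt["cue"] == "A" else "v_a"
        assert nxt[unpresented] == before[unpresented]


def test_geometric_decay_without_reinforcement():
    """With no shocks every cue's EV decays as v0 * (1 - alpha)^k."""
    config = TaskConfig(reinforced_per_block=0)
    s = generate_trial_sequence(config, seed=3)
    alpha = 0.17
    trace = simulate_ev_trace(s, ModelParams.feedback(alpha, v0_cs_plus=0.9,
                                                      v0_cs_minus=0.4))
    seen = {"A": 0, "B": 0}
    v0 = {"A": 0.9, "B": 0.4}
    for row in trace.table.itertuples(index=False):
        expected = closed_form_ev_constant_r(v0[row.cue], alpha, 0, seen[row.cue])
        assert row.v_presented == pytest.approx(expected, abs=1e-12)
        seen[row.cue] += 1


def test_ev_bounded_and_monotone_approach(orders):
    rng = np.random.default_rng(0)
    for _ in range(20):
        params = ModelParams.instructed(rng.uniform(0, 1), rng.uniform(0, 1),
                                        v0_cs_plus=rng.uniform(0, 1),
                                        v0_cs_minus=rng.uniform(0, 1))
        t = simulate_ev_trace(orders[0], params).table
        assert ((t[["v_a", "v_b"]] >= -1e-12).all().all()
                and (t[["v_a", "v_b"]] <= 1 + 1e-12).all().all())
        assert t["delta"].between(-1 - 1e-12, 1 + 1e-12).all()
    # under repeated identical outcomes |V - r| is non-increasing
    v = 0.9
    prev = abs(v - 0)
    for _ in range(50):
        v, _ = rw_update(v, 0, 0.3)
        assert abs(v - 0) <= prev + 1e-15
        prev = abs(v - 0)
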