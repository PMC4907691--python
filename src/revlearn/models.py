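"""Rescorla-Wagner learning with an instructed-reversal parameter.

The feedback-driven model learns an expected value (EV) ``V`` per cue
from shock outcomes ``r`` (1 = shock, 0 = no shock) with a constant
learning rate ``alpha``::

    delta_n = r_n - V_n(x_n)
    V_{n+1}(x_n) = V_n(x_n) + alpha * delta_n

Only the presented cue ``x_n`` updates; the other cue's EV carries
forward. The instructed variant additionally mixes the two cues' EVs at
each instruction event with weight ``rho``::

    V'(a) = rho * V(b) + (1 - rho) * V(a)
    V'(b) = rho * V(a) + (1 - rho) * V(b)

so ``rho = 0`` ignores instructions (the model nests the feedback
variant) and ``rho = 1`` swaps the values completely. The swap is
applied after the last pre-instruction trial's update and before the
next trial's onset value is read.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .task import CS_PLUS, CUES, TrialSequence

__all__ = [
    "ModelParams",
    "EVTrace",
    "rw_update",
    "instructed_swap",
    "simulate_ev_trace",
    "closed_form_ev_constant_r",
    "FEEDBACK",
    "INSTRUCTED",
]

FEEDBACK = "feedback"
INSTRUCTED = "instructed"

#: Default initial EVs. The instructed group was told the initial
#: contingencies, hence asymmetric priors by original role.
V0_DEFAULTS = {FEEDBACK: (0.5, 0.5), INSTRUCTED: (0.75, 0.25)}


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class ModelParams:
    """Learning-model parameters.

    ``v0_cs_plus`` / ``v0_cs_minus`` are initial EVs assigned by the
    cues' *original* (block-1) roles. ``rho`` is ignored for the
    feedback variant.
    """

    alpha: float
    rho: float = 0.0
    v0_cs_plus: float | None = None
    v0_cs_minus: float | None = None
    variant: str = FEEDBACK

    def __post_init__(self) -> None:
        if self.variant not in (FEEDBACK, INSTRUCTED):
            raise ValueError(f"unknown variant {self.variant!r}")
        _check_unit("alpha", self.alpha)
        _check_unit("rho", self.rho)
        defaults = V0_DEFAULTS[self.variant]
        if self.v0_cs_plus is None:
            object.__setattr__(self, "v0_cs_plus", defaults[0])
        if self.v0_cs_minus is None:
            object.__setattr__(self, "v0_cs_minus", defaults[1])
        _check_unit("v0_cs_plus", self.v0_cs_plus)
        _check_unit("v0_cs_minus", self.v0_cs_minus)

    @classmethod
    def feedback(cls, alpha: float, **kw) -> "ModelParams":
        return cls(alpha=alpha, variant=FEEDBACK, **kw)

    @classmethod
    def instructed(cls, alpha: float, rho: float, **kw) -> "ModelParams":
        return cls(alpha=alpha, rho=rho, variant=INSTRUCTED, **kw)


@dataclass
class EVTrace:
    """Per-trial EV and prediction-error trace.

    ``table`` columns: trial, cue, us, v_presented (EV of the shown cue
    at onset), delta (r - v_presented, attributed to cue offset), v_a and
    v_b (both cues' EVs after the trial's update and any instruction
    event).
    """

    table: pd.DataFrame
    params: ModelParams

    @property
    def v_presented(self) -> np.ndarray:
        return self.table["v_presented"].to_numpy()

    @property
    def delta(self) -> np.ndarray:
        return self.table["delta"].to_numpy()

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False)


def rw_update(v: float, r: int, alpha: float) -> tuple[float, float]:
    """One Rescorla-Wagner update; returns (v_next, delta)."""
    v = _check_unit("v", v)
    alpha = _check_unit("alpha", alpha)
    if r not in (0, 1):
        raise ValueError(f"outcome r must be 0 or 1, got {r}")
    delta = r - v
    return v + alpha * delta, delta


def instructed_swap(v_a: float, v_b: float, rho: float) -> tuple[float, float]:
    """Mix the two cues' EVs with weight ``rho`` (0 = identity, 1 = swap)."""
    v_a = _check_unit("v_a", v_a)
    v_b = _check_unit("v_b", v_b)
    rho = _check_unit("rho", rho)
    return rho * v_b + (1 - rho) * v_a, rho * v_a + (1 - rho) * v_b


def closed_form_ev_constant_r(v0: float, alpha: float, r: int, n: int) -> float:
    """EV after ``n`` identical outcomes ``r``: geometric approach to the asymptote.

    Analytic oracle for the iterated update: ``r + (v0 - r) * (1 - alpha)**n``.
    """
    return r + (v0 - r) * (1.0 - alpha) ** n


def _initial_values(seq: TrialSequence, params: ModelParams) -> dict[str, float]:
    """Assign V0 by original (block-1) role."""
    original_plus = seq.config.cs_plus_cue(1)
    original_minus = CUES[1] if original_plus == CUES[0] else CUES[0]
    return {original_plus: params.v0_cs_plus, original_minus: params.v0_cs_minus}


def simulate_ev_trace(seq: TrialSequence, params: ModelParams) -> EVTrace:
    """Run the learning model over a trial sequence.

    The feedback variant ignores instruction events; the instructed
    variant applies :func:`instructed_swap` exactly once immediately
    after each instruction event's preceding trial.
    """
    v = _initial_values(seq, params)
    instructed = params.variant == INSTRUCTED
    instruction_after = (
        set(seq.instructions["after_trial"].astype(int)) if not seq.instructions.empty else set()
    )
    rows = []
    for row in seq.events.itertuples(index=False):
        cue, r, trial = row.cue, int(row.us), int(row.trial)
        v_onset = v[cue]
        v[cue], delta = rw_update(v_onset, r, params.alpha)
        if instructed and trial in instruction_after:
            v["A"], v["B"] = instructed_swap(v["A"], v["B"], params.rho)
        rows.append((trial, cue, r, v_onset, delta, v["A"], v["B"]))
    table = pd.DataFrame(rows, columns=["trial", "cue", "us", "v_presented", "delta", "v_a", "v_b"])
    return EVTrace(table=table, params=params)
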