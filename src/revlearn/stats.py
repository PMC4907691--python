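"""Two-level mixed-model analysis of normalized SCR.

Each unreinforced trial is effect-coded (plus/minus 1/2) as Stimulus
(original CS+ vs original CS-) and Reversal (original vs reversed
contingencies), with their interaction equivalent to current CS+ vs
current CS- (so the interaction beta is the mean differential response),
plus a standardized linear Time regressor for habituation and an
intercept. Reversal boundaries follow the instructions in the
instructed group and the first shock on the previous CS- in the
uninstructed group. Stage one fits each subject by OLS; stage two tests
the betas across subjects, controlling for group via a centered group
code, and tests group differences.

The instructed-reversal contrast compares differential responding
(coded by the *new* contingencies) in the post-instruction,
pre-reinforcement window against the equally many unreinforced trials of
each cue immediately before the instruction, averaged over the three
reversals, with a one-sample t-test across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import CS_PLUS, CUES, ReversalWindow, TrialSequence, instruction_windows

__all__ = [
    "FirstLevelDesign",
    "LMMResult",
    "ContrastResult",
    "TwoLevelSCRModel",
    "build_first_level_design",
    "fit_two_level",
    "instructed_reversal_contrast",
    "mixedlm_crosscheck",
]

EFFECTS = ("intercept", "stimulus", "reversal", "interaction", "time")
SUBSETS = ("all", "post_first_reversal", "second_half_of_each_run")


@dataclass
class FirstLevelDesign:
    """Effect-coded design over the analyzed (unreinforced) trials."""

    frame: pd.DataFrame  # trial, stimulus, reversal, interaction, time, phase
    group: str
    subset: str

    @property
    def matrix(self) -> np.ndarray:
        X = np.column_stack([
            np.ones(len(self.frame)),
            self.frame["stimulus"].to_numpy(),
            self.frame["reversal"].to_numpy(),
            self.frame["interaction"].to_numpy(),
            self.frame["time"].to_numpy(),
        ])
        return X

    @property
    def trials(self) -> np.ndarray:
        return self.frame["trial"].to_numpy()


@dataclass
class LMMResult:
    first_level: pd.DataFrame   # one row per subject: group + effect betas
    second_level: pd.DataFrame  # effect, level, estimate, se, t, df, p, n


@dataclass
class ContrastResult:
    estimate: float
    t_stat: float
    df: int
    p_value: float
    per_subject: np.ndarray


def _phases(seq: TrialSequence, group: str) -> np.ndarray:
    """0-based reversal phase per trial under the group's boundary rule."""
    ev = seq.events
    n = len(ev)
    phase = np.zeros(n, dtype=int)
    if group == "instructed":
        boundaries = (
            seq.instructions["after_trial"].astype(int).to_numpy()
            if not seq.instructions.empty else np.array([], dtype=int)
        )
        for b in boundaries:
            phase[ev["trial"].to_numpy() > b] += 1
    elif group == "uninstructed":
        current_plus = seq.config.cs_plus_cue(1)
        p = 0
        cues = ev["cue"].to_numpy()
        us = ev["us"].to_numpy()
        for i in range(n):
            if us[i] and cues[i] != current_plus:
                p += 1
                current_plus = cues[i]
            phase[i] = p
    else:
        raise ValueError(f"unknown group {group!r}")
    return phase


def build_first_level_design(seq: TrialSequence, group: str,
                             subset: str = "all") -> FirstLevelDesign:
    """Effect-coded first-level design restricted to unreinforced CS trials."""
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}")
    ev = seq.events
    phase = _phases(seq, group)
    stimulus = np.where(ev["original_role"].to_numpy() == CS_PLUS, 0.5, -0.5)
    reversal = np.where(phase % 2 == 0, 0.5, -0.5)
    interaction = 2.0 * stimulus * reversal  # +/- 1/2 for current CS+ vs CS-

    keep = ev["us"].to_numpy() == 0
    if subset == "post_first_reversal":
        keep &= phase >= 1
    elif subset == "second_half_of_each_run":
        half = np.zeros(len(ev), dtype=bool)
        for p in np.unique(phase):
            idx = np.flatnonzero(phase == p)
            half[idx[len(idx) // 2:]] = True
        keep &= half
    if not keep.any():
        raise ValueError(f"subset {subset!r} selects no trials")

    trial = ev["trial"].to_numpy()[keep]
    time = (trial - trial.mean()) / trial.std(ddof=0)
    frame = pd.DataFrame({
        "trial": trial,
        "stimulus": stimulus[keep],
        "reversal": reversal[keep],
        "interaction": interaction[keep],
        "time": time,
        "phase": phase[keep],
    })
    return FirstLevelDesign(frame=frame, group=group, subset=subset)


def _first_level_betas(design: FirstLevelDesign, scores: np.ndarray) -> np.ndarray:
    """OLS betas; effects with a zero-variance column come back NaN."""
    X = design.matrix
    y = np.asarray(scores, float)[design.trials - 1]
    betas = np.full(X.shape[1], np.nan)
    usable = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    Xu = X[:, usable]
    if np.linalg.matrix_rank(Xu) < Xu.shape[1]:
        usable = [0]
        Xu = X[:, :1]
    sol, *_ = np.linalg.lstsq(Xu, y, rcond=None)
    for j, b in zip(usable, sol):
        betas[j] = b
    return betas


def _second_level_rows(effect: str, betas: np.ndarray, group_code: np.ndarray) -> list[dict]:
    ok = ~np.isnan(betas)
    b = betas[ok]
    g = group_code[ok]
    rows = []
    n = b.size
    if np.unique(g).size < 2:
        if n >= 2:
            t, p = sps.ttest_1samp(b, 0.0)
            rows.append(dict(effect=effect, level="within", estimate=float(b.mean()),
                             se=float(b.std(ddof=1) / np.sqrt(n)), t=float(t),
                             df=n - 1, p=float(p), n=n))
    else:
        X = np.column_stack([np.ones(n), g - g.mean()])
        coef, *_ = np.linalg.lstsq(X, b, rcond=None)
        resid = b - X @ coef
        dof = n - 2
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        for level, j in (("within", 0), ("group_diff", 1)):
            se = float(np.sqrt(cov[j, j]))
            t = float(coef[j] / se)
            rows.append(dict(effect=effect, level=level, estimate=float(coef[j]),
                             se=se, t=t, df=dof, p=float(2 * sps.t.sf(abs(t), dof)), n=n))
    return rows


def fit_two_level(designs: list[FirstLevelDesign], responses: list[np.ndarray],
                  groups: list[str] | None = None) -> LMMResult:
    """Stage-one OLS per subject, stage-two t-tests across subjects.

    ``responses`` are full-length per-trial normalized SCR vectors; each
    design selects and codes its subject's analyzed trials. With two
    groups present, within-subject effects are tested controlling for
    group (centered group code at the second level) and group
    differences are tested on the same model's group term.
    """
    if len(designs) != len(responses):
        raise ValueError("designs and responses must have equal length")
    if len(designs) < 2:
        raise ValueError("need at least two subjects")
    if groups is None:
        groups = [d.group for d in designs]

    betas = np.vstack([_first_level_betas(d, y) for d, y in zip(designs, responses)])
    first = pd.DataFrame(betas, columns=EFFECTS)
    first.insert(0, "group", groups)
    first.insert(0, "subject", np.arange(len(designs)))

    uniq = sorted(set(groups))
    code = np.array([0.5 if g == uniq[0] else -0.5 for g in groups]) \
        if len(uniq) == 2 else np.zeros(len(groups))
    rows = []
    for j, effect in enumerate(EFFECTS):
        rows.extend(_second_level_rows(effect, betas[:, j], code))
    return LMMResult(first_level=first, second_level=pd.DataFrame(rows))


class TwoLevelSCRModel:
    """Estimator wrapper around the two-stage summary-statistics analysis."""

    def __init__(self, subset: str = "all"):
        self.subset = subset

    def get_params(self, deep: bool = True) -> dict:
        return {"subset": self.subset}

    def set_params(self, **params) -> "TwoLevelSCRModel":
        for k, v in params.items():
            if k != "subset":
                raise ValueError(f"unknown parameter {k!r}")
            self.subset = v
        return self

    def fit(self, sequences: list[TrialSequence], responses: list[np.ndarray],
            groups: list[str]) -> "TwoLevelSCRModel":
        designs = [build_first_level_design(s, g, self.subset)
                   for s, g in zip(sequences, groups)]
        res = fit_two_level(designs, responses, groups)
        self.designs_ = designs
        self.first_level_ = res.first_level
        self.second_level_ = res.second_level
        self.result_ = res
        return self


def instructed_reversal_contrast(responses: list[np.ndarray],
                                 windows: list[list[ReversalWindow]] |
                                 list[TrialSequence]) -> ContrastResult:
    """Immediate effect of instructions on differential SCR.

    Per subject: mean over reversals of [post-window differential minus
    pre-window differential], with the differential coded as new CS+
    minus new CS- in both windows; one-sample t-test across subjects.
    """
    if len(responses) != len(windows):
        raise ValueError("responses and windows must have equal length")
    if not windows:
        raise ValueError("no subjects supplied")
    per_subject = []
    for y, w in zip(responses, windows):
        if isinstance(w, TrialSequence):
            w = instruction_windows(w)
        if not w:
            raise ValueError("subject has no reversal windows")
        y = np.asarray(y, float)
        effects = []
        for win in w:
            plus = win.new_cs_plus
            minus = CUES[1] if plus == CUES[0] else CUES[0]
            post = (y[np.asarray(win.post_trials[plus]) - 1].mean()
                    - y[np.asarray(win.post_trials[minus]) - 1].mean())
            pre = (y[np.asarray(win.pre_trials[plus]) - 1].mean()
                   - y[np.asarray(win.pre_trials[minus]) - 1].mean())
            effects.append(post - pre)
        per_subject.append(float(np.mean(effects)))
    per_subject = np.asarray(per_subject)
    n = per_subject.size
    if n < 2:
        raise ValueError("need at least two subjects for the t-test")
    t, p = sps.ttest_1samp(per_subject, 0.0)
    return ContrastResult(estimate=float(per_subject.mean()), t_stat=float(t),
                          df=n - 1, p_value=float(p), per_subject=per_subject)


def mixedlm_crosscheck(designs: list[FirstLevelDesign], responses: list[np.ndarray]):
    """Fixed effects from a joint random-intercept mixed model (statsmodels).

    Independent verification path for the two-stage estimates; returns
    the fitted MixedLM results object.
    """
    import statsmodels.api as sm

    frames = []
    for i, (d, y) in enumerate(zip(designs, responses)):
        f = d.frame[["stimulus", "reversal", "interaction", "time"]].copy()
        f["scr"] = np.asarray(y, float)[d.trials - 1]
        f["subject"] = i
        frames.append(f)
    long = pd.concat(frames, ignore_index=True)
    exog = sm.add_constant(long[["stimulus", "reversal", "interaction", "time"]])
    model = sm.MixedLM(long["scr"], exog, groups=long["subject"])
    return model.fit(reml=True)
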