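"""Fitting learning models to trial-by-trial SCR.

The observation model is two-stage: a candidate ``(alpha, rho)`` is
applied to each subject's trial order to produce an expected-value (EV)
timecourse; each subject's SCR is regressed on that timecourse (OLS with
intercept and slope, so per-subject scale and offset are free); the
per-subject predictions are concatenated and the aggregated sum of
squared errors is the objective. "Across-subjects" fits treat the
learning parameters as fixed effects shared by the group while slopes
vary by subject; "within-subject" fits estimate them per individual.

Minimization uses a derivative-free Nelder-Mead simplex restarted from
dispersed starting points. By default the search is unbounded in the
natural parameter space (inside a broad feasibility box), as with a
plain simplex search: a bounded estimator folds all sampling error at a
boundary (e.g. a true ``rho = 0``) to one side and is biased there,
whereas the unbounded estimate is centered on the truth; a logistic
reparameterization enforcing ``alpha, rho in [0, 1]`` is available via
``bounded=True``. Goodness of fit is reported both as raw SSE
and as a Gaussian deviance, ``-2 logLik = N log(2 pi SSE / N) + N`` with
the residual variance at its ML value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .models import FEEDBACK, INSTRUCTED, ModelParams, V0_DEFAULTS
from .synth import Cohort
from .task import TrialSequence

__all__ = [
    "CohortSCR",
    "FitResult",
    "GroupComparison",
    "RescorlaWagnerSCR",
    "DegenerateRegressorError",
    "ev_regressor_for_subject",
    "across_subjects_objective",
    "fit_across_subjects",
    "fit_within_subject",
    "fit_within_cohort",
    "deviance",
    "compare_rho_groups",
]


class DegenerateRegressorError(ValueError):
    """EV regressor has zero variance for one or more subjects."""


# ---------------------------------------------------------------------------
# fast EV recursion on pre-extracted arrays

@dataclass(frozen=True)
class _SeqArrays:
    cue_is_b: np.ndarray        # int8, 0 = cue A, 1 = cue B
    us: np.ndarray              # int8
    instr_after: np.ndarray     # bool, swap applied after this trial
    orig_plus_is_b: bool
    analyzed: np.ndarray        # bool mask of fitted trials (unreinforced CS)

    @classmethod
    def from_sequence(cls, seq: TrialSequence, analyze: str = "unreinforced") -> "_SeqArrays":
        cue_is_b = (seq.events["cue"].to_numpy() == "B").astype(np.int8)
        us = seq.events["us"].to_numpy().astype(np.int8)
        instr = np.zeros(len(cue_is_b), dtype=bool)
        if not seq.instructions.empty:
            instr[seq.instructions["after_trial"].astype(int).to_numpy() - 1] = True
        analyzed = us == 0 if analyze == "unreinforced" else np.ones(len(us), dtype=bool)
        return cls(cue_is_b=cue_is_b, us=us, instr_after=instr,
                   orig_plus_is_b=seq.config.cs_plus_cue(1) == "B", analyzed=analyzed)


def _ev_values(arr: _SeqArrays, alpha: float, rho: float, v0_plus: float,
               v0_minus: float, instructed: bool) -> np.ndarray:
    """EV of the presented cue at onset, for every trial."""
    if arr.orig_plus_is_b:
        va, vb = v0_minus, v0_plus
    else:
        va, vb = v0_plus, v0_minus
    n = arr.cue_is_b.size
    out = np.empty(n)
    cue_is_b, us, instr = arr.cue_is_b, arr.us, arr.instr_after
    for i in range(n):
        if cue_is_b[i]:
            out[i] = vb
            vb += alpha * (us[i] - vb)
        else:
            out[i] = va
            va += alpha * (us[i] - va)
        if instructed and instr[i]:
            va, vb = rho * vb + (1 - rho) * va, rho * va + (1 - rho) * vb
    return out


def ev_regressor_for_subject(seq: TrialSequence, params: ModelParams,
                             analyze: str = "unreinforced") -> np.ndarray:
    """Predicted EV timecourse over the analyzed trials of one sequence."""
    arr = _SeqArrays.from_sequence(seq, analyze)
    ev = _ev_values(arr, params.alpha, params.rho, params.v0_cs_plus,
                    params.v0_cs_minus, params.variant == INSTRUCTED)
    return ev[arr.analyzed]


# ---------------------------------------------------------------------------
# cohort container

@dataclass
class CohortSCR:
    """Scored cohort ready for model fitting.

    One trial sequence per distinct order; each subject carries a
    full-length per-trial response vector and the index of its order.
    Only unreinforced CS trials enter the fit by default (US-trial scores
    reflect the US response and serve normalization, not the CS).
    """

    sequences: list[TrialSequence]
    responses: list[np.ndarray]
    orders: list[int]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.responses) != len(self.orders):
            raise ValueError("responses and orders must have equal length")
        if not self.subject_ids:
            self.subject_ids = [f"s{i:03d}" for i in range(len(self.responses))]
        for i, (y, o) in enumerate(zip(self.responses, self.orders)):
            if len(y) != self.sequences[o].n_trials:
                raise ValueError(f"subject {i}: response length does not match sequence")

    def __len__(self) -> int:
        return len(self.responses)

    @classmethod
    def from_cohort(cls, cohort: Cohort, normalized: bool = False,
                    subjects: list[int] | None = None) -> "CohortSCR":
        """Build from a synthetic cohort's amplitude tables.

        With ``normalized=True``, amplitudes are sqrt-transformed and
        scaled by the mean transformed US response (the analysis scale);
        otherwise raw amplitudes are used (per-subject OLS absorbs
        affine scale anyway).
        """
        from .scoring import transform_normalize

        idx = range(len(cohort.subjects)) if subjects is None else subjects
        responses, orders, ids = [], [], []
        for i in idx:
            s = cohort.subjects[i]
            if normalized:
                seq = cohort.sequences[s.order]
                us = seq.events["us"].to_numpy().astype(bool)
                scores = np.where(us, s.us_amplitudes, s.amplitudes)
                responses.append(transform_normalize(scores, us).normalized)
            else:
                responses.append(s.amplitudes)
            orders.append(s.order)
            ids.append(s.subject_id)
        return cls(sequences=list(cohort.sequences), responses=responses,
                   orders=orders, subject_ids=ids)


# ---------------------------------------------------------------------------
# results

@dataclass
class FitResult:
    params: ModelParams          # point estimates clipped to [0, 1] for simulation
    alpha: float                 # raw point estimate (may sit slightly outside [0, 1])
    rho: float | None
    per_subject: np.ndarray      # (n_subjects, 2): intercept, slope
    sse: float
    deviance: float | None
    n_obs: int
    n_subjects: int
    fit_mode: str
    restarts: list[tuple[float, float | None, float]]  # (alpha, rho, sse) per restart
    degenerate_noiseless: bool = False


@dataclass
class GroupComparison:
    t_stat: float
    df: int
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


# ---------------------------------------------------------------------------
# objective

def _ols_sse(x: np.ndarray, ys: list[np.ndarray]) -> tuple[float, list[tuple[float, float]]]:
    """Per-subject OLS of y on (1, x); returns summed SSE and coefficients."""
    xm = x.mean()
    xc = x - xm
    sxx = float(xc @ xc)
    total = 0.0
    coefs = []
    for y in ys:
        ym = y.mean()
        if sxx < 1e-12:
            # numerically degenerate regressor: intercept-only fallback
            slope = 0.0
        else:
            slope = float(xc @ (y - ym)) / sxx
        intercept = ym - slope * xm
        resid = y - intercept - slope * x
        total += float(resid @ resid)
        coefs.append((intercept, slope))
    return total, coefs


def _cohort_sse(cohort: CohortSCR, alpha: float, rho: float, v0p: float, v0m: float,
                instructed: bool, arrays: list[_SeqArrays]) -> tuple[float, np.ndarray]:
    sse = 0.0
    coefs = np.empty((len(cohort), 2))
    for o, arr in enumerate(arrays):
        members = [i for i, oo in enumerate(cohort.orders) if oo == o]
        if not members:
            continue
        ev = _ev_values(arr, alpha, rho, v0p, v0m, instructed)[arr.analyzed]
        ys = [np.asarray(cohort.responses[i])[arr.analyzed] for i in members]
        s, cs = _ols_sse(ev, ys)
        sse += s
        for i, c in zip(members, cs):
            coefs[i] = c
    return sse, coefs


def across_subjects_objective(params: ModelParams, cohort: CohortSCR,
                              analyze: str = "unreinforced") -> float:
    """Aggregated SSE of concatenated per-subject OLS fits.

    Raises :class:`DegenerateRegressorError` when the EV regressor has
    zero variance (e.g. ``alpha = 0`` in the feedback variant), naming
    the affected sequences.
    """
    arrays = [_SeqArrays.from_sequence(s, analyze) for s in cohort.sequences]
    bad = []
    for o, arr in enumerate(arrays):
        ev = _ev_values(arr, params.alpha, params.rho, params.v0_cs_plus,
                        params.v0_cs_minus, params.variant == INSTRUCTED)[arr.analyzed]
        if np.ptp(ev) == 0.0:
            bad.append(o)
    if bad:
        raise DegenerateRegressorError(
            f"EV regressor constant for trial order(s) {bad}; "
            "subjects on these orders cannot constrain the slope"
        )
    sse, _ = _cohort_sse(cohort, params.alpha, params.rho, params.v0_cs_plus,
                         params.v0_cs_minus, params.variant == INSTRUCTED, arrays)
    return sse


def deviance(sse: float, n_obs: int) -> float:
    """Gaussian -2 log-likelihood at the ML residual variance."""
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    if sse <= 0:
        raise ValueError("SSE is zero: deviance undefined for a noiseless exact fit")
    return n_obs * math.log(2.0 * math.pi * sse / n_obs) + n_obs


def _logistic(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


class RescorlaWagnerSCR:
    """Scikit-learn style estimator for the (instructed) Rescorla-Wagner fit.

    Parameters
    ----------
    variant : {'feedback', 'instructed'}
        'feedback' fits alpha only; 'instructed' fits (alpha, rho) and
        applies the rho-mixing at each instruction event.
    v0_cs_plus, v0_cs_minus : float or None
        Initial EVs by original role; None selects the variant default
        (0.5/0.5 feedback, 0.75/0.25 instructed).
    n_restarts : int
        Nelder-Mead restarts from dispersed starting points; the best
        endpoint is kept.
    restart_seed : int
        Seed for the dispersed starting points.
    analyze : {'unreinforced', 'all'}
        Which trials enter the regression.
    bounded : bool
        False (default): unbounded simplex search in the natural
        parameter space, restricted only to a broad feasibility box
        (alpha in [-0.5, 1.5], rho in [-1, 2]); point estimates may fall
        slightly outside [0, 1] and are reported as found, which keeps
        the estimator unbiased when the truth sits on a boundary.
        True: logistic reparameterization constraining both to (0, 1).

    Fitted attributes: ``alpha_``, ``rho_``, ``params_`` (values clipped
    to [0, 1] for simulation), ``coef_`` (per-subject intercept/slope),
    ``sse_``, ``deviance_``, ``n_obs_``, ``restarts_``, ``result_``.
    """

    #: feasibility box for the unbounded search
    _BOX = {"alpha": (-0.5, 1.5), "rho": (-1.0, 2.0)}

    def __init__(self, variant: str = INSTRUCTED, v0_cs_plus: float | None = None,
                 v0_cs_minus: float | None = None, n_restarts: int = 10,
                 restart_seed: int = 0, analyze: str = "unreinforced",
                 bounded: bool = False, xatol: float = 1e-6, fatol: float = 1e-12,
                 maxiter: int = 600):
        self.variant = variant
        self.v0_cs_plus = v0_cs_plus
        self.v0_cs_minus = v0_cs_minus
        self.n_restarts = n_restarts
        self.restart_seed = restart_seed
        self.analyze = analyze
        self.bounded = bounded
        self.xatol = xatol
        self.fatol = fatol
        self.maxiter = maxiter

    _param_names = ("variant", "v0_cs_plus", "v0_cs_minus", "n_restarts",
                    "restart_seed", "analyze", "bounded", "xatol", "fatol", "maxiter")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "RescorlaWagnerSCR":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ------------------------------------------------------------
    def _v0(self) -> tuple[float, float]:
        d = V0_DEFAULTS[self.variant]
        return (d[0] if self.v0_cs_plus is None else self.v0_cs_plus,
                d[1] if self.v0_cs_minus is None else self.v0_cs_minus)

    def _starts(self) -> list[np.ndarray]:
        """Dispersed starting points: alpha in (0.01, 0.5), rho in (0.05, 0.95)."""
        rng = np.random.default_rng(self.restart_seed)
        starts = []
        for _ in range(self.n_restarts):
            a = rng.uniform(0.01, 0.5)
            p = [a] if not self.bounded else [_logit(a)]
            if self.variant == INSTRUCTED:
                r = rng.uniform(0.05, 0.95)
                p.append(r if not self.bounded else _logit(r))
            starts.append(np.asarray(p))
        return starts

    def fit(self, cohort: CohortSCR | Cohort, y=None) -> "RescorlaWagnerSCR":
        if isinstance(cohort, Cohort):
            cohort = CohortSCR.from_cohort(cohort)
        if len(cohort) < 1:
            raise ValueError("cohort is empty")
        cohort = self._drop_flat_subjects(cohort)
        if self.variant not in (FEEDBACK, INSTRUCTED):
            raise ValueError(f"unknown variant {self.variant!r}")
        v0p, v0m = self._v0()
        instructed = self.variant == INSTRUCTED
        arrays = [_SeqArrays.from_sequence(s, self.analyze) for s in cohort.sequences]

        box_a, box_r = self._BOX["alpha"], self._BOX["rho"]

        def decode(z: np.ndarray) -> tuple[float, float]:
            if self.bounded:
                return _logistic(z[0]), _logistic(z[1]) if instructed else 0.0
            return float(z[0]), float(z[1]) if instructed else 0.0

        def objective(z: np.ndarray) -> float:
            alpha, rho = decode(z)
            if not self.bounded:
                if not box_a[0] <= alpha <= box_a[1]:
                    return np.inf
                if instructed and not box_r[0] <= rho <= box_r[1]:
                    return np.inf
            sse, _ = _cohort_sse(cohort, alpha, rho, v0p, v0m, instructed, arrays)
            if not np.isfinite(sse):
                raise FloatingPointError("non-finite SSE in objective")
            return sse

        best = None
        restarts = []
        for z0 in self._starts():
            res = optimize.minimize(
                objective, z0, method="Nelder-Mead",
                options={"xatol": self.xatol, "fatol": self.fatol,
                         "maxiter": self.maxiter, "maxfev": 4 * self.maxiter},
            )
            alpha, rho = decode(res.x)
            restarts.append((alpha, rho if instructed else None, float(res.fun)))
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("optimization failed to produce a finite SSE")

        alpha, rho = decode(best.x)
        sse, coefs = _cohort_sse(cohort, alpha, rho, v0p, v0m, instructed, arrays)
        n_obs = sum(int(arrays[o].analyzed.sum()) for o in cohort.orders)

        self.alpha_ = alpha
        self.rho_ = rho if instructed else None
        # ModelParams validates [0, 1]; clip for simulation use, report raw above
        self.params_ = ModelParams(
            alpha=float(np.clip(alpha, 0.0, 1.0)),
            rho=float(np.clip(rho, 0.0, 1.0)) if instructed else 0.0,
            v0_cs_plus=v0p, v0_cs_minus=v0m, variant=self.variant)
        self.coef_ = coefs
        self.sse_ = float(sse)
        self.n_obs_ = n_obs
        self.n_subjects_ = len(cohort)
        self.restarts_ = restarts
        # optimizer tolerance leaves a tiny residual even on noiseless data
        self.degenerate_noiseless_ = sse <= 1e-10 * max(n_obs, 1)
        self.deviance_ = None if self.degenerate_noiseless_ else deviance(sse, n_obs)
        self.result_ = FitResult(
            params=self.params_, alpha=self.alpha_, rho=self.rho_,
            per_subject=coefs, sse=self.sse_,
            deviance=self.deviance_, n_obs=n_obs, n_subjects=len(cohort),
            fit_mode="within" if len(cohort) == 1 else "across",
            restarts=restarts, degenerate_noiseless=self.degenerate_noiseless_,
        )
        self._fit_cohort_ = cohort
        return self

    @staticmethod
    def _drop_flat_subjects(cohort: CohortSCR) -> CohortSCR:
        keep = []
        for i, y in enumerate(cohort.responses):
            if np.ptp(y) == 0.0:
                warnings.warn(
                    f"subject {cohort.subject_ids[i]} has constant SCR; excluded from fit",
                    stacklevel=3,
                )
            else:
                keep.append(i)
        if len(keep) == len(cohort.responses):
            return cohort
        if not keep:
            raise ValueError("all subjects have constant SCR; nothing to fit")
        return CohortSCR(
            sequences=cohort.sequences,
            responses=[cohort.responses[i] for i in keep],
            orders=[cohort.orders[i] for i in keep],
            subject_ids=[cohort.subject_ids[i] for i in keep],
        )

    def predict(self, cohort: CohortSCR | Cohort | None = None) -> list[np.ndarray]:
        """Per-subject fitted SCR over the analyzed trials."""
        if cohort is None:
            cohort = self._fit_cohort_
        elif isinstance(cohort, Cohort):
            cohort = CohortSCR.from_cohort(cohort)
        v0p, v0m = self._v0()
        instructed = self.variant == INSTRUCTED
        preds = []
        for i, o in enumerate(cohort.orders):
            arr = _SeqArrays.from_sequence(cohort.sequences[o], self.analyze)
            ev = _ev_values(arr, self.alpha_, self.rho_ or 0.0, v0p, v0m,
                            instructed)[arr.analyzed]
            b0, b1 = self.coef_[min(i, len(self.coef_) - 1)]
            preds.append(b0 + b1 * ev)
        return preds


# ---------------------------------------------------------------------------
# functional wrappers

def fit_across_subjects(cohort: CohortSCR | Cohort, variant: str = INSTRUCTED,
                        **options) -> FitResult:
    """Group-level fit: learning parameters fixed across subjects, slopes free."""
    return RescorlaWagnerSCR(variant=variant, **options).fit(cohort).result_


def fit_within_subject(seq: TrialSequence, scr: np.ndarray, variant: str = INSTRUCTED,
                       **options) -> FitResult:
    """Fit one subject's SCR alone.

    Defaults to the bounded (logistic) search: single-subject SSE
    surfaces are flat and occasionally globally minimized at wild
    parameter values (learning rates above 1, negative mixing weights),
    so constraining to the interpretable range regularizes the
    individual estimates, as in ensemble-of-individuals analyses.
    """
    options.setdefault("bounded", True)
    cohort = CohortSCR(sequences=[seq], responses=[np.asarray(scr, float)], orders=[0])
    return RescorlaWagnerSCR(variant=variant, **options).fit(cohort).result_


def fit_within_cohort(cohort: CohortSCR | Cohort, variant: str = INSTRUCTED,
                      **options) -> list[FitResult]:
    """Independent within-subject fits for every cohort member (bounded by default)."""
    if isinstance(cohort, Cohort):
        cohort = CohortSCR.from_cohort(cohort)
    return [
        fit_within_subject(cohort.sequences[o], y, variant, **options)
        for y, o in zip(cohort.responses, cohort.orders)
    ]


def compare_rho_groups(rho_a: np.ndarray, rho_b: np.ndarray) -> GroupComparison:
    """Pooled-variance two-sample t-test on within-subject rho estimates."""
    a = np.asarray(rho_a, float)
    b = np.asarray(rho_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two subjects per group")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0 and a.mean() == b.mean():
        return GroupComparison(0.0, a.size + b.size - 2, 1.0,
                               float(a.mean()), 0.0, float(b.mean()), 0.0)
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        t_stat=float(t), df=a.size + b.size - 2, p_value=float(p),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
    )
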