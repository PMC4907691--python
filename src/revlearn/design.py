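"""First-level fMRI design construction with EV parametric modulators.

Cue epochs (4-s boxcars at onset), cue-offset sticks, EV modulators on
the onset event, shock and prediction-error modulators on the offset
event, and a 10-s instruction boxcar are built at microtime resolution,
convolved with a canonical double-gamma HRF, and downsampled to the TR
grid. Orthogonalization of successive modulators is a toggle (off by
default, so two EV regressors can share variance symmetrically, as when
contrasting instructed against feedback-driven EV). A collinearity
report exposes the algebraic dependence PE = shock - EV that makes the
three modulators from one trace rank deficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import EVTrace
from .task import TrialSequence

__all__ = [
    "DesignMatrix",
    "CollinearityReport",
    "gamma_hrf",
    "build_fmri_design",
    "collinearity_report",
]


def gamma_hrf(dt: float, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
              ratio: float = 6.0, dispersion: float = 1.0,
              support: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds, unit peak.

    Parametrized by the positive lobe's peak time (mode 6 s), the
    undershoot's peak time (16 s), and the peak/undershoot amplitude
    ratio; gamma shape parameters are ``delay / dispersion + 1`` so the
    mode lands exactly on the stated delay.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a1 = peak_delay / dispersion + 1.0
    a2 = undershoot_delay / dispersion + 1.0

    def shape(tt: np.ndarray) -> np.ndarray:
        return (sps.gamma.pdf(tt, a1, scale=dispersion)
                - sps.gamma.pdf(tt, a2, scale=dispersion) / ratio)

    # normalize on a fixed fine grid so kernels at different dt share one scale
    peak = shape(np.arange(0.0, support, 1e-3)).max()
    return shape(np.arange(0.0, support, dt)) / peak


@dataclass
class DesignMatrix:
    """TR-resolution design with metadata.

    ``modulator_values`` holds the raw per-trial modulator vectors
    (before event placement and convolution); the algebraic dependence
    among EV, shock, and prediction error lives there.
    """

    frame: pd.DataFrame
    tr: float
    modulator_columns: list[str]
    modulator_values: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def to_tsv(self) -> str:
        return self.frame.to_csv(sep="\t", index=False)


@dataclass
class CollinearityReport:
    correlations: pd.DataFrame
    vif: pd.Series
    modulator_rank: int
    n_modulators: int
    rank_deficient: bool
    condition_number: float
    flags: list[str]


def _stick(hi_res: np.ndarray, idx: int, amplitude: float = 1.0) -> None:
    if 0 <= idx < hi_res.size:
        hi_res[idx] += amplitude


def _boxcar(hi_res: np.ndarray, start: int, stop: int, amplitude: float = 1.0) -> None:
    hi_res[max(start, 0):min(stop, hi_res.size)] += amplitude


def build_fmri_design(seq: TrialSequence, traces: dict[str, EVTrace] | EVTrace,
                      tr: float = 2.0, microtime: int = 16,
                      orthogonalize: bool = False, center: bool = True,
                      cue_shape: str = "epoch", include_shock_pe: bool = True,
                      pe_trace: str | None = None) -> DesignMatrix:
    """Assemble the first-level design matrix for one trial sequence.

    ``traces`` maps regressor names to EV traces (one or two); each
    yields an EV modulator of the cue-onset event. Shock (0/1) and the
    prediction error of ``pe_trace`` (default: the first trace) modulate
    the cue-offset event. Modulator values are mean-centered before
    convolution when ``center`` is enabled; with ``orthogonalize`` each
    modulator column is residualized against all earlier columns in
    declared order after convolution.
    """
    if isinstance(traces, EVTrace):
        traces = {"ev": traces}
    for name, tr_ in traces.items():
        if len(tr_.table) != seq.n_trials:
            raise ValueError(f"trace {name!r} does not match the sequence length")

    dt = tr / microtime
    config = seq.config
    onsets = seq.events["onset_s"].to_numpy()
    end = onsets[-1] + config.stim_duration + config.isi
    if not seq.instructions.empty:
        end = max(end, seq.instructions["onset_s"].max() + config.instruction_duration)
    duration = end + 32.0
    n_tr = int(np.ceil(duration / tr))
    n_hi = n_tr * microtime
    stim_bins = max(int(round(config.stim_duration / dt)), 1)

    def onset_idx(t: float) -> int:
        return int(round(t / dt))

    hi_cols: dict[str, np.ndarray] = {}

    def event_column(name: str, times: np.ndarray, amplitudes: np.ndarray,
                     shape: str) -> None:
        col = np.zeros(n_hi)
        for t, a in zip(times, amplitudes):
            i = onset_idx(t)
            if shape == "stick":
                _stick(col, i, a)
            else:
                _boxcar(col, i, i + stim_bins, a)
        hi_cols[name] = col

    offsets = onsets + config.stim_duration
    ones = np.ones(seq.n_trials)
    event_column("cue_onset", onsets, ones, cue_shape)
    event_column("cue_offset", offsets, ones, "stick")

    modulators: list[str] = []
    mod_values: dict[str, np.ndarray] = {}
    for name, trace in traces.items():
        v = trace.v_presented.copy()
        if center:
            v = v - v.mean()
        mod_values[f"ev_{name}"] = v
        event_column(f"ev_{name}", onsets, v, cue_shape)
        modulators.append(f"ev_{name}")

    if include_shock_pe:
        shock = seq.events["us"].to_numpy().astype(float)
        pe_name = pe_trace or next(iter(traces))
        pe = traces[pe_name].delta.copy()
        if center:
            shock = shock - shock.mean()
            pe = pe - pe.mean()
        mod_values["shock"] = shock
        mod_values["pe"] = pe
        event_column("shock", offsets, shock, "stick")
        event_column("pe", offsets, pe, "stick")
        modulators += ["shock", "pe"]

    if not seq.instructions.empty:
        col = np.zeros(n_hi)
        bins = max(int(round(config.instruction_duration / dt)), 1)
        for t in seq.instructions["onset_s"]:
            i = onset_idx(float(t))
            _boxcar(col, i, i + bins)
        hi_cols["instruction"] = col

    kernel = gamma_hrf(dt)
    data = {}
    for name, col in hi_cols.items():
        conv = np.convolve(col, kernel)[:n_hi]
        data[name] = conv[::microtime]
    frame = pd.DataFrame(data)

    if orthogonalize:
        order = list(frame.columns)
        X = frame.to_numpy().copy()
        for j, name in enumerate(order):
            if name not in modulators or j == 0:
                continue
            prev = X[:, :j]
            coefs, *_ = np.linalg.lstsq(prev, X[:, j], rcond=None)
            X[:, j] = X[:, j] - prev @ coefs
        frame = pd.DataFrame(X, columns=order)

    meta = {"tr": tr, "microtime": microtime, "orthogonalized": orthogonalize,
            "centered": center, "cue_shape": cue_shape,
            "hrf": {"peak_delay": 6.0, "undershoot_delay": 16.0, "ratio": 6.0}}
    return DesignMatrix(frame=frame, tr=tr, modulator_columns=modulators,
                        modulator_values=pd.DataFrame(mod_values), metadata=meta)


def collinearity_report(dm: DesignMatrix, rank_tol: float = 1e-8) -> CollinearityReport:
    """Pairwise correlations, VIFs, and rank of the modulator block.

    The rank check runs on the raw per-trial modulator values, where the
    identity ``delta = r - V`` makes EV, shock, and PE from one trace
    exactly dependent; convolution with event-specific supports can mask
    that dependence in the TR-resolution columns.
    """
    cols = [c for c in dm.columns if np.ptp(dm.frame[c].to_numpy()) > 0]
    if len(cols) < 2:
        raise ValueError("need at least two non-constant columns")
    X = dm.frame[cols].to_numpy()
    corr = pd.DataFrame(np.corrcoef(X, rowvar=False), index=cols, columns=cols)

    vif = {}
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    R = np.corrcoef(Z, rowvar=False)
    Rinv = np.linalg.pinv(R)
    for j, c in enumerate(cols):
        vif[c] = float(Rinv[j, j])

    mod_cols = [c for c in dm.modulator_columns if c in cols]
    if dm.modulator_values is not None and mod_cols:
        M = dm.modulator_values[mod_cols].to_numpy()
        M = M - M.mean(axis=0)
    else:
        M = dm.frame[mod_cols].to_numpy()
    s = np.linalg.svd(M, compute_uv=False)
    rank = int(np.sum(s > rank_tol * s[0]))
    deficient = rank < len(mod_cols)
    condition = float(s[0] / s[-1]) if s[-1] > 0 else float("inf")

    flags = []
    if deficient:
        flags.append(
            f"modulator block rank {rank} < {len(mod_cols)}: exact linear dependence "
            "(PE = shock - EV when all three come from one trace)"
        )
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(corr.iloc[i, j]) > 0.999:
                flags.append(f"columns {cols[i]!r} and {cols[j]!r} nearly identical")
    return CollinearityReport(
        correlations=corr, vif=pd.Series(vif), modulator_rank=rank,
        n_modulators=len(mod_cols), rank_deficient=deficient,
        condition_number=condition, flags=flags,
    )
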