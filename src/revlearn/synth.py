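"""Synthetic SCR cohorts with the statistical structure the analysis assumes.

Trial-level skin-conductance amplitudes are generated as a linear
function of the subject's model-derived expected value, plus a
per-subject intercept, a linear habituation drift, and Gaussian trial
noise, floored at zero::

    amp_n = max(0, intercept + slope * V_n(x_n) + habituation * n + eps_n)

US trials additionally receive a US-evoked amplitude (truncated normal).
A mixture fraction of "non-learner" subjects has near-zero EV slope,
mirroring participants whose SCR carries no contingency signal.
Instructed-group subjects follow the instructed EV trace, uninstructed
the feedback trace.

An optional waveform renderer turns trial amplitudes into a 200-Hz
conductance series (canonical SCR impulse shape, jittered latency,
baseline drift, white noise) to exercise the scoring pipeline
end-to-end; the model-fitting path works on amplitudes directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import FEEDBACK, INSTRUCTED, ModelParams, simulate_ev_trace
from .task import TrialSequence

__all__ = [
    "GenParams",
    "WaveformParams",
    "SubjectAmplitudes",
    "SCRWaveform",
    "Cohort",
    "simulate_subject_amplitudes",
    "simulate_waveform",
    "simulate_cohort",
    "scr_impulse_kernel",
]


@dataclass(frozen=True)
class GenParams:
    """Generating parameters for a synthetic cohort (one group).

    Amplitude units are microsiemens. Defaults put the EV-driven
    differential on the order of the habituating, noisy background a
    real cohort shows; ``noise_sd`` defaults to half the mean EV slope
    (the moderate-noise regime used in recovery studies).
    """

    model: ModelParams = field(default_factory=lambda: ModelParams.instructed(0.061, 0.943))
    slope_mean: float = 0.5
    slope_sd: float = 0.15
    intercept_mean: float = 0.2
    intercept_sd: float = 0.08
    habituation_slope: float = -0.0015
    noise_sd: float = 0.25
    us_amp_mean: float = 0.8
    us_amp_sd: float = 0.2
    p_nonlearner: float = 0.35
    n_subjects: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("slope_sd", "intercept_sd", "noise_sd", "us_amp_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_nonlearner <= 1.0:
            raise ValueError("p_nonlearner must lie in [0, 1]")

    @property
    def group(self) -> str:
        return INSTRUCTED if self.model.variant == INSTRUCTED else "uninstructed"


@dataclass(frozen=True)
class WaveformParams:
    """Rendering parameters for raw conductance series."""

    rate_hz: float = 200.0
    rise_tau: float = 0.75
    decay_tau: float = 2.0
    latency_range: tuple[float, float] = (0.5, 4.5)
    baseline: float = 2.0
    drift_amp: float = 0.0
    drift_period: float = 120.0
    noise_sd: float = 0.0
    support_fraction: float = 0.01  # kernel truncated where it falls below this fraction of peak


@dataclass
class SubjectAmplitudes:
    """One subject's trial-level amplitudes plus generating truth."""

    subject_id: str
    group: str
    order: int
    table: pd.DataFrame  # trial, amplitude_uS, us_amplitude_uS
    truth: dict

    @property
    def amplitudes(self) -> np.ndarray:
        return self.table["amplitude_uS"].to_numpy()

    @property
    def us_amplitudes(self) -> np.ndarray:
        return self.table["us_amplitude_uS"].to_numpy()

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False)


@dataclass
class SCRWaveform:
    """Sampled conductance series with ground-truth responses."""

    samples: np.ndarray
    rate_hz: float
    truth: pd.DataFrame  # trial, event ('cs'|'us'), onset_s, latency_s, amplitude_uS

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate_hz


@dataclass
class Cohort:
    """A simulated group of subjects sharing the two canonical trial orders."""

    subjects: list[SubjectAmplitudes]
    sequences: list[TrialSequence]
    gen: GenParams

    def __len__(self) -> int:
        return len(self.subjects)

    def sequence_for(self, subject: SubjectAmplitudes) -> TrialSequence:
        return self.sequences[subject.order]

    def manifest(self) -> dict:
        return {
            "group": self.gen.group,
            "n_subjects": len(self.subjects),
            "generating": {
                "alpha": self.gen.model.alpha,
                "rho": self.gen.model.rho,
                "variant": self.gen.model.variant,
                "slope_mean": self.gen.slope_mean,
                "noise_sd": self.gen.noise_sd,
                "p_nonlearner": self.gen.p_nonlearner,
                "seed": self.gen.seed,
            },
            "subjects": [s.truth | {"subject_id": s.subject_id, "order": s.order}
                         for s in self.subjects],
        }


def simulate_subject_amplitudes(seq: TrialSequence, gen: GenParams,
                                subject_seed: int) -> SubjectAmplitudes:
    """Draw one subject's trial-level SCR amplitudes."""
    rng = np.random.default_rng(subject_seed)
    trace = simulate_ev_trace(seq, gen.model)
    if len(trace.table) != seq.n_trials:
        raise ValueError("EV trace length does not match sequence")

    nonlearner = bool(rng.random() < gen.p_nonlearner)
    if nonlearner:
        slope = rng.normal(0.0, 0.1 * max(gen.slope_mean, 1e-12))
    else:
        slope = rng.normal(gen.slope_mean, gen.slope_sd)
    intercept = rng.normal(gen.intercept_mean, gen.intercept_sd)

    n = np.arange(1, seq.n_trials + 1)
    eps = rng.normal(0.0, gen.noise_sd, size=seq.n_trials)
    amp = intercept + slope * trace.v_presented + gen.habituation_slope * n + eps
    amp = np.maximum(amp, 0.0)

    us = seq.events["us"].to_numpy().astype(bool)
    us_amp = np.zeros(seq.n_trials)
    us_amp[us] = np.maximum(rng.normal(gen.us_amp_mean, gen.us_amp_sd, size=int(us.sum())), 0.0)

    table = pd.DataFrame({
        "trial": seq.events["trial"].to_numpy(),
        "amplitude_uS": amp,
        "us_amplitude_uS": us_amp,
    })
    truth = {
        "slope": float(slope),
        "intercept": float(intercept),
        "nonlearner": nonlearner,
        "alpha": gen.model.alpha,
        "rho": gen.model.rho,
        "subject_seed": int(subject_seed),
    }
    return SubjectAmplitudes(subject_id=f"{gen.group}-{subject_seed}", group=gen.group,
                             order=0, table=table, truth=truth)


def scr_impulse_kernel(wf: WaveformParams) -> np.ndarray:
    """Unit-peak canonical SCR impulse: exponential rise times exponential decay."""
    dt = 1.0 / wf.rate_hz
    t_max = -wf.decay_tau * np.log(wf.support_fraction) + 5 * wf.rise_tau
    t = np.arange(0.0, t_max, dt)
    g = (1.0 - np.exp(-t / wf.rise_tau)) * np.exp(-t / wf.decay_tau)
    g /= g.max()
    last = np.flatnonzero(g >= wf.support_fraction)[-1]
    return g[: last + 1]


def simulate_waveform(amps: SubjectAmplitudes, seq: TrialSequence,
                      wf: WaveformParams | None = None, seed: int = 0) -> SCRWaveform:
    """Render trial amplitudes as a raw conductance waveform.

    Each nonzero CS amplitude becomes one canonical impulse starting at a
    jittered latency after cue onset; US-evoked responses start after the
    US (cue offset). Ground truth (event, latency, amplitude) is stored
    for round-trip tests.
    """
    wf = wf or WaveformParams()
    if len(amps.table) != seq.n_trials:
        raise ValueError("amplitude table length does not match sequence")
    rng = np.random.default_rng(seed)
    kernel = scr_impulse_kernel(wf)
    support_s = kernel.size / wf.rate_hz
    onsets = seq.events["onset_s"].to_numpy()
    spacing = np.diff(onsets).min() if onsets.size > 1 else np.inf
    if spacing < support_s:
        raise ValueError(
            f"trial spacing {spacing:.1f}s shorter than impulse support {support_s:.1f}s"
        )

    duration = onsets[-1] + seq.config.stim_duration + seq.config.isi + support_s + 10.0
    n_samples = int(np.ceil(duration * wf.rate_hz))
    t = np.arange(n_samples) / wf.rate_hz
    y = np.full(n_samples, wf.baseline)
    if wf.drift_amp:
        y = y + wf.drift_amp * np.sin(2 * np.pi * t / wf.drift_period)
    if wf.noise_sd:
        y = y + rng.normal(0.0, wf.noise_sd, size=n_samples)

    lat_lo, lat_hi = wf.latency_range
    truth_rows = []
    events = []
    for row, a, ua in zip(seq.events.itertuples(index=False),
                          amps.amplitudes, amps.us_amplitudes):
        events.append((int(row.trial), "cs", float(row.onset_s), a))
        if row.us:
            events.append((int(row.trial), "us",
                           float(row.onset_s) + seq.config.stim_duration, ua))
    for trial, kind, onset, a in events:
        if a <= 0:
            continue
        latency = rng.uniform(lat_lo, lat_hi)
        start = int(round((onset + latency) * wf.rate_hz))
        stop = min(start + kernel.size, n_samples)
        y[start:stop] += a * kernel[: stop - start]
        truth_rows.append((trial, kind, onset, latency, a))

    truth = pd.DataFrame(truth_rows,
                         columns=["trial", "event", "onset_s", "latency_s", "amplitude_uS"])
    return SCRWaveform(samples=y, rate_hz=wf.rate_hz, truth=truth)


def simulate_cohort(sequences: list[TrialSequence] | TrialSequence,
                    gen: GenParams) -> Cohort:
    """Simulate ``gen.n_subjects`` subjects alternating over the trial orders.

    Fully reproducible from ``gen.seed``: subject seeds are spawned from
    a :class:`numpy.random.SeedSequence` rooted at it.
    """
    if isinstance(sequences, TrialSequence):
        sequences = [sequences]
    if gen.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    root = np.random.SeedSequence(gen.seed)
    seeds = root.generate_state(gen.n_subjects)
    subjects = []
    for i in range(gen.n_subjects):
        order = i % len(sequences)
        subj = simulate_subject_amplitudes(sequences[order], gen, int(seeds[i] % (2**31 - 1)))
        subj.order = order
        subj.subject_id = f"{gen.group}-{i:03d}"
        subjects.append(subj)
    return Cohort(subjects=subjects, sequences=list(sequences), gen=gen)
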