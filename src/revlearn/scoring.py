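"""Trial-level skin-conductance preprocessing and scoring.

Waveforms (200 Hz) are low-pass FIR filtered at 25 Hz and smoothed with
a 10-sample Gaussian kernel, both zero-phase. Each trial is scored as
the base-to-peak amplitude of the first response whose onset (a local
minimum followed by a sustained rise) falls 0.5-4.5 s after cue onset;
US trials are scored relative to the US presentation. Deflections below
0.02 uS count as non-responses (score 0). Raw scores are square-root
transformed and normalized by the subject's mean transformed US
response. A subject is a "learner" if their mean normalized response to
unreinforced CS+ trials exceeds the CS- mean in the second half of the
first block (no significance test; ties resolve to non-learner).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .task import CS_MINUS, CS_PLUS, CUES, TrialSequence

__all__ = [
    "SubjectSCR",
    "SCRScorer",
    "preprocess_waveform",
    "score_trial",
    "transform_normalize",
    "classify_learner",
]


@dataclass
class SubjectSCR:
    """Per-trial raw, sqrt-transformed, and US-normalized amplitudes."""

    table: pd.DataFrame  # trial, raw_uS, sqrt, normalized, is_us
    learner: bool | None = None

    @property
    def normalized(self) -> np.ndarray:
        return self.table["normalized"].to_numpy()

    @property
    def raw(self) -> np.ndarray:
        return self.table["raw_uS"].to_numpy()

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False)


def preprocess_waveform(samples: np.ndarray, rate_hz: float = 200.0,
                        cutoff_hz: float = 25.0, fir_order: int = 64,
                        smooth_samples: int = 10) -> np.ndarray:
    """Zero-phase 25-Hz low-pass FIR filter plus Gaussian smoothing.

    The FIR is a windowed-sinc (Hamming) of the given order applied
    forward-backward; smoothing convolves a unit-sum Gaussian window of
    ``smooth_samples`` points centered on each sample. Output length
    equals input length and DC gain is exactly one.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1:
        raise ValueError("expected a 1-D uniformly sampled waveform")
    if not np.all(np.isfinite(samples)):
        raise ValueError("waveform contains non-finite samples")
    taps = signal.firwin(fir_order + 1, cutoff_hz, fs=rate_hz, window="hamming")
    filtered = signal.filtfilt(taps, [1.0], samples)
    win = signal.windows.gaussian(smooth_samples, std=smooth_samples / 4.0)
    win /= win.sum()
    # forward-backward application: exactly zero-phase even though the
    # kernel has an even number of samples
    return signal.filtfilt(win, [1.0], filtered)


def _response_onsets(deriv: np.ndarray, rate_hz: float, slope_threshold: float,
                     sustain_s: float) -> np.ndarray:
    """Indices where a rise >= slope_threshold uS/s is sustained >= sustain_s."""
    rising = deriv >= slope_threshold
    need = max(int(round(sustain_s * rate_hz)), 1)
    # run-length encode the rising mask
    change = np.flatnonzero(np.diff(rising.astype(int)))
    starts = np.r_[0, change + 1]
    ends = np.r_[change, rising.size - 1]
    onsets = [s for s, e in zip(starts, ends) if rising[s] and e - s + 1 >= need]
    return np.asarray(onsets, dtype=int)


def score_trial(samples: np.ndarray, onset_s: float, rate_hz: float = 200.0,
                window: tuple[float, float] = (0.5, 4.5), floor_uS: float = 0.02,
                slope_threshold: float = 0.01, sustain_s: float = 0.25) -> float:
    """Base-to-peak amplitude of the first response in the latency window.

    A response onset is a local minimum followed by a monotone rise of at
    least ``slope_threshold`` uS/s sustained for ``sustain_s``; the peak
    is the next local maximum. Returns 0 when no onset falls within
    ``[onset_s + window[0], onset_s + window[1]]`` or the deflection is
    below ``floor_uS``.
    """
    samples = np.asarray(samples, dtype=float)
    lo = onset_s + window[0]
    hi = onset_s + window[1]
    if lo < 0 or hi * rate_hz > samples.size - 1:
        raise ValueError("scoring window exceeds the recording")
    deriv = np.gradient(samples) * rate_hz
    onsets = _response_onsets(deriv, rate_hz, slope_threshold, sustain_s)
    lo_i, hi_i = int(np.ceil(lo * rate_hz)), int(np.floor(hi * rate_hz))
    onsets = onsets[(onsets >= lo_i) & (onsets <= hi_i)]
    if onsets.size == 0:
        return 0.0
    start = int(onsets[0])
    base = samples[start]
    # peak: next local maximum (first derivative sign change after the rise)
    after = np.flatnonzero(deriv[start + 1:] < 0)
    peak_i = start + 1 + int(after[0]) if after.size else samples.size - 1
    amp = float(samples[peak_i] - base)
    return amp if amp >= floor_uS else 0.0


def transform_normalize(scores: np.ndarray, us_mask: np.ndarray) -> SubjectSCR:
    """Square-root transform and normalize by the mean transformed US response.

    Raises when no US trial carries a positive response (the subject is
    unanalyzable, mirroring signal-loss exclusion).
    """
    scores = np.asarray(scores, dtype=float)
    us_mask = np.asarray(us_mask, dtype=bool)
    if scores.shape != us_mask.shape:
        raise ValueError("scores and us_mask must have equal length")
    if np.any(scores < 0):
        raise ValueError("raw amplitudes must be non-negative")
    transformed = np.sqrt(scores)
    us_mean = transformed[us_mask].mean() if us_mask.any() else 0.0
    if us_mean <= 0:
        raise ValueError("mean US response is zero; subject cannot be normalized")
    table = pd.DataFrame({
        "trial": np.arange(1, scores.size + 1),
        "raw_uS": scores,
        "sqrt": transformed,
        "normalized": transformed / us_mean,
        "is_us": us_mask.astype(int),
    })
    return SubjectSCR(table=table)


def classify_learner(subject: SubjectSCR, seq: TrialSequence) -> bool:
    """Greater mean normalized SCR to unreinforced CS+ than CS- in late acquisition.

    Late acquisition is the second half of block 1. Strict inequality:
    ties classify as non-learner.
    """
    config = seq.config
    half = config.trials_per_block // 2
    ev = seq.events
    window = ev[(ev["block"] == 1) & (ev["trial"] > half) & (ev["us"] == 0)]
    scores = subject.table.set_index("trial")["normalized"]
    means = {}
    for role in (CS_PLUS, CS_MINUS):
        trials = window.loc[window["role"] == role, "trial"]
        if trials.empty:
            raise ValueError(f"no unreinforced {role} trials in late acquisition")
        means[role] = float(scores.loc[trials].mean())
    return means[CS_PLUS] > means[CS_MINUS]


class SCRScorer:
    """Configured waveform-to-scores transformer.

    Bundles preprocessing, trial scoring, the sqrt/US-normalization, and
    learner classification with a single parameter set; ``score_events``
    maps a raw waveform plus its trial sequence to a :class:`SubjectSCR`.
    """

    def __init__(self, rate_hz: float = 200.0, cutoff_hz: float = 25.0,
                 fir_order: int = 64, smooth_samples: int = 10,
                 window: tuple[float, float] = (0.5, 4.5), floor_uS: float = 0.02,
                 slope_threshold: float = 0.01, sustain_s: float = 0.25,
                 preprocess: bool = True):
        self.rate_hz = rate_hz
        self.cutoff_hz = cutoff_hz
        self.fir_order = fir_order
        self.smooth_samples = smooth_samples
        self.window = window
        self.floor_uS = floor_uS
        self.slope_threshold = slope_threshold
        self.sustain_s = sustain_s
        self.preprocess = preprocess

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "rate_hz", "cutoff_hz", "fir_order", "smooth_samples", "window",
            "floor_uS", "slope_threshold", "sustain_s", "preprocess")}

    def set_params(self, **params) -> "SCRScorer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def score_events(self, samples: np.ndarray, seq: TrialSequence,
                     classify: bool = True) -> SubjectSCR:
        y = preprocess_waveform(samples, self.rate_hz, self.cutoff_hz,
                                self.fir_order, self.smooth_samples) \
            if self.preprocess else np.asarray(samples, dtype=float)
        scores = np.empty(seq.n_trials)
        us_mask = seq.events["us"].to_numpy().astype(bool)
        for i, row in enumerate(seq.events.itertuples(index=False)):
            onset = float(row.onset_s)
            if row.us:  # US trials scored relative to the US presentation
                onset += seq.config.stim_duration
            scores[i] = score_trial(y, onset, self.rate_hz, self.window,
                                    self.floor_uS, self.slope_threshold, self.sustain_s)
        subject = transform_normalize(scores, us_mask)
        if classify:
            subject.learner = classify_learner(subject, seq)
        return subject
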