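"""Raw-trial conditioning: band-pass + notch filtering, IEMG onset
detection, active-segment extraction, and analysis windowing.

The onset detector slides a 256-ms window over the filtered trial, computes
the integrated EMG (mean rectified amplitude) per channel, and declares the
muscles active at the first window whose across-channel maximum IEMG exceeds
a threshold; the following ``active_duration`` seconds are the segment fed
to feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .synth import N_CHANNELS, Trial


class NoActivationError(ValueError):
    """No analysis window exceeded the activation threshold."""


class SegmentOverrunError(ValueError):
    """The requested active segment does not fit inside the trial."""


@dataclass(frozen=True)
class FilterSpec:
    bandpass_low: float = 10.0
    bandpass_high: float = 400.0
    order: int = 4
    zero_phase: bool = True
    notch_freq: float = 50.0
    notch_q: float = 30.0

    def __post_init__(self):
        if not 0 < self.bandpass_low < self.bandpass_high:
            raise ValueError("band edges must satisfy 0 < low < high")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass
class ActiveSegment:
    """The activation portion of one trial (6 channels x active samples)."""

    trial_id: str
    gesture: str
    onset_index: int
    signal: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != N_CHANNELS:
            raise ValueError("segment must be 6 x n_samples")
        if self.onset_index < 0:
            raise ValueError("onset_index must be >= 0")


def bandpass_and_notch(trial: Trial, spec: FilterSpec = FilterSpec()) -> Trial:
    """Butterworth band-pass plus mains notch, zero-phase by default.

    Zero phase is realized by forward-backward filtering, which doubles the
    effective order; the stated order is that of the underlying one-pass
    filter.
    """
    fs = trial.sampling_rate
    if spec.bandpass_high >= fs / 2:
        raise ValueError(
            f"bandpass high edge {spec.bandpass_high} Hz is not below the "
            f"Nyquist frequency {fs / 2} Hz")
    if trial.n_samples <= 3 * spec.order:
        raise ValueError("trial too short for the requested filter order")

    sos = sps.butter(spec.order, (spec.bandpass_low, spec.bandpass_high),
                     btype="bandpass", fs=fs, output="sos")
    b, a = sps.iirnotch(spec.notch_freq, spec.notch_q, fs=fs)
    if spec.zero_phase:
        y = sps.sosfiltfilt(sos, trial.signal, axis=1)
        y = sps.filtfilt(b, a, y, axis=1)
    else:
        y = sps.sosfilt(sos, trial.signal, axis=1)
        y = sps.lfilter(b, a, y, axis=1)
    return Trial(trial.trial_id, trial.gesture, y, fs)


def iemg(window: np.ndarray) -> float:
    """Integrated EMG of a window: mean of the rectified samples.

    The textbook 'average IEMG' of a zero-mean signal would vanish; the
    rectified mean is the form that carries amplitude information and is the
    one used for onset detection here.
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("iemg of an empty window is undefined")
    return float(np.mean(np.abs(window)))


def _window_starts(n: int, window: int, step: int) -> np.ndarray:
    if window > n:
        raise ValueError(f"window ({window} samples) longer than signal ({n})")
    return np.arange(0, n - window + 1, step)


def default_onset_threshold(
    trials: Sequence[Trial],
    rest_duration_s: float,
    window_ms: float = 256.0,
    n_sd: float = 3.0,
) -> float:
    """Dataset-level activation threshold from the rest bookends.

    Computes the across-channel maximum windowed IEMG over every window that
    fits in the first ``rest_duration_s`` seconds of each (filtered) trial
    and returns mean + ``n_sd`` standard deviations of those values.
    """
    values = []
    for trial in trials:
        fs = trial.sampling_rate
        w = int(round(window_ms * fs / 1000.0))
        n_rest = int(round(rest_duration_s * fs))
        if n_rest < w:
            raise ValueError("rest bookend shorter than one analysis window")
        for s in _window_starts(n_rest, w, w):
            seg = trial.signal[:, s:s + w]
            values.append(max(iemg(seg[c]) for c in range(N_CHANNELS)))
    values = np.asarray(values)
    return float(values.mean() + n_sd * values.std())


def detect_onset(
    trial: Trial,
    threshold: float,
    window_ms: float = 256.0,
    overlap_ms: float = 50.0,
    segment_duration_s: float = 4.0,
) -> int:
    """First window start where any channel's windowed IEMG exceeds threshold.

    Raises :class:`NoActivationError` if no window exceeds the threshold and
    :class:`SegmentOverrunError` if the detected onset leaves less than
    ``segment_duration_s`` seconds of signal.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    fs = trial.sampling_rate
    w = int(round(window_ms * fs / 1000.0))
    step = w - int(round(overlap_ms * fs / 1000.0))
    if step <= 0:
        raise ValueError("window must be longer than overlap")
    onset = None
    for s in _window_starts(trial.n_samples, w, step):
        seg = trial.signal[:, s:s + w]
        if max(iemg(seg[c]) for c in range(N_CHANNELS)) > threshold:
            onset = int(s)
            break
    if onset is None:
        raise NoActivationError(
            f"trial {trial.trial_id}: no {window_ms:.0f}-ms window exceeded "
            f"IEMG threshold {threshold:g}")
    n_seg = int(round(segment_duration_s * fs))
    if onset + n_seg > trial.n_samples:
        raise SegmentOverrunError(
            f"trial {trial.trial_id}: onset {onset} + {segment_duration_s}-s "
            f"segment overruns trial of {trial.n_samples} samples")
    return onset


def extract_active(trial: Trial, onset: int,
                   duration_s: float = 4.0) -> ActiveSegment:
    """Slice the active segment [onset, onset + duration) from a trial."""
    fs = trial.sampling_rate
    n_seg = int(round(duration_s * fs))
    if onset < 0:
        raise ValueError("onset must be >= 0")
    if onset + n_seg > trial.n_samples:
        raise SegmentOverrunError(
            f"segment [{onset}, {onset + n_seg}) overruns trial of "
            f"{trial.n_samples} samples")
    return ActiveSegment(trial.trial_id, trial.gesture, onset,
                         trial.signal[:, onset:onset + n_seg].copy(), fs)


def sliding_windows(
    x: np.ndarray,
    window_ms: float,
    overlap_ms: float,
    sampling_rate: float,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Overlapping analysis windows over the last axis of ``x``.

    Returns ``(starts, windows)``; consecutive starts are
    ``window - overlap`` apart and any incomplete trailing window is
    dropped.
    """
    x = np.asarray(x)
    w = int(round(window_ms * sampling_rate / 1000.0))
    step = w - int(round(overlap_ms * sampling_rate / 1000.0))
    if step <= 0:
        raise ValueError("window must be longer than overlap (zero step)")
    starts = _window_starts(x.shape[-1], w, step)
    windows = [x[..., s:s + w] for s in starts]
    return starts, windows
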