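"""Time-domain features on intrinsic mode functions and feature assembly.

Per channel, the zero-crossing count (ZC) and Wilson amplitude (WAMP) of the
first K selected IMFs form an interleaved vector (ZC1, WAMP1, ..., ZCK,
WAMPK); concatenating the six channel blocks yields the per-trial feature
vector (48 entries for K=4).

WAMP is computed in the waveform-length form, i.e. the sum of absolute
successive differences over the feature window; an optional threshold
suppresses differences at or below it (0 keeps every difference, the default
and the form used throughout the pipeline). IMF selection keeps the shortest
prefix of modes whose pooled energy fraction reaches a contribution
threshold, or a fixed K when configured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .emd import IMFDecomposition
from .synth import N_CHANNELS

FIXED_K_DEFAULT = 4
FEATURE_WINDOW_DEFAULT = 2000


@dataclass(frozen=True)
class ChannelFeatures:
    """Interleaved (ZC, WAMP) features of one channel's selected IMFs."""

    channel_index: int
    values: tuple[float, ...]

    def __post_init__(self):
        if not 1 <= self.channel_index <= N_CHANNELS:
            raise ValueError("channel_index must be in 1..6")
        if len(self.values) % 2 != 0:
            raise ValueError("values must interleave (ZC, WAMP) pairs")
        if any(v < 0 for v in self.values):
            raise ValueError("ZC and WAMP are non-negative")


@dataclass(frozen=True)
class TrialFeatures:
    trial_id: str
    gesture: str
    vector: tuple[float, ...]


def zero_crossings(x: np.ndarray, deadband: float = 0.0) -> int:
    """Count sign changes between adjacent samples.

    A pair counts only when the two samples have opposite signs and both
    magnitudes exceed ``deadband`` (a noise-floor guard; 0 counts every
    strict sign change).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    a, b = x[:-1], x[1:]
    return int(np.count_nonzero(
        (a * b < 0) & (np.abs(a) > deadband) & (np.abs(b) > deadband)))


def wamp(x: np.ndarray, threshold: float = 0.0) -> float:
    """Wilson amplitude in waveform-length form: sum of |x_k - x_{k-1}|.

    With ``threshold > 0`` only differences strictly above the threshold
    contribute (still summed, not counted).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    d = np.abs(np.diff(x))
    if threshold > 0:
        d = d[d > threshold]
    return float(d.sum())


def willison_amplitude_count(x: np.ndarray, threshold: float) -> int:
    """Classical thresholded Wilson amplitude: count of |diff| > threshold."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return int(np.count_nonzero(np.abs(np.diff(x)) > threshold))


def select_imfs(
    decompositions: Iterable[IMFDecomposition],
    contribution_threshold: float = 0.90,
    fixed_k: int | None = None,
) -> list[int]:
    """IMF indices (1-based) to keep, by pooled energy contribution.

    Returns the shortest prefix 1..K whose cumulative energy fraction,
    pooled over all decompositions, reaches ``contribution_threshold``;
    ``fixed_k`` overrides the energy rule with a fixed prefix length.
    """
    if fixed_k is not None:
        if fixed_k < 1:
            raise ValueError("fixed_k must be >= 1")
        return list(range(1, fixed_k + 1))
    decomps = list(decompositions)
    if not decomps:
        raise ValueError("need at least one decomposition")
    max_k = max(d.n_imfs for d in decomps)
    if max_k == 0:
        raise ValueError("decompositions contain no IMFs")
    energy = np.zeros(max_k)
    for d in decomps:
        for k, imf in enumerate(d.imfs):
            energy[k] += float(np.sum(imf ** 2))
    total = energy.sum()
    if total <= 0:
        return [1]
    cum = np.cumsum(energy) / total
    k = int(np.searchsorted(cum, contribution_threshold) + 1)
    return list(range(1, min(k, max_k) + 1))


def build_channel_feature(
    decomp: IMFDecomposition,
    selected: Sequence[int],
    feature_window_samples: int = FEATURE_WINDOW_DEFAULT,
    deadband: float = 0.0,
    offset: int = 0,
    channel_index: int = 1,
    wamp_threshold: float = 0.0,
) -> ChannelFeatures:
    """ZC and WAMP of each selected IMF over the feature window.

    The window is ``[offset, offset + feature_window_samples)`` of each IMF.
    Selected indices beyond the decomposition's ``n_imfs`` contribute zeros
    for both features (padding for signals that supported fewer modes).
    """
    if any(k <= 0 for k in selected):
        raise ValueError("selected IMF indices are 1-based and positive")
    if decomp.n_imfs > 0:
        n = decomp.imfs[0].size
        if offset < 0 or offset + feature_window_samples > n:
            raise ValueError(
                f"feature window [{offset}, {offset + feature_window_samples}) "
                f"exceeds IMF length {n}")
    values: list[float] = []
    for k in selected:
        if k <= decomp.n_imfs:
            seg = decomp.imfs[k - 1][offset:offset + feature_window_samples]
            values.append(float(zero_crossings(seg, deadband)))
            values.append(wamp(seg, wamp_threshold))
        else:
            values.extend((0.0, 0.0))
    return ChannelFeatures(channel_index=channel_index, values=tuple(values))


def build_trial_feature(
    per_channel: Sequence[ChannelFeatures],
    trial_id: str,
    gesture: str,
) -> TrialFeatures:
    """Concatenate the six channel blocks in channel order."""
    if len(per_channel) != N_CHANNELS:
        raise ValueError(
            f"need exactly {N_CHANNELS} channel blocks, got {len(per_channel)}")
    indices = sorted(cf.channel_index for cf in per_channel)
    if indices != list(range(1, N_CHANNELS + 1)):
        raise ValueError(f"channel indices must be 1..{N_CHANNELS} exactly "
                         f"once, got {indices}")
    ordered = sorted(per_channel, key=lambda cf: cf.channel_index)
    vector: tuple[float, ...] = ()
    for cf in ordered:
        vector += cf.values
    return TrialFeatures(trial_id=trial_id, gesture=gesture, vector=vector)


def feature_frame(trial_features: Sequence[TrialFeatures]) -> pd.DataFrame:
    """Labeled feature table: columns trial_id, gesture, f01..fNN."""
    if not trial_features:
        raise ValueError("no trial features")
    width = len(trial_features[0].vector)
    cols = [f"f{i + 1:02d}" for i in range(width)]
    rows = []
    for tf in trial_features:
        if len(tf.vector) != width:
            raise ValueError("inconsistent feature vector lengths")
        rows.append({"trial_id": tf.trial_id, "gesture": tf.gesture,
                     **dict(zip(cols, tf.vector))})
    return pd.DataFrame(rows, columns=["trial_id", "gesture", *cols])


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
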