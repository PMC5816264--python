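"""Empirical mode decomposition (EMD).

Decomposes a signal into intrinsic mode functions (IMFs) — oscillatory
components whose numbers of extrema and zero crossings differ by at most
one — plus a residual trend, by iterative sifting: at each step the mean of
the upper and lower cubic-spline envelopes through the local extrema is
subtracted. Sifting stops on a Cauchy-type criterion
``SD = sum((h_prev - h_cur)^2) / sum(h_prev^2) < stop_sd`` (canonical
default 0.2) combined with the IMF extrema/zero-crossing condition;
decomposition stops when the remainder is monotone, has too few extrema, or
``max_imfs`` components have been extracted.

Envelope boundary swing is controlled by mirroring the two extrema nearest
each edge across the signal endpoints before fitting natural cubic splines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

DEFAULT_STOP_SD = 0.2
DEFAULT_MAX_IMFS = 8
DEFAULT_MAX_SIFT_ITERS = 50


class SiftTermination(Exception):
    """Raised when a signal has too few extrema to be sifted further."""


@dataclass
class IMFDecomposition:
    """Ordered IMFs plus residual for one channel signal."""

    imfs: list[np.ndarray]
    residual: np.ndarray

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima; plateaus yield their midpoint."""
    x = np.asarray(x, dtype=float)
    dx = np.diff(x)
    nz = np.flatnonzero(dx)
    if nz.size < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    s = np.sign(dx[nz])
    chg = np.flatnonzero(s[1:] != s[:-1])
    if chg.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    left = nz[chg] + 1          # first sample of the (possibly flat) extremum
    right = nz[chg + 1]         # last sample of it
    mid = (left + right) // 2
    is_max = s[chg] > 0
    return mid[is_max], mid[~is_max]


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Natural cubic spline through extrema, with edge mirroring."""
    n = x.size
    t = idx.astype(int)
    v = x[t]
    # mirror up to two interior extrema across each endpoint
    lm = t[t > 0][:2]
    rm = t[t < n - 1][-2:]
    knots_t = np.concatenate([-lm[::-1], t, 2 * (n - 1) - rm[::-1]])
    knots_v = np.concatenate([x[lm][::-1], v, x[rm][::-1]])
    knots_t, keep = np.unique(knots_t, return_index=True)
    knots_v = knots_v[keep]
    spline = CubicSpline(knots_t, knots_v, bc_type="natural")
    return spline(np.arange(n))


def sift_once(signal: np.ndarray) -> np.ndarray:
    """One sifting step: subtract the mean of the two extremal envelopes.

    Raises :class:`SiftTermination` when the signal has fewer than two maxima
    or two minima (nothing left to sift).
    """
    x = np.asarray(signal, dtype=float)
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise SiftTermination(
            f"too few extrema to sift ({maxima.size} maxima, "
            f"{minima.size} minima)")
    upper = _envelope(x, maxima)
    lower = _envelope(x, minima)
    return x - 0.5 * (upper + lower)


def _count_zero_crossings(x: np.ndarray) -> int:
    return int(np.count_nonzero(x[1:] * x[:-1] < 0))


def _is_imf_like(x: np.ndarray) -> bool:
    maxima, minima = find_extrema(x)
    n_ext = maxima.size + minima.size
    return abs(n_ext - _count_zero_crossings(x)) <= 1


def extract_imf(
    signal: np.ndarray,
    stop_sd: float = DEFAULT_STOP_SD,
    max_sift_iters: int = DEFAULT_MAX_SIFT_ITERS,
) -> tuple[np.ndarray, np.ndarray]:
    """Sift one IMF out of ``signal``; returns ``(imf, remainder)``.

    ``imf + remainder == signal`` holds exactly by construction. Sifting
    stops when the Cauchy SD between successive iterates falls below
    ``stop_sd`` and the iterate satisfies the IMF extrema/zero-crossing
    condition, or after ``max_sift_iters`` iterations.
    """
    x = np.asarray(signal, dtype=float)
    h = x
    for _ in range(max_sift_iters):
        h_new = sift_once(h)
        denom = float(np.sum(h * h))
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < stop_sd and _is_imf_like(h):
            break
    return h, x - h


def _is_monotone(x: np.ndarray) -> bool:
    dx = np.diff(x)
    return bool(np.all(dx >= 0) or np.all(dx <= 0))


def emd(
    signal: np.ndarray,
    max_imfs: int = DEFAULT_MAX_IMFS,
    stop_sd: float = DEFAULT_STOP_SD,
    max_sift_iters: int = DEFAULT_MAX_SIFT_ITERS,
) -> IMFDecomposition:
    """Full empirical mode decomposition of a 1-D signal.

    Stops early when the remainder is monotone or has fewer than 3 extrema;
    the decomposition then holds fewer than ``max_imfs`` modes (recorded in
    ``n_imfs``) and the remainder becomes the residual.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D signal")
    if x.size < 10:
        raise ValueError("signal too short for EMD (need >= 10 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")

    imfs: list[np.ndarray] = []
    remainder = x.copy()
    while len(imfs) < max_imfs:
        maxima, minima = find_extrema(remainder)
        if maxima.size + minima.size < 3 or _is_monotone(remainder):
            break
        try:
            imf, remainder = extract_imf(remainder, stop_sd, max_sift_iters)
        except SiftTermination:
            break
        imfs.append(imf)
    return IMFDecomposition(imfs=imfs, residual=remainder)
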