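"""Independently coded EMD used only as a test oracle.

Deliberately written on different primitives from the library implementation
(scipy.signal.argrelextrema for extrema, make_interp_spline for envelopes,
an explicit while-loop sifting driver) so that agreement between the two is
a genuine cross-check of the algorithm, not of shared code. The algorithm
itself (natural-spline envelopes through mirrored extrema, Cauchy-SD
stopping) is the same documented procedure.
"""

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.signal import argrelextrema


def _oracle_envelope(x, idx, n):
    idx = np.asarray(idx)
    # mirror two extrema across each endpoint
    pre = idx[idx > 0][:2]
    post = idx[idx < n - 1][-2:]
    t = np.r_[-pre[::-1], idx, 2 * (n - 1) - post[::-1]]
    v = np.r_[x[pre][::-1], x[idx], x[post][::-1]]
    t, keep = np.unique(t, return_index=True)
    spline = make_interp_spline(t, v[keep], k=3, bc_type="natural")
    return spline(np.arange(n))


def oracle_emd(signal, max_imfs=8, stop_sd=0.2, max_iters=50):
    """Reference EMD; returns (list of IMFs, residual)."""
    x = np.asarray(signal, dtype=float)
    n = x.size
    imfs = []
    rem = x.copy()
    while len(imfs) < max_imfs:
        maxima = argrelextrema(rem, np.greater)[0]
        minima = argrelextrema(rem, np.less)[0]
        if maxima.size < 2 or minima.size < 2:
            break
        h = rem.copy()
        it = 0
        while True:
            hmax = argrelextrema(h, np.greater)[0]
            hmin = argrelextrema(h, np.less)[0]
            if hmax.size < 2 or hmin.size < 2:
                break
            mean_env = 0.5 * (_oracle_envelope(h, hmax, n)
                              + _oracle_envelope(h, hmin, n))
            h_new = h - mean_env
            num = float(np.sum((h - h_new) ** 2))
            den = float(np.sum(h ** 2))
            h = h_new
            it += 1
            n_ext = (argrelextrema(h, np.greater)[0].size
                     + argrelextrema(h, np.less)[0].size)
            n_zc = int(np.count_nonzero(h[1:] * h[:-1] < 0))
            if (den == 0 or num / den < stop_sd) and abs(n_ext - n_zc) <= 1:
                break
            if it >= max_iters:
                break
        imfs.append(h)
        rem = rem - h
    return imfs, rem
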