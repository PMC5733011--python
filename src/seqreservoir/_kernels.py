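"""Optional numba-compiled inner kernels for the plasticity event updates.

The engine falls back to the vectorized numpy implementation when numba is
unavailable; results are bit-identical because the kernels evaluate the same
expressions in the same order, merely skipping synapses that do not exist
(their masked bound is zero, so their update is identically zero).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap


@njit(cache=True, fastmath=False)
def plasticity_events(w_in, dev, fac, w0m, wmax_in_m, wmax_ee_m,
                      x_pre, x_fast, x_post, se,
                      eta_in, offset, mu, w_max_in,
                      eta1, eta2, w_max_ee):  # pragma: no cover - exercised via engine
    """Eq-1/Eq-2 event updates for one step's postsynaptic spikes ``se``.

    Operates on the lazy-decay representation of the recurrent weights
    (w_ee = w0m + dev * fac per column).  Column updates (both potentiation
    branches) run before row updates (depression), matching the dense
    reference path.
    """
    n_in = w_in.shape[0]
    n_e = dev.shape[0]
    for k in range(se.size):
        j = se[k]
        # input pathway: power-law STDP on the post spike
        for i in range(n_in):
            wm = wmax_in_m[i, j]
            if wm > 0.0:
                wv = w_in[i, j]
                wv += eta_in * (x_pre[i] - offset) * (wm - wv) ** mu
                if wv < 0.0:
                    wv = 0.0
                elif wv > w_max_in:
                    wv = w_max_in
                w_in[i, j] = wv
        # fold the pending heterosynaptic decay into this column
        f = fac[j]
        if f != 1.0:
            for i in range(n_e):
                dev[i, j] *= f
            fac[j] = 1.0
        # recurrent potentiation on the post spike
        a = eta2 * x_post[j]
        for i in range(n_e):
            wm = wmax_ee_m[i, j]
            if wm > 0.0:
                wv = w0m[i, j] + dev[i, j]
                wv += a * x_fast[i] * (wm - wv) ** mu
                if wv < 0.0:
                    wv = 0.0
                elif wv > w_max_ee:
                    wv = w_max_ee
                dev[i, j] = wv - w0m[i, j]
    for k in range(se.size):
        i = se[k]
        # recurrent depression on the pre spike
        for j in range(n_e):
            if wmax_ee_m[i, j] > 0.0:
                f = fac[j]
                wv = w0m[i, j] + dev[i, j] * f
                wv -= eta1 * x_post[j] * wv ** mu
                if wv < 0.0:
                    wv = 0.0
                elif wv > w_max_ee:
                    wv = w_max_ee
                dev[i, j] = (wv - w0m[i, j]) / f
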