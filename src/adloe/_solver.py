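"""Block coordinate-descent kernel for the multi-task elastic net.

The kernel works on precomputed Gram statistics so that a single update
sweep costs O(p^2 T) independent of sample size, which keeps the
resampling loop of the stability analysis tractable.  It is compiled with
numba when available and falls back to the identical pure-Python
implementation otherwise.
"""

from __future__ import annotations

import math

import numpy as np


def _bcd_sweeps(G, C, W, GW, cj, alpha, rho, tol, max_iter):
    """Cyclic block coordinate descent on the row-sparse elastic net.

    Minimises, over W (p rows, T tasks),

        (1/(2n)) ||Rc - X W||_F^2 + alpha*rho * sum_j ||W_j||_2
                                  + (alpha*(1-rho)/2) * ||W||_F^2

    given G = X^T X / n (p x p) and C = X^T Rc / n (p x T), assuming
    standardized columns so G_jj = 1.  GW = G @ W and the scratch row cj
    (length T) are updated in place.  Returns (sweeps used, converged 0/1),
    where convergence is max |coefficient change| in a sweep < tol.
    """
    p, T = W.shape
    thr = alpha * rho
    denom = 1.0 + alpha * (1.0 - rho)
    for it in range(max_iter):
        max_change = 0.0
        for j in range(p):
            nrm2 = 0.0
            for t in range(T):
                c = C[j, t] - GW[j, t] + G[j, j] * W[j, t]
                cj[t] = c
                nrm2 += c * c
            nrm = math.sqrt(nrm2)
            if nrm <= thr:
                scale = 0.0
            else:
                scale = (1.0 - thr / nrm) / denom
            for t in range(T):
                new = scale * cj[t]
                d = new - W[j, t]
                if d != 0.0:
                    W[j, t] = new
                    ad = abs(d)
                    if ad > max_change:
                        max_change = ad
                    for i in range(p):
                        GW[i, t] += G[i, j] * d
        if max_change < tol:
            return it + 1, 1
    return max_iter, 0


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    bcd_sweeps = njit(cache=True, nogil=True)(_bcd_sweeps)
except ImportError:  # pragma: no cover
    bcd_sweeps = _bcd_sweeps


def solve_mt_enet(G, C, alpha, rho, tol=1e-6, max_iter=10_000, W0=None):
    """Solve the Gram-form multi-task elastic net.

    Parameters are as in :func:`_bcd_sweeps`; ``W0`` is an optional warm
    start (copied, not modified).  Returns (W, n_sweeps, converged).
    """
    p, T = C.shape
    if W0 is None:
        W = np.zeros((p, T))
    else:
        W = np.array(W0, dtype=float, copy=True)
    GW = G @ W
    cj = np.empty(T)
    n_it, conv = bcd_sweeps(G, C, W, GW, cj, float(alpha), float(rho),
                            float(tol), int(max_iter))
    return W, int(n_it), bool(conv)
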