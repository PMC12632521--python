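"""Jit-compiled event loop for the two-lineage structured serial coalescent.

The state is (time, deme of lineage 1, deme of lineage 2, epoch index).
Within an epoch all rates are constant, so the next event is exponential
with the current total rate; a draw that overshoots the epoch boundary is
discarded and the clock advanced to the boundary with rates refreshed
(exact for piecewise-constant intensities).
"""

import numpy as np
from numba import njit


@njit(inline="always")
def _pick(cumrow, u, d):
    for k in range(d):
        if u < cumrow[k]:
            return k
    return d - 1


@njit(cache=False)
def _simulate_batch(n, i0, x, j0, y, t_ends, tot_m, cum_m, gamma, seed):
    """Draw n pairwise branch lengths for samples (deme i0, time x) and
    (deme j0, time y), x <= y.  Returns B = 2 T_coal - x - y per replicate."""
    np.random.seed(seed)
    out = np.empty(n)
    n_ep = t_ends.shape[0]
    d = tot_m.shape[1]
    for s in range(n):
        t = x
        c1 = i0
        e = 0
        while t >= t_ends[e]:
            e += 1
        # phase 1: only the younger lineage exists and migrates, until y
        while t < y:
            stop = t_ends[e] if t_ends[e] < y else y
            rate = tot_m[e, c1]
            if rate <= 0.0:
                t = stop
            else:
                dt = -np.log(np.random.random()) / rate
                if t + dt >= stop:
                    t = stop
                else:
                    t = t + dt
                    u = np.random.random() * rate
                    c1 = _pick(cum_m[e, c1], u, d)
                    continue
            if t >= t_ends[e]:
                e += 1
        # phase 2: both lineages migrate; coalescence at rate gamma when co-located
        c2 = j0
        while True:
            r1 = tot_m[e, c1]
            r2 = tot_m[e, c2]
            g = gamma[e, c1] if c1 == c2 else 0.0
            rate = r1 + r2 + g
            if rate <= 0.0:
                if e == n_ep - 1:
                    out[s] = np.nan  # coalescence unreachable; caller validates
                    break
                t = t_ends[e]
                e += 1
                continue
            dt = -np.log(np.random.random()) / rate
            if t + dt >= t_ends[e]:
                t = t_ends[e]
                e += 1
                continue
            t = t + dt
            u = np.random.random() * rate
            if u < g:
                out[s] = 2.0 * t - x - y
                break
            u -= g
            if u < r1:
                c1 = _pick(cum_m[e, c1], u, d)
            else:
                c2 = _pick(cum_m[e, c2], u - r1, d)
    return out
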