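"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's matrix-exponential propagators: the
transport PDE for a contemporaneous pair is integrated by a first-order
upwind method-of-characteristics scheme, and the equilibrium operator is
re-assembled entry-by-entry from its defining equation.
"""

from __future__ import annotations

import numpy as np


def upwind_diagonal_oracle(
    f0: np.ndarray, db: float, L: np.ndarray, gamma: np.ndarray, tau: float
) -> np.ndarray:
    """Integrate the contemporaneous-pair density PDE backward over ``tau``.

    The density g(s, b) of pairwise branch length b after elapsed backward
    time s obeys a transport equation with advection speed 2 in b (each
    unit of backward time adds two units of branch) and source
    ``-(L g + g L^T + diag(gamma) diag{g})``, with inflow boundary
    ``g(s, 0) = diag(gamma) / 2`` (fresh coalescence).  Discretized with an
    upwind step at unit CFL (time step db/2), so transport is exact and the
    O(db) error comes from the source term alone.

    ``f0``: initial density on the grid b = k*db, shape (K+1, d, d).
    Returns the density on the same grid after time ``tau``.
    """
    L = np.asarray(L, float)
    gamma = np.asarray(gamma, float)
    d = L.shape[0]
    ds = db / 2.0
    steps = int(round(tau / ds))
    if abs(steps * ds - tau) > 1e-9:
        raise ValueError("tau must be a multiple of db/2")
    bc = 0.5 * np.diag(gamma)
    cur = f0.copy()
    LT = L.T
    didx = np.arange(d)
    for _ in range(steps):
        src = L[None] @ cur + cur @ LT[None]
        src[:, didx, didx] += gamma * cur[:, didx, didx]
        nxt = np.empty_like(cur)
        nxt[1:] = cur[:-1] - ds * src[:-1]
        nxt[0] = bc
        cur = nxt
    return cur


def assemble_pair_operator(L: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Entrywise assembly of the two-lineage operator on vec'd d x d matrices.

    Row (i, j), column (k, l) of the operator that sends X to
    ``L X + X L^T + diag(gamma) diag{X}``, built by four explicit loops from
    the defining equation (column-stacked vec index = i + j*d).
    """
    L = np.asarray(L, float)
    gamma = np.asarray(gamma, float)
    d = L.shape[0]
    A = np.zeros((d * d, d * d))
    for i in range(d):
        for j in range(d):
            row = i + j * d
            for k in range(d):
                A[row, k + j * d] += L[i, k]  # (L X)_{ij} pulls X_{kj}
                A[row, i + k * d] += L[j, k]  # (X L^T)_{ij} pulls X_{ik}
            if i == j:
                A[row, row] += gamma[i]
    return A


def equilibrium_oracle(L: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Solve the equilibrium mean equation from the independently assembled
    operator (least squares on the entrywise system)."""
    d = L.shape[0]
    A = assemble_pair_operator(L, gamma)
    b, *_ = np.linalg.lstsq(A, 2.0 * np.ones(d * d), rcond=None)
    return b.reshape((d, d), order="F")
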