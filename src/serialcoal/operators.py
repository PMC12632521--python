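"""Linear operators of the two-lineage process.

Single-lineage motion over a duration ``tau`` is the transition matrix
``exp(-L tau)``.  The joint motion-plus-coalescence of two contemporaneous
lineages is governed by the Kronecker-sum operator

    S = L (x) I + I (x) L + sum_i gamma_i e_i e_i^T,      G = sum_i gamma_i e_i,

acting on column-stacked ``vec``-vectors of d x d matrices, where
``e_i = vec(E_i)`` marks the co-located state ``(i, i)``.  With the
column-stacking convention ``vec(A X B^T) = (B (x) A) vec(X)``, applying S to
``vec(X)`` is the same as the matrix map
``X -> L X + X L^T + diag(gamma) diag{X}``.

Two identities carry all downstream conservation laws:

* ``S vec(1_{dxd}) = G`` (because L has zero row sums), which makes branch
  length densities integrate to one and survival probabilities stay in [0,1];
* the equilibrium mean pairwise branch length solves
  ``diag(gamma) diag{B*} + L B* + B* L^T = 2_{dxd}``, i.e.
  ``vec(B*) = 2 S^{-1} vec(1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .demography import EpochParams

__all__ = [
    "transition_matrix",
    "KroneckerOperators",
    "build_operators",
    "equilibrium_mean",
    "expm_action",
    "vec",
    "unvec",
]

# above this size, exp(-S tau) @ V is computed by an action algorithm rather
# than by materializing the dense exponential
_DENSE_EXPM_MAX_DIM = 400


def vec(A: np.ndarray) -> np.ndarray:
    """Column-stacking vectorization (Fortran order)."""
    return np.asarray(A).reshape(-1, order="F")


def unvec(v: np.ndarray, d: int) -> np.ndarray:
    return np.asarray(v).reshape((d, d), order="F")


def transition_matrix(L: np.ndarray, tau: float) -> np.ndarray:
    """Backward-time transition matrix ``exp(-L tau)`` of the migration process.

    Rows sum to one; entries are clipped to ``[0, inf)`` (negative values can
    only arise from roundoff and are clipped silently below 1e-10).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0: propagators run backward in time only")
    L = np.asarray(L, dtype=float)
    if tau == 0:
        return np.eye(L.shape[0])
    T = scipy.linalg.expm(-L * tau)
    m = T.min()
    if m < -1e-10:
        import logging

        logging.getLogger(__name__).warning(
            "transition matrix entry %g below tolerance; clipping", m
        )
    np.clip(T, 0.0, None, out=T)
    return T


@dataclass
class KroneckerOperators:
    """The pair (S, G) of a single epoch, with S kept dense."""

    S: np.ndarray  # d^2 x d^2
    G: np.ndarray  # length d^2
    d: int


def build_operators(epoch: EpochParams) -> KroneckerOperators:
    """Assemble ``S`` and ``G`` for one epoch."""
    L, gamma = epoch.L, epoch.gamma
    d = epoch.d
    eye = np.eye(d)
    S = np.kron(L, eye) + np.kron(eye, L)
    G = np.zeros(d * d)
    idx = np.arange(d) * (d + 1)  # vec position of the co-located state (i, i)
    S[idx, idx] += gamma
    G[idx] = gamma
    return KroneckerOperators(S=S, G=G, d=d)


def equilibrium_mean(epoch: EpochParams) -> np.ndarray:
    """Equilibrium expected pairwise branch length matrix ``B*``.

    Solves ``diag(gamma) diag{B*} + L B* + B* L^T = 2_{dxd}`` as the dense
    linear system ``S vec(B*) = 2 vec(1)``.  A unique solution exists when
    the migration graph lets every pair of lineages reach a coalescing deme
    (S nonsingular).
    """
    ops = build_operators(epoch)
    d = ops.d
    try:
        b = scipy.linalg.solve(ops.S, 2.0 * np.ones(d * d))
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare path
        raise np.linalg.LinAlgError(
            "no unique equilibrium (disconnected graph or zero coalescence)"
        ) from exc
    resid = ops.S @ b - 2.0
    if not np.all(np.isfinite(b)) or np.linalg.norm(resid) > 1e-8 * max(
        1.0, np.linalg.norm(b)
    ):
        raise np.linalg.LinAlgError(
            "no unique equilibrium (disconnected graph or zero coalescence)"
        )
    return unvec(b, d)


def expm_action(S: np.ndarray, tau: float, V: np.ndarray) -> np.ndarray:
    """Compute ``exp(-S tau) @ V`` without forming the exponential when S is large.

    ``V`` may be a vector or a matrix of columns.  For operator dimension
    up to 400 a dense Pade exponential is used; beyond that the
    scaling-and-squaring action algorithm on the columns of V.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    S = np.asarray(S)
    V = np.asarray(V, dtype=float)
    if S.shape[0] != S.shape[1] or S.shape[1] != V.shape[0]:
        raise ValueError(f"shape mismatch: S {S.shape}, V {V.shape}")
    if tau == 0:
        return V.copy()
    if S.shape[0] <= _DENSE_EXPM_MAX_DIM:
        return scipy.linalg.expm(-S * tau) @ V
    return scipy.sparse.linalg.expm_multiply(
        scipy.sparse.csr_matrix(-S * tau), V
    )
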