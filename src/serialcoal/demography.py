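"""Piecewise-constant structured serial coalescent models on deme graphs.

A demographic model is a fixed set of ``d`` demes (nodes of a weighted
directed graph) together with an ordered list of epochs.  Within each epoch
the backward migration rates ``m_ij`` (rate at which a lineage currently in
deme ``i`` traces its ancestry to deme ``j``) and the per-deme pairwise
coalescence rates ``gamma_i`` are constant.  Time is measured backward from
the present: ``t = 0`` is "now" and epochs tile ``[t_0, +inf)`` with
half-open intervals ``[t_start, t_end)``.

The migration jump process has generator ``Q``; we work throughout with the
graph Laplacian ``L = -Q = diag(M @ 1) - M`` so that ``exp(-L * tau)`` is the
backward-time transition matrix over a duration ``tau``.

Rates are per generation.  ``gamma_i`` is the instantaneous rate at which two
lineages co-located in deme ``i`` coalesce; callers converting from an
effective population size use ``gamma = 1 / (ploidy_scaling * N)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EpochParams",
    "DemographicModel",
    "laplacian_from_adjacency",
    "adjacency_from_laplacian",
    "validate_model",
]


def laplacian_from_adjacency(M: np.ndarray) -> np.ndarray:
    """Build the migration Laplacian ``L = diag(M @ 1) - M``.

    Parameters
    ----------
    M
        Square nonnegative matrix of backward migration rates with zero
        diagonal.  Nonzero diagonal entries are ignored (self-migration is
        meaningless) with a logged warning.

    Returns
    -------
    L with zero row sums and off-diagonal entries ``-m_ij``.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got shape {M.shape}")
    neg = np.argwhere(M < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative migration rate m[{i},{j}] = {M[i, j]}; rates must be >= 0"
        )
    if np.any(np.diag(M) != 0):
        logger.warning("ignoring nonzero diagonal entries of adjacency matrix")
        M = M.copy()
        np.fill_diagonal(M, 0.0)
    return np.diag(M.sum(axis=1)) - M


def adjacency_from_laplacian(L: np.ndarray) -> np.ndarray:
    """Inverse of :func:`laplacian_from_adjacency`: ``M = diag(diag L) - L``."""
    L = np.asarray(L, dtype=float)
    M = -L.copy()
    np.fill_diagonal(M, 0.0)
    return M


@dataclass
class EpochParams:
    """Constant rates on ``[t_start, t_end)`` (backward time, generations)."""

    t_start: float
    t_end: float  # may be math.inf
    M: np.ndarray  # d x d backward migration rates, zero diagonal
    gamma: np.ndarray  # length-d pairwise coalescence rates
    L: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float).ravel()
        self.L = laplacian_from_adjacency(self.M)
        if self.gamma.shape[0] != self.M.shape[0]:
            raise ValueError(
                f"gamma has length {self.gamma.shape[0]} but M is "
                f"{self.M.shape[0]}x{self.M.shape[1]}"
            )

    @classmethod
    def from_laplacian(
        cls, t_start: float, t_end: float, L: np.ndarray, gamma: np.ndarray
    ) -> "EpochParams":
        return cls(t_start, t_end, adjacency_from_laplacian(L), gamma)

    @property
    def d(self) -> int:
        return self.M.shape[0]

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def contains(self, t: float) -> bool:
        """Whether backward time ``t`` lies in ``[t_start, t_end)``."""
        return self.t_start <= t < self.t_end

    def covers(self, a: float, b: float, atol: float = 1e-12) -> bool:
        """Whether the closed interval ``[a, b]`` lies within this epoch."""
        return self.t_start - atol <= a and b <= self.t_end + atol


@dataclass
class DemographicModel:
    """Ordered epochs sharing a fixed deme set; terminal epoch is unbounded."""

    epochs: list[EpochParams]
    deme_labels: list[str] | None = None

    @property
    def d(self) -> int:
        return self.epochs[0].d

    @property
    def t0(self) -> float:
        return self.epochs[0].t_start

    def epoch_at(self, t: float) -> EpochParams:
        """Epoch containing backward time ``t`` (terminal epoch for t >= last start)."""
        for ep in self.epochs:
            if ep.contains(t):
                return ep
        if t >= self.epochs[-1].t_start:
            return self.epochs[-1]
        raise ValueError(f"time {t} precedes the model start t0={self.t0}")

    def epoch_index_at(self, t: float) -> int:
        for k, ep in enumerate(self.epochs):
            if ep.contains(t):
                return k
        if t >= self.epochs[-1].t_start:
            return len(self.epochs) - 1
        raise ValueError(f"time {t} precedes the model start t0={self.t0}")


def validate_model(model: DemographicModel) -> list[str]:
    """Check model invariants; return a list of human-readable violations.

    An empty list means the model is valid.  Checked: matching deme counts,
    positive epoch durations, gapless/non-overlapping tiling of
    ``[t0, inf)``, unbounded terminal epoch, nonnegative rates, zero Laplacian
    row sums, and certain coalescence in the terminal epoch (some deme with
    ``gamma > 0`` reachable from every deme — otherwise the branch-length
    distributions are defective).
    """
    issues: list[str] = []
    eps = model.epochs
    if not eps:
        return ["model has no epochs"]
    d = eps[0].d
    for k, ep in enumerate(eps):
        if ep.d != d:
            issues.append(f"epoch {k}: deme count {ep.d} != {d}")
        if not ep.t_start < ep.t_end:
            issues.append(f"epoch {k}: t_start {ep.t_start} >= t_end {ep.t_end}")
        if np.any(ep.gamma < 0):
            issues.append(f"epoch {k}: negative coalescence rate")
        if np.any(ep.M < 0):
            issues.append(f"epoch {k}: negative migration rate")
        if not np.allclose(ep.L.sum(axis=1), 0.0, atol=1e-12):
            issues.append(f"epoch {k}: Laplacian row sums are not zero")
    for k in range(len(eps) - 1):
        gap = eps[k + 1].t_start - eps[k].t_end
        if gap > 1e-12:
            issues.append(f"epoch gap between epochs {k} and {k + 1}")
        elif gap < -1e-12:
            issues.append(f"epoch overlap between epochs {k} and {k + 1}")
    if not math.isinf(eps[-1].t_end):
        issues.append("terminal epoch must have t_end = +inf")
    term = eps[-1]
    if not np.any(term.gamma > 0):
        issues.append("defective terminal epoch: gamma = 0 everywhere")
    else:
        # every deme must be able to reach a coalescing deme
        g = nx.from_numpy_array(term.M, create_using=nx.DiGraph)
        coalescing = set(np.flatnonzero(term.gamma > 0))
        for i in range(term.d):
            if i in coalescing:
                continue
            if not coalescing & nx.descendants(g, i):
                issues.append(
                    f"defective terminal epoch: deme {i} cannot reach a deme "
                    "with positive coalescence rate"
                )
    return issues
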