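"""Expected pairwise branch-length matrices and their propagators.

``B^{x,y}`` is the d x d matrix of expected pairwise branch lengths for
samples at backward times (x, y), x <= y; rows index the deme of the more
recently sampled lineage.  The propagation rules mirror those of the full
densities:

* vertical  — ``B^{x-tau, y} = exp(-L tau) B^{x,y} + tau 1_{dxd}`` (the
  younger lineage mixes among demes and the pair accrues ``tau`` extra
  length).  Migration-only.
* diagonal  — deviations from the epoch equilibrium decay by ``exp(-S tau)``:
  ``vec(B^{t-tau} - B*) = exp(-S tau) vec(B^{t} - B*)`` with
  ``vec(B*) = 2 S^{-1} vec(1)``.
* horizontal — only by composition; :func:`mean_horizontal_check` verifies
  the composed identities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .demography import DemographicModel, EpochParams
from .operators import build_operators, equilibrium_mean, transition_matrix, unvec, vec

__all__ = [
    "MeanMatrix",
    "mean_vertical",
    "mean_diagonal",
    "mean_at",
    "mean_horizontal_check",
]


@dataclass
class MeanMatrix:
    """Expected pairwise branch lengths for samples at times (x, y)."""

    x: float
    y: float
    B: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.x > self.y:
            raise ValueError("require x <= y")

    @property
    def d(self) -> int:
        return self.B.shape[0]


def mean_vertical(
    B_in: MeanMatrix, L_or_epoch: np.ndarray | EpochParams, tau: float
) -> MeanMatrix:
    """(x, y) -> (x - tau, y): ``exp(-L tau) B + tau 1``."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if isinstance(L_or_epoch, EpochParams):
        ep = L_or_epoch
        if not ep.covers(B_in.x - tau, B_in.x):
            raise ValueError(
                f"interval [{B_in.x - tau}, {B_in.x}] crosses an epoch boundary; "
                "chain one mean_vertical call per epoch"
            )
        L = ep.L
    else:
        L = np.asarray(L_or_epoch, dtype=float)
    T = transition_matrix(L, tau)
    return MeanMatrix(x=B_in.x - tau, y=B_in.y, B=T @ B_in.B + tau)


def mean_diagonal(B_old: MeanMatrix, epoch: EpochParams, tau: float) -> MeanMatrix:
    """(t, t) -> (t - tau, t - tau): geometric decay toward the equilibrium B*."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if abs(B_old.x - B_old.y) > 1e-12:
        raise ValueError("diagonal propagation requires a contemporaneous pair")
    if not epoch.covers(B_old.x - tau, B_old.x):
        raise ValueError(
            f"interval [{B_old.x - tau}, {B_old.x}] crosses an epoch boundary; "
            "chain one mean_diagonal call per epoch"
        )
    ops = build_operators(epoch)
    Bstar = equilibrium_mean(epoch)
    dev = scipy.linalg.expm(-ops.S * tau) @ vec(B_old.B - Bstar)
    t_new = B_old.x - tau
    return MeanMatrix(x=t_new, y=t_new, B=Bstar + unvec(dev, B_old.d))


def mean_at(model: DemographicModel, x: float, y: float) -> MeanMatrix:
    """Expected pairwise branch lengths for samples at (x, y), assuming the
    terminal epoch is at equilibrium."""
    if x > y:
        raise ValueError("require x <= y")
    term = model.epochs[-1]
    t_hi = max(y, term.t_start)
    B = MeanMatrix(x=t_hi, y=t_hi, B=equilibrium_mean(term))
    t = t_hi
    while t > y + 1e-12:
        k = model.epoch_index_at(t - 1e-12)
        step_to = max(y, model.epochs[k].t_start)
        B = mean_diagonal(B, model.epochs[k], t - step_to)
        t = step_to
    t = y
    while t > x + 1e-12:
        k = model.epoch_index_at(t - 1e-12)
        step_to = max(x, model.epochs[k].t_start)
        B = mean_vertical(B, model.epochs[k].L, t - step_to)
        t = step_to
    return B


def mean_horizontal_check(
    B_dict: dict[tuple[float, float], MeanMatrix], model: DemographicModel
) -> dict[str, float]:
    """Residuals of the composed horizontal identities on a three-slice layout.

    For times t0 < t1 < t2 aligned with epoch boundaries the checked forms
    are (with tau0 = t1 - t0, tau1 = t2 - t1, and B*_k the epoch-k
    equilibrium):

    * ``vec(B^{t0,t0} - B*_0) = e^{-S0 tau0} vec(e^{L0 tau0} B^{t0,t1} - tau0 1 - B*_0)``
    * ``vec(B^{t1,t1} - B*_1) = e^{-S1 tau1} vec(e^{L1 tau1} B^{t1,t2} - tau1 1 - B*_1)``
    * ``vec(e^{L0 tau0} B^{t0,t1} - tau0 1 - B*_1) =
      e^{-S1 tau1} vec(e^{L1 tau1} e^{L0 tau0} B^{t0,t2} - (t2 - t0) 1 - B*_1)``

    Each inner expression un-mixes the younger lineage back to the older
    sampling time; residuals vanish on inputs generated by the vertical and
    diagonal propagators.
    """
    times = sorted({t for key in B_dict for t in key})
    res: dict[str, float] = {}
    if len(times) < 2:
        return res
    t0, t1 = times[0], times[1]
    t2 = times[2] if len(times) > 2 else None
    tau0 = t1 - t0
    ep0 = model.epoch_at(t0)
    E0inv = scipy.linalg.expm(ep0.L * tau0)

    def _resid(ep: EpochParams, tau: float, Byoung: np.ndarray, Bmixed_unmixed: np.ndarray) -> float:
        ops = build_operators(ep)
        Bstar = equilibrium_mean(ep)
        rhs = vec(Bstar) + scipy.linalg.expm(-ops.S * tau) @ vec(Bmixed_unmixed - Bstar)
        return float(np.max(np.abs(vec(Byoung) - rhs)))

    if (t0, t0) in B_dict and (t0, t1) in B_dict:
        res["young_to_mixed_epoch0"] = _resid(
            ep0, tau0, B_dict[(t0, t0)].B, E0inv @ B_dict[(t0, t1)].B - tau0
        )
    if t2 is not None:
        tau1 = t2 - t1
        ep1 = model.epoch_at(t1)
        E1inv = scipy.linalg.expm(ep1.L * tau1)
        if (t1, t1) in B_dict and (t1, t2) in B_dict:
            res["young_to_mixed_epoch1"] = _resid(
                ep1, tau1, B_dict[(t1, t1)].B, E1inv @ B_dict[(t1, t2)].B - tau1
            )
        if (t0, t1) in B_dict and (t0, t2) in B_dict:
            lhs = E0inv @ B_dict[(t0, t1)].B - tau0
            inner = E1inv @ E0inv @ B_dict[(t0, t2)].B - (t2 - t0)
            res["mixed_to_mixed"] = _resid(ep1, tau1, lhs, inner)
    return res
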