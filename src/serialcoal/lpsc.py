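"""Survival functions of LPSC (IBD) segment lengths.

A long pairwise shared coalescent (LPSC) segment — an identity-by-descent
tract — spanning a pair with total branch length ``b`` survives a length
threshold ``mu`` with probability ``exp(-r b mu)``, where ``r`` is the
recombination rate per unit length per generation.  The survival matrix is
therefore the elementwise Laplace transform of the branch-length density at
``s = r mu``:

    rho^{x,y}(mu) = int exp(-r mu b) f^{x,y}(b) db.

The transform turns the pdf propagators into closed-form recursions on the
shifted operators ``L_mu = L + r mu I`` and ``S_mu = S + 2 r mu I``:

* vertical:  ``rho^{x-tau,y} = exp(-L_mu tau) rho^{x,y}``
* diagonal:  ``vec rho_out = [I - e^{-S_mu tau}] S_mu^{-1} G + e^{-S_mu tau} vec rho_old``

The leading coefficient of the fresh-coalescence term is 1 under this
package's density normalization (f(x, 0) = diag(gamma) / 2), which pins
``rho(mu=0) = 1`` exactly; ``paper_literal=True`` restores the printed
coefficient 2 for comparison.  ``r`` and ``mu`` only enter through the
product ``r * mu``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .branch_pdf import PdfGrid
from .demography import DemographicModel, EpochParams
from .operators import build_operators, transition_matrix, unvec, vec

__all__ = [
    "SurvivalMatrix",
    "survival_from_pdf",
    "survival_vertical",
    "survival_diagonal",
    "stationary_survival",
    "survival_at",
    "survival_horizontal_check",
]


@dataclass
class SurvivalMatrix:
    """P(LPSC segment length > mu) per sampling-deme pair."""

    x: float
    y: float
    r: float
    mu: float
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if self.r < 0 or self.mu < 0:
            raise ValueError("r and mu must be >= 0")

    @property
    def d(self) -> int:
        return self.rho.shape[0]


def survival_from_pdf(f: PdfGrid, r: float, mu: float) -> SurvivalMatrix:
    """Laplace transform of a branch-length density at ``s = r mu``."""
    if r < 0 or mu < 0:
        raise ValueError("r and mu must be >= 0")
    return SurvivalMatrix(x=f.x, y=f.y, r=r, mu=mu, rho=f.laplace(r * mu))


def survival_vertical(
    rho_in: SurvivalMatrix, L_or_epoch: np.ndarray | EpochParams, tau: float
) -> SurvivalMatrix:
    """(x, y) -> (x - tau, y): ``exp(-(L + r mu I) tau) rho``."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if isinstance(L_or_epoch, EpochParams):
        ep = L_or_epoch
        if not ep.covers(rho_in.x - tau, rho_in.x):
            raise ValueError(
                f"interval [{rho_in.x - tau}, {rho_in.x}] crosses an epoch "
                "boundary; chain one survival_vertical call per epoch"
            )
        L = ep.L
    else:
        L = np.asarray(L_or_epoch, dtype=float)
    s = rho_in.r * rho_in.mu
    rho = np.exp(-s * tau) * (transition_matrix(L, tau) @ rho_in.rho)
    return SurvivalMatrix(x=rho_in.x - tau, y=rho_in.y, r=rho_in.r, mu=rho_in.mu, rho=rho)


def _fresh_term(
    epoch: EpochParams, s: float, tau: float, paper_literal: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Return (expm(-S_mu tau), fresh-coalescence contribution vector)."""
    ops = build_operators(epoch)
    n = ops.S.shape[0]
    Smu = ops.S + 2.0 * s * np.eye(n)
    coef = 2.0 if paper_literal else 1.0
    if np.isinf(tau):
        fresh = coef * scipy.linalg.solve(Smu, ops.G)
        return np.zeros((n, n)), fresh
    E = scipy.linalg.expm(-Smu * tau)
    fresh = coef * ((np.eye(n) - E) @ scipy.linalg.solve(Smu, ops.G))
    return E, fresh


def survival_diagonal(
    rho_old: SurvivalMatrix,
    epoch: EpochParams,
    tau: float,
    paper_literal: bool = False,
) -> SurvivalMatrix:
    """(t, t) -> (t - tau, t - tau) on the shifted operator ``S_mu``."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if abs(rho_old.x - rho_old.y) > 1e-12:
        raise ValueError("diagonal propagation requires a contemporaneous pair")
    if not epoch.covers(rho_old.x - tau, rho_old.x):
        raise ValueError(
            f"interval [{rho_old.x - tau}, {rho_old.x}] crosses an epoch "
            "boundary; chain one survival_diagonal call per epoch"
        )
    s = rho_old.r * rho_old.mu
    E, fresh = _fresh_term(epoch, s, tau, paper_literal)
    v = fresh + E @ vec(rho_old.rho)
    t_new = rho_old.x - tau
    return SurvivalMatrix(
        x=t_new, y=t_new, r=rho_old.r, mu=rho_old.mu, rho=unvec(v, rho_old.d)
    )


def stationary_survival(
    epoch: EpochParams, r: float, mu: float, t: float = 0.0, paper_literal: bool = False
) -> SurvivalMatrix:
    """tau -> inf limit: ``vec rho* = S_mu^{-1} G`` (times 2 if paper-literal)."""
    _, fresh = _fresh_term(epoch, r * mu, np.inf, paper_literal)
    d = epoch.d
    return SurvivalMatrix(x=t, y=t, r=r, mu=mu, rho=unvec(fresh, d))


def survival_at(
    model: DemographicModel, x: float, y: float, r: float, mu: float
) -> SurvivalMatrix:
    """Survival matrix for samples at (x, y) under terminal-epoch stationarity."""
    if x > y:
        raise ValueError("require x <= y")
    term = model.epochs[-1]
    t_hi = max(y, term.t_start)
    rho = stationary_survival(term, r, mu, t=t_hi)
    t = t_hi
    while t > y + 1e-12:
        k = model.epoch_index_at(t - 1e-12)
        step_to = max(y, model.epochs[k].t_start)
        rho = survival_diagonal(rho, model.epochs[k], t - step_to)
        t = step_to
    t = y
    while t > x + 1e-12:
        k = model.epoch_index_at(t - 1e-12)
        step_to = max(x, model.epochs[k].t_start)
        rho = survival_vertical(rho, model.epochs[k].L, t - step_to)
        t = step_to
    return rho


def survival_horizontal_check(
    rho_dict: dict[tuple[float, float], SurvivalMatrix],
    model: DemographicModel,
    paper_literal: bool = False,
) -> dict[str, float]:
    """Residuals of the composed horizontal survival relations.

    Mirrors :func:`serialcoal.branch_mean.mean_horizontal_check` with the
    shifted operators: the inner expressions un-mix the younger lineage via
    ``exp(L_mu tau) = exp(s tau) exp(L tau)``.
    """
    times = sorted({t for key in rho_dict for t in key})
    res: dict[str, float] = {}
    if len(times) < 2:
        return res
    any_rho = next(iter(rho_dict.values()))
    s = any_rho.r * any_rho.mu
    t0, t1 = times[0], times[1]
    t2 = times[2] if len(times) > 2 else None
    tau0 = t1 - t0
    ep0 = model.epoch_at(t0)
    E0inv = np.exp(s * tau0) * scipy.linalg.expm(ep0.L * tau0)

    def _resid(ep: EpochParams, tau: float, young: np.ndarray, unmixed: np.ndarray) -> float:
        E, fresh = _fresh_term(ep, s, tau, paper_literal)
        rhs = fresh + E @ vec(unmixed)
        return float(np.max(np.abs(vec(young) - rhs)))

    if (t0, t0) in rho_dict and (t0, t1) in rho_dict:
        res["young_to_mixed_epoch0"] = _resid(
            ep0, tau0, rho_dict[(t0, t0)].rho, E0inv @ rho_dict[(t0, t1)].rho
        )
    if t2 is not None:
        tau1 = t2 - t1
        ep1 = model.epoch_at(t1)
        E1inv = np.exp(s * tau1) * scipy.linalg.expm(ep1.L * tau1)
        if (t1, t1) in rho_dict and (t1, t2) in rho_dict:
            res["young_to_mixed_epoch1"] = _resid(
                ep1, tau1, rho_dict[(t1, t1)].rho, E1inv @ rho_dict[(t1, t2)].rho
            )
        if (t0, t1) in rho_dict and (t0, t2) in rho_dict:
            lhs = E0inv @ rho_dict[(t0, t1)].rho
            inner = E1inv @ E0inv @ rho_dict[(t0, t2)].rho
            res["mixed_to_mixed"] = _resid(ep1, tau1, lhs, inner)
    return res
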