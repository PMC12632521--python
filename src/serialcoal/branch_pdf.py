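"""Pairwise branch-length probability density functions and their propagators.

``f^{x,y}(b)`` is the d x d matrix whose (i, j) entry is the density of the
pairwise branch length B between a lineage sampled in deme i at backward
time x and one sampled in deme j at time y (x <= y).  Its support starts at
``y - x``.  Three propagation rules connect densities across sampling-time
pairs:

* vertical  — only the more recently sampled lineage moves back in time; the
  density is mixed by ``exp(-L tau)`` and shifted by ``tau``.  Depends on
  migration rates only.
* diagonal  — both lineages move together (contemporaneous pair); branch
  lengths shorter than ``2 tau`` come from fresh coalescence inside the
  interval, ``(1/2) exp(-S b / 2) G`` in vec form, and longer ones are the
  old density propagated by ``exp(-S tau)``.
* horizontal — the older sampling time moves; only available by composing
  the other two, which is what :func:`horizontal_pdf_check` verifies.

Normalization convention
------------------------
The fresh-coalescence boundary density at b = 0 is ``(1/2) diag(gamma)``: a
coalescence probability ``gamma dt`` in backward-time ``dt`` is spread over a
branch-length interval of width ``2 dt`` (both lineages accrue length).  With
this factor each entry of f integrates to one, the stationary mean equals the
equilibrium matrix ``B*``, and IBD survival at threshold zero is exactly one.
Propagators also accept ``paper_literal=True`` which drops the 1/2 (and the
matching coefficients downstream) for side-by-side comparison with the
uncorrected printed relations.

Grids are anchored at the support offset, so vertical shifts are exact float
arithmetic on the offset and diagonal shifts are exact index arithmetic when
``2 tau`` is a multiple of the grid spacing (non-commensurate shifts are
snapped to the grid with a warning).  Mass beyond the grid end is carried
analytically by a :class:`PdfTail`, so mass, mean and Laplace transforms are
exact up to quadrature on the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .demography import DemographicModel, EpochParams
from .operators import KroneckerOperators, build_operators, equilibrium_mean, expm_action, transition_matrix, unvec, vec

logger = logging.getLogger(__name__)

__all__ = [
    "PdfTail",
    "PdfGrid",
    "stationary_pdf",
    "propagate_vertical",
    "propagate_diagonal",
    "pdf_at",
    "horizontal_pdf_check",
    "HorizontalReport",
]


@dataclass
class PdfTail:
    """Analytic continuation of a pdf beyond the grid end ``b_end``.

    ``vec(f(b)) = P @ expm(-S (b - b_end) / 2) @ u`` for ``b >= b_end``.
    Every propagator maps a tail of this form to another one, so truncation
    never loses probability mass.
    """

    P: np.ndarray  # d^2 x d^2 accumulated left factor (includes any 1/2)
    S: np.ndarray  # d^2 x d^2 decay generator
    u: np.ndarray  # d^2

    def _Sinv(self, v: np.ndarray) -> np.ndarray:
        return scipy.linalg.solve(self.S, v)

    def mass(self) -> np.ndarray:
        """vec of the total mass beyond the grid."""
        return self.P @ (2.0 * self._Sinv(self.u))

    def first_moment(self, b_end: float) -> np.ndarray:
        """vec of ``int_{b_end}^inf b f(b) db``."""
        w = self._Sinv(self.u)
        return self.P @ (2.0 * b_end * w + 4.0 * self._Sinv(w))

    def laplace(self, s: float, b_end: float) -> np.ndarray:
        """vec of ``int_{b_end}^inf exp(-s b) f(b) db``."""
        A = self.S / 2.0 + s * np.eye(self.S.shape[0])
        return np.exp(-s * b_end) * (self.P @ scipy.linalg.solve(A, self.u))


@dataclass
class PdfGrid:
    """Matrix-valued density sampled on ``b = offset + k * db``.

    ``values[k]`` holds the right-limit of f at the k-th grid point;
    ``left_limits`` stores the left-limit at indices where f jumps (epoch
    seams of the diagonal propagator), so piecewise-trapezoid quadrature is
    second-order accurate despite the discontinuities.
    """

    x: float
    y: float
    db: float
    values: np.ndarray  # (K+1, d, d)
    left_limits: dict[int, np.ndarray] = field(default_factory=dict)
    tail: PdfTail | None = None

    @property
    def offset(self) -> float:
        return self.y - self.x

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def K(self) -> int:
        return self.values.shape[0] - 1

    @property
    def b_grid(self) -> np.ndarray:
        return self.offset + self.db * np.arange(self.values.shape[0])

    @property
    def b_end(self) -> float:
        return self.offset + self.db * self.K

    def _left_values(self) -> np.ndarray:
        if not self.left_limits:
            return self.values
        lv = self.values.copy()
        for k, m in self.left_limits.items():
            if 0 < k <= self.K:
                lv[k] = m
        return lv

    def _segment_integrals(self, weights: np.ndarray) -> np.ndarray:
        """Per-segment trapezoid of ``weights[k] * f`` honoring jumps: (K, d, d)."""
        lv = self._left_values()
        w = weights.reshape(-1, 1, 1)
        return 0.5 * self.db * (w[:-1] * self.values[:-1] + w[1:] * lv[1:])

    def mass(self) -> np.ndarray:
        """Per-entry total probability mass (grid quadrature + analytic tail)."""
        total = self._segment_integrals(np.ones(self.K + 1)).sum(axis=0)
        if self.tail is not None:
            total = total + unvec(self.tail.mass(), self.d)
        return total

    def mean(self) -> np.ndarray:
        """Per-entry ``int b f(b) db`` (unnormalized first moment)."""
        total = self._segment_integrals(self.b_grid).sum(axis=0)
        if self.tail is not None:
            total = total + unvec(self.tail.first_moment(self.b_end), self.d)
        return total

    def laplace(self, s: float) -> np.ndarray:
        """Per-entry ``int exp(-s b) f(b) db``."""
        total = self._segment_integrals(np.exp(-s * self.b_grid)).sum(axis=0)
        if self.tail is not None:
            total = total + unvec(self.tail.laplace(s, self.b_end), self.d)
        return total

    def cdf_grid(self) -> np.ndarray:
        """CDF values at the grid points, (K+1, d, d); starts at 0."""
        seg = self._segment_integrals(np.ones(self.K + 1))
        out = np.zeros_like(self.values)
        np.cumsum(seg, axis=0, out=out[1:])
        return out

    def copy(self) -> "PdfGrid":
        return replace(
            self,
            values=self.values.copy(),
            left_limits={k: v.copy() for k, v in self.left_limits.items()},
            tail=None
            if self.tail is None
            else PdfTail(self.tail.P.copy(), self.tail.S, self.tail.u.copy()),
        )


def _vec_stack(values: np.ndarray) -> np.ndarray:
    """(K+1, d, d) slices -> (d^2, K+1) column-stacked vecs."""
    K1, d, _ = values.shape
    return values.transpose(0, 2, 1).reshape(K1, d * d).T


def _unvec_stack(V: np.ndarray, d: int) -> np.ndarray:
    return V.T.reshape(-1, d, d).transpose(0, 2, 1)


def _fresh_branch(ops: KroneckerOperators, n: int, db: float, coef: float) -> np.ndarray:
    """vec densities ``coef * expm(-S k db / 2) G`` for k = 0..n-1, (d^2, n)."""
    E = scipy.linalg.expm(-ops.S * (db / 2.0))
    out = np.empty((ops.d * ops.d, n))
    v = coef * ops.G
    for k in range(n):
        out[:, k] = v
        v = E @ v
    return out


def default_db(epoch: EpochParams) -> float:
    """Grid spacing heuristic: 0.01 over the mean coalescence rate."""
    g = epoch.gamma[epoch.gamma > 0]
    return 0.01 / float(np.mean(g)) if g.size else 0.01


def stationary_pdf(
    epoch: EpochParams,
    b_max: float | None = None,
    db: float | None = None,
    t: float = 0.0,
    paper_literal: bool = False,
) -> PdfGrid:
    """Stationary contemporaneous density ``vec(f*)(b) = (1/2) expm(-S b/2) G``.

    This is the branch-length density of a pair sampled together anywhere in
    an unbounded epoch.  Its mean is the equilibrium matrix ``B*`` and its
    value at b = 0 is ``(1/2) diag(gamma)``.
    """
    ops = build_operators(epoch)
    if db is None:
        db = default_db(epoch)
    if b_max is None:
        b_max = 4.0 * float(np.max(equilibrium_mean(epoch)))
    K = int(np.ceil(b_max / db - 1e-9))
    coef = 1.0 if paper_literal else 0.5
    V = _fresh_branch(ops, K + 1, db, coef)
    tail = PdfTail(P=coef * np.eye(ops.d**2), S=ops.S, u=V[:, -1] / coef)
    return PdfGrid(x=t, y=t, db=db, values=_unvec_stack(V, ops.d), tail=tail)


def propagate_vertical(
    f: PdfGrid, L_or_epoch: np.ndarray | EpochParams, tau: float
) -> PdfGrid:
    """Move the younger sampling time back by ``tau``: (x, y) -> (x - tau, y).

    Output density is ``exp(-L tau) f(b - tau)``; mass per entry is exactly
    preserved (stochastic mixing plus a pure shift).  The rates must be
    constant over the propagation interval: pass an epoch to have the bounds
    checked, or a raw Laplacian if the caller guarantees it.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if isinstance(L_or_epoch, EpochParams):
        ep = L_or_epoch
        if not ep.covers(f.x - tau, f.x):
            raise ValueError(
                f"interval [{f.x - tau}, {f.x}] crosses an epoch boundary; "
                "chain one propagate_vertical call per epoch"
            )
        L = ep.L
    else:
        L = np.asarray(L_or_epoch, dtype=float)
    if tau == 0:
        return f.copy()
    T = transition_matrix(L, tau)
    values = np.einsum("ia,kaj->kij", T, f.values)
    lls = {k: T @ m for k, m in f.left_limits.items()}
    tail = None
    if f.tail is not None:
        tail = PdfTail(
            P=np.kron(np.eye(f.d), T) @ f.tail.P, S=f.tail.S, u=f.tail.u.copy()
        )
    return PdfGrid(x=f.x - tau, y=f.y, db=f.db, values=values, left_limits=lls, tail=tail)


def propagate_diagonal(
    f_old: PdfGrid, epoch: EpochParams, tau: float, paper_literal: bool = False
) -> PdfGrid:
    """Move a contemporaneous pair back by ``tau``: (t, t) -> (t - tau, t - tau).

    Branch lengths below ``2 tau`` arise from coalescence inside the interval
    (fresh branch ``(1/2) expm(-S b/2) G`` in vec form); above, the old
    density shifted by ``2 tau`` and propagated by ``expm(-S tau)``.  Unit
    mass is preserved thanks to ``S vec(1) = G``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if abs(f_old.offset) > 1e-12:
        raise ValueError(
            "diagonal propagation is defined for contemporaneous pairs (x == y)"
        )
    if not epoch.covers(f_old.x - tau, f_old.x):
        raise ValueError(
            f"interval [{f_old.x - tau}, {f_old.x}] crosses an epoch boundary; "
            "chain one propagate_diagonal call per epoch"
        )
    if tau == 0:
        return f_old.copy()
    db = f_old.db
    m = int(round(2.0 * tau / db))
    if abs(2.0 * tau - m * db) > 1e-9 * max(1.0, 2.0 * tau):
        logger.warning(
            "2*tau = %g is not a multiple of db = %g; snapping the shift to "
            "%d grid steps",
            2 * tau,
            db,
            m,
        )
    ops = build_operators(epoch)
    d = ops.d
    coef = 1.0 if paper_literal else 0.5
    K_new = m + f_old.K
    values = np.empty((K_new + 1, d, d))
    values[:m] = _unvec_stack(_fresh_branch(ops, m, db, coef), d)
    V_old = _vec_stack(f_old.values)
    A = scipy.linalg.expm(-ops.S * tau) if d * d <= 400 else None
    prop = (A @ V_old) if A is not None else expm_action(ops.S, tau, V_old)
    values[m:] = _unvec_stack(prop, d)

    AG = (A @ ops.G) if A is not None else expm_action(ops.S, tau, ops.G)
    lls = {m: coef * unvec(AG, d)}
    for k, mat in f_old.left_limits.items():
        v = (A @ vec(mat)) if A is not None else expm_action(ops.S, tau, vec(mat))
        lls[k + m] = unvec(v, d)
    tail = None
    if f_old.tail is not None:
        P = (A @ f_old.tail.P) if A is not None else expm_action(ops.S, tau, f_old.tail.P)
        tail = PdfTail(P=P, S=f_old.tail.S, u=f_old.tail.u.copy())
    t_new = f_old.x - tau
    return PdfGrid(x=t_new, y=t_new, db=db, values=values, left_limits=lls, tail=tail)


def pdf_at(
    model: DemographicModel,
    x: float,
    y: float,
    db: float | None = None,
    b_max: float | None = None,
    paper_literal: bool = False,
) -> PdfGrid:
    """Density of B for samples at (x, y), assuming stationarity in the
    terminal epoch.

    Decomposes the request into per-epoch steps: starting from the stationary
    density of the terminal epoch, diagonal steps bring the contemporaneous
    pair down to time ``y``, then vertical steps bring the younger lineage
    down to ``x``.
    """
    if x > y:
        raise ValueError("require x <= y (x is the more recent sampling time)")
    term = model.epochs[-1]
    if db is None:
        db = default_db(term)
    t_hi = max(y, term.t_start)
    f = stationary_pdf(term, b_max=b_max, db=db, t=t_hi, paper_literal=paper_literal)
    # diagonal steps down to y
    t = t_hi
    while t > y + 1e-12:
        k = model.epoch_index_at(t - 1e-12)
        step_to = max(y, model.epochs[k].t_start)
        f = propagate_diagonal(f, model.epochs[k], t - step_to, paper_literal=paper_literal)
        t = step_to
    # vertical steps down to x
    t = y
    while t > x + 1e-12:
        k = model.epoch_index_at(t - 1e-12)
        step_to = max(x, model.epochs[k].t_start)
        f = propagate_vertical(f, model.epochs[k].L, t - step_to)
        t = step_to
    return f


@dataclass
class HorizontalReport:
    """Max-abs residuals of the composed horizontal relations."""

    residuals: dict[str, float]

    @property
    def max_residual(self) -> float:
        return max(self.residuals.values()) if self.residuals else 0.0


def _steps(tau: float, db: float) -> int:
    m = int(round(tau / db))
    if abs(tau - m * db) > 1e-9 * max(1.0, tau):
        raise ValueError(f"duration {tau} is not commensurate with db = {db}")
    return m


def horizontal_pdf_check(
    f_dict: dict[tuple[float, float], PdfGrid],
    model: DemographicModel,
    paper_literal: bool = False,
) -> HorizontalReport:
    """Verify the horizontal relations on a three-slice layout.

    ``f_dict`` maps sampling-time pairs (x, y) to densities on commensurate
    grids for times t0 < t1 < t2 aligned with the first two epoch boundaries.
    The horizontal relations link (t0,t0)->(t0,t1), (t1,t1)->(t1,t2) and
    (t0,t1)->(t0,t2); each is evaluated on the overlapping grid points and
    the max-abs residual reported.  Residuals vanish identically when the
    inputs were produced by the vertical/diagonal propagators.
    """
    times = sorted({t for key in f_dict for t in key})
    if len(times) < 2:
        return HorizontalReport({})
    coef = 1.0 if paper_literal else 0.5
    res: dict[str, float] = {}
    t0, t1 = times[0], times[1]
    t2 = times[2] if len(times) > 2 else None
    ep0 = model.epoch_at(t0)
    ops0 = build_operators(ep0)

    def _diag_residual(f_young: PdfGrid, f_mixed: PdfGrid, ep: EpochParams, tau: float) -> float:
        # vec f_young(b) vs fresh branch for b < 2 tau, and
        # expm(-S tau) vec( expm(L tau) f_mixed(b - tau) ) for b >= 2 tau
        ops = build_operators(ep)
        db = f_young.db
        m2 = _steps(2 * tau, db)
        lhs = _vec_stack(f_young.values)
        n_fresh = min(m2, lhs.shape[1])
        rhs_fresh = _fresh_branch(ops, n_fresh, db, coef)
        r = float(np.max(np.abs(lhs[:, :n_fresh] - rhs_fresh))) if n_fresh else 0.0
        K_use = min(f_young.K, m2 + f_mixed.K)
        if K_use >= m2:
            A = scipy.linalg.expm(-ops.S * tau)
            Einv = scipy.linalg.expm(ep.L * tau)
            mixed = np.einsum("ia,kaj->kij", Einv, f_mixed.values[: K_use - m2 + 1])
            rhs = A @ _vec_stack(mixed)
            r = max(r, float(np.max(np.abs(lhs[:, m2 : K_use + 1] - rhs))))
        return r

    if (t0, t0) in f_dict and (t0, t1) in f_dict:
        res["young_to_mixed_epoch0"] = _diag_residual(
            f_dict[(t0, t0)], f_dict[(t0, t1)], ep0, t1 - t0
        )
    if t2 is not None:
        ep1 = model.epoch_at(t1)
        if (t1, t1) in f_dict and (t1, t2) in f_dict:
            res["young_to_mixed_epoch1"] = _diag_residual(
                f_dict[(t1, t1)], f_dict[(t1, t2)], ep1, t2 - t1
            )
        if (t0, t1) in f_dict and (t0, t2) in f_dict:
            # vec( expm(L0 tau0) f^{t0,t1}(b) ) equals the fresh branch of epoch 1
            # shifted to support tau0 for b - tau0 < 2 tau1, and
            # expm(-S1 tau1) vec( expm(L1 tau1) expm(L0 tau0) f^{t0,t2}(b - tau1) ) beyond
            tau0, tau1 = t1 - t0, t2 - t1
            ops1 = build_operators(ep1)
            f01, f02 = f_dict[(t0, t1)], f_dict[(t0, t2)]
            db = f01.db
            m2 = _steps(2 * tau1, db)
            E0inv = scipy.linalg.expm(ep0.L * tau0)
            lhs = _vec_stack(np.einsum("ia,kaj->kij", E0inv, f01.values))
            n_fresh = min(m2, lhs.shape[1])
            rhs_fresh = _fresh_branch(ops1, n_fresh, db, coef)
            r = float(np.max(np.abs(lhs[:, :n_fresh] - rhs_fresh))) if n_fresh else 0.0
            K_use = min(f01.K, m2 + f02.K)
            if K_use >= m2:
                A1 = scipy.linalg.expm(-ops1.S * tau1)
                E1inv = scipy.linalg.expm(ep1.L * tau1)
                mixed = np.einsum(
                    "ia,ab,kbj->kij", E1inv, E0inv, f02.values[: K_use - m2 + 1]
                )
                rhs = A1 @ _vec_stack(mixed)
                r = max(r, float(np.max(np.abs(lhs[:, m2 : K_use + 1] - rhs))))
            res["mixed_to_mixed"] = r
    return HorizontalReport(res)
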