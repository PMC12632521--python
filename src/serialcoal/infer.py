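"""Sequential inference of migration (and coalescence) rates from expected
pairwise branch-length matrices.

The estimators exploit the vertical relation — migration-only, so migration
rates are identifiable in absolute units and fully decoupled from
coalescence rates.  Given an estimated matrix ``B_hat`` at the younger pair
and a (previously estimated) matrix at the older pair, the per-epoch
Laplacian is fitted by minimizing the squared relative error

    sum_ij ((exp(-L(w) tau) B_older + tau 1 - B_hat)_ij / B_hat_ij)^2
        + lambda * Psi(w)

over nonnegative edge weights ``w`` on a declared edge set, where ``Psi`` is
a smoothness penalty on spatially adjacent same-orientation edges (the
standard migration-surface prior) and ``lambda`` is chosen by K-fold
cross-validation over matrix cells.  Optimization is quasi-Newton on log
weights with the analytic gradient obtained from the Frechet derivative of
the matrix exponential.

The sequential protocol starts at the oldest sampling time (equilibrium
estimate, with model-based imputation for vacant demes) and walks toward the
present, one epoch at a time, refining each branch-length matrix through the
fitted vertical relation before it feeds the next step.  The refinement uses
``B_refined = exp(-L_hat tau) B_older + tau 1``, the form obtained by
composing the vertical relation itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .branch_mean import MeanMatrix
from .operators import build_operators, unvec, vec

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeSet",
    "grid_edge_set",
    "full_edge_set",
    "LaplacianFit",
    "infer_L_vertical",
    "refine_B",
    "cross_validate_lambda",
    "CVResult",
    "impute_B_equilibrium",
    "ImputationResult",
    "infer_gamma_diagonal",
    "sequential_migration_inference",
    "InferenceResult",
]

_W_MIN, _W_MAX = 1e-8, 1e4


@dataclass
class EdgeSet:
    """Directed edges allowed to carry migration, plus penalty structure.

    ``penalty_pairs`` lists index pairs (a, b) into ``edges`` whose weights
    are pulled together by the smoothness penalty
    ``Psi(w) = sum (w_a - w_b)^2``.
    """

    d: int
    edges: list[tuple[int, int]]
    penalty_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weights_to_M(self, w: np.ndarray) -> np.ndarray:
        M = np.zeros((self.d, self.d))
        for e, (i, j) in enumerate(self.edges):
            M[i, j] = w[e]
        return M

    def weights_to_L(self, w: np.ndarray) -> np.ndarray:
        M = self.weights_to_M(w)
        return np.diag(M.sum(axis=1)) - M

    def weights_from_M(self, M: np.ndarray) -> np.ndarray:
        return np.array([M[i, j] for i, j in self.edges])

    def penalty(self, w: np.ndarray) -> tuple[float, np.ndarray]:
        val = 0.0
        grad = np.zeros_like(w)
        for a, b in self.penalty_pairs:
            diff = w[a] - w[b]
            val += diff * diff
            grad[a] += 2 * diff
            grad[b] -= 2 * diff
        return val, grad


def full_edge_set(d: int) -> EdgeSet:
    """Every ordered pair; no smoothness structure."""
    return EdgeSet(d=d, edges=[(i, j) for i in range(d) for j in range(d) if i != j])


def grid_edge_set(rows: int, cols: int) -> EdgeSet:
    """Rook-adjacency directed edges with same-orientation smoothness pairs.

    Two edges are penalty-coupled when they point in the same compass
    direction and their source demes are rook-adjacent.
    """
    d = rows * cols
    edges: list[tuple[int, int]] = []
    for r in range(rows):
        for c in range(cols):
            u = r * cols + c
            if c + 1 < cols:
                edges += [(u, u + 1), (u + 1, u)]
            if r + 1 < rows:
                edges += [(u, u + cols), (u + cols, u)]
    index = {e: k for k, e in enumerate(edges)}
    coords = {u: (u // cols, u % cols) for u in range(d)}
    pairs = []
    for (i, j), a in index.items():
        di = (coords[j][0] - coords[i][0], coords[j][1] - coords[i][1])
        for dr, dc in ((0, 1), (1, 0)):
            r2, c2 = coords[i][0] + dr, coords[i][1] + dc
            if not (0 <= r2 < rows and 0 <= c2 < cols):
                continue
            i2 = r2 * cols + c2
            j2 = i2 + (di[0] * cols + di[1])
            b = index.get((i2, j2))
            if b is not None:
                pairs.append((a, b))
    return EdgeSet(d=d, edges=edges, penalty_pairs=pairs)


@dataclass
class LaplacianFit:
    """Result of one vertical-relation migration fit."""

    edge_set: EdgeSet
    weights: np.ndarray
    lam: float
    objective: float
    data_objective: float
    n_iter: int
    converged: bool
    message: str
    objective_trace: list[float] = field(default_factory=list)

    @property
    def L(self) -> np.ndarray:
        return self.edge_set.weights_to_L(self.weights)

    @property
    def M(self) -> np.ndarray:
        return self.edge_set.weights_to_M(self.weights)


def _as_pairs(B_older, B_hat_younger):
    if isinstance(B_older, MeanMatrix):
        B_older = [B_older]
        B_hat_younger = [B_hat_younger]
    return list(B_older), list(B_hat_younger)


def _obs_mask(Bh: np.ndarray) -> np.ndarray:
    mask = np.isfinite(Bh)
    if np.any(Bh[mask] <= 0):
        raise ValueError(
            "observed branch-length estimates must be positive for the "
            "relative-error objective"
        )
    return mask


def infer_L_vertical(
    B_older,
    B_hat_younger,
    tau: float,
    edge_set: EdgeSet,
    lam: float = 0.0,
    w_init: float | np.ndarray = 0.1,
    train_masks: list[np.ndarray] | None = None,
    maxiter: int = 2000,
    polish: bool = True,
) -> LaplacianFit:
    """Fit per-edge migration rates from one or more vertical relations.

    ``B_older`` and ``B_hat_younger`` are matching :class:`MeanMatrix`
    objects (or lists of them) separated by the same duration ``tau``;
    the prediction ``exp(-L(w) tau) B_older + tau 1`` is fitted to the
    younger estimates in squared relative error.  NaN cells in the younger
    estimates are treated as unobserved; ``train_masks`` further restricts
    the cells entering the objective (used by cross-validation).
    Deterministic given the inputs and initialization.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    olders, youngers = _as_pairs(B_older, B_hat_younger)
    data = []
    for Bo, Bh, k in zip(olders, youngers, range(len(olders))):
        mask = _obs_mask(Bh.B)
        if train_masks is not None:
            mask = mask & train_masks[k]
        data.append((Bo.B, Bh.B, mask))
    ne = edge_set.n_edges
    w0 = np.full(ne, w_init, dtype=float) if np.isscalar(w_init) else np.asarray(w_init, float)
    theta0 = np.log(np.clip(w0, _W_MIN, _W_MAX))
    trace: list[float] = []

    def fun(theta):
        w = np.exp(theta)
        L = edge_set.weights_to_L(w)
        X = -tau * L
        A = scipy.linalg.expm(X)
        obj = 0.0
        H = np.zeros_like(L)  # d obj / d A
        for Bo, Bh, mask in data:
            pred = A @ Bo + tau
            res = np.where(mask, (pred - Bh) / np.where(mask, Bh, 1.0), 0.0)
            obj += float(np.sum(res * res))
            H += (2.0 * res / np.where(mask, Bh, 1.0)) @ Bo.T
        gX = scipy.linalg.expm_frechet(X.T, H, compute_expm=False)
        gL = -tau * gX
        gw = np.empty(ne)
        for e, (i, j) in enumerate(edge_set.edges):
            gw[e] = gL[i, i] - gL[i, j]
        pen, gpen = edge_set.penalty(w)
        trace.append(obj + lam * pen)
        return obj + lam * pen, (gw + lam * gpen) * w

    bounds = [(np.log(_W_MIN), np.log(_W_MAX))] * ne
    opt = scipy.optimize.minimize(
        fun,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12},
    )
    w = np.exp(opt.x)
    if polish:
        # Gauss-Newton refinement in linear weight space: quasi-Newton on the
        # log scale plateaus near zero weights and at ~1e-3 relative accuracy
        sq_lam = np.sqrt(lam)
        pp = edge_set.penalty_pairs

        def residuals(wv):
            A = scipy.linalg.expm(-tau * edge_set.weights_to_L(wv))
            parts = [
                ((A @ Bo + tau - Bh) / Bh)[mask] for Bo, Bh, mask in data
            ]
            if lam > 0 and pp:
                parts.append(sq_lam * np.array([wv[a] - wv[b] for a, b in pp]))
            return np.concatenate(parts)

        def jac(wv):
            X = -tau * edge_set.weights_to_L(wv)
            n_res = sum(int(mask.sum()) for _, _, mask in data)
            n_pen = len(pp) if lam > 0 else 0
            J = np.zeros((n_res + n_pen, ne))
            for e, (i, j) in enumerate(edge_set.edges):
                D = np.zeros_like(X)
                D[i, i] = -tau
                D[i, j] = tau
                dA = scipy.linalg.expm_frechet(X, D, compute_expm=False)
                row = 0
                for Bo, Bh, mask in data:
                    dpred = (dA @ Bo) / Bh
                    m = int(mask.sum())
                    J[row : row + m, e] = dpred[mask]
                    row += m
            if lam > 0 and pp:
                for k, (a, b) in enumerate(pp):
                    J[n_res + k, a] = sq_lam
                    J[n_res + k, b] = -sq_lam
            return J

        ls = scipy.optimize.least_squares(
            residuals,
            np.clip(w, 0.0, _W_MAX),
            jac=jac,
            bounds=(0.0, _W_MAX),
            method="trf",
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=300,
        )
        if ls.cost * 2.0 <= opt.fun + 1e-15:
            w = ls.x
        trace.append(float(2.0 * ls.cost))
    pen, _ = edge_set.penalty(w)
    A_fin = scipy.linalg.expm(-tau * edge_set.weights_to_L(w))
    data_obj = sum(
        float(np.sum((((A_fin @ Bo + tau - Bh) / Bh)[mask]) ** 2))
        for Bo, Bh, mask in data
    )
    return LaplacianFit(
        edge_set=edge_set,
        weights=w,
        lam=lam,
        objective=data_obj + lam * pen,
        data_objective=data_obj,
        n_iter=int(opt.nit),
        converged=bool(opt.success),
        message=str(opt.message),
        objective_trace=trace,
    )


def refine_B(B_older: MeanMatrix, L_hat: np.ndarray, tau: float) -> MeanMatrix:
    """Model-projected estimate at the younger pair:
    ``exp(-L_hat tau) B_older + tau 1`` (variance reduction over the raw
    sample mean once L_hat is fitted)."""
    A = scipy.linalg.expm(-np.asarray(L_hat, float) * tau)
    return MeanMatrix(x=B_older.x - tau, y=B_older.y, B=A @ B_older.B + tau)


@dataclass
class CVResult:
    lambda_grid: list[float]
    mean_errors: np.ndarray  # per lambda, mean held-out sq. rel. error
    se_errors: np.ndarray
    best_lambda: float
    folds: list[list[tuple[int, int, int]]]  # (pair index, i, j) cells


def cross_validate_lambda(
    B_older,
    B_hat_younger,
    tau: float,
    edge_set: EdgeSet,
    lambda_grid,
    n_folds: int = 5,
    seed: int = 0,
    one_se: bool = False,
    w_init: float = 0.1,
    maxiter: int = 500,
) -> CVResult:
    """K-fold cross-validation of the smoothness hyperparameter.

    Observed matrix cells (not demes) are partitioned into folds at random;
    for each lambda the fit is repeated holding out each fold and scored by
    held-out mean squared relative error.  Returns the argmin, or the
    largest lambda within one standard error of it when ``one_se`` is set.
    Deterministic given the seed.
    """
    lambda_grid = list(lambda_grid)
    olders, youngers = _as_pairs(B_older, B_hat_younger)
    cells = [
        (k, i, j)
        for k, Bh in enumerate(youngers)
        for i, j in zip(*np.where(np.isfinite(Bh.B)))
    ]
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cells))
    folds: list[list[tuple[int, int, int]]] = [
        [cells[p] for p in perm[f::n_folds]] for f in range(n_folds)
    ]
    if any(len(f) == len(cells) for f in folds):
        raise ValueError("a fold has an empty training set")
    d = edge_set.d
    errs = np.zeros((len(lambda_grid), n_folds))
    for fi, fold in enumerate(folds):
        masks = [np.ones((d, d), dtype=bool) for _ in youngers]
        for k, i, j in fold:
            masks[k][i, j] = False
        for li, lam in enumerate(lambda_grid):
            fit = infer_L_vertical(
                olders,
                youngers,
                tau,
                edge_set,
                lam=lam,
                w_init=w_init,
                train_masks=masks,
                maxiter=maxiter,
            )
            A = scipy.linalg.expm(-fit.L * tau)
            tot, cnt = 0.0, 0
            for k, i, j in fold:
                pred = A[i] @ olders[k].B[:, j] + tau
                obs = youngers[k].B[i, j]
                tot += ((pred - obs) / obs) ** 2
                cnt += 1
            errs[li, fi] = tot / max(cnt, 1)
    mean_errs = errs.mean(axis=1)
    se_errs = errs.std(axis=1, ddof=1) / np.sqrt(n_folds)
    best_i = int(np.argmin(mean_errs))
    best = lambda_grid[best_i]
    if one_se:
        thresh = mean_errs[best_i] + se_errs[best_i]
        admissible = [l for l, m in zip(lambda_grid, mean_errs) if m <= thresh]
        best = max(admissible)
    return CVResult(
        lambda_grid=lambda_grid,
        mean_errors=mean_errs,
        se_errors=se_errs,
        best_lambda=float(best),
        folds=folds,
    )


@dataclass
class ImputationResult:
    B_full: MeanMatrix
    L: np.ndarray
    gamma: np.ndarray
    weights: np.ndarray
    objective: float
    converged: bool
    imputed: bool


def _equilibrium_and_solver(L, gamma):
    d = L.shape[0]
    eye = np.eye(d)
    S = np.kron(L, eye) + np.kron(eye, L)
    idx = np.arange(d) * (d + 1)
    S[idx, idx] += gamma
    lu = scipy.linalg.lu_factor(S)
    bstar = scipy.linalg.lu_solve(lu, 2.0 * np.ones(d * d))
    return S, lu, bstar


def impute_B_equilibrium(
    B_partial: MeanMatrix,
    edge_set: EdgeSet,
    lam: float = 0.0,
    w_init: float = 0.1,
    gamma_init: float = 1.0,
    maxiter: int = 2000,
) -> ImputationResult:
    """Model-based completion of the oldest branch-length matrix.

    Assumes the process before the oldest sampling time ran at equilibrium
    under unknown rates (L_inf, gamma_inf); fits them by squared relative
    error between the equilibrium matrix ``vec(B*) = 2 S^{-1} vec(1)`` and
    the observed cells, then returns the fitted complete matrix.  Skipped
    (input returned unchanged) when no cell is missing.
    """
    Bobs = B_partial.B
    d = B_partial.d
    mask = np.isfinite(Bobs)
    if mask.all():
        return ImputationResult(
            B_full=B_partial,
            L=np.full((d, d), np.nan),
            gamma=np.full(d, np.nan),
            weights=np.array([]),
            objective=0.0,
            converged=True,
            imputed=False,
        )
    if not mask.any():
        raise ValueError("cannot impute a fully missing matrix")
    n_obs = int(mask.sum())
    if n_obs < d:
        logger.warning(
            "only %d observed cells for %d demes; equilibrium fit may be "
            "underdetermined",
            n_obs,
            d,
        )
    if np.any(Bobs[mask] <= 0):
        raise ValueError("observed cells must be positive")
    ne = edge_set.n_edges
    theta0 = np.concatenate(
        [np.full(ne, np.log(w_init)), np.full(d, np.log(gamma_init))]
    )
    idx = np.arange(d) * (d + 1)

    def fun(theta):
        w = np.exp(theta[:ne])
        gamma = np.exp(theta[ne:])
        L = edge_set.weights_to_L(w)
        S, lu, bstar = _equilibrium_and_solver(L, gamma)
        Bstar = unvec(bstar, d)
        res = np.where(mask, (Bstar - Bobs) / np.where(mask, Bobs, 1.0), 0.0)
        obj = float(np.sum(res * res))
        # adjoint: d obj / d vec(B*) , then d vec(B*)/d p = -S^{-1} (dS/dp) vec(B*)
        gB = vec(2.0 * res / np.where(mask, Bobs, 1.0))
        adj = scipy.linalg.lu_solve(lu, gB, trans=1)
        grad = np.empty(ne + d)
        Bm = unvec(bstar, d)
        for e, (i, j) in enumerate(edge_set.edges):
            # (dS/dw_e) vec(B*) unvec'd: dL/dw_e = E_ii - E_ij acts on both sides
            dSB = np.zeros((d, d))
            dSB[i, :] += Bm[i, :] - Bm[j, :]  # (dL) B*
            dSB[:, i] += Bm[:, i] - Bm[:, j]  # B* (dL)^T
            grad[e] = -float(adj @ vec(dSB)) * w[e]
        for i in range(d):
            grad[ne + i] = -float(adj[idx[i]] * bstar[idx[i]]) * gamma[i]
        pen, gpen = edge_set.penalty(w)
        grad[:ne] += lam * gpen * w
        return obj + lam * pen, grad

    bounds = [(np.log(_W_MIN), np.log(_W_MAX))] * ne + [
        (np.log(1e-8), np.log(1e4))
    ] * d
    opt = scipy.optimize.minimize(
        fun,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12},
    )
    w = np.exp(opt.x[:ne])
    gamma = np.exp(opt.x[ne:])
    L = edge_set.weights_to_L(w)
    _, _, bstar = _equilibrium_and_solver(L, gamma)
    B_full = np.where(mask, Bobs, unvec(bstar, d))
    return ImputationResult(
        B_full=MeanMatrix(x=B_partial.x, y=B_partial.y, B=B_full),
        L=L,
        gamma=gamma,
        weights=w,
        objective=float(opt.fun),
        converged=bool(opt.success),
        imputed=True,
    )


def infer_gamma_diagonal(
    B_hat_t1t1: MeanMatrix,
    B_t2t2: MeanMatrix,
    L_hat: np.ndarray,
    tau: float,
    gamma_init: float = 1.0,
    maxiter: int = 500,
) -> tuple[np.ndarray, dict]:
    """Estimate per-deme coalescence rates from the diagonal relation.

    With the epoch Laplacian fixed at ``L_hat`` (estimated from the
    migration-only vertical relation beforehand), minimizes the squared
    relative error between ``B_hat_t1t1`` and the diagonal prediction
    ``vec(B*) + exp(-S tau) vec(B_t2t2 - B*)``, rebuilding S and B* for each
    candidate gamma.  Demes with no observed data in their row or column are
    non-identifiable and returned as NaN.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    L_hat = np.asarray(L_hat, float)
    d = L_hat.shape[0]
    Bobs = B_hat_t1t1.B
    mask = np.isfinite(Bobs)
    if np.any(Bobs[mask] <= 0):
        raise ValueError("observed cells must be positive")
    identifiable = np.array(
        [mask[i, :].any() or mask[:, i].any() for i in range(d)]
    )

    def predict(gamma):
        S, lu, bstar = _equilibrium_and_solver(L_hat, gamma)
        dev = scipy.linalg.expm(-S * tau) @ (vec(B_t2t2.B) - bstar)
        return unvec(bstar + dev, d)

    def fun(theta):
        gamma = np.exp(theta)
        pred = predict(gamma)
        res = (pred[mask] - Bobs[mask]) / Bobs[mask]
        return float(np.sum(res * res))

    theta0 = np.full(d, np.log(gamma_init))
    opt = scipy.optimize.minimize(
        fun,
        theta0,
        method="L-BFGS-B",
        bounds=[(np.log(1e-8), np.log(1e4))] * d,
        options={"maxiter": maxiter, "ftol": 1e-15},
    )
    gamma = np.exp(opt.x)
    gamma_out = np.where(identifiable, gamma, np.nan)
    report = {
        "objective": float(opt.fun),
        "converged": bool(opt.success),
        "non_identifiable": [int(i) for i in np.where(~identifiable)[0]],
        "predicted": predict(gamma),
    }
    return gamma_out, report


@dataclass
class InferenceResult:
    """Output of the sequential protocol: one Laplacian per inferred epoch.

    Epoch k covers ``[t_k, t_{k+1})``; the terminal epoch's rates are not
    inferred (they only enter through the oldest-slice matrix, which is
    estimated or imputed directly).
    """

    times: list[float]
    edge_set: EdgeSet
    L_hat: dict[int, np.ndarray]
    weights: dict[int, np.ndarray]
    lambda_used: dict[int, float]
    cv_tables: dict[int, CVResult]
    fits: dict[int, LaplacianFit]
    refined: dict[tuple[float, float], MeanMatrix]
    gamma_hat: dict[int, np.ndarray] = field(default_factory=dict)
    imputation: ImputationResult | None = None


def sequential_migration_inference(
    data: dict[tuple[float, float], MeanMatrix],
    times,
    edge_set: EdgeSet,
    lambda_grid=(0.0,),
    n_folds: int = 5,
    seed: int = 0,
    impute: bool = False,
    use_both_relations: bool = True,
    estimate_gamma: bool = False,
    w_init: float = 0.1,
) -> InferenceResult:
    """Oldest-first sequential estimation of per-epoch migration rates.

    ``data`` maps sampling-time pairs to estimated branch-length matrices
    (NaN cells are vacant demes); ``times`` are the sampling times aligned
    with the epoch boundaries, oldest last.  The oldest contemporaneous
    slice seeds the recursion (imputed under the equilibrium model if it has
    missing cells and ``impute`` is set); each vertical step fits one
    Laplacian, with lambda selected by cross-validation when ``lambda_grid``
    has more than one entry, and refines the matrices it used for the next
    step.  When ``use_both_relations`` is set, every available vertical
    relation for the epoch enters a joint least-squares fit with equal
    weight.  With ``estimate_gamma``, coalescence rates are additionally
    estimated per epoch from the diagonal relation where contemporaneous
    data allow.
    """
    times = sorted(times)
    K = len(times) - 1
    tK = times[-1]
    key_old = (tK, tK)
    if key_old not in data:
        raise ValueError(f"missing oldest contemporaneous slice {key_old}")
    lambda_grid = list(lambda_grid)
    result = InferenceResult(
        times=times,
        edge_set=edge_set,
        L_hat={},
        weights={},
        lambda_used={},
        cv_tables={},
        fits={},
        refined={},
    )
    B_old = data[key_old]
    if not np.isfinite(B_old.B).all():
        if not impute:
            bad = np.where(~np.isfinite(B_old.B))
            missing = sorted({int(i) for i in bad[0]} | {int(j) for j in bad[1]})
            raise ValueError(
                f"vacant demes {missing} in the oldest slice; rerun with "
                "impute=True for the equilibrium-model completion"
            )
        result.imputation = impute_B_equilibrium(B_old, edge_set)
        B_old = result.imputation.B_full
    result.refined[key_old] = B_old

    for k in range(K - 1, -1, -1):
        t_young, t_old = times[k], times[k + 1]
        tau = t_old - t_young
        pairs_old, pairs_young, refine_keys = [], [], []
        for t_anchor in times[k + 1 :]:
            old_key = (t_old, t_anchor)
            young_key = (t_young, t_anchor)
            # prefer the model-refined older matrix; fall back to a raw
            # estimate when the pair was observed but never refined
            B_ref_old = result.refined.get(old_key, data.get(old_key))
            if B_ref_old is not None and young_key in data:
                pairs_old.append(B_ref_old)
                pairs_young.append(data[young_key])
                refine_keys.append((old_key, young_key))
            if not use_both_relations and pairs_old:
                break
        if not pairs_old:
            raise ValueError(
                f"no usable vertical relation for epoch {k} "
                f"(times {t_young} -> {t_old})"
            )
        if len(lambda_grid) > 1:
            cv = cross_validate_lambda(
                pairs_old,
                pairs_young,
                tau,
                edge_set,
                lambda_grid,
                n_folds=n_folds,
                seed=seed + k,
                w_init=w_init,
            )
            lam = cv.best_lambda
            result.cv_tables[k] = cv
        else:
            lam = lambda_grid[0]
        fit = infer_L_vertical(
            pairs_old, pairs_young, tau, edge_set, lam=lam, w_init=w_init
        )
        result.fits[k] = fit
        result.L_hat[k] = fit.L
        result.weights[k] = fit.weights
        result.lambda_used[k] = lam
        for (old_key, young_key), B_ref_old in zip(refine_keys, pairs_old):
            result.refined[young_key] = refine_B(B_ref_old, fit.L, tau)
        if estimate_gamma:
            old_diag, young_diag = (t_old, t_old), (t_young, t_young)
            if old_diag in result.refined and young_diag in data:
                gamma_k, rep = infer_gamma_diagonal(
                    data[young_diag], result.refined[old_diag], fit.L, tau
                )
                result.gamma_hat[k] = gamma_k
                result.refined[young_diag] = MeanMatrix(
                    x=t_young, y=t_young, B=rep["predicted"]
                )
    return result
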