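"""Exact two-lineage Monte-Carlo simulation and synthetic grid demographies.

The simulator is the stochastic counterpart of the propagator modules: a
Gillespie realization of the two-lineage continuous-time Markov chain with
piecewise-constant migration and coalescence rates.  Backward from the
younger sampling time the single younger lineage migrates alone; from the
older sampling time both lineages migrate independently and coalesce at
rate ``gamma_k`` while co-located in deme ``k``.  For piecewise-constant
rates the scheme is exact, so the empirical distributions are an independent
oracle for every analytic quantity in the package.

The module also generates the stepping-stone grid demographies used in the
simulation studies: rook-adjacency grids with a directional, converging or
mixed migration topology imposed on a uniform background rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gillespie import _simulate_batch
from .branch_mean import MeanMatrix
from .demography import DemographicModel, EpochParams, validate_model

__all__ = [
    "simulate_pair",
    "simulate_branch_lengths",
    "simulate_mean_matrix",
    "attach_lpsc_lengths",
    "empirical_B",
    "EmpiricalB",
    "GridDemography",
    "make_grid_demography",
    "grid_net_flux",
    "random_epoch",
]

SAMPLE_COLUMNS = ["deme_i", "x", "deme_j", "y", "branch_length"]


@dataclass
class PairwiseSample:
    """One simulated pairwise branch length and its sampling configuration.

    ``branch_length = 2 T_coal - x - y`` where ``T_coal >= y`` is the
    realized backward coalescence time; rows of the tabular output follow
    this schema.
    """

    deme_i: int
    x: float
    deme_j: int
    y: float
    branch_length: float
    lpsc_length: float | None = None


def _pack_model(model: DemographicModel):
    d = model.d
    t_ends = np.array([ep.t_end for ep in model.epochs], dtype=float)
    tot_m = np.stack([ep.M.sum(axis=1) for ep in model.epochs])
    cum_m = np.stack([np.cumsum(ep.M, axis=1) for ep in model.epochs])
    gamma = np.stack([ep.gamma for ep in model.epochs])
    return t_ends, tot_m, cum_m, gamma


def simulate_branch_lengths(
    model: DemographicModel,
    i: int,
    x: float,
    j: int,
    y: float,
    n: int,
    seed: int,
    validate: bool = True,
) -> np.ndarray:
    """Raw array of n simulated branch lengths (fast path; no table)."""
    if x > y:
        raise ValueError("require x <= y")
    if n < 1:
        raise ValueError("n must be >= 1")
    if validate:
        issues = validate_model(model)
        if issues:
            raise ValueError("invalid model: " + "; ".join(issues))
    t_ends, tot_m, cum_m, gamma = _pack_model(model)
    return _simulate_batch(
        n, i, float(x), j, float(y), t_ends, tot_m, cum_m, gamma, int(seed) % 2**31
    )


def simulate_mean_matrix(
    model: DemographicModel, x: float, y: float, n_per_cell: int, seed: int
) -> tuple[MeanMatrix, np.ndarray]:
    """Sample-mean branch-length matrix over all deme pairs at times (x, y).

    Returns the mean matrix and its per-cell standard errors.  For a
    contemporaneous slice (x == y) the branch length is exchangeable in the
    two demes, so only unordered pairs are simulated and mirrored.
    """
    issues = validate_model(model)
    if issues:
        raise ValueError("invalid model: " + "; ".join(issues))
    d = model.d
    B = np.zeros((d, d))
    se = np.zeros((d, d))
    ss = np.random.SeedSequence(seed)
    contemporaneous = abs(x - y) < 1e-12
    cells = [
        (i, j)
        for i in range(d)
        for j in range(d)
        if not (contemporaneous and j < i)
    ]
    for child, (i, j) in zip(ss.spawn(len(cells)), cells):
        b = simulate_branch_lengths(
            model,
            i,
            x,
            j,
            y,
            n_per_cell,
            int(child.generate_state(1)[0] % 2**31),
            validate=False,
        )
        B[i, j] = b.mean()
        se[i, j] = b.std(ddof=1) / np.sqrt(n_per_cell)
        if contemporaneous and i != j:
            B[j, i], se[j, i] = B[i, j], se[i, j]
    return MeanMatrix(x=float(x), y=float(y), B=B), se


def simulate_pair(
    model: DemographicModel, i: int, x: float, j: int, y: float, n: int, seed: int
) -> pd.DataFrame:
    """Simulate n pairwise branch lengths; returns a tidy sample table.

    Columns: deme_i, x, deme_j, y, branch_length (one row per replicate,
    matching the :class:`PairwiseSample` schema).
    """
    b = simulate_branch_lengths(model, i, x, j, y, n, seed)
    return pd.DataFrame(
        {
            "deme_i": np.full(n, i, dtype=int),
            "x": np.full(n, float(x)),
            "deme_j": np.full(n, j, dtype=int),
            "y": np.full(n, float(y)),
            "branch_length": b,
        }
    )


def attach_lpsc_lengths(samples: pd.DataFrame, r: float, seed: int) -> pd.DataFrame:
    """Draw an LPSC (IBD) segment length per sample: Exponential(rate r * b).

    Conditional on pairwise branch length b the segment length survives mu
    with probability exp(-r b mu), i.e. it is exponential with rate r b.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    rng = np.random.default_rng(seed)
    b = samples["branch_length"].to_numpy()
    out = samples.copy()
    out["lpsc_length"] = rng.exponential(scale=1.0 / (r * np.maximum(b, 1e-300)))
    return out


@dataclass
class EmpiricalB:
    """Sample-mean branch-length matrix with per-cell standard errors."""

    mean: MeanMatrix
    se: np.ndarray  # NaN where undefined (fewer than 2 samples)
    counts: np.ndarray
    missing: list[tuple[int, int]]  # cells with no samples (vacant demes)


def empirical_B(samples: pd.DataFrame, d: int) -> EmpiricalB:
    """Per-(deme_i, deme_j) sample means and SEs of branch lengths.

    All rows must share one sampling-time configuration (x, y).  Cells with
    no samples are flagged as missing — the vacant-deme situation that the
    inference module's equilibrium imputation addresses.
    """
    xs, ys = samples["x"].unique(), samples["y"].unique()
    if len(xs) != 1 or len(ys) != 1:
        raise ValueError("samples mix sampling-time configurations")
    B = np.full((d, d), np.nan)
    se = np.full((d, d), np.nan)
    counts = np.zeros((d, d), dtype=int)
    grouped = samples.groupby(["deme_i", "deme_j"])["branch_length"]
    for (i, j), vals in grouped:
        counts[i, j] = len(vals)
        B[i, j] = vals.mean()
        if len(vals) > 1:
            se[i, j] = vals.std(ddof=1) / np.sqrt(len(vals))
    missing = [(i, j) for i in range(d) for j in range(d) if counts[i, j] == 0]
    return EmpiricalB(
        mean=MeanMatrix(x=float(xs[0]), y=float(ys[0]), B=B),
        se=se,
        counts=counts,
        missing=missing,
    )


# ---------------------------------------------------------------------------
# grid demographies


@dataclass
class GridDemography:
    """Rook-adjacency stepping-stone grid with an imposed migration topology."""

    rows: int
    cols: int
    topology: str
    base_rate: float
    feature_rate: float
    M: np.ndarray
    gamma: np.ndarray
    coords: np.ndarray = field(repr=False)  # (n, 2) as (col, row) positions

    @property
    def d(self) -> int:
        return self.rows * self.cols

    def to_epoch(self, t_start: float = 0.0, t_end: float = np.inf) -> EpochParams:
        return EpochParams(t_start=t_start, t_end=t_end, M=self.M, gamma=self.gamma)


def _grid_edges(rows: int, cols: int) -> list[tuple[int, int]]:
    """All ordered rook-adjacent pairs; node index = row * cols + col."""
    edges = []
    for r in range(rows):
        for c in range(cols):
            u = r * cols + c
            if c + 1 < cols:
                v = u + 1
                edges += [(u, v), (v, u)]
            if r + 1 < rows:
                v = u + cols
                edges += [(u, v), (v, u)]
    return edges


def make_grid_demography(
    rows: int,
    cols: int,
    topology: str,
    base_rate: float = 0.1,
    feature_rate: float = 1.0,
    gamma_spec=None,
    seed: int = 0,
) -> GridDemography:
    """Build one of the three study migration topologies on a rows x cols grid.

    * ``directional`` — backward migration elevated on all west-to-east
      edges (lineages trace from the left boundary to the right).
    * ``converging`` — elevated on every edge pointing closer to the grid
      center (lineages converge backward to the center).
    * ``mixed`` — several randomly placed small-scale motifs (local sources,
      sinks and straight corridors) on the uniform background.

    All remaining edges carry ``base_rate``.  Coalescence rates are drawn
    from ``gamma_spec`` (default Uniform(0.5, 2) per deme) with the given
    seed, so a model is reproducible from its arguments.
    """
    if rows < 2 or cols < 2:
        raise ValueError("rows and cols must be >= 2")
    n = rows * cols
    rng = np.random.default_rng(seed)
    coords = np.array([(u % cols, u // cols) for u in range(n)], dtype=float)
    edges = _grid_edges(rows, cols)
    M = np.zeros((n, n))
    for u, v in edges:
        M[u, v] = base_rate

    if topology == "directional":
        for u, v in edges:
            if coords[v, 0] == coords[u, 0] + 1:  # eastward
                M[u, v] = feature_rate
    elif topology == "converging":
        center = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
        dist = np.linalg.norm(coords - center, axis=1)
        for u, v in edges:
            if dist[v] < dist[u] - 1e-9:
                M[u, v] = feature_rate
    elif topology == "mixed":
        n_motifs = max(2, n // 6)
        for _ in range(n_motifs):
            kind = rng.choice(3)
            if kind == 2:  # corridor: one straight line, one direction
                if rng.random() < 0.5:
                    r = int(rng.integers(rows))
                    sgn = 1 if rng.random() < 0.5 else -1
                    for c in range(cols - 1):
                        u, v = r * cols + c, r * cols + c + 1
                        M[(u, v) if sgn > 0 else (v, u)] = feature_rate
                else:
                    c = int(rng.integers(cols))
                    sgn = 1 if rng.random() < 0.5 else -1
                    for r in range(rows - 1):
                        u, v = r * cols + c, (r + 1) * cols + c
                        M[(u, v) if sgn > 0 else (v, u)] = feature_rate
            else:  # local source (edges out of the cell) or sink (into it)
                cell = int(rng.integers(n))
                for u, v in edges:
                    if kind == 0 and u == cell:
                        M[u, v] = feature_rate
                    elif kind == 1 and v == cell:
                        M[u, v] = feature_rate
    else:
        raise ValueError(f"unknown topology {topology!r}")

    if gamma_spec is None:
        gamma = rng.uniform(0.5, 2.0, size=n)
    elif np.isscalar(gamma_spec):
        gamma = np.full(n, float(gamma_spec))
    elif isinstance(gamma_spec, dict):
        gamma = rng.uniform(gamma_spec["low"], gamma_spec["high"], size=n)
    else:
        gamma = np.asarray(gamma_spec, dtype=float)
    return GridDemography(
        rows=rows,
        cols=cols,
        topology=topology,
        base_rate=base_rate,
        feature_rate=feature_rate,
        M=M,
        gamma=gamma,
        coords=coords,
    )


def grid_net_flux(rows: int, cols: int, M: np.ndarray) -> np.ndarray:
    """Per-deme net backward migration flux vector, (n, 2) in (x, y) axes.

    Sum over rook neighbors of ``(m_uv - m_vu)`` times the unit vector from
    u to v; captures the large-scale directional/converging sign structure
    of a migration surface.
    """
    n = rows * cols
    coords = np.array([(u % cols, u // cols) for u in range(n)], dtype=float)
    flux = np.zeros((n, 2))
    for u, v in _grid_edges(rows, cols):
        flux[u] += (M[u, v] - M[v, u]) * (coords[v] - coords[u])
    return flux / 2.0  # each ordered pair visited twice


def random_epoch(
    d: int,
    rng: np.random.Generator,
    t_start: float = 0.0,
    t_end: float = np.inf,
    rate_range: tuple[float, float] = (0.2, 2.0),
    gamma_range: tuple[float, float] = (0.5, 2.0),
    extra_edges: int | None = None,
) -> EpochParams:
    """Random strongly-connected epoch: a directed ring plus extra edges,
    with weights and coalescence rates drawn uniformly.  Test fixture
    generator for the consistency and recovery suites."""
    M = np.zeros((d, d))
    lo, hi = rate_range
    if d > 1:
        for i in range(d):
            M[i, (i + 1) % d] = rng.uniform(lo, hi)
        n_extra = extra_edges if extra_edges is not None else d
        for _ in range(n_extra):
            i, j = rng.integers(d, size=2)
            if i != j:
                M[i, j] = rng.uniform(lo, hi)
    gamma = rng.uniform(*gamma_range, size=d)
    return EpochParams(t_start=t_start, t_end=t_end, M=M, gamma=gamma)
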