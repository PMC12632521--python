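# Methods

## Model and conventions

Time is measured backward from the present (t = 0) in generations, and a
demography is a fixed set of `d` demes with epochs `[t_k, t_{k+1})` tiling
`[t_0, ∞)`.  Within an epoch the backward migration rates `m_ij` (adjacency
matrix `M`, Laplacian `L = diag(M·1) − M`) and per-deme pairwise
coalescence rates `γ_i` are constant.  All rates are per generation; `γ_i`
is the instantaneous rate at which two co-located lineages merge, so users
converting from an effective size use `γ = 1/(ploidy · N)` (the config
format accepts `Ne` plus an explicit `ploidy_scaling`, default 2).  `M`
must have a zero diagonal — self-migration has no meaning in this model and
nonzero diagonals are dropped with a warning.

The pairwise branch length for samples at backward times `x ≤ y` is
`B = 2·T_coal − x − y`.  Densities `f^{x,y}(b)` are matrix-valued with
support `[y − x, ∞)`; `vec(·)` is column-stacking, chosen so that
`vec(A X Bᵀ) = (B ⊗ A) vec(X)` and the Kronecker-sum operator
`S = L⊗I + I⊗L + Σ γ_i ε_i ε_iᵀ` is exactly the map
`X ↦ L X + X Lᵀ + diag(γ) diag{X}` (asserted by a property test).  The
co-located state `(i, i)` sits at vec index `i(d+1)` (0-based).

## Normalization of the fresh-coalescence density

The boundary density of the contemporaneous-pair PDE at `b = 0` is taken as
`½·diag(γ)`, not `diag(γ)`: a coalescence probability `γ·dt` accrued over
backward time `dt` spreads over a branch-length window of width `2·dt`
(both lineages grow).  Three facts pin the ½ down:

1. per-entry mass: `∫₀^{2τ} ½ e^{−Sb/2} G db = (I − e^{−Sτ}) S⁻¹G` equals
   `(I − e^{−Sτ}) vec(1)` by the identity `S vec(1) = G`, so propagated
   densities keep unit mass;
2. the stationary mean `∫ b · ½ e^{−Sb/2} G db = 2 S⁻¹ vec(1)` equals the
   equilibrium matrix `B*` defined by
   `diag(γ)diag{B*} + L B* + B* Lᵀ = 2` (for d = 1, γ = 1: mean 2 = B*,
   whereas the unhalved form gives 4);
3. IBD survival at threshold zero is exactly one (the unhalved diagonal
   recursion coefficient yields survival 2/3 > bound at stationarity for
   γ = 2rμ = 1, and values above 1 for small rμ).

Every propagator and residual check uses the self-consistent ½ form; the
unhalved variants remain available behind `paper_literal=True` flags so the
two conventions can be compared side by side (the `validate` CLI exposes
this as `--paper-literal`, under which the mass check fails by design).

## Density grids, tails, and quadrature

`PdfGrid` stores `f` at `b = offset + k·db` with the offset tracked as a
float, so vertical propagation (mix rows by `e^{−Lτ}`, shift support by τ)
is exact.  Diagonal propagation shifts by `2τ` grid steps and therefore
wants `2τ` commensurate with `db`; non-commensurate shifts are snapped to
the nearest step with a warning (choose `db` dividing twice the epoch
durations for exact chains — the tests use multiples of 0.25 with
`db = 0.0125`).  The default spacing is `0.01/mean(γ)` and the default
extent `4·max(B*)` of the anchoring stationary density.

Mass beyond the grid end is never truncated: every constructed density
carries an analytic tail `vec f(b) = P e^{−S(b−b_end)/2} u`, and both
propagators map tails to tails (`P ← (I⊗e^{−Lτ})P` or `P ← e^{−Sτ}P`), so
mass, first moments, and Laplace transforms include closed-form tail
contributions.  The diagonal propagator introduces a genuine jump at
`b = 2τ` whenever γ changes between epochs; grids store the left limit at
jump indices and the trapezoid quadrature is applied piecewise, keeping the
integration second-order despite discontinuities.  Observed quadrature
errors are ~1e−5 on mass and means at the default spacing (tolerances 1e−4
and 1e−3 in the consistency suite).

Matrix exponentials are dense Padé up to operator dimension 400 (d ≤ 20)
and switch to the scaling-and-squaring action algorithm on vectors beyond,
so `e^{−Sτ}` is never materialized for large grids of demes.

## Exact two-lineage simulator

The Monte-Carlo oracle is a Gillespie realization of the two-lineage
continuous-time Markov chain, jit-compiled for throughput.  From `x` the
single younger lineage migrates alone; from `y` both migrate independently
and coalesce at `γ_k` while co-located.  Epoch boundaries are handled by
the standard discard-and-refresh rule for piecewise-constant intensities
(a drawn waiting time that overshoots the boundary advances the clock to
the boundary and redraws), which is exact — a model split into two
identical epochs is distributionally indistinguishable from the unsplit one
(KS-tested).  IBD segment lengths attach to simulated pairs as
`Exponential(rate r·b)` draws, matching the `e^{−rbμ}` survival kernel.
Seeds fully determine the stream.

The synthetic grid demographies place three migration topologies on a
rook-adjacency stepping-stone grid: directional (all eastward edges
elevated), converging (edges pointing closer to the center elevated), and
mixed (randomly placed local source/sink/corridor motifs).  Defaults are
base rate 0.1, feature rate 1.0, and `γ ~ Uniform(0.5, 2)` per deme —
strong but recoverable contrast on the 5×5 study grid.  These generators
emulate the *structure* of spatially varying gene flow, not real data:
branch lengths are observed without tree-reconstruction error, every deme
is sampled, and rates are exactly piecewise-constant.  Passing tests
therefore demonstrate correctness of the theory and estimator under the
model, not robustness to genealogy-inference noise, unsampled demes, or
continuous rate variation.

## Inference

`infer_L_vertical` fits per-epoch edge weights `w ≥ 0` on a declared edge
set by minimizing `Σ ((e^{−L(w)τ} B_old + τ·1 − B̂)/B̂)² + λ·Ψ(w)`.  The
relative-error form makes cells of very different magnitude comparable and
requires strictly positive observations (enforced).  `Ψ` is the standard
migration-surface smoothness prior, `Σ (w_e − w_{e'})²` over
same-orientation edges with rook-adjacent sources on grids; the penalty
structure is a plain list of index pairs, so alternative priors plug in.
Optimization is two-stage and deterministic: L-BFGS-B on log-weights
(bounds `[1e−8, 1e4]`, uniform start `w = 0.1`, analytic adjoint gradient
via one Fréchet-derivative call per iteration), then a Gauss–Newton
(`least_squares`/TRF) polish in linear weight space with an analytic
per-edge Fréchet Jacobian — the log-scale quasi-Newton plateaus near zero
weights and at ~1e−3 relative accuracy, and the polish reaches ~1e−6.
Noiseless recovery is verified to 1e−3 per edge up to d = 10 with
regression slope 1.000 (absolute-scale identifiability).

`λ` is chosen by K-fold cross-validation over observed matrix cells
(default 5 folds, seeded random partition, optional one-standard-error
rule).  The sequential protocol consumes slices oldest-first: the oldest
contemporaneous matrix seeds the recursion (with an equilibrium-model
completion for vacant demes — fitting `(L∞, γ∞)` so that
`vec(B*) = 2 S⁻¹ vec(1)` matches the observed cells; note equilibrium
matrices are symmetric, which is what identifies a missing off-diagonal
cell), then each step fits one Laplacian from every available vertical
relation jointly (equal weight), refines the matrices it used via
`B̂ ← e^{−L̂τ} B_old + τ·1` (the form obtained by inverting the vertical
relation itself), and hands them to the next step.  Per-cell standard
errors from the simulator are carried in `EmpiricalB` so users can audit
error propagation across steps; block-wise multi-epoch fitting is left as
future work.  Coalescence rates, when requested, are estimated per epoch
from the diagonal relation with the epoch's `L̂` held fixed, by bounded
quasi-Newton on `log γ` with numerical gradients (S and B* are rebuilt per
candidate γ); demes with no observed data in their row or column are
flagged non-identifiable and returned as NaN.

## Verification design

* An independent first-order upwind method-of-characteristics solver
  integrates the contemporaneous-pair PDE at unit CFL (transport exact,
  O(Δ) source error) and matches the closed-form propagator to <1e−3 at
  Δ = 1e−3, with the error halving under grid refinement.
* The equilibrium solve is cross-checked against an operator assembled
  entry-by-entry from the defining equation, and against msprime for a
  two-deme island model.
* Horizontal (older-time) relations are implemented only as composition
  checks, with residuals <1e−8 on propagator-generated inputs; the printed
  middle horizontal mean relation is replaced by the form implied by
  composing the vertical and diagonal rules (the consistent choice).
* The grid study scores recovery by Spearman rank correlation of edge
  weights.  Two-level topologies make the true weight vector heavily tied,
  which caps plain Spearman below 1 even for perfect recovery (0.750 for
  the 60/20 directional split, 0.866 for 40/40 converging); the study
  therefore also reports the perfect-recovery ceiling (the correlation of
  the tied truth with any consistent strict ranking) and the normalized
  ratio, which equals plain Spearman whenever the truth is untied.
  Measured maps sit at the ceiling (normalized ≈ 1.0), with flux-direction
  agreement at 100% of demes and slope ≈ 0.98.  Study sizes — 5×5 grid,
  10⁴ pairs per deme pair, three slices — keep the full suite at about two
  minutes while leaving Monte-Carlo noise well below the decision
  thresholds.

## Limitations

* Rates must be piecewise constant; continuously varying rates are out of
  scope of the underlying relations.
* The IBD survival kernel is the single-sided `e^{−rbμ}` form; the
  two-sided/Erlang refinements used by some IBD callers are deliberately
  not applied.
* `B̂` matrices are taken as input (here, simulated sample means); deriving
  them from genotype covariance or reconstructed genealogies — and the
  biases those introduce — is outside the package.
* Vacant-deme completion is model-based (equilibrium fit) only; no
  geographic kriging.
* Dense `S` limits the diagonal/coalescence machinery to a few hundred
  demes; the migration-only vertical path scales as O(d³) and further with
  sparse structure.
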