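# serialcoal

Pairwise genealogies under the **structured serial coalescent**: analytic
propagators for pairwise branch-length distributions, expectations, and
IBD-segment-length survival functions on deme graphs with piecewise-constant
rates, an exact two-lineage Monte-Carlo simulator, and a sequential protocol
for inferring time-varying migration rates — in absolute units, decoupled
from coalescence rates.

It is aimed at population geneticists working with time-stratified samples
(ancient DNA time transects, serially sampled pathogens, longitudinal
conservation sampling) who want migration-surface inference that handles
serial sampling and epoch-wise rate changes on hundreds of demes.

## Model

Demes are nodes of a weighted directed graph.  Backward in time, a lineage
in deme *i* jumps to deme *j* at rate *m<sub>ij</sub>(t)*; two lineages
co-located in deme *i* coalesce at rate *γ<sub>i</sub>(t)*.  Rates are
piecewise constant over epochs.  With the graph Laplacian
*L = diag(M·1) − M*, the single-lineage transition matrix over a duration
*τ* is *e<sup>−Lτ</sup>*.

The central object is the **pairwise branch length**
*B<sup>x,y</sup><sub>ij</sub>*: the summed branch lengths from two lineages
sampled in demes *i*, *j* at backward times *x ≤ y* up to their common
ancestor (equal to *2 T<sub>MRCA</sub> − x − y*; twice the coalescence time
for a contemporaneous pair).  Writing *f<sup>x,y</sup>(b)* for the matrix of
its densities, three propagation rules connect sampling-time pairs:

* **vertical** (only the younger sampling time moves; migration-only):
  *f<sup>x−τ,y</sup>(b) = e<sup>−Lτ</sup> f<sup>x,y</sup>(b − τ)*, and for
  means *B̄<sup>x−τ,y</sup> = e<sup>−Lτ</sup> B̄<sup>x,y</sup> + τ·1*;
* **diagonal** (a contemporaneous pair moves together): in vec form, with
  the Kronecker-sum operator
  *S = L⊗I + I⊗L + Σ<sub>i</sub> γ<sub>i</sub> ε<sub>i</sub>ε<sub>i</sub><sup>T</sup>*
  and *G = Σ<sub>i</sub> γ<sub>i</sub> ε<sub>i</sub>*,
  branch lengths below *2τ* carry the fresh-coalescence density
  *½ e<sup>−Sb/2</sup> G* and longer ones the old density propagated by
  *e<sup>−Sτ</sup>*; means decay toward the equilibrium matrix *B\**
  solving *diag(γ)diag{B\*} + L B\* + B\* L<sup>T</sup> = 2*;
* **horizontal** (the older time moves): obtainable only by composing the
  other two; the package verifies these composed identities numerically.

The identity *S·vec(1) = G* makes every density integrate to one, and the
survival probability of an IBD segment (length threshold *μ*, recombination
rate *r*) is the Laplace transform *ρ = ∫ e<sup>−rμb</sup> f(b) db*, which
obeys the same recursions on the shifted operators *L + rμI*, *S + 2rμI*.

Because the vertical relations involve **only** migration rates, a
time-stratified set of estimated *B̄* matrices identifies per-epoch
migration rates absolutely, without knowing any coalescence rate.  The
sequential protocol starts from the oldest contemporaneous slice
(equilibrium-imputed where demes lack samples) and walks toward the
present, fitting one epoch Laplacian per step by penalized squared relative
error and refining the matrices it used for the next step.

## Worked example

```python
import numpy as np
from serialcoal import (DemographicModel, EpochParams, equilibrium_mean,
                        mean_at, stationary_survival, simulate_branch_lengths,
                        infer_L_vertical, full_edge_set, MeanMatrix, mean_vertical)

epoch = EpochParams(t_start=0.0, t_end=np.inf, M=[[0.0, 1.0], [1.0, 0.0]], gamma=[1.0, 1.0])
model = DemographicModel([epoch])

print(equilibrium_mean(epoch))                 # stationary pairwise branch lengths
print(mean_at(model, x=0.0, y=2.0).B)          # one sample 2 generations older
print(stationary_survival(epoch, r=1e-8, mu=2e7).rho)   # IBD > 0.2 Morgan

b = simulate_branch_lengths(model, 0, 0.0, 1, 2.0, 100_000, seed=1)
print(b.mean())

edges = full_edge_set(2)
L_true = np.array([[0.7, -0.7], [-0.3, 0.3]])
B_young = mean_vertical(MeanMatrix(1.0, 1.0, equilibrium_mean(epoch)), L_true, tau=1.0)
fit = infer_L_vertical(MeanMatrix(1.0, 1.0, equilibrium_mean(epoch)),
                       B_young, tau=1.0, edge_set=edges)
print(fit.weights)
```

Output:

```
[[4. 5.]
 [5. 4.]]
[[6.49084218 6.50915782]
 [6.50915782 6.49084218]]
[[0.5769 0.4808]
 [0.4808 0.5769]]
6.508 ...
[0.7 0.3]
```

Reading the numbers: for a symmetric two-deme system with migration rate 1
and coalescence rate 1, a contemporaneous pair from the same deme has mean
branch length 4 and from different demes 5 (between − within = 1/m).  With
one sample two generations older, the expectations shift up by the serial
offset and mix across demes.  The IBD survival entries are the probability
a shared segment exceeds 0.2 Morgan.  The simulated mean (6.508 at
n = 10⁵) agrees with the analytic 6.509, and the migration fit recovers the
true asymmetric rates (0.7, 0.3) from exact mean matrices.

A command-line interface mirrors the library:

```bash
serialcoal simulate --model m.yaml --pairs pairs.tsv --n 100000 --seed 1 --out sim/
serialcoal forward  --model m.yaml --quantity mean --x 0 --y 2 --out B.tsv
serialcoal infer    --data matrices/ --edges grid:5x5 --lambda-grid 0,0.01 --out fit/
serialcoal validate --model m.yaml
```

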