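# stpotts

Nonparametric Bayesian cell typing for single-cell spatial transcriptomics.

Modern imaging- and sequencing-based spatial transcriptomics assays (MERFISH,
STARmap, Slide-seq) measure gene expression together with the spatial
position of each cell. Clustering such cells into types benefits from the
spatial coordinates — neighbouring cells tend to share a type — but most
spatial clustering tools require the number of cell types up front. This
package clusters cells jointly from expression features and coordinates
while **learning the number of cell types from the data**.

## Model

Let `C = (C_1, …, C_n)` be cell-type labels on a directed k-nearest-neighbour
graph over the cell coordinates (`Nei_k(i)` = the k cells nearest to cell i).
The labels follow a nonparametric Potts prior

```
P(C | β, {π_ℓ}) ∝ ∏_i π_{C_i} · exp( β Σ_i Σ_{j ∈ Nei_k(i)} 1[C_i = C_j] )
```

where `β > 0` is the spatial interaction strength and the external-field
weights `π_ℓ` come from a stick-breaking process (`π_1 = ξ_1`,
`π_ℓ = ξ_ℓ ∏_{m<ℓ}(1−ξ_m)`, `ξ_ℓ ~ Beta(1, α)`), so labels range over all
positive integers and the number of occupied clusters is inferred. Expression
enters through the top `H` principal components `Y` of the normalized,
log-transformed count matrix, with diagonal Gaussian emissions
`Y_hi | C_i = ℓ ~ N(η_hℓ, σ_h²)`.

Posterior inference is a partially collapsed Gibbs sampler:

* **(a)** joint update of `(β, {ξ_ℓ})` by double Metropolis–Hastings
  (exchange algorithm): auxiliary labels are simulated under the proposal and
  the intractable Potts normalizing constant cancels from the acceptance
  ratio;
* **(b)** slice variables `u_i ~ Unif(0, π_{C_i})` truncate the infinite
  label space to finite candidate sets `{ℓ : π_ℓ ≥ u_i}`;
* **(c)** a sequential sweep redraws each label from
  `P(C_i=ℓ) ∝ exp(β · #agreeing incident edges) · N(Y_i | η_ℓ, σ²)`;
* **(d, e)** conjugate updates of cluster means and variances;
* plus a merge–split Metropolis–Hastings move that carries mixing across
  cluster numbers (see `docs/methods.md`).

Clusterings are compared with the adjusted Rand index (ARI).

## Worked example

```python
import numpy as np
from stpotts import SimConfig, simulate_dataset, PottsCellTyper, adjusted_rand_index

# simulate 500 cells, 4 spatially coherent cell types, 5-sigma separation
cfg = SimConfig(n_cells=500, K_true=4, beta_gen=1.0, mean_separation=5.0,
                H_sim=3, k_sim=6, seed=11)
coords, truth, pcs = simulate_dataset(cfg)

model = PottsCellTyper(n_neighbors=6, n_iter=2000, burn_in=1000,
                       init_k=8, random_state=3)
labels = model.fit_predict(pcs.Y.T, coords=coords.xy)

print("detected cell types:", model.n_clusters_)
print("ARI vs truth:       ", round(adjusted_rand_index(labels, truth), 3))
print("posterior mean beta:", round(model.beta_samples_.mean(), 3))
```

Output:

```
detected cell types: 4
ARI vs truth:        1.0
posterior mean beta: 1.604
```

The chain was started from 8 clusters but settles on the 4 that generated
the data, and the point labels match the simulated truth exactly. The
interaction-strength posterior is conditioned on the single realized label
field, so its mean sits near — here somewhat above — the generating
`β = 1`; it varies by roughly ±0.3 across chain seeds.

The same pipeline is available from the shell:

```bash
stpotts simulate --out sim --n-cells 500 --k-true 4 --seed 11
stpotts fit --pcs sim_pcs.csv --coords sim_coords.csv --out run \
            --k 6 --n-iter 2000 --burn-in 1000 --init-k 8 --seed 3
stpotts evaluate --pred run_labels.csv --truth sim_truth.csv
stpotts self-check        # tiny-instance oracle checks
```

For raw counts, `stpotts preprocess` (or the `ExpressionPCA` transformer)
performs median-library normalization, `log1p` and PCA.

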