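# scvdmc

Variance-driven multitask clustering of single-cell RNA-seq populations with
embedded marker-gene selection.

## The problem

Single-cell RNA-seq studies increasingly profile the *same* cell types across
several populations — biological replicates, donors, or patient/control
pairs. Clustering each population separately wastes the shared structure and
returns incomparable clusters; naively pooling all cells lets batch and
population effects dominate the geometry, so pooled clusters track sample
origin rather than cell type. `scvdmc` clusters all populations (*domains*)
jointly: every domain keeps its own cluster centers, while a single small set
of marker genes — selected inside the optimization, not beforehand — defines
the space in which all domains are clustered.

## The model

For domains d = 1..D with expression matrices X⁽ᵈ⁾ ∈ R^{m×n⁽ᵈ⁾} (genes ×
cells, log scale), the method minimizes over per-domain centers U⁽ᵈ⁾ ∈
R^{m×k}, one-hot assignments V⁽ᵈ⁾ ∈ {0,1}^{n⁽ᵈ⁾×k}, and a binary selection
vector B ∈ {0,1}^m with ∑B = λ:

    J = ½ Σ_d ‖D_B (X⁽ᵈ⁾ − U⁽ᵈ⁾V⁽ᵈ⁾ᵀ)‖²_F
        − w Σ_d Σ_i B_i Var(U⁽ᵈ⁾_{i,:})
        + α Σ_{i,j} B_i Var([U⁽¹⁾_{i,j}, …, U⁽ᴰ⁾_{i,j}])

where D_B = diag(B) and Var(·) is the population variance. The three terms
are the k-means reconstruction error on the selected genes, a reward for
within-domain center separation (marker genes should spread the cell types
apart), and a penalty on cross-domain disagreement of matched centers
(weight α couples the domains). Optimization alternates three exact block
updates: B by sorting m linear coefficients, each V⁽ᵈ⁾ by nearest-center
assignment over the selected genes, and each U⁽ᵈ⁾ by one shared k×k linear
solve. A Gershgorin diagonal-dominance bound on w
(`w_upper_bound_implemented`) guarantees the center subproblem stays convex,
which makes every iteration non-increasing in J.

## Worked example

```python
import numpy as np
from scvdmc import (HyperParams, SimulationConfig, adjusted_rand_index,
                    fit, pooled_kmeans, simulate_multidomain)

# three populations (33, 33, 34 cells), four cell types, 1000 genes,
# two planted markers, per-domain rotation/rescaling as technical bias
dataset, truth = simulate_multidomain(SimulationConfig(seed=6))

params = HyperParams(k=4, lam=2, w=1.0, alpha=0.5, seed=6)
result = fit(dataset, params)

print("selected markers:", [dataset.gene_ids[i] for i in np.flatnonzero(result.B)])
print("iterations:", result.n_iter, "converged:", result.converged)
for dom, pred, true in zip(dataset.domains, result.labels, truth.labels):
    print(dom.domain_id, "ARI =", round(adjusted_rand_index(pred, true), 3))
pooled = pooled_kmeans(dataset, k=4, seed=6)
print("pooled k-means ARI =", round(np.mean(
    [adjusted_rand_index(lv.labels, t) for lv, t in zip(pooled, truth.labels)]), 3))
```

Output:

```
selected markers: ['gene0000', 'gene0001']
iterations: 4 converged: True
domain0 ARI = 1.0
domain1 ARI = 1.0
domain2 ARI = 1.0
pooled k-means ARI = 0.56
```

The model found exactly the two planted marker genes out of 1000, recovered
every population's cell types perfectly, and beat pooled k-means, which is
confused by the simulated technical differences between the populations.

The same pipeline is available from the shell:

```sh
scvdmc simulate --out sim --seed 6
scvdmc fit -i sim/domain0.tsv -i sim/domain1.tsv -i sim/domain2.tsv \
       --k 4 --lam 2 --w 1.0 --alpha 0.5 --seed 6 --out run
scvdmc evaluate --pred run/assignments_domain0.tsv \
       --pred run/assignments_domain1.tsv --pred run/assignments_domain2.tsv \
       --truth sim/truth.tsv
```

Other subcommands: `preprocess` (expression filters), `scan-k` (elbow curve
for choosing k), `scan-alpha` (cross-domain center-agreement diagnostic).

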