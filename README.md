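# gule

Unsupervised clustering and visualization preparation built on a single
principle: nearby points usually share a class (local consistency), and
that local evidence can be propagated globally through a graph. `gule`
implements this as a two-layer self-learning pipeline aimed at data whose
classes have awkward shapes, unequal densities, or entangled topology —
the regime where centroid methods (k-means) and subspace methods fail.
It was showcased on single-cell transcriptomics-style problems but is
representation-agnostic: anything that yields a numeric feature matrix
(rows = samples) works.

## The method

Given `n` samples and a class count `K`, each layer performs:

1. **Class-consistent neighborhoods.** Every point keeps its
   `kc = k0 + ⌊log2(n/K)⌋` nearest points (itself included, `k0 = 5`),
   with exclusion radius `ωᵢ` = distance to the first excluded neighbor.
   In the second layer the size is chosen adaptively per point by the
   largest forward gap in its sorted distances, capped at `⌊n/K⌋`.
2. **Credibility graph.** A neighbor pair `(i, j)` is weighted by the
   sigmoid-lifted Gaussian credibility
   `a_ij = 2 / (1 + exp((α γ_ij)² / 2))` of its normalized distance
   `γ_ij = d(i,j) / max(ωᵢ, ωⱼ)`; `α` (9 or 6 in layer 1, 2 in layer 2)
   sets how sharply boundary neighbors are discounted.
3. **Adaptive graph cutting (Acut).** The partition objective
   `Σ_k (Σ_{i,j∈C_k} a_ij) / (Σ_{t∈C_k} d_t^β)` with `β = 1 − s`
   (where `s` is the graph's average connection strength) interpolates
   between the normalized cut (`β → 1`, sparse weak graphs) and ratio
   association (`β → 0`, dense strong graphs). Its relaxation is solved
   by the `K` dominant eigenvectors `U` of `D^{−β/2} A D^{−β/2}`.

The rows of `U` are the projected points: layer 2 repeats the procedure
on them under the cosine distance. Finally, **CPF clustering** rotates
the eigenbasis toward the nonnegative ideal basis by minimizing
`¼‖QQᵀ − I‖_F² + (K/n)‖(UQ)⁻‖_F²` (gradient descent, multi-restart) and
labels each point by `argmax_k |(UQ)_{ik}|` — deterministic under a seed,
unlike a k-means readout. For visualization, the convex combination of
normalized raw distances and projection cosine distances is handed to
t-SNE/UMAP via their precomputed-distance interfaces, which widens
inter-class separation while preserving within-class topology.

Numeric diagnostics for the supporting perturbation theory (the
spectral-norm bound on the deviation from the ideal block-diagonal graph,
the subspace perturbation bound, and the resulting mislabel bound) live
in `gule.theory`.

## Worked example

```python
from gule import make_entangled, run_gule, GULEConfig, clustering_accuracy

ds = make_entangled(n=900, seed=0)           # three interlocking spiral arms
res = run_gule(ds.X, K=3, config=GULEConfig(seed=0))

print("ACC :", clustering_accuracy(res.labels, ds.truth))
for s in res.summaries:
    print(f"layer {s.layer}: alpha={s.alpha:g} kc={s.kc} s={s.s:.3f} "
          f"beta={s.beta:.3f} eigengap={s.gap:.3g}")
```

prints

```
ACC : 1.0
layer 1: alpha=6 kc=13 s=0.150 beta=0.850 eigengap=0.0112
layer 2: alpha=2 kc=13 s=1.000 beta=0.000 eigengap=300
```

Layer 1 sees a sparse weak graph (`s = 0.15`, so the cut behaves like a
normalized cut) and already separates the three arms; layer 2's graph is
dense and strongly connected (`s = 1`, ratio-association behavior) with a
huge eigen-gap, and the rotation labeling recovers the generator classes
exactly (ACC 1.0).

The same pipeline from the shell:

```
gule synth --name entangled --n 900 --seed 0 --out data.csv,truth.csv
gule cluster --input data.csv --k 3 --labels truth.csv --out run/
gule visualize --input data.csv --k 3 --lambda 0.5 --out coords.csv
```

`run/report.json` records per-layer `s`, `β`, `kc`, the eigen-gap, the
rotation objective, and ACC/NMI/ARI against the supplied truth.

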