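# iimpute

Self-consistent imputation of dropout events in single-cell RNA-seq count
matrices.

scRNA-seq protocols miss a large fraction of truly expressed transcripts,
recording them as zeros. Downstream analyses — clustering, cell-type
assignment, differential expression — degrade badly on these zero-inflated
matrices. `iimpute` recovers the missing entries and, unlike tools tuned
against ground-truth cluster labels, judges its own output by an internal
criterion: *self-consistency*. The imputation mapping f is applied to its
own result until re-imputation barely changes it,

    sqrt(||X_out − f(X_out)||_F² / (M·N)) < θ,      θ = 0.1,

at which point the matrix contains no dropouts by the model's own account.

One pass of the mapping works on the library-size-normalized,
log10(x + 1.01) matrix X (genes × cells):

1. **Dropout probabilities.** Each gene's values follow a Gamma–Normal
   mixture π·Gamma(α, β) + (1−π)·Normal(μ, σ), fitted by EM; the dropout
   probability D_ij is the posterior weight of the low (Gamma) component
   at X_ij.
2. **Cell affinity.** An adaptive Gaussian kernel on PCA coordinates,
   A_ij = exp(−Dist(i,j)/2σ_i²) truncated beyond σ_i, the distance to the
   n-th nearest neighbor (n = 40), so each cell trusts exactly its n
   nearest neighbors.
3. **Weighted non-negative lasso.** Per cell j, with y = (1−D_j)∘X_j and
   design W[:,c] = (1−D_c)·A_jc·X_c:

       min_b 0.5·||y − W b||² + λ||b||₁,  b ≥ 0,

   solved by coordinate descent. Entries with D_ij ≥ t (t = 0.5) are
   replaced by the confidence-weighted neighbor average (W b normalized by
   the summed effective weights); everything else is kept bit-identical.

The package also ships a Splat-style simulator (grouped zero-inflated
counts with logistic mean-dependent dropout and known ground truth) and an
evaluation suite (RMSE, Pearson, ARI, NMI, silhouette width, Ward
hierarchical clustering). See `docs/methods.md` for the full model account.

## Worked example

```python
from iimpute import simulate, iimpute, normalize_counts, evaluate

ds = simulate(n_genes=500, n_cells=90, dropout_mid=2, seed=7)
out, report = iimpute(ds.observed_counts, n_neighbor=30)
print(report.rmse_trace, report.self_consistent)

truth = normalize_counts(ds.true_counts)
print(evaluate(out.values, truth.values, ds.labels).to_dict())
```

Output (dropout baseline → imputed):

```
self-consistency trace: [0.563, 0.0396]   self-consistent: True
rmse:       0.5639 -> 0.1207
pearson:    0.8024 -> 0.9831
ari:        0.0168 -> 0.8372
nmi:        0.0422 -> 0.8059
silhouette: 0.0004 -> 0.0868
```

The trace is the between-iteration RMSE of the outer loop: the second pass
changes the matrix by only 0.04 log-units per entry (< θ = 0.1), so the
result is self-consistent after two iterations. Against the pre-dropout
ground truth, imputation cuts the per-entry error by more than 4×, lifts
the correlation with the truth from 0.80 to 0.98, and largely restores the
three simulated cell groups (ARI 0.84 from a baseline of 0.02).

The same pipeline is available from the shell:

```bash
iimpute-sim --genes 2000 --cells 150 --dropout-mid 3 --seed 42 --out-prefix sim/
iimpute --input sim/observed_counts.csv --output imputed.csv -n 40 -t 0.5 --theta 0.1
iimpute-eval --imputed imputed.csv --truth sim/true_counts.csv \
             --labels sim/labels.csv --report report.json
```

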