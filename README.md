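# graphscca

Sparse canonical correlation analysis (SCCA) with a graph-OSCAR grouping
penalty. Given two paired data matrices `X` (n samples × p features) and `Y`
(n × q), the solver finds sparse loading vectors `(u, v)` maximizing the
correlation between `X u` and `Y v` while penalizing every feature-graph edge
`(i, j)` by `max(|u_i|, |u_j|)`. Because this equals
`(|u_i - u_j| + |u_i + u_j|) / 2`, highly correlated features are pulled to
equal loading magnitudes whether their correlation is positive or negative —
no pre-estimated correlation signs are needed. With no feature graph supplied
the penalty runs on the complete graph (group-pursuit mode).

## What's inside

- `graphscca.penalty_graph` — feature graphs, the penalty, and the
  iteratively reweighted Laplacian matrices (`L = D - W`, signless
  `L_hat = D_hat + W_hat`, elementwise diagonal) with uniform
  `sqrt(x^2 + zeta)` smoothing.
- `graphscca.solver` — the alternating solver: each side is updated by a
  symmetric positive-definite linear solve
  `(lambda (L + L_hat) + beta Lambda + gamma M'M) w = M'N other`, iterated
  until `max|du| <= tau` and `max|dv| <= tau` (defaults `tau = 1e-5`,
  100 iterations). Includes standardization (zero-mean, unit-norm columns),
  the penalized objective, Pearson correlation with a NaN failure convention,
  and KKT diagnostics.
- `graphscca.grouping` — per-edge reports checking the analytic loading-gap
  bound `2 lambda w_ij / gamma + sqrt(2 (1 - rho_ij)) / gamma` for isolated
  same-sign edges.
- `graphscca.synthetic` — latent-factor paired-data generator with
  group-structured true loadings, `exp(-|u_j - u_k|)` covariance kernels, and
  sign swaps of half of the first nonzero group applied jointly to loadings
  and data columns (so `X' u' = X u` exactly). Four shipped scenarios at
  n=80, p=100, q=120.
- `graphscca.evaluation` — nested k-fold cross-validation with tuning on the
  first outer training fold only, the default 7×7×3 tied hyperparameter grid,
  and paired t-test method comparison.
- `graphscca.io` / `graphscca.cli` — TSV/CSV matrix and edge-list I/O
  (lossless round trips) and the command-line interface.

## Command-line usage

```sh
# generate a synthetic dataset with known ground truth
graphscca simulate --scenario 1 --seed 7 --out-dir sim/

# fit loadings (complete graphs by default; pass --x-edges/--y-edges for
# prior feature networks)
graphscca fit --x sim/X.tsv --y sim/Y.tsv \
    --lambda1 0.001 --lambda2 0.001 --beta1 0.01 --beta2 0.01 \
    --out-dir fit/

# nested 5-fold cross-validation on the default grid
graphscca cv --x sim/X.tsv --y sim/Y.tsv --k-folds 5 --out-dir cv/

# per-edge grouping-bound report
graphscca bound-report --x sim/X.tsv --y sim/Y.tsv --side u --out-dir rep/
```

Matrix files are delimited text (tab or comma, sniffed) with feature names in
the first row and sample IDs in the first column; X and Y are inner-joined on
sample IDs. Edge lists are two tab-separated feature names per line. Every
run writes a `run_metadata.json` with the configuration, seed, input digests,
and convergence summary.

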