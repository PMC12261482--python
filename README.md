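# causalscca

Causality-aware sparse multi-view canonical correlation analysis for
genotype–phenotype association.

## The problem

Imaging-genetics studies relate a genotype matrix **X** (n subjects × p
SNPs, additive allele dosages) to several phenotype views **Y_f** (brain
imaging measures, protein levels, cognitive scores) and a diagnosis **z**.
Sparse CCA finds weight vectors u_f, v_f whose projections Xu_f and Y_f v_f
correlate — but linkage disequilibrium (LD) makes nearby SNPs strongly
correlated, so SNPs with no direct effect inherit the association of their
neighbours and contaminate the selected markers.

This package implements a causality-aware variant for researchers who want
LD-robust marker selection: it learns nonnegative per-subject weights
**Q** (ΣQ_i = n) that shrink the weighted covariance between SNP pairs
inside each LD block, emulating a decorrelated population in which indirect
associations vanish, while jointly optimizing

- a Q-weighted bidirectional association term per view,
  −u_f′X′diag(Q)Y_f v_f with ‖Xu_f‖ = ‖Y_f v_f‖ = 1,
- a diagnosis loss ψ(v_f; Y_f, z) (linear or logistic) with equal weight,
- a decorrelation loss η Σ_k Σ_{i<j∈π_k} cov_Q(X_i, X_j)²,
- a hybrid sparsity penalty λ_u1‖U‖_FGL2,1 + λ_u2‖U‖_2,1 + λ_u3‖U‖_1,1 on
  the genetic weights, ℓ1 on each v_f, and ℓ2 on Q.

The U subproblem is solved in closed form block-by-block (iteratively
reweighted diagonal surrogates + the weighted block Gram), which reduces the
dominant cost from O(np²) to O(n Σ_k p_k²) and makes chromosome-scale
panels tractable.  Q and V take safeguarded projected/proximal gradient
steps, so the objective decreases monotonically.  See
[docs/methods.md](docs/methods.md) for the full model.

## Worked example

```sh
python examples/01_simulate_and_fit.py
```

```
100 SNPs partitioned into 9 LD blocks
converged=True after 74 iterations
in-sample CCC, genotype vs view1: 0.976
in-sample CCC, genotype vs view2: 0.975
in-sample CCC, genotype vs view3: 0.975
top-10 SNPs (signed mean weight): ['snp68:+0.005', 'snp69:+0.004', ...]
support recovery at k=20: precision 0.95
```

The simulator plants a sparse signed genetic signal inside whole LD blocks
and a shared latent score linking genotype, phenotypes, and diagnosis.  A
canonical correlation (CCC) near 1 on held-out subjects means the learned
weights generalize; support precision 1.0 means every top-ranked SNP lies in
the planted causal set.  `examples/` also demonstrates LD-block
partitioning, nested cross-validation over the 10^i grid, and the
spurious-proxy experiment where sample reweighting protects a causal SNP
from being outranked by its r = 0.9 LD proxy.

The same pipeline runs from the shell on TSV or PLINK `.raw` inputs:

```sh
causalscca simulate --preset data1 --seed 1 --out-dir simdata
causalscca partition --data-dir simdata
causalscca fit --data-dir simdata --out-dir fit_out --lambda-u 1.0
causalscca report --fit-dir fit_out --top-m 10
```

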