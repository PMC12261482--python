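"""Sample reweighting versus an LD proxy of a causal SNP.

One SNP drives the phenotype; a second SNP is correlated r = 0.9 with it but
has no direct effect.  With small n and heavy noise an association-only model
sometimes ranks the proxy above the causal SNP; the decorrelation module
reweights subjects so the pair's weighted covariance shrinks, protecting the
causal ranking.  Counts how often each model ranks the causal SNP first.
"""

import numpy as np

from causalscca import (HyperParams, PenaltyWeights, fit,
                        make_spurious_pair_dataset, pairwise_corr,
                        partition_ld_blocks)

wins = {"reweighting on": 0, "reweighting off": 0}
for seed in range(1, 21):
    geno, pheno, labels, causal, proxy = make_spurious_pair_dataset(seed)
    part = partition_ld_blocks(pairwise_corr(geno))
    models = {
        "reweighting on": HyperParams(eta=0.1,
                                      penalty=PenaltyWeights(lambda_Q=0.01)),
        "reweighting off": HyperParams(eta=0.0, fix_q=True),
    }
    for name, hp in models.items():
        u = np.abs(fit((geno, pheno, labels), part, hp, seed=0).U[:, 0])
        wins[name] += int(u[causal] > u[proxy])

for name, w in wins.items():
    print(f"{name:>16}: causal SNP ranked above its proxy in {w}/20 seeds")
# Removing the weighted within-block covariance strips the proxy of its only
# association path; at the default eta = 0.1 the reweighting is mild, so the
# two counts are typically close (see docs/methods.md on decorrelation
# strength).
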