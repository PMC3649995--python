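"""Configuration Bayes factors and tissue-activity posteriors for one
gene-SNP pair measured in three tissues.

Simulates a SNP that is an eQTL in tissues 1 and 2 but not tissue 3,
computes the Bayes factor for every activity configuration, averages them
into the BMA test statistic, and reports the posterior probability that
the eQTL is active in each tissue.
"""

import numpy as np

from tissueqtl import (
    bf_bma,
    config_posterior,
    default_weights,
    build_grid,
    gene_log_bf,
    GenePair,
)

rng = np.random.default_rng(0)
n = 80
g = rng.binomial(2, 0.3, n).astype(float)
b_true = [0.6, 0.6, 0.0]  # standardized effects per tissue
ys = [b * g + rng.standard_normal(n) for b in b_true]

pair = GenePair("GENE1", ["rs1"], ys, [g[None, :]] * 3, shared_individuals=True)
grid = build_grid("default")
eta = default_weights(3)

log_bf = gene_log_bf(pair, eta.configs, grid)  # (1 SNP, 7 configs, 15 grid pts)
print("SNP-level BMA Bayes factor:", f"{bf_bma(log_bf[0], eta, grid):.3g}")
print("  (evidence against 'no eQTL in any tissue'; >> 1 is strong)")

post = config_posterior(log_bf[0], eta, grid)
print("\nTop configurations (gamma : posterior | eQTL present):")
for p, c in sorted(zip(post.config_probs, post.configs), reverse=True)[:3]:
    print(f"  {c.label()} : {p:.3f}")
print("\nPer-tissue activity probabilities:")
for s, p in enumerate(post.tissue_probs):
    print(f"  tissue {s + 1} (true effect {b_true[s]}): {p:.3f}")
print("\nTissues 1-2 are near 1; tissue 3 stays genuinely uncertain")
print("(~0.5) because a null z-score is compatible both with inactivity")
print("and with a shared eQTL the noise happened to hide — the prior's")
print("weight on the consistent configuration keeps that door open.")
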