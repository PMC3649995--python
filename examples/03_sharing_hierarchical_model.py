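"""Estimating eQTL sharing across tissues with the hierarchical model,
versus naive overlap of per-tissue calls.

Simulates three tissues where 88% of eQTLs are shared by all tissues at
moderate per-tissue power, fits (pi0, eta, lambda) by EM, and contrasts
the fitted consistent-configuration weight with the fraction of genes
called in all three tissues by independent per-tissue analyses.
"""

from tissueqtl.experiments import sharing_contrast

res = sharing_contrast(seed=0, n_genes=600, n_perm=150)
print(f"true fraction of eQTLs shared by all 3 tissues : {res['true_consistent']:.3f}")
print(f"hierarchical-model estimate eta(1,1,1)         : {res['eta_consistent']:.3f}")
print(f"estimated null-gene fraction pi0               : {res['pi0_hat']:.3f}")
print()
print(f"tissue-by-tissue overlap, all-3-tissues fraction: {res['overlap_consistent']:.3f}")
print(f"tissue-by-tissue overlap, single-tissue fraction: {res['overlap_singleton']:.3f}")
print()
print("The EM estimate recovers the simulated sharing; counting overlaps")
print("of per-tissue significance calls dramatically understates it,")
print("because each tissue misses a different subset of true eQTLs")
print("(the incomplete-power artifact).")
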