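"""Power of the joint BMA test against the tissue-by-tissue and pooled
ANOVA baselines.

Simulates 400 gene-SNP pairs in five tissues (half null, half with an
eQTL active in all five tissues, effect sizes drawn across the prior
grid at an expected PVE of 20%) and counts discoveries at a
truth-matched FDR of 5%.
"""

from tissueqtl.experiments import power_comparison

res = power_comparison(seed=0, q_active=5, equal_variances=True, n_pairs=400)
print("eQTL active in all 5 tissues, equal error variances")
print(f"  BMA joint statistic : {res['bma']} discoveries")
print(f"  tissue-by-tissue    : {res['tbt']} discoveries")
print(f"  ANOVA (pooled var)  : {res['anova']} discoveries")
print("  (out of 200 true eQTLs, at truth-matched FDR 0.05)")

res1 = power_comparison(seed=0, q_active=1, equal_variances=True, n_pairs=400)
print("\neQTL active in 1 of 5 tissues")
print(f"  BMA joint statistic : {res1['bma']} discoveries")
print(f"  tissue-by-tissue    : {res1['tbt']} discoveries")
print("\nSharing helps when eQTLs are shared: the joint test wins for")
print("broadly active eQTLs and gives up little for tissue-specific ones.")
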