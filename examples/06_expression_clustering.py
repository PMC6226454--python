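"""Process the tissue-expression matrix: normalize, cluster, summarize.

FPKM values are divided by the grand mean and log2-transformed; genes
are clustered by average-linkage (UPGMA) on Euclidean distances.
"""

import famscan

config = famscan.GeneratorConfig(seed=42)
bundle = famscan.generate(config)
fpkm = famscan.simulate_expression(bundle, config)

normalized = famscan.normalize(fpkm)
print(f"matrix: {fpkm.shape[0]} genes x {fpkm.shape[1]} tissues")
print(f"mean of 2^log-ratios (should be 1): {(2.0 ** normalized.values).mean():.6f}")

dendro = famscan.hcluster(normalized)
print("leaf order after clustering:", ", ".join(dendro.leaf_order()[:5]), "...")

counts = famscan.expressed_tissue_counts(fpkm, threshold=1.0)
narrow = counts[counts <= 3].sort_values()
print("genes expressed in three or fewer tissues:")
print(narrow.to_string())

# StHsp70-15/-16 are silent, StHsp70-11 is root+tuber only and
# StHsp70-20 root+tuber+stolon: the planted tissue patterns.
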