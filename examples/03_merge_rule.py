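"""The contingency split rule on a hand-built example.

One RNA cluster of 100 cells overlaps three ATAC clusters at 60%, 35%
and 5%. Overlaps strictly between 10% and 90% qualify; with two
qualifying ATAC clusters the RNA cluster is split in two, and the 5%
remainder is reattached to the nearest sub-cluster by mean Euclidean
distance in RNA PCA space.
"""

import numpy as np

from scmoc import Clustering, Embedding, contingency, scmoc_merge

cells = [f"cell{i}" for i in range(100)]
rna = Clustering([0] * 100, cells, "rna")
atac = Clustering([0] * 60 + [1] * 35 + [2] * 5, cells, "atac_imputed")

table = contingency(rna, atac)
print("row fractions:", np.round(table.row_fractions, 2))

# RNA coordinates: the 5 leftover cells sit on top of the first block
coords = np.r_[np.zeros(60), np.ones(35), np.zeros(5)][:, None]
merged = scmoc_merge(rna, atac, Embedding(coords, "pca", cells))

print(f"merged clusters: {merged.n_clusters} "
      f"(sizes {np.bincount(merged.labels)})")
print("labels of the 5 leftover cells:", merged.labels[95:])
print("-> the 60% and 35% overlaps become sub-clusters; the 5% cells are "
      "reassigned to the sub-cluster they are closest to in RNA space.")
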