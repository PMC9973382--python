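"""Nominate driver genes from a mutation table with the outlier rule.

A gene passes in a group when its nonsynonymously-mutated-tumor count is
strictly above Q3 + 3*IQR of the group's per-gene counts, is at least 3,
and (for tumor suppressors) fewer than 20% of its mutations are silent.
"""

import pandas as pd

from panhallmark.curation import select_tumor_suppressors
from panhallmark.io_formats import MutationTable

rows = []
# a clear driver: 8 distinct tumors with nonsynonymous hits
rows += [dict(sample=f"S{i}", gene="TP53_LIKE",
              variant_classification="Missense_Mutation") for i in range(8)]
# background genes with 0-1 hits each
for k in range(6):
    rows += [dict(sample=f"S{k}", gene=f"BG{k}",
                  variant_classification="Missense_Mutation")]
# a hypermutated-looking gene failing the silent-fraction rule
rows += [dict(sample=f"S{i}", gene="NOISY",
              variant_classification="Missense_Mutation") for i in range(5)]
rows += [dict(sample=f"S{i}", gene="NOISY",
              variant_classification="Silent") for i in range(5)]

muts = MutationTable(pd.DataFrame(rows))
groups = {f"S{i}": "T1" for i in range(10)}
catalog = select_tumor_suppressors(muts, groups,
                                   ["TP53_LIKE", "NOISY"]
                                   + [f"BG{k}" for k in range(6)])

cols = ["gene", "group", "n_mutated", "silent_fraction", "threshold",
        "passed", "reason"]
print(catalog.table[cols].to_string(index=False))
print("\npassing gene-tumor-type combinations:")
print(catalog.combos.to_string(index=False))
print("\nTP53_LIKE clears the count threshold; NOISY is 50% silent and")
print("fails; the background genes sit below the outlier threshold.")
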