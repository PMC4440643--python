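"""Differential methylation screen: ER+ vs ER- two-tailed t-test, BH at 0.05.

Significant CpGs split into hypermethylated (ER+ > ER-) and hypomethylated
sets. Reports how many of the generator's planted differential CpGs the
screen recovers.
"""

import os

from common import get_bundle, get_cohort, results_dir

ds = get_cohort()
bundle = get_bundle()
res = bundle["screens"][("diffmeth", None)]["raw"]

res.to_csv(os.path.join(results_dir(), "02_diffmeth.tsv"), sep="\t", index=False)

counts = res["direction"].value_counts()
sig = res[res["direction"] != "none"]
recovered = sig["cpg_id"].isin(ds.truth.diffmeth_cpg_ids)
print(f"tested CpGs:          {res['tested'].sum()}")
print(f"hypermethylated:      {counts.get('hyper', 0)}")
print(f"hypomethylated:       {counts.get('hypo', 0)}")
print(f"true differential among significant: {recovered.sum()}/{len(sig)}")
print(
    f"recall of planted differential CpGs: "
    f"{recovered.sum()}/{len(ds.truth.diffmeth_cpg_ids)}"
)
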