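"""Univariate Cox screen: each CpG's beta as the sole covariate, Wald P<0.02.

Labels CpGs protective (HR<1) or hazardous (HR>1) and reports how many of
the generator's causal survival CpGs the screen recovers.
"""

import os

from common import get_bundle, get_cohort, results_dir

ds = get_cohort()
bundle = get_bundle()
res = bundle["screens"][("survival", None)]["raw"]

res.to_csv(os.path.join(results_dir(), "03_survival.tsv"), sep="\t", index=False)

counts = res["category"].value_counts()
sig = res[res["category"].isin(["protective", "hazardous"])]
causal_hits = sig["cpg_id"].isin(ds.truth.causal_cpg_ids).sum()
print(f"tested CpGs:   {int(res['converged'].sum())}")
print(f"protective:    {counts.get('protective', 0)}")
print(f"hazardous:     {counts.get('hazardous', 0)}")
print(f"causal CpGs among pro+haz: {causal_hits}/{len(sig)}")
print(f"recall of causal CpGs:     {causal_hits}/{len(ds.truth.causal_cpg_ids)}")
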