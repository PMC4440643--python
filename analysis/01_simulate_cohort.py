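"""Generate the synthetic breast-cancer methylation cohort used by all drivers.

Writes the cohort's on-disk inputs (FASTA genome, beta TSV, annotation,
clinical table, MEME motif file, TF edge list, ground truth) under scratch/
and a small summary table under results/analysis/.
"""

import os

import pandas as pd

from common import SCRATCH, get_cohort, results_dir
from methmotif.synthdata import write_simulation

ds = get_cohort()
write_simulation(ds, os.path.join(SCRATCH, "cohort_files"))

summary = pd.DataFrame(
    [
        ("chromosomes", len(ds.genome)),
        ("genome_bp", sum(map(len, ds.genome.values()))),
        ("cpgs", len(ds.annotation)),
        ("samples", ds.beta.shape[1]),
        ("motifs_planted", len(ds.truth.planted_motif_ids)),
        ("motifs_decoy", len(ds.pwms) - len(ds.truth.planted_motif_ids)),
        ("causal_survival_cpgs", len(ds.truth.causal_cpg_ids)),
        ("differential_cpgs", len(ds.truth.diffmeth_cpg_ids)),
        ("planted_motif_sites", len(ds.truth.planted_site_coordinates)),
        ("censored_fraction", round(1 - ds.clinical["event"].mean(), 3)),
        ("er_positive_samples", int((ds.clinical["ER"] == "ER+").sum())),
    ],
    columns=["quantity", "value"],
)
summary.to_csv(os.path.join(results_dir(), "01_cohort_summary.tsv"), sep="\t", index=False)
print(summary.to_string(index=False))
print(f"\ncohort files written to {os.path.join(SCRATCH, 'cohort_files')}")
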