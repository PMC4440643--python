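"""102-bp CpG regions: construction, greedy overlap filtering, sequence extraction.

A CpG region is the 102-bp genomic window covering the CG dinucleotide plus
50 bp of flank on each side (50 + 2 + 50). For a CpG whose C sits at 1-based
position p, the region is [p-51, p+51) in 0-based half-open coordinates.

Overlap filtering works per (chromosome, strand): within each connected
component of the interval-overlap graph, the region with the smallest
p-value is kept as reference, everything overlapping it is removed, and the
rule repeats on the remainder until the component is exhausted. Regions on
different chromosomes or strands never conflict.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

REGION_LENGTH = 102
FLANK = 50

REGION_COLUMNS = ["cpg_id", "chrom", "start", "end", "strand", "p_value", "category"]


def make_regions(selected: pd.DataFrame, annotation: pd.DataFrame, genome: dict) -> pd.DataFrame:
    """Build 102-bp windows around selected CpGs.

    ``selected`` needs columns cpg_id and p_value (category optional).
    CpGs whose window would leave the chromosome are dropped (a warning
    reports the count) so all scanned regions have equal length.
    """
    ann = annotation.set_index("cpg_id")
    missing = [c for c in selected["cpg_id"] if c not in ann.index]
    if missing:
        raise ValueError(f"CpGs absent from annotation: {missing[:5]}")
    rows = []
    n_dropped = 0
    for rec in selected.itertuples(index=False):
        info = ann.loc[rec.cpg_id]
        chrom = info["chrom"]
        if chrom not in genome:
            raise ValueError(f"CpG {rec.cpg_id} on unknown chromosome {chrom!r}")
        p = int(info["position"])  # 1-based C position
        start, end = p - FLANK - 1, p + FLANK + 1
        if start < 0 or end > len(genome[chrom]):
            n_dropped += 1
            continue
        rows.append(
            (rec.cpg_id, chrom, start, end, info["strand"], float(rec.p_value),
             getattr(rec, "category", "none"))
        )
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} CpG(s) too close to a chromosome end", stacklevel=2)
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def _greedy_component(comp: pd.DataFrame) -> list:
    """Greedy min-p selection within one overlap component (one chrom+strand)."""
    remaining = list(comp.itertuples(index=False))
    kept = []
    while remaining:
        # smallest p; ties -> smaller start, then lexicographic cpg_id
        ref = min(remaining, key=lambda r: (r.p_value, r.start, str(r.cpg_id)))
        kept.append(ref)
        remaining = [r for r in remaining if r.start >= ref.end or r.end <= ref.start]
    return kept


def filter_overlapping_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Remove overlapping regions per (chromosome, strand) by the greedy min-p rule.

    The output is pairwise non-overlapping within each (chromosome, strand);
    the operation is idempotent and keeps every component's smallest-p region.
    """
    if regions.empty:
        return regions.copy()
    kept_rows = []
    for (_, _), grp in regions.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values(["start", "end", "cpg_id"], kind="mergesort")
        # connected components of the interval-overlap graph via running max end
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        comp_break = np.zeros(len(grp), dtype=bool)
        running_end = -np.inf
        for i in range(len(grp)):
            if starts[i] >= running_end:
                comp_break[i] = True
                running_end = ends[i]
            else:
                running_end = max(running_end, ends[i])
        comp_id = np.cumsum(comp_break)
        for _, comp in grp.groupby(comp_id, sort=True):
            kept_rows.extend(_greedy_component(comp))
    out = pd.DataFrame(kept_rows, columns=regions.columns.tolist())
    return out.sort_values(["chrom", "start", "strand"], kind="mergesort").reset_index(drop=True)


def extract_region_sequences(regions: pd.DataFrame, genome: dict) -> pd.Series:
    """Plus-strand genomic substring for each region (uppercase; N allowed).

    Scanning is strand-symmetric, so minus-strand regions get the same
    plus-strand substring as a plus-strand region at the same coordinates.
    """
    seqs = {}
    for rec in regions.itertuples(index=False):
        chrom_seq = genome[rec.chrom]
        if rec.start < 0 or rec.end > len(chrom_seq):
            raise ValueError(f"region {rec.cpg_id} out of chromosome bounds")
        seqs[rec.cpg_id] = chrom_seq[rec.start:rec.end]
    return pd.Series(seqs, name="sequence")
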