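"""Motif enrichment in CpG-region sets by two-sided Fisher's exact test.

For each motif, a 2x2 table counts regions with/without the motif in a
foreground set versus a background set. The two-sided p-value sums the
hypergeometric probabilities (margins fixed) of every table at most as
probable as the observed one, matching R's fisher.test convention
(relative gate 1 + 1e-7). Relative enrichment (RE) is the ratio of presence
proportions, foreground over background: RE > 1 enriched, RE < 1 depleted.
P-values are BH-adjusted across the motif family of each analysis.

By default the background for an analysis is all overlap-filtered tested
CpG regions not in the foreground; alternative backgrounds are a caller
choice, since the counts come in as explicit id sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffassoc import bh_adjust

_GATE = 1.0 + 1e-7


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Computed as a vectorized hypergeometric tail sum in log space (stable up
    to N ~ 1e5 and beyond). Any zero margin carries no information -> p = 1.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_fg = a + b
    n1 = a + c
    N = a + b + c + d
    if n_fg == 0 or c + d == 0 or n1 == 0 or b + d == 0:
        return 1.0
    support = np.arange(max(0, n1 - (c + d)), min(n1, n_fg) + 1)
    logp = stats.hypergeom.logpmf(support, N, n1, n_fg)
    log_obs = stats.hypergeom.logpmf(a, N, n1, n_fg)
    p = float(np.exp(logp[logp <= log_obs + np.log(_GATE)]).sum())
    return min(max(p, np.nextafter(0, 1)), 1.0)


def relative_enrichment(a: int, b: int, c: int, d: int) -> float:
    """Foreground presence fraction over background presence fraction."""
    if a + b == 0 or c + d == 0:
        raise ValueError("empty foreground or background")
    fg = a / (a + b)
    bg = c / (c + d)
    if bg == 0:
        return np.inf if a > 0 else np.nan
    return fg / bg


def _direction(re_value: float, a: int, c: int) -> str:
    if a == 0 and c == 0:
        return "flat"
    if np.isnan(re_value) or re_value == 1.0:
        return "flat"
    return "enriched" if re_value > 1.0 else "depleted"


def motif_enrichment(
    presence: pd.DataFrame,
    foreground_ids,
    background_ids,
    tf_names: dict | None = None,
    analysis: str = "",
) -> pd.DataFrame:
    """Per-motif Fisher enrichment of a foreground region set vs a background.

    ``presence`` is the Boolean region x motif matrix; the two id sets must
    be disjoint, non-empty, and present in it. Rows are ordered by
    adjusted_p then motif_id for determinism.
    """
    fg = pd.Index(foreground_ids)
    bg = pd.Index(background_ids)
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("foreground and background must be non-empty")
    overlap = fg.intersection(bg)
    if len(overlap):
        raise ValueError(f"foreground and background overlap: {list(overlap[:5])}")
    missing = fg.union(bg).difference(presence.index)
    if len(missing):
        raise ValueError(f"ids absent from presence matrix: {list(missing[:5])}")

    fg_counts = presence.loc[fg].sum(axis=0).astype(int)
    bg_counts = presence.loc[bg].sum(axis=0).astype(int)
    rows = []
    for motif_id in presence.columns:
        a = int(fg_counts[motif_id])
        c = int(bg_counts[motif_id])
        b = len(fg) - a
        d = len(bg) - c
        p = fisher_two_sided(a, b, c, d)
        re_value = relative_enrichment(a, b, c, d)
        rows.append(
            {
                "motif_id": motif_id,
                "tf_name": (tf_names or {}).get(motif_id, motif_id),
                "a": a, "b": b, "c": c, "d": d,
                "relative_enrichment": re_value,
                "raw_p": p,
                "direction": _direction(re_value, a, c),
                "analysis": analysis,
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bh_adjust(out["raw_p"].to_numpy())
    out = out.sort_values(["adjusted_p", "motif_id"], kind="mergesort").reset_index(drop=True)
    return out[
        ["motif_id", "tf_name", "a", "b", "c", "d", "relative_enrichment",
         "raw_p", "adjusted_p", "direction", "analysis"]
    ]


def match_set_sizes(set_a: pd.DataFrame, set_b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Equalize two scored CpG sets to the top-n most significant CpGs each.

    n is the smaller set size; each set keeps its n smallest p-values, with
    boundary ties broken by genomic coordinate (chrom, position if present)
    then cpg_id, for determinism. Controls enrichment power when comparing
    differently sized CpG sets.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("cannot size-match an empty CpG set")
    n = min(len(set_a), len(set_b))

    def top_n(df: pd.DataFrame) -> pd.DataFrame:
        sort_cols = [c for c in ["p_value", "chrom", "position", "start", "cpg_id"] if c in df.columns]
        return df.sort_values(sort_cols, kind="mergesort").head(n).reset_index(drop=True)

    return top_n(set_a), top_n(set_b)
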