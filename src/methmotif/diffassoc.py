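"""Two-group differential screens over CpG methylation and gene expression.

Differential methylation uses a two-tailed Student t-test (pooled variance)
or a Wilcoxon rank-sum test per CpG; differential expression uses Wilcoxon
plus a fold change of group means. P-values are Benjamini-Hochberg adjusted
across the tested features, and significant CpGs are split into
hypermethylated (group1 > group2, statistic > 0) and hypomethylated sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` defaults to ``len(p)``; a larger m (e.g. when untestable features
    were dropped beforehand but should still count) scales the adjustment.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= number of p-values")
    adj = multipletests(p, method="fdr_bh")[1]
    if m > p.size:
        # re-apply the step-up with the larger m: adj_i = min_{p_(j)>=p_(i)} m p_(j)/j
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, p.size + 1)
        adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty_like(p)
        adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def _two_group_arrays(values: np.ndarray, g1_mask, g2_mask):
    x = values[g1_mask]
    y = values[g2_mask]
    return x[~np.isnan(x)], y[~np.isnan(y)]


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p and the Mann-Whitney U statistic (centered sign).

    Exact distribution for small tie-free samples (n1, n2 <= 25), normal
    approximation with tie correction otherwise.
    """
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def diff_methylation(
    beta: pd.DataFrame,
    groups: dict,
    method: str = "student_t",
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-CpG two-group differential methylation with BH adjustment.

    ``groups`` maps sample_id -> group label (exactly two labels). Direction
    is assigned at adjusted_p < alpha: ``hyper`` when group1 mean exceeds
    group2 (statistic > 0), ``hypo`` when below. CpGs with fewer than two
    complete samples in either group are flagged untested and excluded from
    the BH family.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    samples = [s for s in beta.columns if s in groups]
    g1_mask = np.array([groups[s] == labels[0] for s in samples])
    g2_mask = ~g1_mask
    if g1_mask.sum() == 0 or g2_mask.sum() == 0:
        raise ValueError("a group has no samples")
    values = beta[samples].to_numpy(dtype=float)

    rows = []
    for i, cpg in enumerate(beta.index):
        x, y = _two_group_arrays(values[i], g1_mask, g2_mask)
        if len(x) < 2 or len(y) < 2:
            rows.append((cpg, np.nan, np.nan, False))
            continue
        if method == "student_t":
            if np.ptp(np.concatenate([x, y])) == 0:
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.ttest_ind(x, y, equal_var=equal_var)
        elif method == "wilcoxon":
            u, p = _wilcoxon_p(x, y)
            stat = u - len(x) * len(y) / 2.0  # centered: >0 means group1 higher
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append((cpg, float(stat), float(p), True))

    out = pd.DataFrame(rows, columns=["cpg_id", "statistic", "raw_p", "tested"])
    out["adjusted_p"] = np.nan
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "adjusted_p"] = bh_adjust(out.loc[tested, "raw_p"].to_numpy())
    sig = tested & (out["adjusted_p"].to_numpy() < alpha)
    direction = np.where(
        sig & (out["statistic"] > 0), "hyper", np.where(sig & (out["statistic"] < 0), "hypo", "none")
    )
    out["direction"] = direction
    return out


def diff_expression(expr: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum test with fold change = mean(g1)/mean(g2)."""
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    samples = [s for s in expr.columns if s in groups]
    g1_mask = np.array([groups[s] == labels[0] for s in samples])
    g2_mask = ~g1_mask
    values = expr[samples].to_numpy(dtype=float)

    rows = []
    for i, gene in enumerate(expr.index):
        x, y = _two_group_arrays(values[i], g1_mask, g2_mask)
        if len(x) < 2 or len(y) < 2:
            rows.append((gene, np.nan, np.nan, False))
            continue
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0
        else:
            _, p = _wilcoxon_p(x, y)
        m2 = y.mean()
        if m2 == 0:
            import warnings

            warnings.warn(f"gene {gene}: group-2 mean is 0, fold change set to inf", stacklevel=2)
            fc = np.inf
        else:
            fc = x.mean() / m2
        rows.append((gene, float(p), fc, True))

    out = pd.DataFrame(rows, columns=["gene_id", "raw_p", "fold_change", "tested"])
    out["adjusted_p"] = np.nan
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "adjusted_p"] = bh_adjust(out.loc[tested, "raw_p"].to_numpy())
    return out[["gene_id", "raw_p", "adjusted_p", "fold_change", "tested"]]
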