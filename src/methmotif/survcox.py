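"""Univariate Cox proportional-hazards screen over CpG beta-values.

Each CpG's beta-value vector is used alone as the covariate in a Cox model;
the coefficient is the log hazard per unit beta and its Wald test decides
significance. CpGs with unadjusted Wald P below the screen cutoff are
labeled ``protective`` (hazard ratio < 1) or ``hazardous`` (hazard ratio
> 1); the screen is deliberately not multiplicity-adjusted.

The partial likelihood is maximized by Newton-Raphson with Efron's tie
approximation (Breslow available for cross-checks). A dedicated
single-covariate implementation is used because the screens fit one model
per CpG across tens of thousands of CpGs; each iteration is O(n) in numpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CoxFit:
    coefficient: float
    standard_error: float
    hazard_ratio: float
    wald_z: float
    wald_p: float
    n_samples: int
    n_events: int
    converged: bool
    loglik: float = np.nan


def _partial_lik_derivs(beta, x, r_groups, d_sizes, event_x_sum, first_risk, event_pos, group_inv, ties):
    """(loglik, gradient, observed information) of the partial likelihood at beta."""
    risk = np.exp(beta * x)
    rx = risk * x
    rx2 = rx * x
    S0 = np.cumsum(risk[::-1])[::-1]
    S1 = np.cumsum(rx[::-1])[::-1]
    S2 = np.cumsum(rx2[::-1])[::-1]
    R0 = S0[first_risk]
    R1 = S1[first_risk]
    R2 = S2[first_risk]
    loglik = beta * event_x_sum
    grad = event_x_sum
    info = 0.0
    if ties == "efron":
        D0 = np.bincount(group_inv, weights=risk[event_pos], minlength=len(d_sizes))
        D1 = np.bincount(group_inv, weights=rx[event_pos], minlength=len(d_sizes))
        D2 = np.bincount(group_inv, weights=rx2[event_pos], minlength=len(d_sizes))
        for l in range(int(d_sizes.max())):
            mask = d_sizes > l
            f = l / d_sizes[mask]
            den = R0[mask] - f * D0[mask]
            n1 = (R1[mask] - f * D1[mask]) / den
            n2 = (R2[mask] - f * D2[mask]) / den
            loglik -= np.log(den).sum()
            grad -= n1.sum()
            info += (n2 - n1 * n1).sum()
    elif ties == "breslow":
        n1 = R1 / R0
        loglik -= (d_sizes * np.log(R0)).sum()
        grad -= (d_sizes * n1).sum()
        info += (d_sizes * (R2 / R0 - n1 * n1)).sum()
    else:
        raise ValueError(f"unknown tie method {ties!r}")
    return loglik, grad, info


def cox_fit_univariate(
    covariate,
    time,
    event,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a single-covariate Cox model by Newton-Raphson.

    Convergence: |change in beta| < ``tol``. Monotone-likelihood data (the
    coefficient diverging) yields ``converged=False`` with ``wald_p`` NaN
    rather than an exception.
    """
    x = np.asarray(covariate, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    keep = ~(np.isnan(x) | np.isnan(t))
    x, t, e = x[keep], t[keep], e[keep]
    n = len(x)
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("no events")
    if np.ptp(x) == 0:
        raise ValueError("degenerate covariate (constant)")
    center = x.mean()

    order = np.argsort(t, kind="mergesort")
    t_s, e_s = t[order], e[order]
    x_s = x[order] - center
    event_pos = np.flatnonzero(e_s == 1)
    uniq_times, group_inv = np.unique(t_s[event_pos], return_inverse=True)
    d_sizes = np.bincount(group_inv).astype(float)
    first_risk = np.searchsorted(t_s, uniq_times, side="left")
    event_x_sum = x_s[event_pos].sum()

    beta = 0.0
    loglik, grad, info = _partial_lik_derivs(
        beta, x_s, None, d_sizes, event_x_sum, first_risk, event_pos, group_inv, ties
    )
    converged = False
    for _ in range(max_iter):
        if info <= 0 or not np.isfinite(info):
            break
        step = grad / info
        step = np.clip(step, -2.0, 2.0)  # damp early overshoot
        new_beta = beta + step
        new_ll, new_grad, new_info = _partial_lik_derivs(
            new_beta, x_s, None, d_sizes, event_x_sum, first_risk, event_pos, group_inv, ties
        )
        # step-halving if the likelihood worsened
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _partial_lik_derivs(
                new_beta, x_s, None, d_sizes, event_x_sum, first_risk, event_pos, group_inv, ties
            )
            halvings += 1
        delta = new_beta - beta
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(beta) > 100:  # monotone likelihood
            break
        if abs(delta) < tol:
            converged = True
            break

    if not converged or info <= 0:
        return CoxFit(beta, np.nan, np.exp(np.clip(beta, -700, 700)), np.nan, np.nan, n, n_events, False, loglik)
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxFit(beta, se, float(np.exp(beta)), z, max(p, np.nextafter(0, 1)), n, n_events, True, loglik)


def _categorize(p, hr, p_cut):
    if np.isfinite(p) and p < p_cut:
        if hr < 1:
            return "protective"
        if hr > 1:
            return "hazardous"
    return "none"


def screen_survival_cpgs(
    beta: pd.DataFrame,
    clinical: pd.DataFrame,
    stratum: tuple | None = None,
    p_cut: float = 0.02,
    min_samples: int = 20,
    min_events: int = 5,
    ties: str = "efron",
) -> pd.DataFrame:
    """Per-CpG univariate Cox screen within an optional subtype stratum.

    ``stratum`` is ``(clinical_column, label)``, e.g. ``("ER", "ER-")``;
    ``None`` screens all samples. Samples missing time, event or the CpG's
    beta are dropped per CpG (pairwise-complete). Untestable CpGs (too few
    samples/events, constant beta, non-convergence) are flagged.
    """
    clin = clinical.dropna(subset=["survival_time", "event"])
    if stratum is not None:
        column, label = stratum
        if column not in clin.columns:
            raise ValueError(f"no clinical column {column!r}; available: {list(clin.columns)}")
        available = sorted(clin[column].dropna().unique())
        if label not in available:
            raise ValueError(f"stratum label {label!r} not in column {column!r}; available: {available}")
        clin = clin[clin[column] == label]
    samples = [s for s in beta.columns if s in set(clin["sample_id"])]
    if len(samples) < min_samples:
        raise ValueError(f"stratum selects {len(samples)} samples; floor is {min_samples}")
    clin = clin.set_index("sample_id").loc[samples]
    time = clin["survival_time"].to_numpy(float)
    event = clin["event"].to_numpy(int)
    if event.sum() < min_events:
        raise ValueError(f"stratum has {int(event.sum())} events; floor is {min_events}")
    values = beta[samples].to_numpy(float)

    rows = []
    for i, cpg in enumerate(beta.index):
        x = values[i]
        ok = ~np.isnan(x)
        if ok.sum() < min_samples or event[ok].sum() < min_events or np.ptp(x[ok]) == 0:
            rows.append((cpg, np.nan, np.nan, np.nan, np.nan, np.nan, int(ok.sum()), int(event[ok].sum()), False, "untested"))
            continue
        fit = cox_fit_univariate(x[ok], time[ok], event[ok], ties=ties)
        cat = _categorize(fit.wald_p, fit.hazard_ratio, p_cut) if fit.converged else "untested"
        rows.append(
            (cpg, fit.coefficient, fit.standard_error, fit.hazard_ratio, fit.wald_z,
             fit.wald_p, fit.n_samples, fit.n_events, fit.converged, cat)
        )
    out = pd.DataFrame(
        rows,
        columns=["cpg_id", "coefficient", "se", "hazard_ratio", "wald_z", "wald_p",
                 "n", "n_events", "converged", "category"],
    )
    out["stratum"] = "all" if stratum is None else f"{stratum[0]}={stratum[1]}"
    return out
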