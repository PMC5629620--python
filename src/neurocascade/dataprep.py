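"""Preprocessing of the pulse-chase measurement tables.

Two transformations take the raw observations to the quantities the fit
uses:

1. **Re-proportioning.**  At intermediate timepoints, cells transiting from
   ANP to NB are picked up by both markers, so the observed per-type
   proportions sum to more than 1.  With the target joint ANP+NB proportion
   d_t = 1 - (NSC + GC + apoptotic fraction) and an excess
   e = p_ANP + p_NB - d_t, a fraction alpha of the double-counted excess is
   removed from NB and 1 - alpha from ANP (alpha = 1/2 absent prior
   knowledge):

       ANP' =  alpha p_ANP + (alpha - 1) p_NB + (1 - alpha) d_t
       NB'  = -alpha p_ANP + (1 - alpha) p_NB +      alpha  d_t

   Uncertainty propagates through the linear map (independent inputs).

2. **Counts from proportions.**  With the total BrdU+ count Y ~ N(mu_Y,
   sigma_Y^2), the per-type proportion P ~ N(mu_P, sigma_P^2) independent of
   Y, and X | Y, P ~ Binomial(Y, P),

       E[X] = Ybar * Pbar
       V[X] = S_P^2 (Ybar^2 + S_Y^2 - Ybar) + Pbar^2 (S_Y^2 - Ybar) + Ybar Pbar.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ObservedDataset",
    "AdjustedDataset",
    "reproportion",
    "counts_from_proportions",
    "adjust_dataset",
    "measurements",
]

PROPORTION_TYPES = ("NSC", "ANP", "NB", "GC")
DEFAULT_ADJUST_TIMES = (1.0, 2.0, 4.0, 8.0)


@dataclass
class ObservedDataset:
    """Raw measurement tables.

    ``counts``: per timepoint (``time_days``) the number of animals ``n``,
    total BrdU+ mean/sem and apoptotic BrdU+ mean/sem.
    ``proportions``: per timepoint and cell type, proportion mean/sem on the
    0-1 scale with the per-experiment animal count (NaN where unavailable).
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"time_days", "n", "total_mean", "total_sem", "apop_mean", "apop_sem"}
        if not need <= set(self.counts.columns):
            raise ValueError(f"counts table must have columns {sorted(need)}")
        for typ in PROPORTION_TYPES:
            for col in (f"{typ.lower()}_mean", f"{typ.lower()}_sem"):
                if col not in self.proportions.columns:
                    raise ValueError(f"proportions table missing column {col}")
        for df in (self.counts, self.proportions):
            numeric = df.drop(columns=["time_days"]).to_numpy(dtype=float)
            if np.nanmin(numeric) < 0:
                raise ValueError("means, sems and sample sizes must be nonnegative")

    def apoptotic_fraction(self, time_days: float) -> float:
        row = self.counts.loc[self.counts.time_days == time_days]
        if row.empty:
            raise KeyError(f"no count data at t={time_days} d")
        return float(row.apop_mean.iloc[0] / row.total_mean.iloc[0])


@dataclass
class AdjustedDataset:
    """Adjusted proportions and derived count estimates (both per timepoint)."""

    proportions: pd.DataFrame
    cell_counts: pd.DataFrame
    alpha: float


def reproportion(
    p_anp: float,
    p_nb: float,
    p_other_sum: float,
    alpha: float = 0.5,
    sem_anp: float = 0.0,
    sem_nb: float = 0.0,
):
    """Remove the double-counted ANP/NB excess.

    Returns ``(anp_adj, nb_adj, sem_anp_adj, sem_nb_adj)``.  When there is
    no excess (the observed proportions already fit under the target joint
    proportion) the inputs are returned unchanged.
    """
    for name, v in (("p_anp", p_anp), ("p_nb", p_nb), ("p_other_sum", p_other_sum)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    d_t = 1.0 - p_other_sum
    if d_t <= 0.0:
        raise ValueError(
            f"other proportions sum to {p_other_sum}; no room for ANP+NB"
        )
    excess = p_anp + p_nb - d_t
    if excess < 0.0:
        return p_anp, p_nb, sem_anp, sem_nb
    anp_adj = alpha * p_anp + (alpha - 1.0) * p_nb + (1.0 - alpha) * d_t
    nb_adj = -alpha * p_anp + (1.0 - alpha) * p_nb + alpha * d_t
    # linear propagation through X' = A X + B with COV[X1, X2] = 0
    var_anp = alpha**2 * sem_anp**2 + (alpha - 1.0) ** 2 * sem_nb**2
    var_nb = alpha**2 * sem_anp**2 + (1.0 - alpha) ** 2 * sem_nb**2
    return anp_adj, nb_adj, math.sqrt(var_anp), math.sqrt(var_nb)


def counts_from_proportions(y_mean: float, y_sem: float, p_mean: float, p_sem: float):
    """Mean and sem of a per-type count from the total count and the type's
    proportion.  Returns ``(mean, sem)``."""
    if y_mean <= 0:
        raise ValueError(f"total count mean must be positive, got {y_mean}")
    if not (0.0 <= p_mean <= 1.0):
        raise ValueError(f"proportion mean must be in [0, 1], got {p_mean}")
    e_x = y_mean * p_mean
    v_x = (
        p_sem**2 * (y_mean**2 + y_sem**2 - y_mean)
        + p_mean**2 * (y_sem**2 - y_mean)
        + y_mean * p_mean
    )
    if v_x < 0.0:
        warnings.warn(
            "negative count variance from the delta formula; "
            "clamping at the binomial variance"
        )
        v_x = y_mean * p_mean * (1.0 - p_mean)
    return e_x, math.sqrt(v_x)


def adjust_dataset(
    observed: ObservedDataset,
    alpha: float = 0.5,
    adjust_times=DEFAULT_ADJUST_TIMES,
) -> AdjustedDataset:
    """Apply re-proportioning at the double-labeled timepoints, then convert
    every available proportion to a count estimate."""
    props = observed.proportions.copy().reset_index(drop=True)
    for t in adjust_times:
        mask = props.time_days == t
        if not mask.any():
            continue
        i = props.index[mask][0]
        row = props.loc[i]
        if np.isnan(row.anp_mean) or np.isnan(row.nb_mean):
            continue
        other = np.nansum([row.nsc_mean, row.gc_mean]) + observed.apoptotic_fraction(t)
        anp, nb, s_anp, s_nb = reproportion(
            row.anp_mean, row.nb_mean, other, alpha, row.anp_sem, row.nb_sem
        )
        props.loc[i, ["anp_mean", "anp_sem", "nb_mean", "nb_sem"]] = (
            anp, s_anp, nb, s_nb,
        )

    rows = []
    counts = observed.counts.set_index("time_days")
    for _, row in props.iterrows():
        t = row.time_days
        if t not in counts.index:
            continue
        y_mean, y_sem = counts.loc[t, "total_mean"], counts.loc[t, "total_sem"]
        rec = {"time_days": t, "total_mean": y_mean, "total_sem": y_sem,
               "apop_mean": counts.loc[t, "apop_mean"],
               "apop_sem": counts.loc[t, "apop_sem"]}
        for typ in PROPORTION_TYPES:
            p_mean, p_sem = row[f"{typ.lower()}_mean"], row[f"{typ.lower()}_sem"]
            if np.isnan(p_mean):
                rec[f"{typ.lower()}_mean"], rec[f"{typ.lower()}_sem"] = np.nan, np.nan
                continue
            e_x, s_x = counts_from_proportions(y_mean, y_sem, p_mean, p_sem)
            rec[f"{typ.lower()}_mean"], rec[f"{typ.lower()}_sem"] = e_x, s_x
        rows.append(rec)
    return AdjustedDataset(
        proportions=props, cell_counts=pd.DataFrame(rows), alpha=alpha
    )


def measurements(
    observed: ObservedDataset, adjusted: AdjustedDataset
) -> pd.DataFrame:
    """The non-zero measurement set the objective sums over.

    One row per (time, class) with columns ``time_days``, ``time_h``,
    ``cls``, ``mean``, ``sem``: all non-zero total and apoptotic counts plus
    all non-zero per-type count estimates.
    """
    rows = []
    for _, r in observed.counts.iterrows():
        if r.total_mean > 0:
            rows.append((r.time_days, "Total", r.total_mean, r.total_sem))
        if r.apop_mean > 0:
            rows.append((r.time_days, "Apop", r.apop_mean, r.apop_sem))
    for _, r in adjusted.cell_counts.iterrows():
        for typ in PROPORTION_TYPES:
            mean = r[f"{typ.lower()}_mean"]
            if not np.isnan(mean) and mean > 0:
                rows.append((r.time_days, typ, mean, r[f"{typ.lower()}_sem"]))
    df = pd.DataFrame(rows, columns=["time_days", "cls", "mean", "sem"])
    df.insert(1, "time_h", df.time_days * 24.0)
    return df.sort_values(["time_days", "cls"]).reset_index(drop=True)
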