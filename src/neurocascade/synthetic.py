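"""Synthetic pulse-chase experiments with known ground truth.

The generator emulates the structure of the real measurement tables so the
whole preprocessing-and-fitting pipeline can be exercised against a known
parameter set: per-timepoint groups of animals, each animal an independent
stochastic realization of the labeled cohort; multiplicative Gaussian
measurement noise on counts; and, at the intermediate timepoints, an
artificial ANP/NB double-labeling inflation — a fraction ``overlap`` of the
cells currently in the ANP-to-NB transition window is added to *both* the
ANP and NB proportions, so the per-type proportions sum to more than one
and the re-proportioning stage has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataprep import ObservedDataset
from .params import CascadeParameters
from .simulate import CascadeSimulator, _CurveRecorder
from .transition import OBSERVABLE_CLASSES

__all__ = ["SyntheticDesign", "generate_experiment", "DEFAULT_TIMEPOINTS_H"]

# the pulse-chase observation design: 2 h, 12 h, then days 1-32
DEFAULT_TIMEPOINTS_H = (
    2.0, 12.0, 24.0, 48.0, 72.0, 96.0, 192.0, 264.0, 360.0, 432.0, 528.0, 768.0,
)
DEFAULT_ADJUST_TIMES_H = (24.0, 48.0, 96.0, 192.0)


@dataclass(frozen=True)
class SyntheticDesign:
    """Ground truth and measurement design of a synthetic experiment.

    ``cv`` is the multiplicative measurement-noise coefficient of variation
    on counts; ``overlap`` the double-labeling inflation fraction applied at
    ``adjust_times_h``.
    """

    params: CascadeParameters
    timepoints_h: tuple = DEFAULT_TIMEPOINTS_H
    n_animals: int = 5
    cv: float = 0.10
    overlap: float = 0.3
    adjust_times_h: tuple = DEFAULT_ADJUST_TIMES_H
    include_nsc: bool = True

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if not (0.0 <= self.overlap <= 0.5):
            raise ValueError("overlap must be in [0, 0.5]")


def generate_experiment(design: SyntheticDesign, rng: np.random.Generator | int | None = None):
    """Simulate one synthetic experiment.

    Returns ``(ObservedDataset, ground_truth)`` where the dataset has the
    same table layout the preprocessing reads and ``ground_truth`` records
    the generating parameters and design.
    """
    rng = np.random.default_rng(rng)
    sim = CascadeSimulator(design.params, include_nsc=design.include_nsc)
    cls_map = sim.class_of_comp()
    tps = np.sort(np.asarray(design.timepoints_h, dtype=float))
    n_t, n_a = len(tps), design.n_animals

    # one independent cohort realization per animal, observed at all times
    raw = np.zeros((n_a, n_t, len(OBSERVABLE_CLASSES)))
    for a in range(n_a):
        rec = _CurveRecorder(tps, cls_map)
        sim.run_replicate(rec, rng)
        raw[a] = rec.counts()
    if design.cv > 0:
        noise = np.clip(1.0 + design.cv * rng.standard_normal(raw.shape), 0.0, None)
        raw = raw * noise

    ci = {c: OBSERVABLE_CLASSES.index(c) for c in OBSERVABLE_CLASSES}
    total = raw.sum(axis=2)
    apop = raw[:, :, ci["Apop"]]
    nsc = raw[:, :, ci["NSC"]]
    anp = raw[:, :, ci["ANP"]] + raw[:, :, ci["ANP_NB"]] + raw[:, :, ci["ANP_APOP"]]
    window = raw[:, :, ci["ANP_NB"]]  # the ANP->NB transition window
    nb = raw[:, :, ci["NB"]]
    gc = raw[:, :, ci["GC"]]

    with np.errstate(invalid="ignore", divide="ignore"):
        p_nsc = np.where(total > 0, nsc / total, 0.0)
        p_anp = np.where(total > 0, anp / total, 0.0)
        p_nb = np.where(total > 0, nb / total, 0.0)
        p_gc = np.where(total > 0, gc / total, 0.0)
        p_win = np.where(total > 0, window / total, 0.0)
    adjust = np.isin(tps, np.asarray(design.adjust_times_h))
    p_anp = p_anp + design.overlap * p_win * adjust[None, :]
    p_nb = p_nb + design.overlap * p_win * adjust[None, :]

    def mean_sem(x):
        m = x.mean(axis=0)
        s = x.std(axis=0, ddof=1) / np.sqrt(n_a) if n_a > 1 else np.zeros(n_t)
        return m, s

    t_m, t_s = mean_sem(total)
    a_m, a_s = mean_sem(apop)
    counts = pd.DataFrame(
        {
            "time_days": tps / 24.0,
            "n": n_a,
            "total_mean": t_m,
            "total_sem": t_s,
            "apop_mean": a_m,
            "apop_sem": a_s,
        }
    )
    prop = {"time_days": tps / 24.0, "n_exp1": n_a, "n_exp2": n_a}
    for name, arr in (("nsc", p_nsc), ("anp", p_anp), ("nb", p_nb), ("gc", p_gc)):
        m, s = mean_sem(arr)
        prop[f"{name}_mean"], prop[f"{name}_sem"] = m, s
    proportions = pd.DataFrame(prop)

    ground_truth = {
        "params": design.params.to_dict(),
        "n_animals": n_a,
        "cv": design.cv,
        "overlap": design.overlap,
        "timepoints_h": list(map(float, tps)),
        "adjust_times_h": list(map(float, design.adjust_times_h)),
    }
    return ObservedDataset(counts=counts, proportions=proportions), ground_truth
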