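"""Compartment bookkeeping and the expected-progeny transition matrix.

Each compartment is one bookkeeping state of the multitype age-dependent
branching process: a cell-cycle phase of one ANP (or NSC) generation, a
transition stage (ANP-NB, ANP-Apop), a post-mitotic stage (NB, optional IN),
the apoptotic clearance stage, or an absorbing terminal fate (GC, Astro).

Entry ``m[i, j]`` is the expected number of type-``j`` cells produced when a
type-``i`` cell leaves its stage.  Death at the end of a cycle phase with
rate ``d_i`` routes to the apoptotic compartment; a surviving G2M cell of a
generation eligible for renewal splits into two daughters that continue with
renewal probability ``p`` or become non-proliferating ANPs headed to NB
(probability 1 - d_ANP) or apoptosis (d_ANP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import ShiftedGamma
from .params import CascadeParameters

__all__ = ["TransitionMatrix", "build_transition_matrix", "OBSERVABLE_CLASSES"]

# Fine-grained observable classes; "ANP" in reported curves aggregates the
# cycling phases with the two transition stages (their occupants are still
# phenotypically ANPs, though non-proliferating).
OBSERVABLE_CLASSES = ("NSC", "ANP", "ANP_NB", "ANP_APOP", "NB", "GC", "Astro", "Apop")


@dataclass
class TransitionMatrix:
    """Ordered compartments, expected-progeny matrix and per-stage durations.

    ``durations[i]`` is ``None`` for absorbing compartments (GC, Astro);
    their lifetime cdf is identically zero (they never leave).
    """

    labels: list[str]
    m: np.ndarray
    durations: list[ShiftedGamma | None]
    classes: list[str]
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        n = len(self.labels)
        if self.m.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if np.any(self.m < 0):
            raise ValueError("expected-progeny entries must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]

    @property
    def absorbing_mask(self) -> np.ndarray:
        return np.array([d is None for d in self.durations])

    @property
    def s_phase_mask(self) -> np.ndarray:
        return np.array([lab.split("(")[0].endswith("_S") for lab in self.labels])

    def class_weights(self, classes=OBSERVABLE_CLASSES) -> np.ndarray:
        """Indicator matrix (n_compartments x n_classes)."""
        w = np.zeros((self.n, len(classes)))
        for i, cls in enumerate(self.classes):
            if cls in classes:
                w[i, classes.index(cls)] = 1.0
        return w

    def spectral_radius(self) -> float:
        """Spectral radius of m restricted to non-absorbing compartments."""
        keep = ~self.absorbing_mask
        sub = self.m[np.ix_(keep, keep)]
        return float(np.max(np.abs(np.linalg.eigvals(sub)))) if sub.size else 0.0

    def mean_durations(self) -> np.ndarray:
        """Expected stage durations; infinite for absorbing compartments."""
        return np.array([np.inf if d is None else d.mean for d in self.durations])


def build_transition_matrix(
    params: CascadeParameters,
    include_nsc: bool = True,
    include_absorbing: bool = True,
    include_in: bool | None = None,
) -> TransitionMatrix:
    """Assemble the compartment system for a parameter set.

    Compartment order: NSC generations (if included), ANP generations
    (G1/S/G2M per generation), ANP-NB, NB, optional IN, ANP-Apop, Apop,
    then absorbing GC and Astro (if included).
    """
    if include_in is None:
        include_in = params.in_stage is not None
    if include_in and params.in_stage is None:
        raise ValueError("include_in=True requires params.in_stage")

    labels: list[str] = []
    durations: list[ShiftedGamma | None] = []
    classes: list[str] = []

    def add(label: str, duration, cls: str) -> None:
        labels.append(label)
        durations.append(duration)
        classes.append(cls)

    b_nsc = params.nsc_divisions.max_divisions
    if include_nsc:
        for g in range(1, b_nsc + 1):
            add(f"NSC_G1({g})", params.nsc_g1.duration, "NSC")
            add(f"NSC_S({g})", params.nsc_s.duration, "NSC")
            add(f"NSC_G2M({g})", params.nsc_g2m.duration, "NSC")

    b = params.anp_divisions.max_divisions
    for g in range(1, b + 1):
        add(f"ANP_G1({g})", params.anp_g1.duration, "ANP")
        add(f"ANP_S({g})", params.anp_s.duration, "ANP")
        add(f"ANP_G2M({g})", params.anp_g2m.duration, "ANP")
    add("ANP-NB", params.anp_nb_duration, "ANP_NB")
    add("NB", params.nb.duration, "NB")
    if include_in:
        add("IN", params.in_stage.duration, "NB")
    add("ANP-Apop", params.anp_apop_duration, "ANP_APOP")
    add("Apop", params.apop_duration, "Apop")
    if include_absorbing:
        add("GC", None, "GC")
        add("Astro", None, "Astro")

    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    m = np.zeros((n, n))

    def has(label: str) -> bool:
        return label in idx

    def put(row: str, col: str, value: float) -> None:
        if has(col) and value != 0.0:
            m[idx[row], idx[col]] += value

    if include_nsc:
        a_n, p_n = params.nsc_divisions.min_divisions, params.nsc_divisions.renewal_prob
        for g in range(1, b_nsc + 1):
            put(f"NSC_G1({g})", f"NSC_S({g})", 1.0)
            put(f"NSC_S({g})", f"NSC_G2M({g})", 1.0)
            # asymmetric division: one newborn ANP, the NSC itself continues
            put(f"NSC_G2M({g})", "ANP_G1(1)", 1.0)
            if g < a_n:
                put(f"NSC_G2M({g})", f"NSC_G1({g + 1})", 1.0)
            elif g < b_nsc:
                put(f"NSC_G2M({g})", f"NSC_G1({g + 1})", p_n)
                put(f"NSC_G2M({g})", "Astro", 1.0 - p_n)
            else:
                put(f"NSC_G2M({g})", "Astro", 1.0)

    a, p = params.anp_divisions.min_divisions, params.anp_divisions.renewal_prob
    d_g1 = params.anp_g1.death_rate
    d_s = params.anp_s.death_rate
    d_g2m = params.anp_g2m.death_rate
    d_anp = params.d_anp
    s_g2m = 1.0 - d_g2m
    for g in range(1, b + 1):
        put(f"ANP_G1({g})", f"ANP_S({g})", 1.0 - d_g1)
        put(f"ANP_G1({g})", "Apop", d_g1)
        put(f"ANP_S({g})", f"ANP_G2M({g})", 1.0 - d_s)
        put(f"ANP_S({g})", "Apop", d_s)
        row = f"ANP_G2M({g})"
        put(row, "Apop", d_g2m)
        if g < a:
            put(row, f"ANP_G1({g + 1})", 2.0 * s_g2m)
        elif g < b:
            put(row, f"ANP_G1({g + 1})", 2.0 * p * s_g2m)
            put(row, "ANP-NB", 2.0 * s_g2m * (1.0 - p) * (1.0 - d_anp))
            put(row, "ANP-Apop", 2.0 * s_g2m * (1.0 - p) * d_anp)
        else:
            put(row, "ANP-NB", 2.0 * s_g2m * (1.0 - d_anp))
            put(row, "ANP-Apop", 2.0 * s_g2m * d_anp)

    put("ANP-NB", "NB", 1.0)
    put("ANP-Apop", "Apop", 1.0)
    d_nb = params.nb.death_rate
    put("NB", "IN" if include_in else "GC", 1.0 - d_nb)
    put("NB", "Apop", d_nb)
    if include_in:
        d_in = params.in_stage.death_rate
        put("IN", "GC", 1.0 - d_in)
        put("IN", "Apop", d_in)
    # Apop, GC and Astro rows are all zero.

    return TransitionMatrix(labels=labels, m=m, durations=durations, classes=classes)
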