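"""Event-based Monte-Carlo simulation of BrdU pulse-chase labeling curves.

A BrdU pulse labels every cell in S phase.  The simulator seeds a cohort of
labeled cells from the stationary S-phase occupancy, then traces each
lineage event by event: stage durations are drawn from the shifted-gamma
transit laws, death occurs at the end of a stage with the stage's death
rate, a surviving G2M cell divides into two labeled daughters, and every
lineage terminates in a granule cell, an astrocyte, or cleared apoptosis.

The number of division rounds N of an ANP clone is drawn once per founder
(P(N=a) = 1-p, geometric continuation up to b), so the realized progeny
count is exactly 2^N; for labeled cells picked up mid-cascade in generation
g, N is drawn conditioned on N >= g (the continuation decisions are
memoryless).  NSCs never die: each division round emits one labeled ANP and
the NSC finally becomes an astrocyte.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expectations import combined_stationary_state, labeled_initial_state
from .params import CascadeParameters
from .transition import OBSERVABLE_CLASSES, TransitionMatrix, build_transition_matrix

__all__ = [
    "LabeledCell",
    "LabelingCurve",
    "sample_initial_cohort",
    "simulate_cell",
    "simulate_labeling_curves",
    "simulate_steady_occupancy",
    "simulate_multitype",
]

_G1, _S, _G2M = 0, 1, 2


@dataclass(frozen=True)
class LabeledCell:
    """One labeled founder: where it is at t=0 and what its clone will do."""

    compartment: str  # e.g. "ANP_S(2)" or "NSC_S(1)"
    generation: int
    target_divisions: int  # clone-wide division count N (>= generation)
    entry_time: float = 0.0
    exit_time: float = 0.0  # scheduled end of the current stage

    def __post_init__(self) -> None:
        if self.exit_time < self.entry_time:
            raise ValueError("exit time must be >= entry time")
        if self.generation > self.target_divisions:
            raise ValueError("generation exceeds the clone's division target")

    @property
    def is_nsc(self) -> bool:
        return self.compartment.startswith("NSC")


@dataclass
class LabelingCurve:
    """Per-class BrdU+ counts at the observation timepoints.

    ``counts`` has shape (n_replicates, n_timepoints, n_classes) over the
    fine classes; ``observables()`` aggregates to the reported classes
    (ANP = cycling ANPs + ANP-NB + ANP-Apop occupants) and adds the Total.
    """

    timepoints: np.ndarray
    classes: tuple
    counts: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[0]

    def mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    def sem(self) -> np.ndarray:
        r = self.n_replicates
        if r == 1:
            return np.zeros_like(self.counts[0], dtype=float)
        return self.counts.std(axis=0, ddof=1) / np.sqrt(r)

    def _aggregate(self, values: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(values, columns=list(self.classes))
        out = pd.DataFrame({"time_h": self.timepoints})
        out["Total"] = df.sum(axis=1).to_numpy()
        out["Apop"] = df["Apop"].to_numpy()
        out["NSC"] = df["NSC"].to_numpy()
        out["ANP"] = (df["ANP"] + df["ANP_NB"] + df["ANP_APOP"]).to_numpy()
        out["NB"] = df["NB"].to_numpy()
        out["GC"] = df["GC"].to_numpy()
        out["Astro"] = df["Astro"].to_numpy()
        return out

    def observables(self) -> pd.DataFrame:
        """Replicate-mean observable curves (Total, Apop, NSC, ANP, NB, GC, Astro)."""
        return self._aggregate(self.mean())

    def observables_sem(self) -> pd.DataFrame:
        out = self._aggregate(np.zeros_like(self.counts[0], dtype=float))
        per_rep = np.stack(
            [self._aggregate(self.counts[r]).drop(columns="time_h").to_numpy()
             for r in range(self.n_replicates)]
        )
        sem = (
            per_rep.std(axis=0, ddof=1) / np.sqrt(self.n_replicates)
            if self.n_replicates > 1
            else np.zeros_like(per_rep[0])
        )
        out.loc[:, out.columns != "time_h"] = sem
        return out


# ---------------------------------------------------------------------------
# recorders


class _CurveRecorder:
    """Counts occupancy of each class at fixed timepoints via a difference
    array: an interval [t0, t1) increments every timepoint inside it."""

    def __init__(self, timepoints, class_of_comp):
        self.tp = list(timepoints)
        self.t_max = self.tp[-1]
        self.cls = class_of_comp
        self.diff = np.zeros((len(self.tp) + 1, int(class_of_comp.max()) + 1))

    def add(self, comp: int, t0: float, t1: float) -> None:
        i0 = bisect_left(self.tp, t0)
        i1 = bisect_left(self.tp, t1)
        if i0 != i1:
            c = self.cls[comp]
            self.diff[i0, c] += 1.0
            self.diff[i1, c] -= 1.0

    def counts(self) -> np.ndarray:
        return np.cumsum(self.diff[:-1], axis=0)


class _OccupancyRecorder:
    """Accumulates per-compartment person-time inside an averaging window."""

    def __init__(self, n_comps: int, window: tuple[float, float]):
        self.w0, self.w1 = window
        self.t_max = self.w1
        self.occ = np.zeros(n_comps)

    def add(self, comp: int, t0: float, t1: float) -> None:
        lo = t0 if t0 > self.w0 else self.w0
        hi = t1 if t1 < self.w1 else self.w1
        if hi > lo:
            self.occ[comp] += hi - lo

    def time_average(self) -> np.ndarray:
        return self.occ / (self.w1 - self.w0)


class _TraceRecorder:
    def __init__(self, labels):
        self.labels = labels
        self.t_max = np.inf
        self.events: list[tuple[str, float, float]] = []

    def add(self, comp: int, t0: float, t1: float) -> None:
        self.events.append((self.labels[comp], t0, t1))


# ---------------------------------------------------------------------------
# the engine


class CascadeSimulator:
    """Shared machinery: compartment indices, stationary seeding, clone sim."""

    def __init__(
        self,
        params: CascadeParameters,
        include_nsc: bool = True,
        residual_mode: str = "stationary",
    ):
        if residual_mode not in ("stationary", "start"):
            raise ValueError("residual_mode must be 'stationary' or 'start'")
        self.params = params
        self.include_nsc = include_nsc
        self.residual_mode = residual_mode
        self.tm = build_transition_matrix(params, include_nsc=include_nsc)
        idx = self.tm.index
        b = params.anp_divisions.max_divisions
        self._anp_phase_idx = [
            (idx(f"ANP_G1({g})"), idx(f"ANP_S({g})"), idx(f"ANP_G2M({g})"))
            for g in range(1, b + 1)
        ]
        if include_nsc:
            bn = params.nsc_divisions.max_divisions
            self._nsc_phase_idx = [
                (idx(f"NSC_G1({g})"), idx(f"NSC_S({g})"), idx(f"NSC_G2M({g})"))
                for g in range(1, bn + 1)
            ]
        self._i_anp_nb = idx("ANP-NB")
        self._i_nb = idx("NB")
        self._i_in = idx("IN") if "IN" in self.tm.labels else None
        self._i_anp_apop = idx("ANP-Apop")
        self._i_apop = idx("Apop")
        self._i_gc = idx("GC")
        self._i_astro = idx("Astro")
        # (shape, scale, shift) per stage, pulled out of the dataclasses
        p = params

        def coef(dist):
            return (dist.shape, dist.scale, dist.shift)

        self._c_g1 = coef(p.anp_g1.duration)
        self._c_s = coef(p.anp_s.duration)
        self._c_g2m = coef(p.anp_g2m.duration)
        self._c_anp_nb = coef(p.anp_nb_duration)
        self._c_anp_apop = coef(p.anp_apop_duration)
        self._c_nb = coef(p.nb.duration)
        self._c_in = coef(p.in_stage.duration) if p.in_stage is not None else None
        self._c_apop = coef(p.apop_duration)
        if include_nsc:
            self._c_nsc = (
                coef(p.nsc_g1.duration),
                coef(p.nsc_s.duration),
                coef(p.nsc_g2m.duration),
            )
        self._stationary = None

    # -- seeding ------------------------------------------------------------

    def stationary(self):
        if self._stationary is None:
            self._stationary = combined_stationary_state(self.params, self.tm)
        return self._stationary

    def labeled_means(self) -> np.ndarray:
        return labeled_initial_state(self.tm, self.stationary())

    def sample_initial_cohort(self, rng: np.random.Generator) -> list[LabeledCell]:
        """Poisson-sample labeled cells per S-phase compartment; residual
        S time per cell from the stationary age distribution (or a fresh
        full draw in 'start' mode)."""
        means = self.labeled_means()
        cohort: list[LabeledCell] = []
        for i in np.flatnonzero(means > 0):
            label = self.tm.labels[i]
            n = int(rng.poisson(means[i]))
            if n == 0:
                continue
            gen = int(label.split("(")[1].rstrip(")"))
            dist = self.tm.durations[i]
            if self.residual_mode == "stationary":
                rem = np.atleast_1d(dist.rvs_residual(rng, size=n))
            else:
                rem = np.atleast_1d(dist.rvs(rng, size=n))
            if label.startswith("NSC"):
                law, kind = self.params.nsc_divisions, "NSC"
            else:
                law, kind = self.params.anp_divisions, "ANP"
            a, b, p = law.min_divisions, law.max_divisions, law.renewal_prob
            for r in rem:
                cohort.append(
                    LabeledCell(
                        compartment=label,
                        generation=gen,
                        target_divisions=_draw_target(rng, a, b, p, gen),
                        entry_time=0.0,
                        exit_time=float(r),
                    )
                )
        return cohort

    # -- clone simulation -----------------------------------------------------

    def _enter_apop(self, t, rec, rng):
        k, s, v = self._c_apop
        rec.add(self._i_apop, t, t + v + s * rng.gamma(k))

    def _nonproliferating_fate(self, t, rec, rng):
        """A surviving daughter of the final division: transition to NB
        (prob 1 - d_ANP) or to apoptosis (d_ANP), via the transition stage."""
        p = self.params
        if rng.random() < p.d_anp:
            k, s, v = self._c_anp_apop
            t1 = t + v + s * rng.gamma(k)
            rec.add(self._i_anp_apop, t, t1)
            self._enter_apop(t1, rec, rng)
            return
        k, s, v = self._c_anp_nb
        t1 = t + v + s * rng.gamma(k)
        rec.add(self._i_anp_nb, t, t1)
        self._nb_fate(t1, rec, rng)

    def _nb_fate(self, t, rec, rng):
        p = self.params
        k, s, v = self._c_nb
        t1 = t + v + s * rng.gamma(k)
        rec.add(self._i_nb, t, t1)
        if rng.random() < p.nb.death_rate:
            self._enter_apop(t1, rec, rng)
            return
        if self._i_in is not None:
            k, s, v = self._c_in
            t2 = t1 + v + s * rng.gamma(k)
            rec.add(self._i_in, t1, t2)
            if rng.random() < self.params.in_stage.death_rate:
                self._enter_apop(t2, rec, rng)
                return
            t1 = t2
        rec.add(self._i_gc, t1, np.inf)

    def _run_anp_clone(self, t, gen, phase, remaining, target_n, rec, rng):
        """Trace one ANP cell and all its descendants (clone division target
        ``target_n``).  ``remaining`` overrides the first stage's duration
        (labeled mid-stage founders); None draws afresh."""
        p = self.params
        d_g1, d_s = p.anp_g1.death_rate, p.anp_s.death_rate
        d_g2m = p.anp_g2m.death_rate
        stack = [(t, gen, phase, remaining)]
        while stack:
            t, gen, phase, rem = stack.pop()
            if t > rec.t_max:
                continue
            alive = True
            while alive:
                i_g1, i_s, i_g2m = self._anp_phase_idx[gen - 1]
                if phase == _G1:
                    k, s, v = self._c_g1
                    dur = rem if rem is not None else v + s * rng.gamma(k)
                    rem = None
                    rec.add(i_g1, t, t + dur)
                    t += dur
                    if rng.random() < d_g1:
                        self._enter_apop(t, rec, rng)
                        break
                    phase = _S
                elif phase == _S:
                    k, s, v = self._c_s
                    dur = rem if rem is not None else v + s * rng.gamma(k)
                    rem = None
                    rec.add(i_s, t, t + dur)
                    t += dur
                    if rng.random() < d_s:
                        self._enter_apop(t, rec, rng)
                        break
                    phase = _G2M
                else:  # G2M
                    k, s, v = self._c_g2m
                    dur = rem if rem is not None else v + s * rng.gamma(k)
                    rem = None
                    rec.add(i_g2m, t, t + dur)
                    t += dur
                    if rng.random() < d_g2m:
                        self._enter_apop(t, rec, rng)
                        break
                    if gen < target_n:
                        stack.append((t, gen + 1, _G1, None))
                        gen += 1
                        phase = _G1
                    else:
                        self._nonproliferating_fate(t, rec, rng)
                        self._nonproliferating_fate(t, rec, rng)
                        break

    def _run_nsc(self, t, gen, phase, remaining, target_n, rec, rng):
        """Trace one NSC: emits one newborn labeled ANP per division round
        (each starting its own clone), then becomes an astrocyte."""
        law = self.params.anp_divisions
        a, b, p = law.min_divisions, law.max_divisions, law.renewal_prob
        rem = remaining
        for g in range(gen, target_n + 1):
            if t > rec.t_max:
                return
            i_g1, i_s, i_g2m = self._nsc_phase_idx[g - 1]
            for ph, idx_c in ((_G1, i_g1), (_S, i_s), (_G2M, i_g2m)):
                if g == gen and ph < phase:
                    continue
                k, s, v = self._c_nsc[ph]
                dur = rem if (rem is not None and g == gen and ph == phase) else (
                    v + s * rng.gamma(k)
                )
                if g == gen and ph == phase:
                    rem = None
                rec.add(idx_c, t, t + dur)
                t += dur
            # asymmetric division: one newborn ANP, clone target drawn afresh
            self._run_anp_clone(t, 1, _G1, None, _draw_target(rng, a, b, p, 1), rec, rng)
        rec.add(self._i_astro, t, np.inf)

    def simulate_founder(self, cell: LabeledCell, rec, rng: np.random.Generator) -> None:
        remaining = cell.exit_time - cell.entry_time
        stem = cell.compartment.split("(")[0]
        try:
            phase = {"G1": _G1, "S": _S, "G2M": _G2M}[stem.split("_")[1]]
        except (IndexError, KeyError):
            raise ValueError(
                f"founders must start in a cycling phase, got {cell.compartment}"
            ) from None
        if cell.is_nsc:
            self._run_nsc(
                cell.entry_time, cell.generation, phase, remaining,
                cell.target_divisions, rec, rng,
            )
        else:
            self._run_anp_clone(
                cell.entry_time, cell.generation, phase, remaining,
                cell.target_divisions, rec, rng,
            )

    def run_replicate(self, rec, rng: np.random.Generator) -> int:
        cohort = self.sample_initial_cohort(rng)
        for cell in cohort:
            self.simulate_founder(cell, rec, rng)
        return len(cohort)

    def class_of_comp(self) -> np.ndarray:
        return np.array([OBSERVABLE_CLASSES.index(c) for c in self.tm.classes])


def _draw_target(rng, a: int, b: int, p: float, gen: int) -> int:
    """Clone division count N | N >= gen: minimum a, geometric continuation
    with probability p per extra round, capped at b."""
    n = a if gen < a else gen
    while n < b and rng.random() < p:
        n += 1
    return n


# ---------------------------------------------------------------------------
# public operations


def sample_initial_cohort(
    params: CascadeParameters,
    rng: np.random.Generator,
    include_nsc: bool = True,
    residual_mode: str = "stationary",
) -> list[LabeledCell]:
    """Draw the BrdU-labeled cohort at injection time (Poisson per S
    compartment around the stationary occupancy)."""
    sim = CascadeSimulator(params, include_nsc=include_nsc, residual_mode=residual_mode)
    return sim.sample_initial_cohort(rng)


def simulate_cell(
    cell: LabeledCell,
    params: CascadeParameters,
    rng: np.random.Generator,
    include_nsc: bool = True,
) -> list[tuple[str, float, float]]:
    """Trace one labeled cell and its descendants; returns the event list
    of (compartment, entry, exit) ending in GC, Astro or cleared apoptosis."""
    sim = CascadeSimulator(params, include_nsc=include_nsc)
    rec = _TraceRecorder(sim.tm.labels)
    sim.simulate_founder(cell, rec, rng)
    return rec.events


def simulate_labeling_curves(
    params: CascadeParameters,
    timepoints,
    n_replicates: int = 10,
    rng: np.random.Generator | int | None = None,
    include_nsc: bool = True,
    residual_mode: str = "stationary",
) -> LabelingCurve:
    """Simulate per-class BrdU+ labeling curves, averaged over replicates.

    Each replicate draws an independent labeled cohort and traces every
    lineage; counts at each timepoint bin cells by observable class.
    """
    timepoints = np.sort(np.asarray(timepoints, dtype=float))
    if timepoints.size == 0 or timepoints[0] < 0:
        raise ValueError("timepoints must be nonnegative")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(rng)
    sim = CascadeSimulator(params, include_nsc=include_nsc, residual_mode=residual_mode)
    cls_map = sim.class_of_comp()
    counts = np.zeros((n_replicates, len(timepoints), len(OBSERVABLE_CLASSES)))
    total_founders = 0
    for r in range(n_replicates):
        rec = _CurveRecorder(timepoints, cls_map)
        total_founders += sim.run_replicate(rec, rng)
        counts[r] = rec.counts()
    if total_founders == 0:
        import warnings

        warnings.warn("empty labeled cohort in every replicate; curves are all zero")
    return LabelingCurve(
        timepoints=timepoints, classes=OBSERVABLE_CLASSES, counts=counts
    )


def simulate_steady_occupancy(
    params: CascadeParameters,
    horizon: float = 2000.0,
    window: tuple[float, float] = (800.0, 2000.0),
    n_replicates: int = 8,
    rng: np.random.Generator | int | None = None,
    include_nsc: bool = True,
):
    """Long-run time-averaged occupancy per compartment under constant
    Poisson influx (the simulation counterpart of the stationary state).

    Returns (labels, mean, sem) with the time averages taken over ``window``
    and the sem across replicates.
    """
    rng = np.random.default_rng(rng)
    sim = CascadeSimulator(params, include_nsc=include_nsc)
    law = params.anp_divisions
    a, b, p = law.min_divisions, law.max_divisions, law.renewal_prob
    reps = np.zeros((n_replicates, sim.tm.n))
    for r in range(n_replicates):
        rec = _OccupancyRecorder(sim.tm.n, window)
        n_arr = rng.poisson(params.influx * horizon)
        for t in np.sort(rng.uniform(0.0, horizon, n_arr)):
            sim._run_anp_clone(t, 1, _G1, None, _draw_target(rng, a, b, p, 1), rec, rng)
        if include_nsc:
            law_n = params.nsc_divisions
            an, bn, pn = law_n.min_divisions, law_n.max_divisions, law_n.renewal_prob
            n_arr = rng.poisson(params.nsc_activation_rate * horizon)
            for t in np.sort(rng.uniform(0.0, horizon, n_arr)):
                sim._run_nsc(t, 1, _G1, None, _draw_target(rng, an, bn, pn, 1), rec, rng)
        reps[r] = rec.time_average()
    mean = reps.mean(axis=0)
    sem = (
        reps.std(axis=0, ddof=1) / np.sqrt(n_replicates)
        if n_replicates > 1
        else np.zeros(sim.tm.n)
    )
    return list(sim.tm.labels), mean, sem


def simulate_multitype(
    tm: TransitionMatrix,
    ancestor: str,
    timepoints,
    n_ancestors: int,
    rng: np.random.Generator | int | None = None,
):
    """Monte-Carlo occupancy for a general single-offspring compartment
    system (every row of ``m`` sub-stochastic): the independent oracle for
    the renewal-equation solver on toy cascades.

    Returns (mean, sem) arrays of shape (n_timepoints, n_compartments),
    per-ancestor occupancy with the sem over ancestors.
    """
    rng = np.random.default_rng(rng)
    row_sums = tm.m.sum(axis=1)
    if np.any(row_sums > 1.0 + 1e-12):
        raise ValueError("simulate_multitype requires sub-stochastic rows")
    timepoints = np.asarray(timepoints, dtype=float)
    tp = list(timepoints)
    n_t, n_c = len(tp), tm.n
    start = tm.index(ancestor)
    cum = np.cumsum(tm.m, axis=1)
    counts = np.zeros((n_ancestors, n_t, n_c), dtype=np.int64)
    for k in range(n_ancestors):
        comp, t = start, 0.0
        while True:
            dist = tm.durations[comp]
            t1 = np.inf if dist is None else t + float(dist.rvs(rng))
            i0, i1 = bisect_left(tp, t), bisect_left(tp, t1)
            counts[k, i0:i1, comp] += 1
            if dist is None or t1 > timepoints[-1]:
                break
            u = rng.random()
            nxt = int(np.searchsorted(cum[comp], u))
            if nxt >= n_c or u >= cum[comp, -1]:
                break  # no offspring: the particle vanishes
            comp, t = nxt, t1
    mean = counts.mean(axis=0)
    sem = counts.std(axis=0, ddof=1) / np.sqrt(n_ancestors)
    return mean, sem
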