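"""Calibration of the cascade against labeling-curve data.

The goodness-of-fit is a variance-weighted least-squares error

    sum over measurements  (E - S)^2 / sigma^2

with E and sigma^2 the experimental mean and variance at a (time, class)
point and S the model value there.  Parameters are searched by a genetic
algorithm over the admissible ranges: each searched parameter is encoded as
a fixed-width bit field spanning its range, individuals are bit strings,
and the population evolves by tournament selection, uniform crossover,
per-bit mutation and elitism.

The two influx scales (direct newborn-ANP influx ``lambda`` and labeled-NSC
activation rate ``mu``) are never searched: expected curves are linear in
them, so for any candidate parameter set they have a closed-form weighted
least-squares solution (``calibrate_influx``).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expectations import (
    initial_cohort_curves,
    labeled_initial_state,
    solve_expected_class_curves,
    stationary_distribution,
)
from .params import CascadeParameters
from .transition import OBSERVABLE_CLASSES, build_transition_matrix

__all__ = [
    "GAConfig",
    "FitResult",
    "ParameterCodec",
    "PARAMETER_RANGES",
    "objective",
    "calibrate_influx",
    "run_ga",
    "ExpectationEngine",
    "SimulationEngine",
]

OBSERVABLE_COLUMNS = ("Total", "Apop", "NSC", "ANP", "NB", "GC", "Astro")

# Admissible ranges of the searchable model parameters.
# kind "int": inclusive integer range; kind "float": continuous interval.
PARAMETER_RANGES: dict[str, tuple] = {
    "min_divisions_anp": ("int", 1, 3),
    "max_divisions_anp": ("int", 2, 8),
    "renewal_prob_anp": ("float", 0.0, 1.0),
    "t_g1_anp_mean": ("float", 6.0, 20.0),
    "t_g1_anp_shape": ("float", 2.0, 16.0),
    "t_g1_anp_min": ("float", 2.0, 5.0),
    "t_s_anp_mean": ("float", 5.0, 12.0),
    "t_s_anp_shape": ("float", 5.0, 40.0),
    "t_s_anp_min": ("float", 1.0, 4.0),
    "t_g2m_anp_mean": ("float", 1.0, 4.0),
    "t_g2m_anp_shape": ("float", 5.0, 20.0),
    "t_g2m_anp_min": ("float", 0.0, 0.75),
    "t_anp_nb_mean": ("float", 4.0, 64.0),
    "t_anp_nb_shape": ("float", 2.0, 16.0),
    "t_anp_nb_min": ("float", 0.0, 3.0),
    "t_anp_apop_mean": ("float", 4.0, 64.0),
    "t_anp_apop_shape": ("float", 2.0, 16.0),
    "t_anp_apop_min": ("float", 0.0, 3.0),
    "t_nb_mean": ("float", 120.0, 430.0),
    "t_nb_shape": ("float", 2.0, 16.0),
    "t_nb_min": ("float", 10.0, 80.0),
    "t_apop_mean": ("float", 0.4, 3.0),
    "t_apop_shape": ("float", 2.0, 16.0),
    "t_apop_min": ("float", 0.0, 0.3),
    "d_g1": ("float", 0.0, 0.99),
    "d_s": ("float", 0.0, 0.99),
    "d_g2m": ("float", 0.0, 0.99),
    "d_anp": ("float", 0.0, 0.99),
    "d_nb": ("float", 0.0, 0.99),
    "min_divisions_nsc": ("int", 1, 3),
    "max_divisions_nsc": ("int", 2, 6),
    "renewal_prob_nsc": ("float", 0.0, 1.0),
    "t_g1_nsc_mean": ("float", 8.0, 36.0),
    "t_g1_nsc_shape": ("float", 2.0, 16.0),
    "t_g1_nsc_min": ("float", 2.0, 5.0),
    "t_s_nsc_mean": ("float", 5.0, 12.0),
    "t_s_nsc_shape": ("float", 5.0, 40.0),
    "t_s_nsc_min": ("float", 1.0, 4.0),
    "t_g2m_nsc_mean": ("float", 1.0, 4.0),
    "t_g2m_nsc_shape": ("float", 5.0, 20.0),
    "t_g2m_nsc_min": ("float", 0.0, 0.75),
}

SIGMA_FLOOR = 1.0  # variance floor in the objective


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters (defaults sized to ~20 parameters)."""

    population: int = 100
    generations: int = 200
    bits_per_param: int = 8
    crossover_rate: float = 0.7
    mutation_rate: float = 0.01
    tournament_size: int = 3
    elitism: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.bits_per_param < 1:
            raise ValueError("bits_per_param must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FitResult:
    best_params: CascadeParameters
    objective: float
    history: list[float]
    influx: float
    nsc_activation: float
    n_evaluations: int = 0


class ParameterCodec:
    """Bit-field encoding of a subset of the model parameters.

    Each parameter maps to ``2**bits`` evenly spaced values across its
    admissible range (integer parameters to their enumerated set); decoding
    applies the values onto a base parameter set.
    """

    def __init__(
        self,
        base: CascadeParameters,
        names: list[str] | None = None,
        bits: int = 8,
        ranges: dict | None = None,
    ):
        self.ranges = dict(PARAMETER_RANGES if ranges is None else ranges)
        self.names = list(self.ranges) if names is None else list(names)
        unknown = [n for n in self.names if n not in self.ranges]
        if unknown:
            raise KeyError(f"no admissible range for parameter(s) {unknown}")
        self.base = base
        self.bits = bits
        self.n_bits = bits * len(self.names)

    def _grid(self, name: str) -> np.ndarray:
        kind, lo, hi = self.ranges[name]
        n_codes = 2**self.bits
        if kind == "int":
            values = np.arange(lo, hi + 1, dtype=float)
            idx = np.round(
                np.linspace(0, len(values) - 1, n_codes)
            ).astype(int)
            return values[idx]
        return np.linspace(lo, hi, n_codes)

    def encode(self, params: CascadeParameters) -> np.ndarray:
        d = params.to_dict()
        bits = np.zeros(self.n_bits, dtype=np.uint8)
        for k, name in enumerate(self.names):
            kind, lo, hi = self.ranges[name]
            v = d[name]
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise ValueError(
                    f"{name}={v} outside its admissible range [{lo}, {hi}]"
                )
            grid = self._grid(name)
            code = int(np.argmin(np.abs(grid - v)))
            for j in range(self.bits):
                bits[k * self.bits + j] = (code >> j) & 1
        return bits

    def decode(self, bits: np.ndarray) -> CascadeParameters:
        overrides: dict[str, float] = {}
        for k, name in enumerate(self.names):
            code = 0
            for j in range(self.bits):
                code |= int(bits[k * self.bits + j]) << j
            kind, _, _ = self.ranges[name]
            v = float(self._grid(name)[code])
            overrides[name] = int(v) if kind == "int" else v
        # structural validity: the division-count bounds must be ordered
        for who in ("anp", "nsc"):
            lo_k, hi_k = f"min_divisions_{who}", f"max_divisions_{who}"
            lo_v = overrides.get(lo_k, getattr(self.base, f"{who}_divisions").min_divisions)
            if hi_k in overrides and overrides[hi_k] < lo_v:
                overrides[hi_k] = int(lo_v)
        return self.base.replace_values(**overrides)


def objective(observed: pd.DataFrame, simulated: pd.DataFrame) -> float:
    """Variance-weighted least-squares error between the measurement set
    (columns ``time_h``, ``cls``, ``mean``, ``sem``) and model curves
    (column ``time_h`` plus one column per observable class)."""
    sim_times = simulated["time_h"].to_numpy()
    total = 0.0
    missing = []
    for _, row in observed.iterrows():
        hit = np.flatnonzero(np.isclose(sim_times, row.time_h, atol=1e-6))
        if hit.size == 0 or row.cls not in simulated.columns:
            missing.append((row.time_h, row.cls))
            continue
        s = float(simulated[row.cls].iloc[hit[0]])
        var = max(float(row["sem"]) ** 2, SIGMA_FLOOR)
        total += (float(row["mean"]) - s) ** 2 / var
    if missing:
        raise ContractError(f"simulated curves missing measurement points {missing}")
    return total


def calibrate_influx(
    observed: pd.DataFrame,
    unit_anp: pd.DataFrame,
    unit_nsc: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Closed-form weighted least-squares influx scales.

    ``unit_anp`` / ``unit_nsc`` are expected observable curves at unit
    direct-ANP influx and unit NSC-activation rate.  Returns ``(lambda,
    mu)``; ``mu`` is 0 when no NSC stream is supplied.  With one stream this
    reduces to  lambda = sum(E*S1/sigma^2) / sum(S1^2/sigma^2).
    """
    cols = [unit_anp] + ([unit_nsc] if unit_nsc is not None else [])
    x, y, w = [], [], []
    for _, row in observed.iterrows():
        vals = []
        ok = True
        for unit in cols:
            hit = np.flatnonzero(
                np.isclose(unit["time_h"].to_numpy(), row.time_h, atol=1e-6)
            )
            if hit.size == 0 or row.cls not in unit.columns:
                ok = False
                break
            vals.append(float(unit[row.cls].iloc[hit[0]]))
        if not ok:
            raise ContractError(f"unit curves missing point ({row.time_h}, {row.cls})")
        x.append(vals)
        y.append(float(row["mean"]))
        w.append(1.0 / max(float(row["sem"]) ** 2, SIGMA_FLOOR))
    x = np.asarray(x)
    y = np.asarray(y)
    w = np.asarray(w)
    if np.all(x == 0.0):
        raise ValueError("all-zero unit curves: influx scale is undefined")
    xtwx = (x * w[:, None]).T @ x
    xtwy = (x * w[:, None]).T @ y
    try:
        theta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        theta = np.linalg.lstsq(xtwx, xtwy, rcond=None)[0]
    theta = np.clip(theta, 0.0, None)
    # if a clipped component was negative, refit the other alone
    if unit_nsc is not None and (theta == 0.0).any() and not (theta == 0.0).all():
        j = int(np.flatnonzero(theta > 0.0)[0])
        denom = np.sum(w * x[:, j] ** 2)
        theta[j] = np.sum(w * y * x[:, j]) / denom if denom > 0 else 0.0
    lam = float(theta[0])
    mu = float(theta[1]) if unit_nsc is not None else 0.0
    return lam, mu


class ExpectationEngine:
    """Deterministic objective engine on analytic expected curves.

    For a candidate parameter set it solves the class-aggregated renewal
    equation once, seeds it with the two unit-influx stationary S-phase
    cohorts, calibrates ``(lambda, mu)`` in closed form and returns the
    weighted least-squares objective.
    """

    def __init__(
        self,
        timepoints_h,
        include_nsc: bool = True,
        step: float = 1.0,
        residual_mode: str = "stationary",
    ):
        self.timepoints_h = np.sort(np.asarray(timepoints_h, dtype=float))
        self.include_nsc = include_nsc
        self.step = step
        self.residual_mode = residual_mode

    def unit_curves(self, params: CascadeParameters):
        tm = build_transition_matrix(params, include_nsc=self.include_nsc)
        horizon = max(float(self.timepoints_h.max()), self.step)
        times, Z = solve_expected_class_curves(tm, horizon, self.step)
        weights = tm.class_weights(OBSERVABLE_CLASSES)
        rows = np.clip(
            np.round(self.timepoints_h / self.step).astype(int), 0, len(times) - 1
        )

        def stream(ancestor: str) -> pd.DataFrame:
            stat = stationary_distribution(tm, 1.0, ancestor)
            c0 = labeled_initial_state(tm, stat)
            fine = initial_cohort_curves(
                tm, c0, times, Z, weights,
                residual=(self.residual_mode == "stationary"),
            )[rows]
            df = pd.DataFrame(fine, columns=list(OBSERVABLE_CLASSES))
            out = pd.DataFrame({"time_h": self.timepoints_h})
            out["Total"] = df.sum(axis=1).to_numpy()
            out["Apop"] = df["Apop"].to_numpy()
            out["NSC"] = df["NSC"].to_numpy()
            out["ANP"] = (df["ANP"] + df["ANP_NB"] + df["ANP_APOP"]).to_numpy()
            out["NB"] = df["NB"].to_numpy()
            out["GC"] = df["GC"].to_numpy()
            out["Astro"] = df["Astro"].to_numpy()
            return out

        unit_anp = stream("ANP_G1(1)")
        unit_nsc = stream("NSC_G1(1)") if self.include_nsc else None
        return unit_anp, unit_nsc

    def curves(self, params: CascadeParameters, lam: float, mu: float) -> pd.DataFrame:
        unit_anp, unit_nsc = self.unit_curves(params)
        out = unit_anp.copy()
        for col in OBSERVABLE_COLUMNS:
            out[col] = lam * unit_anp[col] + (
                mu * unit_nsc[col] if unit_nsc is not None else 0.0
            )
        return out

    def evaluate(self, params: CascadeParameters, observed: pd.DataFrame):
        unit_anp, unit_nsc = self.unit_curves(params)
        lam, mu = calibrate_influx(observed, unit_anp, unit_nsc)
        fitted = unit_anp.copy()
        for col in OBSERVABLE_COLUMNS:
            fitted[col] = lam * unit_anp[col] + (
                mu * unit_nsc[col] if unit_nsc is not None else 0.0
            )
        return objective(observed, fitted), lam, mu


class SimulationEngine:
    """Stochastic objective engine: averages a few event-based simulation
    replicates per candidate, with a per-candidate seed derived from the
    genome hash so that repeated evaluations are identical.  The parameter
    set's own influx scales are used for seeding; a single least-squares
    scale factor is applied to the mean curves before scoring."""

    def __init__(
        self,
        timepoints_h,
        include_nsc: bool = True,
        n_replicates: int = 5,
        base_seed: int = 0,
    ):
        self.timepoints_h = np.sort(np.asarray(timepoints_h, dtype=float))
        self.include_nsc = include_nsc
        self.n_replicates = n_replicates
        self.base_seed = base_seed

    def _seed_for(self, params: CascadeParameters) -> int:
        digest = hashlib.sha256(
            repr(sorted(params.to_dict().items())).encode()
            + str(self.base_seed).encode()
        ).digest()
        return int.from_bytes(digest[:4], "little")

    def evaluate(self, params: CascadeParameters, observed: pd.DataFrame):
        from .simulate import simulate_labeling_curves

        rng = np.random.default_rng(self._seed_for(params))
        curve = simulate_labeling_curves(
            params,
            self.timepoints_h,
            n_replicates=self.n_replicates,
            rng=rng,
            include_nsc=self.include_nsc,
        )
        mean = curve.observables()
        lam, _ = calibrate_influx(observed, mean)
        fitted = mean.copy()
        for col in OBSERVABLE_COLUMNS:
            fitted[col] = lam * mean[col]
        return (
            objective(observed, fitted),
            lam * params.influx,
            lam * params.nsc_activation_rate,
        )


def run_ga(
    config: GAConfig,
    observed: pd.DataFrame,
    codec: ParameterCodec,
    engine=None,
) -> FitResult:
    """Minimize the variance-weighted objective by a genetic algorithm.

    ``observed`` is the measurement set (``dataprep.measurements`` output);
    ``codec`` defines the searched parameters.  Deterministic under a fixed
    ``config.seed``; returns the best-ever individual.
    """
    if engine is None:
        engine = ExpectationEngine(np.unique(observed["time_h"]))
    rng = np.random.default_rng(config.seed)
    n_bits = codec.n_bits
    pop = (rng.random((config.population, n_bits)) < 0.5).astype(np.uint8)
    # seed the base point so the search starts no worse than the defaults
    pop[0] = codec.encode(codec.base)

    cache: dict[bytes, tuple] = {}

    def fitness(bits: np.ndarray):
        key = bits.tobytes()
        if key not in cache:
            params = codec.decode(bits)
            cache[key] = engine.evaluate(params, observed)
        return cache[key]

    scores = np.array([fitness(ind)[0] for ind in pop])
    best_idx = int(np.argmin(scores))
    best_bits, best_score = pop[best_idx].copy(), float(scores[best_idx])
    history = [best_score]

    for _ in range(config.generations):
        order = np.argsort(scores)
        elite = pop[order[: config.elitism]].copy()
        children = []
        while len(children) < config.population - config.elitism:
            def pick():
                idx = rng.integers(0, config.population, size=config.tournament_size)
                return pop[idx[np.argmin(scores[idx])]]

            c1, c2 = pick().copy(), pick().copy()
            if rng.random() < config.crossover_rate:
                mask = rng.random(n_bits) < 0.5
                c1[mask], c2[mask] = c2[mask], c1[mask].copy()
            for c in (c1, c2):
                flips = rng.random(n_bits) < config.mutation_rate
                c[flips] ^= 1
                children.append(c)
        pop = np.vstack([elite, np.array(children[: config.population - config.elitism])])
        scores = np.array([fitness(ind)[0] for ind in pop])
        gen_best = int(np.argmin(scores))
        if scores[gen_best] < best_score:
            best_score = float(scores[gen_best])
            best_bits = pop[gen_best].copy()
        history.append(best_score)

    best_params = codec.decode(best_bits)
    _, lam, mu = fitness(best_bits)
    best_params = best_params.replace_values(influx=lam, nsc_activation=mu)
    return FitResult(
        best_params=best_params,
        objective=best_score,
        history=history,
        influx=lam,
        nsc_activation=mu,
        n_evaluations=len(cache),
    )
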