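"""Analytic first moments of the branching cascade.

Two quantities are computed without simulation:

* ``M(t)``, the matrix of expected type-``j`` counts at time ``t`` per
  type-``i`` ancestor at time 0.  It is the unique locally-bounded-variation
  solution of the renewal equation

      M(t) = T(t) * [m M(t)] + [I - T(t)]

  (``*`` a Lebesgue-Stieltjes convolution against the lifetime cdfs
  ``T_i``), solved by fixed-point iteration on a uniform grid; the iterates
  are the partial sums of the series  sum_k (Tm)^{*k} * (I - T).  For the
  feed-forward cascade the series terminates at the longest compartment
  path, so the iteration converges exactly.

* ``pi``, the stationary expected population under a constant Poisson
  influx, by the closed form  pi = rate * e_i' (I - m)^{-1} E[T]  on the
  non-absorbing compartments.

Convolutions use trapezoidal cdf increments and one batched FFT per
iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as _fft

from .params import CascadeParameters
from .transition import OBSERVABLE_CLASSES, TransitionMatrix, build_transition_matrix

__all__ = [
    "ExpectationSolution",
    "StationaryState",
    "solve_expectation_matrix",
    "stationary_distribution",
    "labeled_initial_state",
    "expected_labeling_curves",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ExpectationSolution:
    """M(t) on a uniform grid: ``matrix[n, i, j]`` = E[# type-j at times[n]
    | one type-i ancestor at 0]."""

    times: np.ndarray
    matrix: np.ndarray
    labels: list[str]

    def at(self, t: float) -> np.ndarray:
        n = int(round(t / (self.times[1] - self.times[0])))
        return self.matrix[n]

    def to_frame(self, ancestor: str):
        """One ancestor's expected counts as a DataFrame (time_h, one column
        per compartment); ready for ``to_csv``."""
        import pandas as pd

        i = self.labels.index(ancestor)
        df = pd.DataFrame(self.matrix[:, i, :], columns=self.labels)
        df.insert(0, "time_h", self.times)
        return df


@dataclass
class StationaryState:
    """Expected steady-state counts per compartment under constant influx.

    Absorbing compartments accumulate without bound; their entries are NaN
    and flagged in ``at_steady_state``.
    """

    labels: list[str]
    pi: np.ndarray
    influx: float
    at_steady_state: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.pi))

    def to_frame(self):
        """Steady state as a one-row DataFrame (one column per compartment)."""
        import pandas as pd

        return pd.DataFrame([self.pi], columns=self.labels)


def _cdf_increments(tm: TransitionMatrix, times: np.ndarray) -> np.ndarray:
    """dT[n, i] = T_i(t_n) - T_i(t_{n-1}) (zero row at n=0; absorbing = 0)."""
    n_t, n_c = len(times), tm.n
    cdf = np.zeros((n_t, n_c))
    for i, dist in enumerate(tm.durations):
        if dist is not None:
            cdf[:, i] = dist.cdf(times)
    dT = np.zeros_like(cdf)
    dT[1:] = np.diff(cdf, axis=0)
    return cdf, dT


def _renewal_solve(
    tm: TransitionMatrix,
    base: np.ndarray,
    horizon: float,
    step: float,
    tol: float = 1e-10,
    max_iter: int = 200,
):
    """Solve Z_i = T_i * (m Z)_i + base_i for Z of shape (n_times, n, w).

    ``base`` has shape (n_times, n, w); for the expectation matrix it is
    (1 - T_i(t)) delta_ij, for class-aggregated curves (1 - T_i(t)) W_ij.
    """
    if step <= 0 or horizon < step:
        raise ValueError("require step > 0 and horizon >= step")
    times = np.arange(0.0, horizon + 0.5 * step, step)
    n_t = len(times)
    _, dT = _cdf_increments(tm, times)

    # Trapezoidal Lebesgue-Stieltjes quadrature:
    #   (A * B)(t_n) ~ sum_j 0.5 (A[n-j] + A[n-j+1]) dB[j]
    # which is 0.5 * (c[n] + c[n-1]) for c = conv(A, dB).  Batched via one
    # real FFT per iteration with per-compartment kernels.
    nfft = _fft.next_fast_len(2 * n_t)
    ker = _fft.rfft(dT[1:], n=nfft, axis=0)  # (nfft/2+1, n)

    Z = base.copy()
    for it in range(max_iter):
        mz = np.einsum("ik,nkw->niw", tm.m, Z)
        spec = _fft.rfft(mz, n=nfft, axis=0)
        c = _fft.irfft(spec * ker[:, :, None], n=nfft, axis=0)[:n_t]
        conv = np.empty_like(c)
        conv[0] = 0.0
        conv[1:] = 0.5 * (c[1:] + c[:-1])
        Z_new = conv + base
        delta = float(np.max(np.abs(Z_new - Z)))
        Z = Z_new
        if delta < tol:
            return times, Z
    raise ConvergenceError(
        f"renewal iteration did not converge in {max_iter} iterations "
        f"(last residual {delta:.3e})"
    )


def solve_expectation_matrix(
    tm: TransitionMatrix,
    horizon: float,
    step: float = 0.1,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> ExpectationSolution:
    """Solve the renewal equation for the full expectation matrix M(t)."""
    times = np.arange(0.0, horizon + 0.5 * step, step)
    cdf, _ = _cdf_increments(tm, times)
    base = (1.0 - cdf)[:, :, None] * np.eye(tm.n)[None, :, :]
    times, Z = _renewal_solve(tm, base, horizon, step, tol=tol, max_iter=max_iter)
    return ExpectationSolution(times=times, matrix=Z, labels=list(tm.labels))


def solve_expected_class_curves(
    tm: TransitionMatrix,
    horizon: float,
    step: float = 0.1,
    classes=OBSERVABLE_CLASSES,
    tol: float = 1e-10,
    max_iter: int = 200,
):
    """Per-ancestor expected counts aggregated into observable classes.

    Returns (times, Z) with Z of shape (n_times, n_compartments, n_classes):
    Z[n, i, c] = expected class-c cells at times[n] from one type-i ancestor.
    Solving the class-weighted system directly avoids the full n x n matrix.
    """
    times = np.arange(0.0, horizon + 0.5 * step, step)
    cdf, _ = _cdf_increments(tm, times)
    w = tm.class_weights(classes)
    base = (1.0 - cdf)[:, :, None] * w[None, :, :]
    return _renewal_solve(tm, base, horizon, step, tol=tol, max_iter=max_iter)


def _ls_convolve(a: np.ndarray, db: np.ndarray) -> np.ndarray:
    """Trapezoidal Lebesgue-Stieltjes convolution of grid function ``a``
    (n_t, ...) against cdf increments ``db`` (n_t,)."""
    n_t = a.shape[0]
    flat = a.reshape(n_t, -1)
    out = np.zeros_like(flat)
    for j in range(flat.shape[1]):
        c = np.convolve(flat[:, j], db[1:])[:n_t]
        out[1:, j] = 0.5 * (c[1:] + c[:-1])
    return out.reshape(a.shape)


def initial_cohort_curves(
    tm: TransitionMatrix,
    c0: np.ndarray,
    times: np.ndarray,
    Z: np.ndarray,
    weights: np.ndarray,
    residual: bool = True,
) -> np.ndarray:
    """Expected class curves for a cohort seeded mid-stage.

    ``Z`` is the fresh-entry solution from :func:`solve_expected_class_curves`
    and ``weights`` the compartment-to-class indicator used to build it.
    With ``residual=True`` the seeded cells' first transition uses the
    stationary-age residual-life distribution of their stage,
    G_i(t) = int_0^t (1 - T_i(u)) du / E[T_i]; with ``residual=False`` the
    seeded cells start their stage afresh (start-of-stage convention) and
    the result is exactly ``c0' Z``.
    """
    if not residual:
        return np.einsum("i,niw->nw", c0, Z)
    step = times[1] - times[0]
    out = np.zeros(Z.shape[::2])
    for i in np.flatnonzero(c0 != 0.0):
        dist = tm.durations[i]
        surv = 1.0 - dist.cdf(times)
        g = np.concatenate(
            [[0.0], np.cumsum(0.5 * (surv[1:] + surv[:-1]) * step)]
        ) / dist.mean
        g = np.clip(g, 0.0, 1.0)
        dg = np.zeros_like(g)
        dg[1:] = np.diff(g)
        mz_i = np.einsum("k,nkw->nw", tm.m[i], Z)
        out += c0[i] * (_ls_convolve(mz_i, dg) + (1.0 - g)[:, None] * weights[i])
    return out


def stationary_distribution(
    tm: TransitionMatrix,
    influx: float,
    ancestor: str = "ANP_G1(1)",
) -> StationaryState:
    """Closed-form steady state pi = influx * e_ancestor' (I - m)^{-1} E[T].

    ``ancestor`` names the entry compartment fed by the Poisson influx
    (newborn-ANP entry ``ANP_G1(1)``, or ``NSC_G1(1)`` for activations).
    """
    transient = ~tm.absorbing_mask
    sub = tm.m[np.ix_(transient, transient)]
    n_sub = sub.shape[0]
    radius = np.max(np.abs(np.linalg.eigvals(sub))) if n_sub else 0.0
    if radius >= 1.0 - 1e-12:
        raise ValueError(
            "non-dissipative cycle among transient compartments "
            f"(spectral radius {radius:.6f} >= 1); (I - m) is singular"
        )
    idx_map = np.flatnonzero(transient)
    a = int(np.where(idx_map == tm.index(ancestor))[0][0])
    e = np.zeros(n_sub)
    e[a] = 1.0
    visits = np.linalg.solve((np.eye(n_sub) - sub).T, e)  # e' (I - m)^{-1}
    means = tm.mean_durations()[transient]
    pi = np.full(tm.n, np.nan)
    pi[idx_map] = influx * visits * means
    return StationaryState(
        labels=list(tm.labels),
        pi=pi,
        influx=influx,
        at_steady_state=transient,
    )


def combined_stationary_state(
    params: CascadeParameters, tm: TransitionMatrix | None = None
) -> StationaryState:
    """Steady state of the full cascade under its two Poisson entry streams.

    The system is fed by direct newborn-ANP arrivals at rate ``influx``
    (entering ``ANP_G1(1)``) and, when NSC compartments are modelled, by NSC
    activations at rate ``nsc_activation_rate`` (entering ``NSC_G1(1)``,
    whose divisions emit further ANPs).  By linearity the combined steady
    state is the sum of the two single-stream closed forms.  The two rates
    are independent scale factors; ``calibrate_influx`` fits both to data.
    """
    if tm is None:
        tm = build_transition_matrix(params)
    stat_a = stationary_distribution(tm, params.influx, "ANP_G1(1)")
    if "NSC_G1(1)" not in tm.labels:
        return stat_a
    stat_n = stationary_distribution(tm, params.nsc_activation_rate, "NSC_G1(1)")
    pi = np.where(stat_a.at_steady_state, stat_a.pi + stat_n.pi, np.nan)
    return StationaryState(
        labels=stat_a.labels,
        pi=pi,
        influx=params.influx,
        at_steady_state=stat_a.at_steady_state,
    )


def labeled_initial_state(tm: TransitionMatrix, stationary: StationaryState) -> np.ndarray:
    """Expected BrdU-labeled cells at injection: pi restricted to S-phase
    compartments (a pulse labels exactly the cells synthesizing DNA)."""
    pi = np.where(np.isnan(stationary.pi), 0.0, stationary.pi)
    return np.where(tm.s_phase_mask, pi, 0.0)


def expected_labeling_curves(
    params: CascadeParameters,
    timepoints,
    step: float = 0.1,
    include_nsc: bool = True,
    classes=OBSERVABLE_CLASSES,
    residual_mode: str = "stationary",
):
    """Expected BrdU+ labeling curves per observable class (analytic route).

    Seeds the renewal solution with the stationary S-phase occupancy.  In
    the default ``"stationary"`` mode the labeled cells carry residual
    (stationary-age) S times, matching the event simulator; ``"start"``
    treats them as beginning S afresh (the start-of-S convention, which
    matters only within roughly the joint S + G2M duration).
    """
    import pandas as pd

    if residual_mode not in ("stationary", "start"):
        raise ValueError("residual_mode must be 'stationary' or 'start'")
    timepoints = np.asarray(timepoints, dtype=float)
    tm = build_transition_matrix(params, include_nsc=include_nsc)
    stat = combined_stationary_state(params, tm)
    c0 = labeled_initial_state(tm, stat)
    horizon = max(float(timepoints.max()), step)
    times, Z = solve_expected_class_curves(tm, horizon, step, classes=classes)
    w = tm.class_weights(classes)
    curves = initial_cohort_curves(
        tm, c0, times, Z, w, residual=(residual_mode == "stationary")
    )
    rows = np.clip(np.round(timepoints / step).astype(int), 0, len(times) - 1)
    out = pd.DataFrame(curves[rows], columns=list(classes))
    out.insert(0, "time_h", timepoints)
    out["ANP_all"] = out["ANP"] + out["ANP_NB"] + out["ANP_APOP"]
    out["Total"] = out[list(classes)].sum(axis=1)
    return out
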