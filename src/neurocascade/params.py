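"""Parameter set of the neurogenic cascade.

The cascade is driven by a Poisson influx of newborn amplifying
neuroprogenitors (ANPs) emitted by neural stem cells (NSCs).  An ANP clone
divides through G1/S/G2M a bounded number of times; after the minimum number
of divisions it keeps proliferating with renewal probability ``p``.
Non-proliferating ANPs pass through a transition stage on their way to
neuroblast (ANP-NB) or apoptosis (ANP-Apop).  Neuroblasts mature into
granule cells or die; apoptotic cells occupy a short clearance stage before
removal by microglia.  Every stage-end carries a death rate ``d_i``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .distributions import ShiftedGamma

__all__ = [
    "ProgenyModel",
    "StageSpec",
    "CascadeParameters",
    "progeny_distribution",
    "expected_divisions",
]


@dataclass(frozen=True)
class ProgenyModel:
    """Division law of a proliferating lineage.

    A founder performs at least ``min_divisions`` (a) and at most
    ``max_divisions`` (b) rounds of division; after each completed round
    beyond the minimum it continues with renewal probability ``renewal_prob``
    (p).  The number of division rounds N of the clone therefore satisfies

        P(N = a)     = 1 - p
        P(N = a + i) = p^i (1 - p),   1 <= i <= b - a - 1
        P(N = b)     = p^(b - a)

    and the clone's final progeny count is X = 2^N.
    """

    min_divisions: int
    max_divisions: int
    renewal_prob: float

    def __post_init__(self) -> None:
        a, b, p = self.min_divisions, self.max_divisions, self.renewal_prob
        if a < 1:
            raise ValueError(f"min_divisions must be >= 1, got {a}")
        if b < a:
            raise ValueError(f"max_divisions ({b}) must be >= min_divisions ({a})")
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"renewal_prob must be in [0, 1], got {p}")

    def division_count_pmf(self, at_least: int | None = None) -> dict[int, float]:
        """pmf of the number of division rounds N, optionally given N >= at_least."""
        a, b, p = self.min_divisions, self.max_divisions, self.renewal_prob
        lo = a if at_least is None else max(a, at_least)
        if lo > b:
            raise ValueError(f"conditioning generation {at_least} exceeds max {b}")
        pmf = {}
        for n in range(lo, b):
            pmf[n] = p ** (n - lo) * (1.0 - p)
        pmf[b] = p ** (b - lo)
        return pmf

    def progeny_pmf(self) -> dict[int, float]:
        """pmf of the clone's total progeny count X = 2^N over {2^a, ..., 2^b}."""
        return {2**n: w for n, w in self.division_count_pmf().items()}

    @property
    def expected_progeny(self) -> float:
        return sum(x * w for x, w in self.progeny_pmf().items())

    @property
    def expected_divisions(self) -> float:
        """log2 of the expected progeny count; exactly ``a`` when a == b."""
        if self.min_divisions == self.max_divisions:
            return float(self.min_divisions)
        return math.log2(self.expected_progeny)

    @property
    def expected_division_count(self) -> float:
        """E[N]: for an asymmetrically dividing lineage, the expected number
        of daughters emitted (one per division round)."""
        return sum(n * w for n, w in self.division_count_pmf().items())

    def sample_division_count(self, rng: np.random.Generator, at_least: int | None = None) -> int:
        pmf = self.division_count_pmf(at_least=at_least)
        ns = list(pmf)
        return int(rng.choice(ns, p=np.array([pmf[n] for n in ns])))


def progeny_distribution(a: int, b: int, p: float) -> dict[int, float]:
    """pmf of the clone progeny count X over {2^a, ..., 2^b}."""
    return ProgenyModel(a, b, p).progeny_pmf()


def expected_divisions(a: int, b: int, p: float) -> float:
    """Expected number of divisions, log2 E[X] (equal to a when a == b)."""
    return ProgenyModel(a, b, p).expected_divisions


@dataclass(frozen=True)
class StageSpec:
    """A cascade stage: its label, transit-time law and stage-end death rate."""

    label: str
    duration: ShiftedGamma
    death_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.death_rate <= 1.0):
            raise ValueError(
                f"death rate of {self.label} must be in [0, 1], got {self.death_rate}"
            )


# (mean, shape, shift) triple helpers keyed by the flat serialization names.
_DIST_FIELDS = ("mean", "shape", "min")


@dataclass(frozen=True)
class CascadeParameters:
    """Full parameter set of the cascade (the object the GA searches over).

    ``influx`` is the rate of newborn-ANP arrivals (cells/hour).
    ``nsc_activation`` is the NSC activation rate (activations/hour); when
    ``None`` it is tied to the influx so that the expected ANP emission rate
    of the NSC sub-model equals ``influx``.
    """

    influx: float
    anp_divisions: ProgenyModel
    anp_g1: StageSpec
    anp_s: StageSpec
    anp_g2m: StageSpec
    d_anp: float  # death rate of non-proliferating ANPs
    anp_nb_duration: ShiftedGamma
    anp_apop_duration: ShiftedGamma
    nb: StageSpec
    apop_duration: ShiftedGamma
    nsc_divisions: ProgenyModel
    nsc_g1: StageSpec
    nsc_s: StageSpec
    nsc_g2m: StageSpec
    in_stage: Optional[StageSpec] = None
    nsc_activation: Optional[float] = None

    def __post_init__(self) -> None:
        if self.influx < 0:
            raise ValueError(f"influx must be >= 0, got {self.influx}")
        if not (0.0 <= self.d_anp <= 1.0):
            raise ValueError(f"d_anp must be in [0, 1], got {self.d_anp}")
        for spec in (self.nsc_g1, self.nsc_s, self.nsc_g2m):
            if spec.death_rate != 0.0:
                raise ValueError("NSCs do not undergo apoptosis; death rates must be 0")

    @property
    def nsc_activation_rate(self) -> float:
        """NSC activation rate; derived from influx unless set explicitly."""
        if self.nsc_activation is not None:
            return self.nsc_activation
        return self.influx / self.nsc_divisions.expected_division_count

    def with_influx(self, influx: float) -> "CascadeParameters":
        return replace(self, influx=influx)

    def death_rates(self) -> dict[str, float]:
        rates = {
            "d_g1": self.anp_g1.death_rate,
            "d_s": self.anp_s.death_rate,
            "d_g2m": self.anp_g2m.death_rate,
            "d_anp": self.d_anp,
            "d_nb": self.nb.death_rate,
        }
        if self.in_stage is not None:
            rates["d_in"] = self.in_stage.death_rate
        return rates

    def scale_death_rates(self, multiplier: float) -> "CascadeParameters":
        """Return a copy with every death rate multiplied by ``multiplier``."""
        if not (0.0 <= multiplier <= 1.0):
            raise ValueError(f"multiplier must be in [0, 1], got {multiplier}")
        m = multiplier

        def sc(spec: StageSpec) -> StageSpec:
            return replace(spec, death_rate=spec.death_rate * m)

        return replace(
            self,
            anp_g1=sc(self.anp_g1),
            anp_s=sc(self.anp_s),
            anp_g2m=sc(self.anp_g2m),
            d_anp=self.d_anp * m,
            nb=sc(self.nb),
            in_stage=None if self.in_stage is None else sc(self.in_stage),
        )

    # -- flat serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "influx": self.influx,
            "min_divisions_anp": self.anp_divisions.min_divisions,
            "max_divisions_anp": self.anp_divisions.max_divisions,
            "renewal_prob_anp": self.anp_divisions.renewal_prob,
            "d_g1": self.anp_g1.death_rate,
            "d_s": self.anp_s.death_rate,
            "d_g2m": self.anp_g2m.death_rate,
            "d_anp": self.d_anp,
            "d_nb": self.nb.death_rate,
            "min_divisions_nsc": self.nsc_divisions.min_divisions,
            "max_divisions_nsc": self.nsc_divisions.max_divisions,
            "renewal_prob_nsc": self.nsc_divisions.renewal_prob,
        }
        if self.nsc_activation is not None:
            d["nsc_activation"] = self.nsc_activation
        dists = {
            "t_g1_anp": self.anp_g1.duration,
            "t_s_anp": self.anp_s.duration,
            "t_g2m_anp": self.anp_g2m.duration,
            "t_anp_nb": self.anp_nb_duration,
            "t_anp_apop": self.anp_apop_duration,
            "t_nb": self.nb.duration,
            "t_apop": self.apop_duration,
            "t_g1_nsc": self.nsc_g1.duration,
            "t_s_nsc": self.nsc_s.duration,
            "t_g2m_nsc": self.nsc_g2m.duration,
        }
        for key, dist in dists.items():
            d[f"{key}_mean"] = dist.mean
            d[f"{key}_shape"] = dist.shape
            d[f"{key}_min"] = dist.shift
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeParameters":
        def dist(key: str) -> ShiftedGamma:
            return ShiftedGamma.from_mean(
                mean=float(d[f"{key}_mean"]),
                shape=float(d[f"{key}_shape"]),
                shift=float(d[f"{key}_min"]),
            )

        return cls(
            influx=float(d["influx"]),
            nsc_activation=(
                float(d["nsc_activation"]) if d.get("nsc_activation") is not None else None
            ),
            anp_divisions=ProgenyModel(
                int(d["min_divisions_anp"]),
                int(d["max_divisions_anp"]),
                float(d["renewal_prob_anp"]),
            ),
            anp_g1=StageSpec("ANP_G1", dist("t_g1_anp"), float(d["d_g1"])),
            anp_s=StageSpec("ANP_S", dist("t_s_anp"), float(d["d_s"])),
            anp_g2m=StageSpec("ANP_G2M", dist("t_g2m_anp"), float(d["d_g2m"])),
            d_anp=float(d["d_anp"]),
            anp_nb_duration=dist("t_anp_nb"),
            anp_apop_duration=dist("t_anp_apop"),
            nb=StageSpec("NB", dist("t_nb"), float(d["d_nb"])),
            apop_duration=dist("t_apop"),
            nsc_divisions=ProgenyModel(
                int(d["min_divisions_nsc"]),
                int(d["max_divisions_nsc"]),
                float(d["renewal_prob_nsc"]),
            ),
            nsc_g1=StageSpec("NSC_G1", dist("t_g1_nsc")),
            nsc_s=StageSpec("NSC_S", dist("t_s_nsc")),
            nsc_g2m=StageSpec("NSC_G2M", dist("t_g2m_nsc")),
        )

    def replace_values(self, **overrides: float) -> "CascadeParameters":
        """Return a copy with flat-dict keys overridden (codec / GA surface)."""
        d = self.to_dict()
        unknown = set(overrides) - set(d) - {"nsc_activation"}
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        d.update(overrides)
        return CascadeParameters.from_dict(d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def best_fit(cls, influx: float | None = None) -> "CascadeParameters":
        """The packaged best-fit parameter set (with a calibrated influx)."""
        from .fixtures import load_best_fit_params

        p = load_best_fit_params()
        return p if influx is None else p.with_influx(influx)
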