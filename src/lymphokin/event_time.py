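"""Event-time distributions for cell fate and stationary (steady-state) initialization.

A cell is born at mitosis with two independent clocks drawn from the same
distribution: a time to divide and a time to die/differentiate.  The first
clock to ring decides the cell's fate; the time to that first event is the
cell's *lifespan*.  The shape of the event-time distribution determines which
paradigm of cell fate the population obeys:

* exponential (gamma with shape 1) — constant hazard, *age-independent* fate;
* gamma shape < 1 (or lognormal with mode < 2 days) — hazard decreasing with
  cell age, the *risk* paradigm (recently divided cells are more at risk);
* gamma shape > 1 (or lognormal with mode > 7 days) — hazard increasing with
  cell age, the *cyton* paradigm (recently divided cells are safer).

Because division and death share one distribution, the branching process is
critical and the population is in homeostasis.  A population that has been in
homeostasis for a long time is *not* a population of newborns: its age density
is proportional to ``survival(a)**2`` (both clocks must have stayed silent),
and the remaining clock times must be drawn conditional on exceeding the
current age.  :func:`sample_stationary_cells` implements that initialization.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import integrate, interpolate, optimize, special, stats

__all__ = [
    "Paradigm",
    "ParadigmError",
    "EventTimeDistribution",
    "PopulationSpec",
    "StationaryCellDraw",
    "survival",
    "hazard",
    "classify_paradigm",
    "median_lifespan",
    "sample_stationary_cell",
    "sample_stationary_cells",
]


class Paradigm(enum.Enum):
    """The three paradigms of cell-fate age dependence."""

    AGE_INDEPENDENT = "age_independent"
    RISK = "risk"
    CYTON = "cyton"


class ParadigmError(ValueError):
    """Raised when a distribution does not fall in any paradigm's parameter space."""


_FAMILIES = ("exponential", "gamma", "lognormal")

# Lognormal mode band excluded from classification: the constrained fits only
# ever place the mode above 7 days (cyton) or below 2 days (risk).
LOGNORMAL_CYTON_MODE_MIN = 7.0
LOGNORMAL_RISK_MODE_MAX = 2.0


@dataclass(frozen=True)
class EventTimeDistribution:
    """Distribution of the time (days) from a cell's birth to one fate event.

    Exactly one of the parameterizations is active depending on ``family``:
    gamma/exponential use ``shape``/``scale`` (exponential is gamma with shape
    exactly 1), lognormal uses ``mu`` (log-days) and ``sigma``.
    """

    family: str
    shape: float | None = None
    scale: float | None = None
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        if self.family in ("gamma", "exponential"):
            if self.scale is None or self.scale <= 0:
                raise ValueError("gamma/exponential scale must be a positive number of days")
            if self.family == "exponential":
                if self.shape not in (None, 1, 1.0):
                    raise ValueError("exponential is gamma with shape exactly 1")
                object.__setattr__(self, "shape", 1.0)
            elif self.shape is None or self.shape <= 0:
                raise ValueError("gamma shape must be positive")
            if self.mu is not None or self.sigma is not None:
                raise ValueError("mu/sigma are lognormal parameters")
        else:
            if self.mu is None:
                raise ValueError("lognormal requires mu (log-days)")
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("lognormal sigma must be positive")
            if self.shape is not None or self.scale is not None:
                raise ValueError("shape/scale are gamma parameters")

    # -- constructors ------------------------------------------------------
    @classmethod
    def exponential(cls, scale: float) -> "EventTimeDistribution":
        """Exponential event times with the given mean (days)."""
        return cls(family="exponential", scale=scale)

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "EventTimeDistribution":
        return cls(family="gamma", shape=shape, scale=scale)

    @classmethod
    def lognormal(cls, mu: float, sigma: float) -> "EventTimeDistribution":
        return cls(family="lognormal", mu=mu, sigma=sigma)

    # -- scipy backing -----------------------------------------------------
    @cached_property
    def _frozen(self):
        if self.family in ("gamma", "exponential"):
            return stats.gamma(self.shape, scale=self.scale)
        return stats.lognorm(self.sigma, scale=math.exp(self.mu))

    @property
    def mean(self) -> float:
        """Mean event time in days (finite for all admissible parameters)."""
        if self.family in ("gamma", "exponential"):
            return self.shape * self.scale
        return math.exp(self.mu + 0.5 * self.sigma**2)

    @property
    def mode(self) -> float:
        """Mode of the event-time density in days."""
        if self.family in ("gamma", "exponential"):
            return max(0.0, (self.shape - 1.0) * self.scale)
        return math.exp(self.mu - self.sigma**2)

    def survival(self, t):
        # direct special-function evaluation; this is the hot path of the
        # deterministic engine so the scipy frozen-dist machinery is bypassed
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival is defined for t >= 0 only")
        if self.family in ("gamma", "exponential"):
            return special.gammaincc(self.shape, t / self.scale)
        with np.errstate(divide="ignore"):
            z = np.where(t > 0, (np.log(np.maximum(t, 1e-300)) - self.mu) / self.sigma, -np.inf)
        return special.ndtr(-z)

    def pdf(self, t):
        return self._frozen.pdf(t)

    def cdf(self, t):
        return 1.0 - self.survival(t)

    def isf(self, q):
        if self.family in ("gamma", "exponential"):
            return special.gammainccinv(self.shape, q) * self.scale
        return np.exp(self.mu - self.sigma * special.ndtri(np.asarray(q, dtype=float)))

    def hazard(self, t):
        """Instantaneous event rate per day at age t: pdf(t)/survival(t)."""
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("hazard is defined for t > 0 only")
        s = self._frozen.sf(t)
        if np.any(s <= 0):
            raise FloatingPointError(
                "survival underflowed to 0; hazard is numerically undefined this far "
                "into the tail of the distribution"
            )
        return self._frozen.pdf(t) / s

    def rvs(self, size, rng: np.random.Generator):
        """Draw event times using the numpy generator directly (fast path)."""
        if self.family in ("gamma", "exponential"):
            return rng.gamma(self.shape, self.scale, size=size)
        return rng.lognormal(self.mu, self.sigma, size=size)

    # -- serialization -----------------------------------------------------
    def to_config(self) -> dict:
        cfg: dict = {"family": self.family}
        if self.family in ("gamma", "exponential"):
            cfg["shape"] = float(self.shape)
            cfg["scale"] = float(self.scale)
        else:
            cfg["mu"] = float(self.mu)
            cfg["sigma"] = float(self.sigma)
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "EventTimeDistribution":
        return cls(
            family=cfg["family"],
            shape=cfg.get("shape"),
            scale=cfg.get("scale"),
            mu=cfg.get("mu"),
            sigma=cfg.get("sigma"),
        )


@dataclass(frozen=True)
class PopulationSpec:
    """One or two independently homeostatic subpopulations with mixing proportions.

    Within a subpopulation the same distribution governs both the time to die
    and the time to divide; proportions are positive and sum to one.
    """

    subpops: tuple[tuple[EventTimeDistribution, float], ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.subpops) <= 2:
            raise ValueError("a population has 1 or 2 subpopulations")
        props = [p for _, p in self.subpops]
        if any(p <= 0 for p in props):
            raise ValueError("mixing proportions must be positive")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        object.__setattr__(self, "subpops", tuple((d, float(p)) for d, p in self.subpops))

    @classmethod
    def homogeneous(cls, dist: EventTimeDistribution) -> "PopulationSpec":
        return cls(subpops=((dist, 1.0),))

    @classmethod
    def heterogeneous(
        cls, dist_a: EventTimeDistribution, dist_b: EventTimeDistribution, proportion_a: float
    ) -> "PopulationSpec":
        return cls(subpops=((dist_a, proportion_a), (dist_b, 1.0 - proportion_a)))

    @property
    def distributions(self) -> list[EventTimeDistribution]:
        return [d for d, _ in self.subpops]

    @property
    def proportions(self) -> np.ndarray:
        return np.array([p for _, p in self.subpops])

    def to_config(self) -> dict:
        return {
            "subpops": [
                {"distribution": d.to_config(), "proportion": p} for d, p in self.subpops
            ]
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "PopulationSpec":
        return cls(
            subpops=tuple(
                (EventTimeDistribution.from_config(s["distribution"]), s["proportion"])
                for s in cfg["subpops"]
            )
        )


@dataclass(frozen=True)
class StationaryCellDraw:
    """A single cell drawn from the steady-state population.

    ``age`` is days since the cell's birth; the residuals are the remaining
    days until each clock rings (both strictly positive by conditioning).
    """

    age: float
    residual_divide: float
    residual_die: float


def survival(dist: EventTimeDistribution, t):
    """P(T > t) for the event-time distribution; survival(dist, 0) == 1."""
    return dist.survival(t)


def hazard(dist: EventTimeDistribution, t):
    """Event rate conditioned on survival to age t (per day)."""
    return dist.hazard(t)


def classify_paradigm(dist: EventTimeDistribution) -> Paradigm:
    """Map a distribution's parameters to the cell-fate paradigm it encodes.

    Gamma: shape 1 is age-independent (exponential), shape < 1 risk,
    shape > 1 cyton.  Lognormal cannot express age-independence; its mode
    ``exp(mu - sigma**2)`` must be above 7 days (cyton) or below 2 days (risk);
    anything in between is rejected rather than silently mislabeled.
    """
    if dist.family in ("gamma", "exponential"):
        if math.isclose(dist.shape, 1.0, rel_tol=1e-12):
            return Paradigm.AGE_INDEPENDENT
        return Paradigm.RISK if dist.shape < 1.0 else Paradigm.CYTON
    mode = dist.mode
    if mode > LOGNORMAL_CYTON_MODE_MIN:
        return Paradigm.CYTON
    if mode < LOGNORMAL_RISK_MODE_MAX:
        return Paradigm.RISK
    raise ParadigmError(
        f"lognormal mode {mode:.3g} d lies in the unclassifiable band "
        f"[{LOGNORMAL_RISK_MODE_MAX}, {LOGNORMAL_CYTON_MODE_MIN}] d"
    )


def median_lifespan(spec: PopulationSpec | EventTimeDistribution) -> float:
    """Median time to first event (division or death) in days.

    The lifespan is min(T_divide, T_die) with the two times iid, so for a
    homogeneous population the median m solves survival(m)**2 = 1/2; for a
    mixture the subpopulation min-survivals are weighted by proportion.
    """
    if isinstance(spec, EventTimeDistribution):
        spec = PopulationSpec.homogeneous(spec)

    dists = spec.distributions
    props = spec.proportions

    def min_survival(t: float) -> float:
        return float(sum(p * d.survival(t) ** 2 for d, p in zip(dists, props)))

    hi = max(float(d.isf(1.0 - 2.0 ** -0.5)) for d in dists)  # homogeneous answer bound
    while min_survival(hi) > 0.5:
        hi *= 2.0
    return float(optimize.brentq(lambda t: min_survival(t) - 0.5, 0.0, hi, xtol=1e-10, rtol=1e-12))


# --------------------------------------------------------------------------
# Stationary-age sampling
# --------------------------------------------------------------------------

_AGE_SAMPLER_CACHE: dict[EventTimeDistribution, tuple] = {}


def _stationary_age_tables(dist: EventTimeDistribution, quantile: float = 1.0 - 1e-6):
    """Inverse-CDF tables for the stationary age density ∝ survival(a)**2.

    Built by trapezoid quadrature of survival**2 on a composite linear+log grid
    extending to where the squared survival is negligible, then truncated at
    the requested quantile and inverted with a monotone (PCHIP) interpolant.
    """
    cached = _AGE_SAMPLER_CACHE.get(dist)
    if cached is not None:
        return cached
    t_hi = float(dist.isf(1e-9))
    grid = np.unique(
        np.concatenate(
            [
                [0.0],
                np.geomspace(max(t_hi * 1e-9, 1e-9), t_hi, 6000),
            ]
        )
    )
    s2 = dist.survival(grid) ** 2
    cdf = integrate.cumulative_trapezoid(s2, grid, initial=0.0)
    total = cdf[-1]
    cdf /= total
    keep = int(np.searchsorted(cdf, quantile)) + 1
    grid, cdf = grid[: keep + 1], cdf[: keep + 1]
    # strictly increasing cdf needed for interpolation
    mono = np.concatenate([[True], np.diff(cdf) > 0])
    inv = interpolate.PchipInterpolator(cdf[mono], grid[mono])
    tables = (inv, float(cdf[mono][-1]))
    _AGE_SAMPLER_CACHE[dist] = tables
    return tables


def sample_stationary_cells(
    dist: EventTimeDistribution, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized stationary draw: (ages, time_to_divide, time_to_die).

    Event times are measured from birth (so the residuals are ``t_div - age``
    and ``t_die - age``), drawn conditional on both clocks exceeding the age.
    """
    inv, u_max = _stationary_age_tables(dist)
    ages = np.asarray(inv(rng.uniform(0.0, u_max, size=n)), dtype=float)
    ages = np.maximum(ages, 0.0)
    sf_a = dist.survival(ages)
    # T | T > a sampled as isf(u * sf(a)) — stable deep in the tail.
    t_div = dist.isf(rng.uniform(size=n) * sf_a)
    t_die = dist.isf(rng.uniform(size=n) * sf_a)
    t_div = np.maximum(t_div, ages + 1e-12)
    t_die = np.maximum(t_die, ages + 1e-12)
    return ages, t_div, t_die


def sample_stationary_cell(
    dist: EventTimeDistribution, rng: np.random.Generator
) -> StationaryCellDraw:
    """Draw one steady-state cell: age ∝ survival(a)**2, residuals conditioned > 0."""
    ages, t_div, t_die = sample_stationary_cells(dist, 1, rng)
    return StationaryCellDraw(
        age=float(ages[0]),
        residual_divide=float(t_div[0] - ages[0]),
        residual_die=float(t_die[0] - ages[0]),
    )
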