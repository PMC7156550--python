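"""Deuterium label availability U(t) for heavy-water and glucose protocols.

Heavy water equilibrates with body water, so its enrichment rises with
saturation kinetics toward a plateau ``f`` at turnover rate ``delta`` from an
initial primed level ``beta``, and decays exponentially once intake stops at
day ``tau``:

    U(t) = f (1 - exp(-delta t)) + beta exp(-delta t)          t <= tau
    U(t) = U(tau) exp(-delta (t - tau))                        t >  tau

Deuterated glucose turns over within minutes, so a 24 h infusion is modelled
as a square pulse of height ``U`` and length ``tau``.

The simulation engines consume the *normalized* availability ``U(t)/f`` so
that a fully turned-over population approaches a labeled fraction of 1,
matching published labeling curves which are normalized fractions of labeled
DNA; the absolute enrichment scale carries no free parameter in the fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "HeavyWaterProtocol",
    "GlucoseProtocol",
    "EnrichmentSeries",
    "EnrichmentFit",
    "water_enrichment",
    "glucose_enrichment",
    "fit_enrichment",
]


@dataclass(frozen=True)
class HeavyWaterProtocol:
    """Body-water enrichment model: plateau f, turnover delta (/day), prime beta, end day tau."""

    f: float
    delta: float
    beta: float
    tau: float

    def __post_init__(self) -> None:
        if not 0 < self.f <= 1:
            raise ValueError("plateau enrichment f must lie in (0, 1]")
        if self.delta <= 0:
            raise ValueError("body-water turnover delta must be positive")
        if not 0 <= self.beta <= self.f:
            raise ValueError("prime enrichment beta must lie in [0, f]")
        if self.tau <= 0:
            raise ValueError("label-end day tau must be positive")

    def enrichment(self, t):
        return water_enrichment(self, t)

    def normalized(self, t):
        """U(t)/f — availability on the normalized labeled-DNA scale."""
        return water_enrichment(self, t) / self.f

    def to_config(self) -> dict:
        return {
            "kind": "heavy_water",
            "f": self.f,
            "delta": self.delta,
            "beta": self.beta,
            "tau": self.tau,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "HeavyWaterProtocol":
        return cls(f=cfg["f"], delta=cfg["delta"], beta=cfg["beta"], tau=cfg["tau"])


@dataclass(frozen=True)
class GlucoseProtocol:
    """Square-pulse glucose enrichment: height U for t <= tau (days), 0 after."""

    U: float
    tau: float

    def __post_init__(self) -> None:
        if not 0 < self.U <= 1:
            raise ValueError("pulse enrichment U must lie in (0, 1]")
        if self.tau <= 0:
            raise ValueError("pulse length tau must be positive")

    def enrichment(self, t):
        return glucose_enrichment(self, t)

    def normalized(self, t):
        # The Annexin signature is invariant to the absolute enrichment scale,
        # so the normalized pulse is simply 1 during intake.
        t = np.asarray(t, dtype=float)
        return np.where(t <= self.tau, 1.0, 0.0)

    def to_config(self) -> dict:
        return {"kind": "glucose", "U": self.U, "tau": self.tau}

    @classmethod
    def from_config(cls, cfg: dict) -> "GlucoseProtocol":
        return cls(U=cfg["U"], tau=cfg["tau"])


@dataclass(frozen=True)
class EnrichmentSeries:
    """Measured label availability (plasma or urine): strictly increasing days, fractions."""

    times: np.ndarray
    enrichment: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.enrichment, dtype=float)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and enrichment must be 1-d arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((e < 0) | (e > 1)):
            raise ValueError("enrichment values must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "enrichment", e)


def water_enrichment(p: HeavyWaterProtocol, t):
    """Heavy-water enrichment U(t); continuous at the intake end t = tau."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    rising = p.f * (1.0 - np.exp(-p.delta * t)) + p.beta * np.exp(-p.delta * t)
    u_tau = p.f * (1.0 - np.exp(-p.delta * p.tau)) + p.beta * np.exp(-p.delta * p.tau)
    falling = u_tau * np.exp(-p.delta * (t - p.tau))
    out = np.where(t <= p.tau, rising, falling)
    return out if out.ndim else float(out)


def glucose_enrichment(p: GlucoseProtocol, t):
    """Square pulse: U during intake (t <= tau, boundary inclusive), 0 after."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = np.where(t <= p.tau, p.U, 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class EnrichmentFit:
    """Least-squares availability fit: protocol, residual sum, and standard errors."""

    protocol: HeavyWaterProtocol
    ssr: float
    stderr: dict[str, float]


def fit_enrichment(series: EnrichmentSeries, tau: float) -> EnrichmentFit:
    """Estimate (f, delta, beta) from an enrichment series with tau fixed by protocol.

    Requires at least 4 observations; warns when the series does not span both
    the labeling and delabeling phases (delta weakly identified) or when the
    series is flat (beta ≈ f leaves delta undetermined).
    """
    t, y = series.times, series.enrichment
    if t.size < 4:
        raise ValueError("need at least 4 observations to estimate f, delta, beta")
    if np.all(t <= tau) or np.all(t > tau):
        warnings.warn(
            "enrichment series lies entirely within one phase; the turnover rate "
            "delta is weakly identified",
            stacklevel=2,
        )
    if np.ptp(y) < 1e-3 * max(y.max(), 1e-12):
        warnings.warn(
            "enrichment series is effectively constant (beta ≈ f): delta is not "
            "identifiable from these data",
            stacklevel=2,
        )

    def model(tt, f, delta, beta_frac):
        p = HeavyWaterProtocol(f=f, delta=delta, beta=beta_frac * f, tau=tau)
        return water_enrichment(p, tt)

    f0 = max(float(y.max()), 1e-6)
    p0 = (f0, 0.1, min(max(float(y[0]) / f0, 0.0), 1.0))
    popt, pcov = optimize.curve_fit(
        model, t, y, p0=p0, bounds=([1e-9, 1e-6, 0.0], [1.0, 10.0, 1.0]),
        maxfev=20000, ftol=1e-14, xtol=1e-14, gtol=1e-14,
    )
    f, delta, beta_frac = popt
    proto = HeavyWaterProtocol(f=float(f), delta=float(delta), beta=float(beta_frac * f), tau=tau)
    resid = y - water_enrichment(proto, t)
    perr = np.sqrt(np.diag(pcov))
    stderr = {"f": float(perr[0]), "delta": float(perr[1]), "beta": float(perr[2] * f)}
    return EnrichmentFit(protocol=proto, ssr=float(resid @ resid), stderr=stderr)
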