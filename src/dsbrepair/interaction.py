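"""Spatial misrepair kernel for DSB free-end interactions.

Two free DNA ends separated by a distance ``d`` interact (misrejoin) at a
rate ``zeta(d) = exp(-d^2 / 2 sigma^2)``, normalised so that the two ends of
a single break (d = 0) interact at rate 1.  With that normalisation the
total competing interaction rate seen by one break among N uniformly placed
breaks is ``eta = (N - 1) * theta(R, sigma)``, where ``theta`` is the mean of
``2 zeta`` over independent uniform point pairs in the spherical nucleus,
and the correct-rejoining probability is ``(1 - e^-eta)/eta`` (see
:mod:`dsbrepair.repair`).

``theta`` is evaluated by deterministic quadrature over the analytic
pair-distance density for a uniform sphere; it is scale invariant,
``theta(kR, k sigma, k r_max) == theta(R, sigma, r_max)``.
"""

from __future__ import annotations

import functools
import math

import numpy as np
from scipy import integrate

__all__ = ["zeta", "sphere_pair_distance_pdf", "theta", "eta_uniform",
           "InteractionRates", "interaction_rates"]


def zeta(d, sigma: float):
    """Pairwise end-interaction rate at separation ``d`` (same length units).

    Gaussian in the separation, ``zeta(0) = 1``.  Accepts scalars or arrays.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be strictly positive, got {sigma}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("separation d must be non-negative")
    out = np.exp(-0.5 * (d / sigma) ** 2)
    return float(out) if out.ndim == 0 else out


def sphere_pair_distance_pdf(s, radius: float):
    """Density of the distance between two uniform points in a sphere.

    f(s) = 3 s^2/R^3 - 9 s^3/(4 R^4) + 3 s^5/(16 R^6) on [0, 2R].
    """
    if not radius > 0:
        raise ValueError("radius must be strictly positive")
    s = np.asarray(s, dtype=float)
    x = s / radius
    f = (3.0 * x ** 2 - 2.25 * x ** 3 + 0.1875 * x ** 5) / radius
    f = np.where((x >= 0) & (x <= 2.0), f, 0.0)
    return float(f) if f.ndim == 0 else f


@functools.lru_cache(maxsize=4096)
def _theta_cached(radius: float, sigma: float, r_max: float | None) -> float:
    upper = 2.0 * radius if r_max is None else min(float(r_max), 2.0 * radius)
    if upper <= 0.0:
        return 0.0

    def integrand(s):
        return 2.0 * zeta(s, sigma) * sphere_pair_distance_pdf(s, radius)

    # Split at ~the Gaussian scale so quad resolves a narrow kernel in a
    # large sphere (sigma can be ~2% of the radius).
    pts = [p for p in (sigma, 3 * sigma, 6 * sigma) if 0 < p < upper]
    val, _ = integrate.quad(integrand, 0.0, upper, points=pts or None,
                            limit=200, epsabs=1e-13, epsrel=1e-10)
    return val


def theta(radius: float, sigma: float, r_max: float | None = None) -> float:
    """Mean pair interaction rate ``E[2 zeta(d)]`` in a sphere.

    When ``r_max`` is given, only pairs closer than ``r_max`` are counted
    (not renormalised), so ``theta(R, sigma, r_max) <= theta(R, sigma)`` with
    equality for ``r_max >= 2R``.
    """
    if not radius > 0:
        raise ValueError(f"radius must be strictly positive, got {radius}")
    if not sigma > 0:
        raise ValueError(f"sigma must be strictly positive, got {sigma}")
    if r_max is not None and not r_max > 0:
        raise ValueError(f"r_max must be strictly positive, got {r_max}")
    return _theta_cached(float(radius), float(sigma),
                         None if r_max is None else float(r_max))


def eta_uniform(n_dsb: float, radius: float, sigma: float) -> float:
    """Total competing interaction rate for ``n_dsb`` uniform DSBs.

    ``eta = (N - 1) theta(R, sigma)`` for N >= 1, zero below one break.
    Continuous N is allowed (expectation-level arithmetic).
    """
    if n_dsb < 0:
        raise ValueError(f"n_dsb must be non-negative, got {n_dsb}")
    if n_dsb <= 1.0:
        return 0.0
    return (n_dsb - 1.0) * theta(radius, sigma)


from dataclasses import dataclass


@dataclass(frozen=True)
class InteractionRates:
    """Bundle of sphere-averaged interaction rates for one configuration."""

    theta_full: float
    theta_restricted: float
    eta_uniform: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_restricted <= self.theta_full <= 2.0:
            raise ValueError("require 0 <= theta_restricted <= theta_full <= 2")
        if self.eta_uniform < 0:
            raise ValueError("eta_uniform must be non-negative")


def interaction_rates(n_dsb: float, radius: float, sigma: float,
                      r_max: float | None = None) -> InteractionRates:
    full = theta(radius, sigma)
    restricted = theta(radius, sigma, r_max) if r_max is not None else full
    return InteractionRates(theta_full=full, theta_restricted=restricted,
                            eta_uniform=eta_uniform(n_dsb, radius, sigma))
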