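"""Shared fixtures and brute-force Monte-Carlo oracles.

The oracles deliberately avoid the package's quadrature/discretisation code
paths: they sample explicit spatial configurations and average the pairwise
interaction kernel directly, providing an independent reference for the
sphere-averaged rates and the intra-track interaction rate.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dsbrepair as dr
from dsbrepair.tracks import radial_dsb_density

settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return dr.ModelParameters()


@pytest.fixture(scope="session")
def geometry(params):
    return dr.geometry_from_edsb(params.e_dsb, params)


@pytest.fixture(scope="session")
def phenotypes():
    return {p.name: p for p in dr.bundled_phenotypes()}


@pytest.fixture(scope="session")
def human(phenotypes):
    return phenotypes["human-normal"]


@pytest.fixture(scope="session")
def hamster(phenotypes):
    return phenotypes["hamster"]


# ---------------------------------------------------------------------------
# Monte-Carlo oracles

def sample_sphere(n: int, rng: np.random.Generator, radius: float = 1.0):
    """Uniform points in a ball: isotropic direction, r ~ u^(1/3)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return radius * v * rng.uniform(0.0, 1.0, n)[:, None] ** (1.0 / 3.0)


def mc_theta(radius: float, sigma: float, rng: np.random.Generator,
             n_pairs: int = 1_000_000, r_max: float | None = None):
    """Mean of 2 zeta(d) over uniform point pairs; returns (mean, stderr)."""
    a = sample_sphere(n_pairs, rng, radius)
    b = sample_sphere(n_pairs, rng, radius)
    d = np.linalg.norm(a - b, axis=1)
    vals = 2.0 * np.exp(-0.5 * (d / sigma) ** 2)
    if r_max is not None:
        vals = np.where(d < r_max, vals, 0.0)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_pairs))


def mc_eta_placements(n_dsb: int, radius: float, sigma: float,
                      rng: np.random.Generator, n_placements: int = 4000):
    """Place n_dsb points, average sum of 2 zeta over competing pairs.

    Returns (mean, stderr) of the per-break competing interaction rate,
    averaged over placements.
    """
    means = np.empty(n_placements)
    for k in range(n_placements):
        pts = sample_sphere(n_dsb, rng, radius)
        dm = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        z = np.exp(-0.5 * (dm / sigma) ** 2)
        np.fill_diagonal(z, 0.0)
        means[k] = 2.0 * z.sum(axis=1).mean()
    return float(means.mean()), float(means.std(ddof=1) / np.sqrt(n_placements))


def _one_track_realisation(profile, e_dsb, sigma_nm, rng, target_dsbs,
                           margin_um):
    dens = radial_dsb_density(profile, e_dsb)
    lam = dens.sum()  # DSB per um of track
    length_um = max(target_dsbs / lam, 4.0 * margin_um)
    n = rng.poisson(lam * length_um)
    p_bin = dens / dens.sum()
    idx = rng.choice(len(dens), size=n, p=p_bin)
    lo = profile.bin_edges_nm[idx]
    hi = profile.bin_edges_nm[idx + 1]
    r = np.sqrt(rng.uniform(lo ** 2, hi ** 2))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    x, y = r * np.cos(phi), r * np.sin(phi)
    z = np.sort(rng.uniform(0.0, length_um * 1e3, n))
    win = margin_um * 1e3
    central = (z > win) & (z < z[-1] - win)
    j0 = np.searchsorted(z, z - win)
    j1 = np.searchsorted(z, z + win)
    total, count = 0.0, 0
    for i in np.nonzero(central)[0]:
        sl = slice(j0[i], j1[i])
        d2 = (x[sl] - x[i]) ** 2 + (y[sl] - y[i]) ** 2 + (z[sl] - z[i]) ** 2
        total += 2.0 * (np.exp(-0.5 * d2 / sigma_nm ** 2).sum() - 1.0)
        count += 1
    return total / count


def mc_eta_track(profile, e_dsb: float, sigma_abs_um: float,
                 rng: np.random.Generator, target_dsbs: int = 100_000,
                 n_replicates: int = 6, margin_um: float = 5.0):
    """Explicit 3D track simulation of the intra-track interaction rate.

    DSBs are placed along a long track segment with the radial density
    implied by the profile (bin chosen by energy, radius area-uniform in the
    bin, angle uniform, longitudinal position uniform); for every break in
    the central region the sum of 2 zeta over neighbours within the margin
    is accumulated.  The estimate is averaged over independent replicate
    tracks and the standard error taken from the replicate spread, which is
    robust to the heavy-tailed close-pair statistics at low LET.
    """
    sigma_nm = sigma_abs_um * 1e3
    reps = np.array([
        _one_track_realisation(profile, e_dsb, sigma_nm, rng,
                               target_dsbs // n_replicates, margin_um)
        for _ in range(n_replicates)])
    return float(reps.mean()), float(reps.std(ddof=1) / np.sqrt(n_replicates))
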