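"""DSB induction, repair-pathway assignment, kinetics and aberration yields.

The pipeline for a single exposure is: dose -> expected initial break count
N0 (proportional to dose and DNA content) -> assignment of breaks to repair
pathways by phase and phenotype -> probability of correct rejoining under
competition from nearby breaks -> classification of misrepaired events into
dicentrics, large deletions and (in G2) inter-arm events:

    N_mis      = N0 (1 - P_correct)
    N_dic      = P_asym * N_mis (1 - P_intra)
    N_del      = P_asym * N_mis * P_intra (1 - P_del<D)
    N_interArm = N_mis * P_intra * P_interArm

Chromosomes are modelled as equal spherical territories of radius
r_c = R / n_c^(1/3).  The probability that a misrepair partner lies in the
same chromosome weights the within-territory pair rate by the fraction of
breaks in one territory: P_intra = theta(r_c, sigma) / (n_c theta(R, sigma)),
which tends to 1 for a single chromosome and to the random-partner limit
1/n_c when the rejoining range is large compared to the nucleus.

Deletion sizes map to spatial separation through D = 2 L r_D^3 / R^3 (L the
total DNA length in bp), so the fraction of intra-chromosome events smaller
than the lethal threshold is a ratio of distance-restricted to full pair
rates within a territory.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .config import CellCyclePhase, CellPhenotype, ModelParameters, NuclearGeometry
from .interaction import eta_uniform, sphere_pair_distance_pdf, theta, zeta

__all__ = [
    "PathwayAssignment", "DamageState", "AberrationYields",
    "induce_dsbs", "assign_pathways", "remaining_dsbs",
    "correct_repair_probability", "intra_chromosome_probability",
    "deletion_distance", "deletion_below_probability",
    "inter_arm_probability", "aberration_yields",
]

_PATHWAYS = ("NHEJ", "HR", "MMEJ")


@dataclass(frozen=True)
class PathwayAssignment:
    """Fractions of breaks handled by each pathway plus fidelity/rate maps."""

    fractions: dict  # pathway -> fraction of DSBs
    fidelities: dict  # pathway -> probability of faithful rejoin
    rates: dict       # pathway -> repair rate, 1/h

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pathway fractions must sum to 1, got {total}")

    @property
    def effective_fidelity(self) -> float:
        return sum(self.fractions[p] * self.fidelities[p] for p in _PATHWAYS)


@dataclass(frozen=True)
class DamageState:
    """Expected damage and repair context for one exposure of one phase."""

    n_dsb_initial: float
    frac_complex: float
    pathway_fractions: dict
    effective_fidelity: float
    eta_total: float


@dataclass(frozen=True)
class AberrationYields:
    n_mis: float
    n_dic: float
    n_del: float
    n_inter_arm: float
    p_intra: float
    p_del_below: float
    p_inter_arm: float

    def __post_init__(self) -> None:
        for name in ("n_mis", "n_dic", "n_del", "n_inter_arm"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{name} must be non-negative")
        for name in ("p_intra", "p_del_below", "p_inter_arm"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_dic + self.n_del > self.n_mis * (1 + 1e-9) + 1e-12:
            raise ValueError("n_dic + n_del cannot exceed n_mis")


def induce_dsbs(dose: float, phenotype: CellPhenotype,
                params: ModelParameters | None = None) -> float:
    """Expected initial DSB count N0 for a dose in Gy.

    Proportional to dose and total DNA content (doubled after replication in
    G2/M).  Requires a resolved (non-asynchronous) phase.
    """
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    params = params or ModelParameters()
    return dose * params.dsb_yield * phenotype.genome_bp() / 1e9


def assign_pathways(phenotype: CellPhenotype,
                    params: ModelParameters | None = None) -> PathwayAssignment:
    """Distribute breaks over NHEJ / HR / MMEJ by phase and competence.

    Simple breaks use NHEJ throughout the cycle; complex breaks use NHEJ in
    G1 and HR after replication.  A break routed to a defective pathway
    fails over to MMEJ with probability ``p_fail``; the remainder is rejoined
    by NHEJ machinery (retaining NHEJ kinetics and fidelity, also when NHEJ
    itself is the compromised pathway).
    """
    params = params or ModelParameters()
    phase = phenotype.phase
    if phase is CellCyclePhase.ASYNC:
        raise ValueError("asynchronous populations must be expanded to G1/G2 "
                         "before pathway assignment")

    if phase.replicated:
        intended = {"NHEJ": 1.0 - params.p_complex, "HR": params.p_complex}
    else:
        intended = {"NHEJ": 1.0}

    competent = {"NHEJ": phenotype.nhej_competent, "HR": phenotype.hr_competent}
    frac = {"NHEJ": 0.0, "HR": 0.0, "MMEJ": 0.0}
    for pathway, share in intended.items():
        if competent[pathway]:
            frac[pathway] += share
        else:
            frac["MMEJ"] += share * params.p_fail
            frac["NHEJ"] += share * (1.0 - params.p_fail)

    return PathwayAssignment(
        fractions=frac,
        fidelities={"NHEJ": params.mu_nhej, "HR": params.mu_hr,
                    "MMEJ": params.mu_mmej},
        rates={"NHEJ": params.lambda_fast, "HR": params.lambda_slow,
               "MMEJ": params.lambda_mmej},
    )


def remaining_dsbs(t, n_dsb_initial: float, assignment: PathwayAssignment):
    """Unrepaired break count N(t): tri-exponential decay, t in hours."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = n_dsb_initial * sum(
        assignment.fractions[p] * np.exp(-assignment.rates[p] * t)
        for p in _PATHWAYS)
    return float(out) if np.ndim(out) == 0 else out


def correct_repair_probability(eta_total, fidelity: float = 1.0):
    """P_correct = mu (1 - e^-eta)/eta, with the eta -> 0 limit equal to mu."""
    if not 0.0 <= fidelity <= 1.0:
        raise ValueError("fidelity must lie in [0, 1]")
    eta = np.asarray(eta_total, dtype=float)
    if np.any(eta < 0):
        raise ValueError("eta_total must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(eta > 1e-12, -np.expm1(-eta) / np.where(eta > 0, eta, 1.0),
                        1.0 - eta / 2.0)
    out = fidelity * frac
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Aberration classification

def chromosome_radius(geometry: NuclearGeometry, n_chromosomes: int) -> float:
    """Equal-volume spherical territory radius r_c = R / n_c^(1/3), in um."""
    return geometry.radius_um / n_chromosomes ** (1.0 / 3.0)


@functools.lru_cache(maxsize=1024)
def _p_intra_cached(n_chromosomes: int, sigma_rel: float) -> float:
    r_c_rel = n_chromosomes ** (-1.0 / 3.0)
    return min(theta(r_c_rel, sigma_rel)
               / (n_chromosomes * theta(1.0, sigma_rel)), 1.0)


def intra_chromosome_probability(phenotype: CellPhenotype,
                                 geometry: NuclearGeometry) -> float:
    """Probability a misrepair partner lies within the same chromosome.

    Within-territory pair rate weighted by the 1/n_c share of breaks in one
    territory, relative to the whole-nucleus rate.  Depends only on the
    chromosome count and the relative rejoining range sigma/R (the pair
    rates are scale invariant), so it is evaluated on the unit sphere and
    cached.
    """
    return _p_intra_cached(phenotype.n_chromosomes,
                           geometry.sigma_abs_um / geometry.radius_um)


def deletion_distance(size_bp: float, genome_bp: float,
                      geometry: NuclearGeometry) -> float:
    """Spatial separation r_D (um) producing a deletion of ``size_bp``.

    Inverts D = 2 L r_D^3 / R^3 with L the total DNA length in bp.
    """
    if size_bp < 0:
        raise ValueError("deletion size must be non-negative")
    return geometry.radius_um * (size_bp / (2.0 * genome_bp)) ** (1.0 / 3.0)


@functools.lru_cache(maxsize=1024)
def _restricted_theta_table(n_chromosomes: int, sigma_rel: float,
                            n_grid: int = 4001):
    """Cumulative within-territory pair rate on the unit-radius nucleus.

    Returns (separation grid in units of R, cumulative theta(r_c, sigma, r))
    for r up to the territory diameter; the last entry is the full
    theta(r_c, sigma).
    """
    r_c = n_chromosomes ** (-1.0 / 3.0)
    s = np.linspace(0.0, 2.0 * r_c, n_grid)
    g = 2.0 * zeta(s, sigma_rel) * sphere_pair_distance_pdf(s, r_c)
    cum = integrate.cumulative_trapezoid(g, s, initial=0.0)
    return s, cum


def deletion_below_probability(size_bp: float, phenotype: CellPhenotype,
                               geometry: NuclearGeometry) -> float:
    """P_del<D: fraction of intra-chromosome events smaller than ``size_bp``.

    The deletion threshold maps to a relative separation r_D/R =
    (D / 2L)^(1/3); the probability is the ratio of the distance-restricted
    to the full within-territory pair rate, clamped to 1 when r_D exceeds
    the territory diameter.
    """
    if size_bp < 0:
        raise ValueError("deletion size must be non-negative")
    sigma_rel = geometry.sigma_abs_um / geometry.radius_um
    r_d_rel = (size_bp / (2.0 * phenotype.genome_bp())) ** (1.0 / 3.0)
    return _deletion_below_rel(r_d_rel, phenotype.n_chromosomes, sigma_rel)


def _deletion_below_rel(r_d_rel: float, n_chromosomes: int,
                        sigma_rel: float) -> float:
    s, cum = _restricted_theta_table(n_chromosomes, sigma_rel)
    if r_d_rel <= 0.0:
        return 0.0
    if r_d_rel >= s[-1]:
        return 1.0
    return float(np.interp(r_d_rel, s, cum) / cum[-1])


@functools.lru_cache(maxsize=1024)
def _inter_arm_cached(n_chromosomes: int, sigma_rel: float, genome_bp: float,
                      n_points: int) -> float:
    l_c = genome_bp / n_chromosomes
    half = 0.5 * l_c
    # P_del>b decays on the genomic scale where r(b) ~ sigma; cluster nodes
    # there with a power-law grid.
    u = np.linspace(0.0, 1.0, n_points)
    b = half * u ** 3
    r_rel = (b / (2.0 * genome_bp)) ** (1.0 / 3.0)
    p_above = np.array([1.0 - _deletion_below_rel(r, n_chromosomes, sigma_rel)
                        for r in r_rel])
    integral = integrate.simpson(p_above, x=b)
    return float(min(max(integral / half, 0.0), 1.0))


def inter_arm_probability(phenotype: CellPhenotype,
                          geometry: NuclearGeometry,
                          params: ModelParameters | None = None,
                          n_points: int = 257) -> float:
    """Probability an intra-chromosome misrepair spans the centromere (G2).

    A break at genomic distance b from the (central) centromere of an
    equal-size chromosome of length l_c = L / n_c joins across the
    centromere when its partner is further than b away in the genome:
    P_interArm(b) = P_del>b.  Averaging over b uniform on [0, l_c/2] gives
    P_interArm = (2/l_c) * Integral_0^{l_c/2} P_del>b db, evaluated by
    Simpson quadrature on a grid dense near b = 0 where the integrand
    varies fastest.
    """
    genome = phenotype.genome_bp()
    if genome <= 0:
        return 0.0
    return _inter_arm_cached(phenotype.n_chromosomes,
                             geometry.sigma_abs_um / geometry.radius_um,
                             genome, n_points)


def aberration_yields(n_dsb: float, p_correct: float,
                      phenotype: CellPhenotype, geometry: NuclearGeometry,
                      params: ModelParameters | None = None,
                      p_inter_arm: float | None = None) -> AberrationYields:
    """Misrepair and aberration-class yields for one phase exposure.

    ``p_inter_arm`` may be supplied to reuse a precomputed value; it is only
    meaningful (and only used by survival) for replicated phases.
    """
    params = params or ModelParameters()
    if not 0.0 <= p_correct <= 1.0:
        raise ValueError("p_correct must lie in [0, 1]")
    if n_dsb < 0:
        raise ValueError("n_dsb must be non-negative")

    p_intra = intra_chromosome_probability(phenotype, geometry)
    p_below = deletion_below_probability(params.deletion_threshold,
                                         phenotype, geometry)
    if p_inter_arm is None:
        p_inter_arm = (inter_arm_probability(phenotype, geometry, params)
                       if phenotype.phase.replicated else 0.0)

    n_mis = n_dsb * (1.0 - p_correct)
    n_dic = params.p_asym * n_mis * (1.0 - p_intra)
    n_del = params.p_asym * n_mis * p_intra * (1.0 - p_below)
    n_inter = n_mis * p_intra * p_inter_arm
    return AberrationYields(n_mis=n_mis, n_dic=n_dic, n_del=n_del,
                            n_inter_arm=n_inter, p_intra=p_intra,
                            p_del_below=p_below, p_inter_arm=p_inter_arm)


def damage_state(dose: float, phenotype: CellPhenotype,
                 geometry: NuclearGeometry,
                 params: ModelParameters | None = None,
                 eta_track: float = 0.0) -> DamageState:
    """Assemble the expected damage summary for one exposure."""
    params = params or ModelParameters()
    n0 = induce_dsbs(dose, phenotype, params)
    assignment = assign_pathways(phenotype, params)
    eta = eta_uniform(n0, geometry.radius_um, geometry.sigma_abs_um) + eta_track
    return DamageState(n_dsb_initial=n0, frac_complex=params.p_complex,
                       pathway_fractions=assignment.fractions,
                       effective_fidelity=assignment.effective_fidelity,
                       eta_total=eta)
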