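"""Cell survival, linear-quadratic fitting, MID, D10 and RBE.

Survival combines three death routes, each Poisson-distributed around the
expected yields from :mod:`dsbrepair.repair`:

* aberration lethality — ``exp(-N_dic - N_del)`` for cells irradiated in G1
  (dicentrics plus deletions above the lethal threshold) and
  ``exp(-N_dic - N_interArm)`` in G2/M (inter-arm events replace deletions,
  whose double-lethality in G2 is neglected);
* mitotic catastrophe for cells irradiated in G2/M, ``exp(-psi_m N_m)`` with
  ``N_m`` the initial break count;
* G1 arrest/apoptosis for cells irradiated in G1, ``exp(-phi_a N_G1)``,
  applied only in lines with a functional G1 arrest; ``N_G1`` is the break
  count when the cell resumes cycling (optionally decayed over a replating
  delay using the repair kinetics).

Asynchronous populations are a 2:1 G1:G2 mixture.  Dose-response curves on
a 0-10 Gy grid are summarised by a non-negative least-squares LQ fit
(ln S = -alpha D - beta D^2), the mean inactivation dose

    MID = Integral_0^inf e^(-aD - bD^2) dD
        = e^(a^2/4b) sqrt(pi) erfc(a / 2 sqrt(b)) / (2 sqrt(b))

and D10; RBE is the ratio of reference (X-ray) to ion dose at the same
endpoint.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .config import (CellCyclePhase, CellPhenotype, ModelParameters,
                     NuclearGeometry, geometry_from_edsb)
from .interaction import theta
from .repair import (assign_pathways, correct_repair_probability,
                     deletion_below_probability, induce_dsbs,
                     inter_arm_probability, intra_chromosome_probability,
                     remaining_dsbs)
from .tracks import IonContext, track_count_average

__all__ = [
    "DoseResponse", "phase_survival", "asynchronous_survival", "survival",
    "survival_given_dsbs", "dose_response", "fit_lq", "mid_closed_form",
    "mid_quadrature", "d10", "rbe", "DEFAULT_DOSE_GRID",
]

DEFAULT_DOSE_GRID = np.arange(0.0, 10.0 + 1e-9, 0.5)


@functools.lru_cache(maxsize=512)
class _PhaseModel:
    """Precomputed constants for one (phenotype, geometry, params) phase.

    Hashable frozen inputs make this safely memoisable; the per-call work in
    :meth:`survival_given_dsbs` is then a handful of vectorised operations,
    which keeps Poisson track averaging and the E_DSB fit cheap.
    """

    def __init__(self, phenotype: CellPhenotype, geometry: NuclearGeometry,
                 params: ModelParameters):
        if phenotype.phase is CellCyclePhase.ASYNC:
            raise ValueError("phase must be resolved to G1/G2/M")
        self.phenotype = phenotype
        self.geometry = geometry
        self.params = params
        self.assignment = assign_pathways(phenotype, params)
        self.mu_eff = self.assignment.effective_fidelity
        self.theta_nucleus = theta(geometry.radius_um, geometry.sigma_abs_um)
        self.p_intra = intra_chromosome_probability(phenotype, geometry)
        self.p_del_below = deletion_below_probability(
            params.deletion_threshold, phenotype, geometry)
        self.replicated = phenotype.phase.replicated
        self.p_inter_arm = (inter_arm_probability(phenotype, geometry, params)
                            if self.replicated else 0.0)

    def survival_given_dsbs(self, n_dsb, eta_track: float = 0.0,
                            replating_delay_h: float | None = None):
        """Survival for an array of initial DSB counts (vectorised)."""
        n = np.asarray(n_dsb, dtype=float)
        p = self.params
        eta = np.clip(n - 1.0, 0.0, None) * self.theta_nucleus + eta_track
        p_correct = correct_repair_probability(eta, self.mu_eff)
        n_mis = n * (1.0 - p_correct)

        if self.replicated:
            lethal = (p.p_asym * n_mis * (1.0 - self.p_intra)
                      + n_mis * self.p_intra * self.p_inter_arm)
            lethal = lethal + p.mitotic_sensitivity * n
        else:
            n_del = p.p_asym * n_mis * self.p_intra * (1.0 - self.p_del_below)
            lethal = p.p_asym * n_mis * (1.0 - self.p_intra) + n_del
            if self.phenotype.g1_arrest_competent:
                n_g1 = n
                if replating_delay_h is not None:
                    n_g1 = remaining_dsbs(replating_delay_h, 1.0,
                                          self.assignment) * n
                lethal = lethal + p.apoptotic_sensitivity * n_g1
        out = np.exp(-lethal)
        return float(out) if out.ndim == 0 else out


def _resolve(phenotype: CellPhenotype, phase, params, geometry):
    params = params or ModelParameters()
    geometry = geometry or geometry_from_edsb(params.e_dsb, params)
    pheno = phenotype.in_phase(phase) if phase is not None else phenotype
    return pheno, params, geometry


def survival_given_dsbs(n_dsb, phenotype: CellPhenotype,
                        params: ModelParameters | None = None,
                        geometry: NuclearGeometry | None = None,
                        eta_track: float = 0.0,
                        replating_delay_h: float | None = None):
    """Survival as a function of the initial break count for one phase."""
    phenotype, params, geometry = _resolve(phenotype, None, params, geometry)
    model = _PhaseModel(phenotype, geometry, params)
    return model.survival_given_dsbs(n_dsb, eta_track, replating_delay_h)


def phase_survival(dose: float, phenotype: CellPhenotype,
                   params: ModelParameters | None = None,
                   geometry: NuclearGeometry | None = None,
                   ion: IonContext | None = None,
                   replating_delay_h: float | None = None) -> float:
    """Survival probability for cells irradiated in one resolved phase.

    For ion exposures where a single traversal is expected to produce more
    than the threshold number of DSBs, the response is averaged over a
    Poisson-distributed number of tracks; otherwise the expected total break
    count is used directly.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    phenotype, params, geometry = _resolve(phenotype, None, params, geometry)
    model = _PhaseModel(phenotype, geometry, params)
    n0 = induce_dsbs(dose, phenotype, params)
    eta_track = ion.eta_track if ion is not None else 0.0
    per_track = ion.dsb_per_track if ion is not None else 0.0
    # After replication a traversal intercepts twice the DNA: both the DSBs
    # per track and the intra-track neighbour density double, keeping the
    # track count at a given dose independent of phase.
    if phenotype.phase.replicated:
        per_track = 2.0 * per_track
        eta_track = 2.0 * eta_track

    def response(n_array):
        return model.survival_given_dsbs(n_array, eta_track,
                                         replating_delay_h)

    return track_count_average(n0, per_track, response,
                               threshold=params.track_poisson_threshold)


def asynchronous_survival(dose: float, phenotype: CellPhenotype,
                          params: ModelParameters | None = None,
                          geometry: NuclearGeometry | None = None,
                          ion: IonContext | None = None,
                          replating_delay_h: float | None = None) -> float:
    """2:1 G1:G2 mixture survival for asynchronous populations."""
    params = params or ModelParameters()
    w = params.async_g1_weight
    s_g1 = phase_survival(dose, phenotype.in_phase(CellCyclePhase.G1), params,
                          geometry, ion, replating_delay_h)
    s_g2 = phase_survival(dose, phenotype.in_phase(CellCyclePhase.G2), params,
                          geometry, ion, replating_delay_h)
    return w * s_g1 + (1.0 - w) * s_g2


def survival(dose: float, phenotype: CellPhenotype,
             params: ModelParameters | None = None,
             geometry: NuclearGeometry | None = None,
             ion: IonContext | None = None,
             replating_delay_h: float | None = None) -> float:
    """Survival for the phenotype's own phase (expanding asynchronous)."""
    if phenotype.phase is CellCyclePhase.ASYNC:
        return asynchronous_survival(dose, phenotype, params, geometry, ion,
                                     replating_delay_h)
    return phase_survival(dose, phenotype, params, geometry, ion,
                          replating_delay_h)


# ---------------------------------------------------------------------------
# Dose-response summaries

@dataclass(frozen=True)
class DoseResponse:
    """Survival versus dose with fitted LQ parameters and derived doses."""

    doses: np.ndarray
    survival: np.ndarray
    alpha: float
    beta: float
    mid: float
    d10: float

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        if doses.shape != surv.shape:
            raise ValueError("doses and survival must have matching shapes")
        if np.any(np.diff(surv) > 1e-12):
            raise ValueError("survival must be non-increasing in dose")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "survival", surv)


def fit_lq(doses, survival_fractions) -> tuple[float, float]:
    """Non-negative least squares fit of ln S = -alpha D - beta D^2."""
    doses = np.asarray(doses, dtype=float)
    surv = np.asarray(survival_fractions, dtype=float)
    mask = (doses > 0) & (surv > 0) & np.isfinite(surv)
    if mask.sum() < 2:
        raise ValueError("need at least two positive-dose survival points")
    d = doses[mask]
    y = -np.log(surv[mask])
    design = np.column_stack([d, d * d])
    coef, _ = optimize.nnls(design, y)
    return float(coef[0]), float(coef[1])


def mid_closed_form(alpha: float, beta: float) -> float:
    """Mean inactivation dose (area under the LQ survival curve), in Gy."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    if alpha == 0 and beta == 0:
        raise ValueError("MID diverges for alpha = beta = 0")
    if beta == 0:
        return 1.0 / alpha
    root = math.sqrt(beta)
    # e^(x^2) erfc(x) written via erfcx to avoid overflow at large alpha^2/beta
    return math.sqrt(math.pi) / (2.0 * root) * special.erfcx(alpha / (2.0 * root))


def mid_quadrature(alpha: float, beta: float) -> float:
    """Direct adaptive quadrature of the survival integral (cross-check)."""
    from scipy import integrate
    if alpha <= 0 and beta <= 0:
        raise ValueError("MID diverges for alpha = beta = 0")
    val, _ = integrate.quad(lambda d: math.exp(-alpha * d - beta * d * d),
                            0.0, np.inf, limit=200)
    return val


def d10(alpha: float, beta: float) -> float:
    """Dose at 10% survival: the positive root of alpha D + beta D^2 = ln 10."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    if alpha == 0 and beta == 0:
        raise ValueError("D10 undefined for alpha = beta = 0")
    target = math.log(10.0)
    if beta == 0:
        return target / alpha
    return (-alpha + math.sqrt(alpha * alpha + 4.0 * beta * target)) / (2.0 * beta)


def dose_response(phenotype: CellPhenotype,
                  params: ModelParameters | None = None,
                  geometry: NuclearGeometry | None = None,
                  ion: IonContext | None = None,
                  doses=None,
                  replating_delay_h: float | None = None) -> DoseResponse:
    """Simulate survival on a dose grid and attach LQ summaries."""
    params = params or ModelParameters()
    doses = DEFAULT_DOSE_GRID if doses is None else np.asarray(doses, float)
    surv = np.array([survival(d, phenotype, params, geometry, ion,
                              replating_delay_h) for d in doses])
    if not np.all(np.isfinite(surv)):
        raise FloatingPointError("non-finite survival encountered")
    alpha, beta = fit_lq(doses, surv)
    return DoseResponse(doses=doses, survival=surv, alpha=alpha, beta=beta,
                        mid=mid_closed_form(alpha, beta),
                        d10=d10(alpha, beta))


def rbe(reference: DoseResponse, test: DoseResponse,
        endpoint: str = "d10") -> float:
    """Relative biological effectiveness: reference dose / test dose.

    ``endpoint`` selects the iso-effect dose: ``'d10'`` (10% survival) or
    ``'mid'`` (mean inactivation dose).
    """
    values = {"d10": (reference.d10, test.d10),
              "mid": (reference.mid, test.mid)}
    try:
        ref_dose, test_dose = values[endpoint]
    except KeyError:
        raise ValueError("endpoint must be 'd10' or 'mid'") from None
    if test_dose <= 0:
        raise ValueError("test endpoint dose must be positive")
    return ref_dose / test_dose
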