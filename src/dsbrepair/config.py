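"""Model constants, cell-line phenotypes and nuclear geometry.

The model describes radiation response with a compact set of constants that
are shared across all cell lines (repair rates, pathway fidelities, the
misrejoining range, death sensitivities) plus a small phenotype record per
cell line (genome size, chromosome count, binary repair/arrest competence,
cell-cycle phase).  A single additional energy parameter ``e_dsb`` — the mean
energy deposition that produces one double-strand break (DSB) — links
physical track structure to the biological model and simultaneously fixes
the nuclear geometry: requiring that 1 Gy produces 35 DSBs in a human G1
cell gives

    V_nuc [um^3] = 5.61 * E_DSB [keV]      r_nuc [um] = 1.1 * E_DSB^(1/3)

(1 Gy deposits ~6.24 keV per um^3 of water, and 35/6.24 ~ 5.61).
"""

from __future__ import annotations

import dataclasses
import enum
import importlib.resources
import math
from dataclasses import dataclass, field, fields

import yaml

__all__ = [
    "CellCyclePhase",
    "ModelParameters",
    "CellPhenotype",
    "NuclearGeometry",
    "geometry_from_edsb",
    "load_parameters",
    "dump_parameters",
    "load_phenotypes",
    "dump_phenotypes",
    "bundled_phenotypes",
    "TABLE_MMEJ_FIDELITY",
]

#: Gy -> keV/um^3 conversion for liquid water (1 J/kg in 1e-15 kg).
KEV_PER_UM3_PER_GY = 6.242

#: Alternative MMEJ fidelity preset (Table-style parameterisation).
TABLE_MMEJ_FIDELITY = 0.465


class CellCyclePhase(str, enum.Enum):
    G1 = "G1"
    G2 = "G2"
    M = "M"
    ASYNC = "asynchronous"

    @classmethod
    def parse(cls, value: "str | CellCyclePhase") -> "CellCyclePhase":
        if isinstance(value, cls):
            return value
        key = str(value).strip()
        aliases = {
            "g1": cls.G1, "g2": cls.G2, "m": cls.M,
            "async": cls.ASYNC, "asynchronous": cls.ASYNC,
        }
        try:
            return aliases[key.lower()]
        except KeyError:
            raise ValueError(f"unknown cell-cycle phase: {value!r}") from None

    @property
    def replicated(self) -> bool:
        """True when DNA has been replicated (G2/M): doubled genome."""
        if self is CellCyclePhase.ASYNC:
            raise ValueError("asynchronous phase must be expanded before use")
        return self in (CellCyclePhase.G2, CellCyclePhase.M)


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def _check_positive(name: str, value: float) -> None:
    if not value > 0.0:
        raise ValueError(f"{name} must be strictly positive, got {value}")


@dataclass(frozen=True)
class ModelParameters:
    """Global model constants.

    Defaults are the model's established best-fit values; none of them is
    cell-line specific.  Rates are per hour, ``e_dsb`` in keV,
    ``deletion_threshold`` in base pairs, sensitivities per break.
    """

    dsb_yield: float = 5.738          # DSBs per Gy per Gbp of DNA
    lambda_fast: float = 3.6          # NHEJ (fast) repair rate, 1/h
    lambda_slow: float = 0.15         # HR (slow) repair rate, 1/h
    lambda_mmej: float = 0.0084       # MMEJ (residual) repair rate, 1/h
    p_complex: float = 0.42           # probability a DSB is complex
    p_fail: float = 0.67              # defective-pathway failure -> MMEJ
    sigma_rel: float = 0.0428         # misrejoining range / nuclear radius
    mu_nhej: float = 0.985            # NHEJ fidelity
    mu_hr: float = 1.0                # HR fidelity
    mu_mmej: float = 0.445            # MMEJ fidelity (preset 0.465 available)
    mitotic_sensitivity: float = 0.014    # per-break mitotic death rate
    apoptotic_sensitivity: float = 0.0085  # per-break apoptotic death rate
    e_dsb: float = 60.7               # mean energy per DSB, keV
    deletion_threshold: float = 3.0e6  # lethal-deletion size cut, bp
    p_asym: float = 0.5               # probability of asymmetric rejoining
    track_poisson_threshold: float = 0.5  # DSBs/track to switch to discrete
    async_g1_weight: float = 2.0 / 3.0    # G1 share of asynchronous cells

    def __post_init__(self) -> None:
        for name in ("p_complex", "p_fail", "mu_nhej", "mu_hr", "mu_mmej",
                     "p_asym", "async_g1_weight", "sigma_rel"):
            _check_prob(name, getattr(self, name))
        for name in ("dsb_yield", "lambda_fast", "lambda_slow", "lambda_mmej",
                     "e_dsb", "deletion_threshold"):
            _check_positive(name, getattr(self, name))
        for name in ("mitotic_sensitivity", "apoptotic_sensitivity",
                     "track_poisson_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.mu_hr >= self.mu_nhej >= self.mu_mmej:
            raise ValueError(
                "pathway fidelities must satisfy mu_hr >= mu_nhej >= mu_mmej")

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    @classmethod
    def with_table_mmej(cls, **changes) -> "ModelParameters":
        """Preset using the tabulated MMEJ fidelity (0.465)."""
        changes.setdefault("mu_mmej", TABLE_MMEJ_FIDELITY)
        return cls(**changes)


@dataclass(frozen=True)
class CellPhenotype:
    """Binary/numeric descriptors of one cell line.

    ``genome_gbp`` is the total (unreplicated, G1) DNA content in Gbp — for
    a diploid human cell ~6.1 Gbp, so the default yield gives ~35 DSB/Gy.
    Doubling for G2/M is applied downstream from ``phase``.
    """

    name: str
    genome_gbp: float
    n_chromosomes: int
    nhej_competent: bool = True
    hr_competent: bool = True
    g1_arrest_competent: bool = True
    phase: CellCyclePhase = CellCyclePhase.ASYNC

    def __post_init__(self) -> None:
        _check_positive("genome_gbp", self.genome_gbp)
        if int(self.n_chromosomes) != self.n_chromosomes or self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be an integer >= 1")
        object.__setattr__(self, "phase", CellCyclePhase.parse(self.phase))

    def in_phase(self, phase: "str | CellCyclePhase") -> "CellPhenotype":
        return dataclasses.replace(self, phase=CellCyclePhase.parse(phase))

    def genome_bp(self, phase: "CellCyclePhase | None" = None) -> float:
        """Total DNA length in base pairs, doubled after replication."""
        phase = CellCyclePhase.parse(phase) if phase is not None else self.phase
        return self.genome_gbp * 1e9 * (2.0 if phase.replicated else 1.0)


@dataclass(frozen=True)
class NuclearGeometry:
    """Spherical nucleus: radius, volume and absolute misrejoining range (um)."""

    radius_um: float
    volume_um3: float
    sigma_abs_um: float

    def __post_init__(self) -> None:
        _check_positive("radius_um", self.radius_um)
        _check_positive("volume_um3", self.volume_um3)
        _check_positive("sigma_abs_um", self.sigma_abs_um)
        sphere = 4.0 / 3.0 * math.pi * self.radius_um ** 3
        if abs(sphere - self.volume_um3) > 0.01 * self.volume_um3:
            raise ValueError(
                "volume and radius inconsistent beyond the 1% rounding of the "
                f"geometry constants: (4/3)pi r^3 = {sphere:.4g}, "
                f"volume = {self.volume_um3:.4g}")


def geometry_from_edsb(e_dsb: float,
                       params: ModelParameters | None = None) -> NuclearGeometry:
    """Nuclear geometry implied by the energy-per-DSB parameter.

    ``V_nuc = 5.61 e_dsb`` um^3 and ``r_nuc = 1.1 e_dsb^(1/3)`` um, both from
    the 35 DSB/Gy human yield and the Gy -> keV/um^3 water conversion; the two
    printed constants are mutually consistent to better than 1%.
    """
    if not e_dsb > 0:
        raise ValueError(f"e_dsb must be strictly positive, got {e_dsb}")
    params = params or ModelParameters()
    radius = 1.1 * e_dsb ** (1.0 / 3.0)
    volume = 5.61 * e_dsb
    return NuclearGeometry(radius_um=radius, volume_um3=volume,
                           sigma_abs_um=params.sigma_rel * radius)


# ---------------------------------------------------------------------------
# Serialization

_PARAM_FIELDS = {f.name for f in fields(ModelParameters)}
_PHENO_FIELDS = {f.name for f in fields(CellPhenotype)}


def load_parameters(config_text: str) -> ModelParameters:
    """Parse a YAML/JSON mapping into :class:`ModelParameters`.

    Absent fields take the defaults; unknown keys and out-of-range values are
    rejected with field-level messages.
    """
    data = yaml.safe_load(config_text) or {}
    if not isinstance(data, dict):
        raise ValueError("parameter config must be a mapping")
    unknown = set(data) - _PARAM_FIELDS
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParameters(**data)


def dump_parameters(params: ModelParameters) -> str:
    return yaml.safe_dump(dataclasses.asdict(params), sort_keys=True)


def load_phenotypes(config_text: str) -> list[CellPhenotype]:
    """Parse a YAML list (or mapping with key ``phenotypes``) of cell records."""
    data = yaml.safe_load(config_text) or []
    if isinstance(data, dict):
        data = data.get("phenotypes", [])
    out = []
    for i, rec in enumerate(data):
        if not isinstance(rec, dict):
            raise ValueError(f"phenotype entry {i} is not a mapping")
        unknown = set(rec) - _PHENO_FIELDS
        if unknown:
            raise ValueError(
                f"phenotype entry {rec.get('name', i)!r}: unknown keys {sorted(unknown)}")
        out.append(CellPhenotype(**rec))
    return out


def dump_phenotypes(phenotypes: list[CellPhenotype]) -> str:
    recs = []
    for p in phenotypes:
        d = dataclasses.asdict(p)
        d["phase"] = p.phase.value
        recs.append(d)
    return yaml.safe_dump(recs, sort_keys=False)


def bundled_phenotypes() -> list[CellPhenotype]:
    """Generic cell-line fixtures shipped with the package."""
    text = (importlib.resources.files("dsbrepair") / "data" / "phenotypes.yaml").read_text()
    return load_phenotypes(text)
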