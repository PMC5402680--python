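"""Anthropometric and renal physiology: closed-form formulas.

Everything here is algebraic — total blood volume from height/weight/sex,
glomerular filtration rate (GFR) from demographic coefficients and serum
creatinine, the molecular-weight-dependent glomerular sieving ("filtration
coefficient"), renal clearance, and the single-compartment elimination
half-life that follows from clearance and blood volume.

Canonical units: masses in ng, volumes in ml (profile volumes are *stored*
in liters and converted at the point of use), time in minutes, clearances in
ml/min, molecular weight in daltons, concentrations in ng/ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

from .errors import InvalidInputError

Sex = Literal["male", "female"]
AgeClass = Literal["neonate", "adult"]
Race = Literal["caucasian", "african_american"]

#: GFR demographic coefficient A by (race, sex).
GFR_COEFF_A: Mapping[tuple[str, str], float] = {
    ("caucasian", "male"): 141.0,
    ("caucasian", "female"): 144.0,
    ("african_american", "male"): 163.0,
    ("african_american", "female"): 166.0,
}

#: Creatinine normalization B (mg/dl) by sex.
GFR_COEFF_B: Mapping[str, float] = {"male": 0.9, "female": 0.7}

#: Creatinine exponent applied when SrCr exceeds the sex norm B.
GFR_CREATININE_EXP = -1.209

#: Per-year age attenuation of GFR.
GFR_AGE_BASE = 0.993

#: Neonatal kidney filtration preset, ml/min normalized to 1.73 m² BSA.
NEONATAL_GFR_PER_173 = 47.0

#: Reference BSA (m²) for the neonatal GFR preset.
REFERENCE_BSA = 1.73

# Sieving-curve constants: a logistic step in MW centered at 27 096 Da.
_CF_OFFSET = -0.04094
_CF_SCALE = 1.19614
_CF_MIDPOINT_DA = 27096.0
_CF_SLOPE = -3.1e-5


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise InvalidInputError(f"{name} must be > 0, got {value!r}")


def _require_nonnegative(name: str, value: float) -> None:
    if value < 0:
        raise InvalidInputError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class SubjectProfile:
    """Demographic and anatomic parameters of a simulated subject.

    Volumes are stored in liters; ``skin_marker_conc`` is the S100B tissue
    concentration of the subject's skin in ng/ml (pigmentation-dependent).
    ``gfr_function`` is the 0–1 kidney-health multiplier (1 = healthy).
    ``serum_creatinine`` defaults to the sex norm B so that the creatinine
    term of the GFR formula is inert unless the user overrides it.
    ``body_surface_area`` (m²) is required for neonates, whose kidney
    filtration is a BSA-scaled preset rather than a creatinine formula.
    """

    age_class: AgeClass
    sex: Sex
    brain_volume: float  # liters
    blood_volume: float  # liters
    race: Race = "caucasian"
    height: float = 1.8  # meters
    weight: float = 80.0  # kilograms
    age: float = 45.0  # years, standardized
    serum_creatinine: float | None = None  # mg/dl; None -> sex norm B
    gfr_function: float = 1.0
    body_surface_area: float | None = None  # m², neonate only
    skin_volume: float = 7.8  # liters
    skin_marker_conc: float = 0.288  # ng/ml

    def __post_init__(self):
        if self.age_class not in ("neonate", "adult"):
            raise InvalidInputError(f"age_class must be neonate/adult, got {self.age_class!r}")
        if self.sex not in ("male", "female"):
            raise InvalidInputError(f"sex must be male/female, got {self.sex!r}")
        if self.race not in ("caucasian", "african_american"):
            raise InvalidInputError(f"race must be caucasian/african_american, got {self.race!r}")
        for name in ("brain_volume", "blood_volume", "skin_volume", "height", "weight"):
            _require_positive(name, getattr(self, name))
        if not 0.0 <= self.gfr_function <= 1.0:
            raise InvalidInputError(f"gfr_function must lie in [0,1], got {self.gfr_function!r}")
        if self.serum_creatinine is not None:
            _require_positive("serum_creatinine", self.serum_creatinine)
        if self.body_surface_area is not None:
            _require_positive("body_surface_area", self.body_surface_area)
        _require_nonnegative("skin_marker_conc", self.skin_marker_conc)

    @property
    def creatinine(self) -> float:
        """Serum creatinine in mg/dl, defaulting to the sex norm B."""
        if self.serum_creatinine is not None:
            return self.serum_creatinine
        return GFR_COEFF_B[self.sex]


@dataclass(frozen=True)
class Biomarker:
    """Physicochemical identity of a blood biomarker.

    ``molecular_weight`` (Da) drives glomerular sieving; ``brain_conc``
    (ng/ml) is the fixed extracellular brain-tissue concentration that acts
    as the source strength; ``organ_concs`` maps extracranial organ names to
    their tissue concentrations.
    """

    name: str
    molecular_weight: float  # daltons
    brain_conc: float  # ng/ml
    organ_concs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        _require_positive("molecular_weight", self.molecular_weight)
        _require_nonnegative("brain_conc", self.brain_conc)
        for organ, conc in self.organ_concs.items():
            _require_nonnegative(f"organ_concs[{organ}]", conc)


@dataclass(frozen=True)
class RenalParams:
    """Resolved renal elimination: GFR, sieving fraction, and their product."""

    gfr: float  # ml/min
    filtration_coefficient: float  # fraction in [0,1]
    renal_clearance: float  # ml/min = gfr * filtration_coefficient

    def __post_init__(self):
        _require_nonnegative("gfr", self.gfr)
        if not 0.0 <= self.filtration_coefficient <= 1.0:
            raise InvalidInputError(
                f"filtration_coefficient must lie in [0,1], got {self.filtration_coefficient!r}"
            )
        if not math.isclose(
            self.renal_clearance, self.gfr * self.filtration_coefficient, rel_tol=1e-9, abs_tol=1e-12
        ):
            raise InvalidInputError("renal_clearance must equal gfr * filtration_coefficient")


def compute_tbv(
    height: float,
    weight: float,
    sex: Sex,
    dialect: Literal["nadler_cubic", "as_printed"] = "nadler_cubic",
) -> float:
    """Total blood volume (liters) from height (m), weight (kg), and sex.

    ``nadler_cubic`` (default) is Nadler's formula with the cubed height
    term; ``as_printed`` keeps the height term linear. The linear variant is
    retained for fidelity to some published transcriptions but yields
    implausibly small volumes for adults (~3.8 l for a 1.8 m / 80 kg male),
    so the cubic form is the default.
    """
    _require_positive("height", height)
    _require_positive("weight", weight)
    if sex not in ("male", "female"):
        raise InvalidInputError(f"sex must be male/female, got {sex!r}")
    if dialect not in ("nadler_cubic", "as_printed"):
        raise InvalidInputError(f"unknown TBV dialect {dialect!r}")
    h = height**3 if dialect == "nadler_cubic" else height
    if sex == "male":
        return 0.3669 * h + 0.03219 * weight + 0.6041
    return 0.3561 * h + 0.03308 * weight + 0.1833


def compute_gfr(profile: SubjectProfile) -> float:
    """Adult glomerular filtration rate in ml/min.

    GFR = gfr_function · A · (SrCr/B)^exp · 0.993^age, with demographic
    coefficients A, B resolved by race and sex, and the creatinine exponent
    −1.209 applied only when SrCr exceeds the sex norm B (elevated
    creatinine depresses GFR; at or below the norm the term is inert).
    Age is standardized to 45 years in the presets.
    """
    if profile.age_class != "adult":
        raise InvalidInputError(
            "compute_gfr supports adult profiles only; use neonatal_gfr for neonates"
        )
    a = GFR_COEFF_A[(profile.race, profile.sex)]
    b = GFR_COEFF_B[profile.sex]
    ratio = profile.creatinine / b
    creatinine_term = ratio**GFR_CREATININE_EXP if ratio > 1.0 else 1.0
    return profile.gfr_function * a * creatinine_term * GFR_AGE_BASE**profile.age


def neonatal_gfr(body_surface_area: float, gfr_function: float) -> float:
    """Neonatal GFR in ml/min: the 47 ml/min/1.73 m² preset scaled to BSA."""
    _require_positive("body_surface_area", body_surface_area)
    if not 0.0 <= gfr_function <= 1.0:
        raise InvalidInputError(f"gfr_function must lie in [0,1], got {gfr_function!r}")
    return gfr_function * NEONATAL_GFR_PER_173 * (body_surface_area / REFERENCE_BSA)


def filtration_coefficient(molecular_weight: float) -> float:
    """Glomerular sieving fraction C_F in [0,1] for a protein of given MW (Da).

    A fitted logistic step in molecular weight, clamped to [0,1]: small
    proteins are filtered nearly freely (C_F → 1), large ones are retained
    (C_F → 0). Monotonically non-increasing in MW.
    """
    _require_positive("molecular_weight", molecular_weight)
    # cap the logistic exponent to avoid float overflow; beyond it the curve
    # is saturated on the clamp anyway
    exponent = min((_CF_MIDPOINT_DA - molecular_weight) * _CF_SLOPE, 300.0)
    raw = _CF_OFFSET + _CF_SCALE / (1.0 + 10.0**exponent)
    return min(1.0, max(0.0, raw))


def renal_clearance(gfr: float, c_f: float) -> float:
    """Renal plasma clearance in ml/min: GFR × sieving fraction."""
    _require_nonnegative("gfr", gfr)
    _require_nonnegative("c_f", c_f)
    return gfr * c_f


def elimination_half_life(total_clearance: float, blood_volume: float) -> float:
    """Single-compartment first-order elimination half-life in minutes.

    t½ = ln 2 · V_blood / CL with V_blood in ml and CL in ml/min. A zero
    clearance returns ``math.inf`` (the marker is never eliminated) — the
    documented sentinel used throughout, e.g. by the kidney-failure sweep.
    """
    _require_nonnegative("total_clearance", total_clearance)
    _require_positive("blood_volume", blood_volume)
    if total_clearance == 0.0:
        return math.inf
    return math.log(2.0) * blood_volume / total_clearance


def renal_params_for(profile: SubjectProfile, biomarker: Biomarker) -> RenalParams:
    """Resolve GFR, C_F, and renal clearance for a subject/marker pair."""
    if profile.age_class == "neonate":
        if profile.body_surface_area is None:
            raise InvalidInputError("neonate profile requires body_surface_area")
        gfr = neonatal_gfr(profile.body_surface_area, profile.gfr_function)
    else:
        gfr = compute_gfr(profile)
    c_f = filtration_coefficient(biomarker.molecular_weight)
    return RenalParams(gfr=gfr, filtration_coefficient=c_f, renal_clearance=renal_clearance(gfr, c_f))
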