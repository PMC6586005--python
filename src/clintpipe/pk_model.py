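"""Well-stirred hepatic clearance model and three-class stability assignment.

Intrinsic clearance (CL_int) measured in human liver microsomes is reported in
several units; the canonical unit here is uL/min/mg microsomal protein.  The
physiological scale-up from microsomal protein to whole body uses the standard
factors 45 mg microsomes per g liver and 21 g liver per kg body weight, so

    1 uL/min/mg  =  45 * 21 / 1000  =  0.945 mL/min/kg.

The well-stirred model (instant mixing, no microsomal binding) then gives the
hepatic clearance CL_h and hepatic availability F_h:

    CL_h = Q_h * f_up * CL_int / (Q_h + f_up * CL_int)
    F_h  = Q_h / (Q_h + f_up * CL_int)

with Q_h the hepatic blood flow (default 21.215 mL/min/kg for humans) and f_up
the fraction of drug unbound in plasma.  Compounds are classed as *stable*
(CL_int < 20 uL/min/mg), *moderate* (20 <= CL_int < 300) or *unstable*
(CL_int >= 300): at CL_int = 20 more than half the dose survives first pass
even at f_up = 1, while at CL_int = 300 availability is poor at any binding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

__all__ = [
    "HEPATIC_BLOOD_FLOW",
    "MG_MICROSOMES_PER_G_LIVER",
    "G_LIVER_PER_KG_BODY",
    "UL_MG_TO_ML_KG",
    "STABLE_CUTOFF",
    "UNSTABLE_CUTOFF",
    "StabilityClass",
    "UnitBasis",
    "UnitSpec",
    "PKParameters",
    "UnitConversionError",
    "convert_units",
    "hepatic_clearance",
    "hepatic_availability",
    "assign_class",
    "round_half_up",
]

#: Human hepatic blood flow in mL/min/kg body weight.
HEPATIC_BLOOD_FLOW = 21.215

#: Scale-up constants from microsomal protein to body weight.
MG_MICROSOMES_PER_G_LIVER = 45.0
G_LIVER_PER_KG_BODY = 21.0

#: 1 uL/min/mg microsomal protein expressed in mL/min/kg body weight.
UL_MG_TO_ML_KG = MG_MICROSOMES_PER_G_LIVER * G_LIVER_PER_KG_BODY / 1000.0  # 0.945

#: Three-class cutoffs on CL_int in uL/min/mg (left-closed upper intervals).
STABLE_CUTOFF = 20.0
UNSTABLE_CUTOFF = 300.0


class StabilityClass(str, Enum):
    """Metabolic-stability category of a compound."""

    STABLE = "stable"
    MODERATE = "moderate"
    UNSTABLE = "unstable"

    def __str__(self) -> str:  # serialized exactly as the lowercase word
        return self.value


class UnitBasis(str, Enum):
    """Normalization basis a CL_int unit refers to."""

    PER_MG_MICROSOME = "per_mg_microsome"
    PER_G_LIVER = "per_g_liver"
    PER_KG_BODY = "per_kg_body"


#: Default basis for each recognised unit string.  "mL/min/g" is, by database
#: convention, read as per g *liver* — exactly the reading that turns a
#: per-mg-microsome value of 42 into an inflated 933.3 under naive conversion.
_UNIT_BASIS: dict[str, UnitBasis] = {
    "uL/min/mg": UnitBasis.PER_MG_MICROSOME,
    "μL/min/mg": UnitBasis.PER_MG_MICROSOME,
    "µL/min/mg": UnitBasis.PER_MG_MICROSOME,
    "mL/min/g": UnitBasis.PER_G_LIVER,
    "mL/min/kg": UnitBasis.PER_KG_BODY,
}


class UnitConversionError(ValueError):
    """Raised for unit/basis combinations the converter does not support.

    Carries a human-readable ``reason`` so the curation layer can turn the
    failure into a rejected-entry record instead of a crash.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class UnitSpec:
    """A CL_int unit together with the basis it normalizes by."""

    unit: str
    basis: UnitBasis | None = None

    def __post_init__(self) -> None:
        if self.basis is None:
            basis = _UNIT_BASIS.get(self.unit)
            if basis is not None:
                object.__setattr__(self, "basis", basis)

    @property
    def recognised(self) -> bool:
        return self.basis is not None

    @classmethod
    def from_unit(cls, unit: str) -> "UnitSpec":
        return cls(unit=unit)


@dataclass(frozen=True)
class PKParameters:
    """Inputs of the well-stirred model.

    Parameters
    ----------
    clint : float
        Intrinsic clearance in uL/min/mg microsomal protein.
    fup : float
        Fraction unbound in plasma, in [0, 1].
    qh : float
        Hepatic blood flow in mL/min/kg; defaults to the human value.
    """

    clint: float
    fup: float
    qh: float = field(default=HEPATIC_BLOOD_FLOW)

    def __post_init__(self) -> None:
        if not self.qh > 0:
            raise ValueError(f"qh must be positive, got {self.qh}")
        if not 0.0 <= self.fup <= 1.0:
            raise ValueError(f"fup must lie in [0, 1], got {self.fup}")
        if not self.clint >= 0:
            raise ValueError(f"clint must be nonnegative, got {self.clint}")

    @property
    def clint_ml_min_kg(self) -> float:
        """CL_int rescaled to mL/min/kg body weight."""
        return self.clint * UL_MG_TO_ML_KG


def convert_units(value: float, spec: UnitSpec) -> float:
    """Convert a CL_int measurement to uL/min/mg microsomal protein.

    ``per_mg_microsome`` values pass through unchanged (mL/min/g microsomes is
    numerically identical to uL/min/mg); ``per_g_liver`` values are divided by
    the 45 mg/g microsomal-protein yield (x 1000/45); ``per_kg_body`` values
    are divided by the full 0.945 scale-up factor.

    Raises
    ------
    UnitConversionError
        If the unit/basis combination is not supported or the value negative.
    """
    if not math.isfinite(value) or value < 0:
        raise UnitConversionError(f"value must be finite and nonnegative, got {value!r}")
    basis = spec.basis
    if basis is UnitBasis.PER_MG_MICROSOME:
        return float(value)
    if basis is UnitBasis.PER_G_LIVER:
        return float(value) * 1000.0 / MG_MICROSOMES_PER_G_LIVER
    if basis is UnitBasis.PER_KG_BODY:
        return float(value) / UL_MG_TO_ML_KG
    raise UnitConversionError(f"unsupported CL_int unit {spec.unit!r}")


def hepatic_clearance(p: PKParameters) -> float:
    """Hepatic clearance CL_h in mL/min/kg under the well-stirred model.

    CL_int is rescaled to mL/min/kg internally before entering the formula.
    Bounded by the hepatic blood flow: 0 <= CL_h < qh.
    """
    ci = p.clint_ml_min_kg
    return p.qh * p.fup * ci / (p.qh + p.fup * ci)


def hepatic_availability(p: PKParameters) -> float:
    """Hepatic availability F_h (fraction escaping first-pass extraction).

    Satisfies CL_h = qh * (1 - F_h) exactly; strictly decreasing in both
    fup and clint, and equal to 1 when fup = 0.
    """
    ci = p.clint_ml_min_kg
    return p.qh / (p.qh + p.fup * ci)


def assign_class(clint: float) -> StabilityClass:
    """Map a CL_int value (uL/min/mg) onto the three-class scheme.

    Boundary values belong to the upper class: 20 is moderate, 300 unstable.
    """
    if not math.isfinite(clint) or clint < 0:
        raise ValueError(f"clint must be finite and nonnegative, got {clint!r}")
    if clint < STABLE_CUTOFF:
        return StabilityClass.STABLE
    if clint < UNSTABLE_CUTOFF:
        return StabilityClass.MODERATE
    return StabilityClass.UNSTABLE


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, for presentation of F_h / CL_h values.

    Internal computation is never rounded; this is applied only when printing
    or reporting, so 0.4280... reports as 0.428.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
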