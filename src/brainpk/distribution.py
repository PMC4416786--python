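"""Brain-to-plasma partitioning with residual-blood correction.

The extent of brain distribution of a drug is summarised by two ratios:

* ``Kp`` — total brain concentration (ng/g tissue) over total plasma
  concentration (ng/ml), units ml/g.
* ``Kp,uu`` — unbound brain interstitial over unbound plasma concentration,
  ``Kp / (Vu,brain * fu,plasma)``.  Values below 1 indicate net efflux at the
  blood-brain barrier, above 1 net active uptake.

Brain homogenate carries residual capillary blood, so the measured homogenate
concentration is first corrected using the effective plasma space

    Veff    = fu,p * Vwater + (1 - fu,p) * Vprotein
    Abrain  = (Cbrain,h - Veff * Cplasma) / (1 - Vwater)

where ``Vwater`` and ``Vprotein`` are the apparent vascular spaces of plasma
water and plasma proteins (ml/g brain).  Their numeric values are treated as
fractions in the ``1 - Vwater`` denominator, as is conventional for this
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple

import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "Genotype",
    "ConcentrationRecord",
    "VascularParams",
    "CorrectedBrain",
    "DistributionResult",
    "compute_kp",
    "effective_plasma_space",
    "correct_residual_blood",
    "compute_kpuu",
    "analyze_animal",
    "kpuu_table",
]


class Genotype(str, Enum):
    """Mouse lines of the efflux-transporter comparison."""

    FVB_WT = "FVB_WT"
    MDR1A1B_KO = "MDR1A1B_KO"
    C57BL6_WT = "C57BL6_WT"
    HMDR1 = "HMDR1"


@dataclass(frozen=True)
class ConcentrationRecord:
    """One animal's paired plasma / brain-homogenate drug measurement.

    ``c_brain_homogenate`` is the concentration measured in the homogenate as
    prepared (ng/ml); ``homogenate_dilution`` is the tissue-to-homogenate
    fold (w/v), e.g. 5 for a brain homogenised in 4 volumes of saline.
    """

    animal_id: str
    genotype: Genotype
    drug: str
    c_plasma: float  # ng/ml
    c_brain_homogenate: float  # ng/ml, as measured in the homogenate
    homogenate_dilution: float = 5.0  # fold, tissue -> homogenate (w/v)
    treatment: str | None = None  # blocker co-administered, if any

    def __post_init__(self) -> None:
        if self.c_plasma < 0:
            raise InvalidInputError(
                f"animal {self.animal_id!r}: negative plasma concentration "
                f"{self.c_plasma}"
            )
        if self.c_brain_homogenate < 0:
            raise InvalidInputError(
                f"animal {self.animal_id!r}: negative brain homogenate "
                f"concentration {self.c_brain_homogenate}"
            )
        if self.homogenate_dilution < 1:
            raise InvalidInputError(
                f"animal {self.animal_id!r}: homogenate dilution must be >= 1, "
                f"got {self.homogenate_dilution}"
            )

    @property
    def c_brain_per_g(self) -> float:
        """Homogenate concentration converted to ng per g brain tissue."""
        return self.c_brain_homogenate * self.homogenate_dilution


@dataclass(frozen=True)
class VascularParams:
    """Apparent vascular spaces of residual blood in brain tissue (ml/g).

    Not measured in-study; these are literature constants and therefore
    mandatory configuration, defaulting to the commonly used values
    ``v_water = 0.0103`` and ``v_protein = 0.0080`` ml/g.
    """

    v_water: float = 0.0103
    v_protein: float = 0.0080

    def __post_init__(self) -> None:
        if not (0 <= self.v_water < 1):
            raise InvalidInputError(f"v_water must be in [0, 1), got {self.v_water}")
        if not (0 <= self.v_protein < 1):
            raise InvalidInputError(
                f"v_protein must be in [0, 1), got {self.v_protein}"
            )


class CorrectedBrain(NamedTuple):
    """Residual-blood-corrected brain amount (ng/g) with provenance."""

    a_brain: float
    v_eff: float
    clamped: bool  # True when the raw correction went negative and was set to 0


def compute_kp(c_brain_total: float, c_plasma: float, *, animal_id: str | None = None) -> float:
    """Total brain-to-plasma partition ratio Kp = Cbrain / Cplasma (ml/g).

    Parameters
    ----------
    c_brain_total : total brain concentration, ng/g tissue.
    c_plasma : total plasma concentration, ng/ml; must be positive.
    """
    if c_plasma <= 0:
        who = f" (animal {animal_id!r})" if animal_id else ""
        raise InvalidInputError(
            f"plasma concentration must be positive to form Kp, got {c_plasma}{who}"
        )
    if c_brain_total < 0:
        who = f" (animal {animal_id!r})" if animal_id else ""
        raise InvalidInputError(
            f"brain concentration must be nonnegative, got {c_brain_total}{who}"
        )
    return c_brain_total / c_plasma


def effective_plasma_space(f_u_plasma: float, params: VascularParams) -> float:
    """Effective residual-plasma space Veff = fu*Vwater + (1-fu)*Vprotein.

    A convex combination, so the result always lies between ``v_water`` and
    ``v_protein``.
    """
    if not (0 <= f_u_plasma <= 1):
        raise InvalidInputError(
            f"unbound plasma fraction must be within [0, 1], got {f_u_plasma}"
        )
    return f_u_plasma * params.v_water + (1 - f_u_plasma) * params.v_protein


def correct_residual_blood(
    c_brain_h_per_g: float,
    c_plasma: float,
    f_u_plasma: float,
    params: VascularParams,
) -> CorrectedBrain:
    """Remove the residual-blood contribution from a homogenate concentration.

    ``Abrain = (Cbrain,h - Veff * Cplasma) / (1 - Vwater)`` with ``Cbrain,h``
    already expressed per g tissue.  A negative numerator (plasma signal
    exceeding the brain signal) is clamped to 0 and flagged: drug amounts are
    physically nonnegative.
    """
    if c_brain_h_per_g < 0 or c_plasma < 0:
        raise InvalidInputError("concentrations must be nonnegative")
    v_eff = effective_plasma_space(f_u_plasma, params)
    raw = (c_brain_h_per_g - v_eff * c_plasma) / (1 - params.v_water)
    if raw < 0:
        return CorrectedBrain(0.0, v_eff, True)
    return CorrectedBrain(raw, v_eff, False)


def compute_kpuu(kp: float, v_u_brain: float, f_u_plasma: float) -> float:
    """Unbound partition coefficient Kp,uu = Kp / (Vu,brain * fu,plasma).

    ``v_u_brain`` (ml/g) is the unbound volume of distribution in brain from
    the slice assay; ``f_u_plasma`` the unbound fraction from equilibrium
    dialysis.  Kp enters as a plain number (its ml/g cancels Vu,brain's).
    """
    if v_u_brain <= 0:
        raise InvalidInputError(f"v_u_brain must be positive, got {v_u_brain}")
    if f_u_plasma <= 0:
        raise InvalidInputError(f"f_u_plasma must be positive, got {f_u_plasma}")
    if kp < 0:
        raise InvalidInputError(f"kp must be nonnegative, got {kp}")
    return kp / (v_u_brain * f_u_plasma)


@dataclass(frozen=True)
class DistributionResult:
    """Per-animal distribution metrics with the inputs that produced them."""

    animal_id: str
    genotype: Genotype
    drug: str
    treatment: str | None
    kp: float  # ml/g, from residual-blood-corrected brain amount
    kp_uncorrected: float  # ml/g, from raw dilution-corrected homogenate
    a_brain: float  # ng/g
    v_eff: float  # ml/g
    kpuu: float
    v_u_brain: float = field(repr=False, default=float("nan"))
    f_u_plasma: float = field(repr=False, default=float("nan"))
    clamped: bool = False


def analyze_animal(
    record: ConcentrationRecord,
    v_u_brain: float,
    f_u_plasma: float,
    params: VascularParams,
) -> DistributionResult:
    """Full per-animal chain: dilution correction, residual-blood correction,
    Kp and Kp,uu."""
    corrected = correct_residual_blood(
        record.c_brain_per_g, record.c_plasma, f_u_plasma, params
    )
    kp = compute_kp(corrected.a_brain, record.c_plasma, animal_id=record.animal_id)
    kp_raw = compute_kp(record.c_brain_per_g, record.c_plasma, animal_id=record.animal_id)
    return DistributionResult(
        animal_id=record.animal_id,
        genotype=record.genotype,
        drug=record.drug,
        treatment=record.treatment,
        kp=kp,
        kp_uncorrected=kp_raw,
        a_brain=corrected.a_brain,
        v_eff=corrected.v_eff,
        kpuu=compute_kpuu(kp, v_u_brain, f_u_plasma),
        v_u_brain=v_u_brain,
        f_u_plasma=f_u_plasma,
        clamped=corrected.clamped,
    )


def kpuu_table(table: pd.DataFrame) -> pd.DataFrame:
    """Compute the Kp,uu column from per-group Kp / Vu,brain / fu columns.

    ``table`` needs columns ``drug, genotype, kp, v_u_brain, f_u_plasma``;
    the returned copy gains a ``kpuu`` column (unrounded — presentation
    rounding belongs to the report layer).
    """
    out = table.copy()
    out["kpuu"] = [
        compute_kpuu(row.kp, row.v_u_brain, row.f_u_plasma)
        for row in table.itertuples()
    ]
    return out
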