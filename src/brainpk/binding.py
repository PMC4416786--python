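"""Binding-assay processing: plasma unbound fraction and brain-slice Vu,brain.

``fu,plasma`` comes from equilibrium dialysis: after incubation to
equilibrium, the buffer side holds the unbound concentration and the plasma
side the total, so ``fu = Cbuffer / Cplasma`` per replicate.  Both sides are
diluted identically with blank matrix before analysis, so any common dilution
cancels in the ratio.

``Vu,brain`` (ml/g) comes from the brain-slice assay: slices equilibrate in a
drug-containing buffer; the amount taken up per g tissue divided by the final
buffer (unbound) concentration gives the unbound volume of distribution,
after subtracting the adherent surface-fluid film ``v_film``:

    A_slice  = C_slice_homog * dilution            (ng/g)
    Vu,brain = (A_slice - v_film * C_buffer) / C_buffer

Slices failing viability QC (end-of-incubation pH < 7.25, or LDH release
above a configurable threshold) are excluded from the mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .exceptions import AssayFailureError, InvalidInputError, QCFailureError

__all__ = [
    "DialysisRecord",
    "SliceAssayRecord",
    "SliceQC",
    "FuPlasmaResult",
    "VuBrainResult",
    "PH_VIABILITY_MIN",
    "compute_fu_plasma",
    "qc_slice",
    "compute_vu_brain",
]

#: End-of-incubation pH below which a slice is considered non-viable.
PH_VIABILITY_MIN = 7.25

#: Default LDH-release fraction above which a slice fails QC (the viability
#: criterion is named by the assay; the cutoff is a configuration choice).
DEFAULT_LDH_THRESHOLD = 0.25


@dataclass(frozen=True)
class DialysisRecord:
    """One equilibrium-dialysis replicate (matrix-matched measurements)."""

    drug: str
    replicate_id: str
    c_buffer_side: float  # ng/ml
    c_plasma_side: float  # ng/ml
    incubation_h: float = 6.0
    genotype: str | None = None  # None/empty = applies to all strains

    def __post_init__(self) -> None:
        if self.c_buffer_side < 0 or self.c_plasma_side < 0:
            raise InvalidInputError(
                f"dialysis replicate {self.replicate_id!r}: negative concentration"
            )

    @property
    def valid(self) -> bool:
        return self.c_plasma_side > 0


@dataclass(frozen=True)
class SliceAssayRecord:
    """One brain slice from the Vu,brain assay."""

    drug: str
    slice_id: str
    slice_weight: float  # g
    c_buffer_final: float  # ng/ml at end of incubation
    c_slice_homog: float  # ng/ml in the slice homogenate
    slice_dilution: float  # fold (w/v), e.g. 10 for 9 volumes of buffer
    end_ph: float
    ldh_release_fraction: float  # fraction of maximum releasable LDH

    def __post_init__(self) -> None:
        if self.slice_weight <= 0:
            raise InvalidInputError(f"slice {self.slice_id!r}: nonpositive weight")
        if not (0 <= self.ldh_release_fraction <= 1):
            raise InvalidInputError(
                f"slice {self.slice_id!r}: LDH release fraction outside [0, 1]"
            )


@dataclass(frozen=True)
class SliceQC:
    passed: bool
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class FuPlasmaResult:
    """Replicate-level unbound plasma fraction with summary statistics."""

    drug: str
    fu_mean: float
    fu_sd: float
    replicate_values: tuple[float, ...]
    n: int
    flagged_above_one: tuple[str, ...] = ()  # replicate ids with fu > 1


@dataclass(frozen=True)
class VuBrainResult:
    """Slice-level Vu,brain with QC status per slice."""

    drug: str
    vu_mean: float
    per_slice: dict[str, float] = field(default_factory=dict)
    qc: dict[str, SliceQC] = field(default_factory=dict)
    n_pass: int = 0
    n_fail: int = 0


def compute_fu_plasma(records: list[DialysisRecord]) -> FuPlasmaResult:
    """Unbound plasma fraction from dialysis replicates: mean of per-replicate
    ``c_buffer_side / c_plasma_side`` with SD.

    Replicates with fu > 1 are retained and flagged (plausible under
    measurement noise for weakly bound drugs) rather than truncated; if the
    mean itself exceeds 1 a warning is emitted.
    """
    if not records:
        raise AssayFailureError("no dialysis replicates supplied")
    drug = records[0].drug
    valid = [r for r in records if r.valid]
    if not valid:
        raise AssayFailureError(
            f"all dialysis replicates for {drug!r} are invalid (plasma side <= 0)"
        )
    values = [r.c_buffer_side / r.c_plasma_side for r in valid]
    flagged = tuple(r.replicate_id for r, v in zip(valid, values) if v > 1)
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
    if mean > 1:
        warnings.warn(
            f"mean fu,plasma for {drug!r} exceeds 1 ({mean:.3g}); "
            "check assay equilibrium",
            stacklevel=2,
        )
    return FuPlasmaResult(drug, mean, sd, tuple(values), n, flagged)


def qc_slice(
    record: SliceAssayRecord, ldh_threshold: float = DEFAULT_LDH_THRESHOLD
) -> SliceQC:
    """Viability QC for one slice: pH >= 7.25 and LDH release <= threshold."""
    reasons: list[str] = []
    if record.end_ph < PH_VIABILITY_MIN:
        reasons.append(f"end pH {record.end_ph:.2f} < {PH_VIABILITY_MIN}")
    if record.ldh_release_fraction > ldh_threshold:
        reasons.append(
            f"LDH release {record.ldh_release_fraction:.2f} > {ldh_threshold}"
        )
    return SliceQC(passed=not reasons, reasons=tuple(reasons))


def compute_vu_brain(
    records: list[SliceAssayRecord],
    v_film: float = 0.0,
    ldh_threshold: float = DEFAULT_LDH_THRESHOLD,
) -> VuBrainResult:
    """Unbound brain volume of distribution from QC-passing slices.

    ``v_film`` (ml/g) corrects for buffer film adhering to the slice surface;
    it defaults to 0 and is exposed in configuration.
    """
    if not records:
        raise AssayFailureError("no slice records supplied")
    drug = records[0].drug
    qc = {r.slice_id: qc_slice(r, ldh_threshold) for r in records}
    per_slice: dict[str, float] = {}
    for r in records:
        if not qc[r.slice_id].passed:
            continue
        if r.c_buffer_final <= 0:
            raise AssayFailureError(
                f"slice {r.slice_id!r}: final buffer concentration must be positive"
            )
        a_slice = r.c_slice_homog * r.slice_dilution  # ng per g tissue
        per_slice[r.slice_id] = (
            a_slice - v_film * r.c_buffer_final
        ) / r.c_buffer_final
    n_fail = sum(not q.passed for q in qc.values())
    if not per_slice:
        raise QCFailureError(
            f"no slice for {drug!r} passed viability QC ({n_fail} failed)"
        )
    vu_mean = sum(per_slice.values()) / len(per_slice)
    return VuBrainResult(
        drug=drug,
        vu_mean=vu_mean,
        per_slice=per_slice,
        qc=qc,
        n_pass=len(per_slice),
        n_fail=n_fail,
    )
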