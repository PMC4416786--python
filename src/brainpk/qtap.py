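"""Targeted absolute proteomics (SRM/MRM) quantification with ULQ censoring.

Each target protein is monitored through one proteotypic peptide and four
precursor/product (Q1/Q3) transition sets, each measured in three analytical
runs against a stable-isotope-labelled internal standard peptide spiked at a
known amount.  Per transition measurement the absolute amount is

    amount (fmol/ug) = (area_analyte / area_IS) * IS_amount / protein_injected

A transition set is *positive* when its signal elutes at the internal
standard's retention time and its amount reaches the per-transition limit of
quantification (LOQ).  A protein is called *expressed* when three or four of
its transition sets are positive; its level is the mean over all positive
transition x run amounts, reported as mean +/- SEM (SEM over the same pooled
technical values — the capillary pool is a single biological sample, so SEM
reflects technical, not inter-animal, variability).  Proteins with fewer than
three positive transitions are censored as ULQ and reported as
``U.L.Q.(< loq)``.

Fold changes between censored quantities propagate the censoring direction:
an expressed level over a ULQ denominator is a lower bound, a ULQ numerator
over an expressed level an upper bound, and both-ULQ is undefined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from scipy import stats as _sps

from .exceptions import InvalidInputError, SchemaError

__all__ = [
    "ProbeSet",
    "ExpressionStatus",
    "FoldKind",
    "TransitionMeasurement",
    "ProteinExpression",
    "FoldChange",
    "GroupComparison",
    "N_TRANSITION_SETS",
    "quantify_transition",
    "assess_positivity",
    "summarize_expression",
    "compute_loq",
    "fold_change",
    "compare_expression_groups",
]

#: Transition sets monitored per peptide probe (Q1/Q3-1 .. Q1/Q3-4).
N_TRANSITION_SETS = 4

#: Positive transition counts that qualify a molecule as expressed.
POSITIVE_COUNTS_EXPRESSED = frozenset({3, 4})


class ProbeSet(str, Enum):
    """Species selectivity of the peptide probe used for a measurement."""

    HUMAN_SPECIFIC = "human_specific"
    MOUSE_SPECIFIC = "mouse_specific"
    COMMON = "common"


class ExpressionStatus(str, Enum):
    EXPRESSED = "expressed"
    ULQ = "ULQ"


class FoldKind(str, Enum):
    POINT = "point"
    LOWER_BOUND = "lower_bound"
    UPPER_BOUND = "upper_bound"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class TransitionMeasurement:
    """One transition x run peak-area pair against its internal standard."""

    molecule: str
    peptide_probe: ProbeSet
    transition_id: str
    run_id: str
    area_analyte: float
    area_is: float
    is_amount: float  # fmol of internal standard injected
    protein_injected: float  # ug protein on column
    rt_match: bool

    def __post_init__(self) -> None:
        if self.area_analyte < 0 or self.area_is < 0:
            raise InvalidInputError(
                f"{self.molecule}/{self.transition_id}/{self.run_id}: negative peak area"
            )
        if self.is_amount <= 0:
            raise InvalidInputError(
                f"{self.molecule}/{self.transition_id}: internal standard amount "
                "must be positive"
            )
        if self.protein_injected <= 0:
            raise InvalidInputError(
                f"{self.molecule}/{self.transition_id}: injected protein must be positive"
            )


@dataclass(frozen=True)
class ProteinExpression:
    """Censoring-aware expression level for one molecule in one group."""

    molecule: str
    group: str
    status: ExpressionStatus
    level: float | None = None  # fmol/ug protein, mean (expressed only)
    sem: float | None = None
    loq: float | None = None  # reported when ULQ
    n_values: int = 0
    positive_count: int = 0

    def __post_init__(self) -> None:
        if self.status is ExpressionStatus.EXPRESSED:
            if self.level is None or self.level < 0:
                raise InvalidInputError(
                    f"{self.molecule}/{self.group}: expressed entry needs level >= 0"
                )
        else:
            if self.loq is None or self.loq <= 0:
                raise InvalidInputError(
                    f"{self.molecule}/{self.group}: ULQ entry needs loq > 0"
                )
            if self.level is not None:
                raise InvalidInputError(
                    f"{self.molecule}/{self.group}: ULQ entry must not carry a level"
                )

    @property
    def expressed(self) -> bool:
        return self.status is ExpressionStatus.EXPRESSED


@dataclass(frozen=True)
class FoldChange:
    numerator: str  # "molecule@group"
    denominator: str
    kind: FoldKind
    value: float | None  # None only when undefined


@dataclass(frozen=True)
class GroupComparison:
    molecule: str
    testable: bool
    t: float | None = None
    df: int | None = None
    p: float | None = None
    significant: bool = False  # at p < 0.01, the table convention
    reason: str | None = None


def quantify_transition(m: TransitionMeasurement) -> float | None:
    """Stable-isotope-dilution amount for one transition measurement, fmol/ug.

    Returns ``None`` for an unusable measurement (internal-standard area 0);
    callers exclude and log such transitions.
    """
    if m.area_is == 0:
        return None
    return (m.area_analyte / m.area_is) * m.is_amount / m.protein_injected


def assess_positivity(
    transitions: Sequence[tuple[float, bool, float]],
) -> tuple[bool, int]:
    """Expression call from the four transition sets of one molecule.

    Each element is ``(amount, rt_match, loq)`` for one transition set
    (already aggregated over runs).  A set is positive when ``rt_match`` holds
    and ``amount >= loq``; the molecule is expressed when 3 or 4 sets are
    positive.
    """
    if len(transitions) != N_TRANSITION_SETS:
        raise SchemaError(
            f"exactly {N_TRANSITION_SETS} transition sets required, "
            f"got {len(transitions)}"
        )
    positive = sum(
        1 for amount, rt_match, loq in transitions if rt_match and amount >= loq
    )
    return positive in POSITIVE_COUNTS_EXPRESSED, positive


def _mean_sem(values: Sequence[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return mean, sd / math.sqrt(n)


def summarize_expression(
    molecule: str,
    group: str,
    amounts: Sequence[float],
    positive_count: int,
    loq: float | None = None,
) -> ProteinExpression:
    """Mean +/- SEM over the pooled positive transition x run amounts.

    ``amounts`` are the contributing values (positive transitions only,
    across the three runs; up to 12 values).  Call only after the molecule
    was assessed expressed; ULQ molecules are built directly with
    ``ProteinExpression(status=ULQ, loq=...)``.
    """
    if not amounts:
        raise InvalidInputError(f"{molecule}/{group}: no contributing amounts")
    mean, sem = _mean_sem(list(amounts))
    return ProteinExpression(
        molecule=molecule,
        group=group,
        status=ExpressionStatus.EXPRESSED,
        level=mean,
        sem=sem,
        loq=loq,
        n_values=len(amounts),
        positive_count=positive_count,
    )


def compute_loq(
    blank_amounts: dict[str, Sequence[float]],
    k_noise: float = 3.0,
    fallback: float | None = None,
) -> tuple[dict[str, float], float | None]:
    """Per-transition LOQ = ``k_noise`` x SD of blank-equivalent amounts.

    ``blank_amounts`` maps transition_id -> amounts (fmol/ug) measured in
    blank/noise regions.  Transitions with fewer than 3 blanks fall back to
    ``fallback`` with a warning.  Returns ``(per_transition_loq,
    molecule_loq)`` where the molecule-level reported LOQ is the minimum over
    its transitions' LOQs (the most sensitive transition defines
    detectability).
    """
    per_transition: dict[str, float] = {}
    for tid, values in blank_amounts.items():
        values = list(values)
        if len(values) < 3:
            if fallback is None:
                raise InvalidInputError(
                    f"transition {tid!r}: fewer than 3 blank measurements and "
                    "no fallback LOQ configured"
                )
            warnings.warn(
                f"transition {tid!r}: insufficient blanks ({len(values)}); "
                f"using fallback LOQ {fallback}",
                stacklevel=2,
            )
            per_transition[tid] = fallback
            continue
        n = len(values)
        mean = sum(values) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
        per_transition[tid] = k_noise * sd
    molecule_loq = min(per_transition.values()) if per_transition else None
    return per_transition, molecule_loq


def _label(e: ProteinExpression) -> str:
    return f"{e.molecule}@{e.group}"


def fold_change(a: ProteinExpression, b: ProteinExpression) -> FoldChange:
    """Censoring-aware ratio ``a / b`` of two expression levels."""
    num, den = _label(a), _label(b)
    if a.expressed and b.expressed:
        if b.level == 0:
            raise InvalidInputError(f"fold change {num}/{den}: zero denominator level")
        return FoldChange(num, den, FoldKind.POINT, a.level / b.level)
    if a.expressed and not b.expressed:
        # denominator censored below its LOQ: the true ratio exceeds level/loq
        return FoldChange(num, den, FoldKind.LOWER_BOUND, a.level / b.loq)
    if not a.expressed and b.expressed:
        return FoldChange(num, den, FoldKind.UPPER_BOUND, a.loq / b.level)
    return FoldChange(num, den, FoldKind.UNDEFINED, None)


def compare_expression_groups(
    molecule: str,
    values_a: Iterable[float] | None,
    values_b: Iterable[float] | None,
    alpha: float = 0.01,
) -> GroupComparison:
    """Unpaired two-tailed t-test on the pooled transition x run amounts.

    The comparison is over technical replicates (single pooled biological
    sample per group); a group censored as ULQ has no usable values and the
    comparison is reported not-testable rather than forced through zeros.
    """
    if values_a is None or values_b is None:
        return GroupComparison(molecule, testable=False, reason="group censored (ULQ)")
    a, b = list(values_a), list(values_b)
    if len(a) < 2 or len(b) < 2:
        return GroupComparison(molecule, testable=False, reason="n < 2 in a group")
    res = _sps.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    p = float(res.pvalue)
    return GroupComparison(
        molecule,
        testable=True,
        t=float(res.statistic),
        df=df,
        p=p,
        significant=p < alpha,
    )
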