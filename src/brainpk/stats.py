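"""Group comparisons and ratio tables for partitioning metrics.

The study design compares Kp / Kp,uu between mouse lines (and with/without
efflux blockers) using an unpaired two-tailed Student's t-test at alpha =
0.05.  Blocker effects are summarised as ratios of group-mean Kp (blocker /
control); following the source table convention these ratios are reported
without variability because group means, not animal-level pairs, form them.
No multiple-testing correction is applied; reports annotate the number of
tests performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats as _sps

from .exceptions import InvalidInputError

__all__ = [
    "TTestResult",
    "GroupSummary",
    "RatioEntry",
    "ttest_unpaired",
    "summarize_group",
    "blocker_ratio_table",
    "significance_stars",
]

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class TTestResult:
    testable: bool
    t: float | None = None
    df: float | None = None
    p: float | None = None
    significant: bool = False
    alpha: float = ALPHA_DEFAULT
    reason: str | None = None


@dataclass(frozen=True)
class GroupSummary:
    """mean/SD/SEM of one drug x genotype x treatment group."""

    drug: str
    genotype: str
    treatment: str | None
    n: int
    mean: float
    sd: float
    sem: float
    single_value: bool = False  # SD reported as 0 by convention, flagged


@dataclass(frozen=True)
class RatioEntry:
    """Mean-Kp ratio blocker/control for one drug x genotype (no variance)."""

    drug: str
    genotype: str
    blocker: str
    ratio: float


def ttest_unpaired(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
    alpha: float = ALPHA_DEFAULT,
) -> TTestResult:
    """Unpaired two-tailed t-test between two groups of animal-level values.

    ``equal_var=True`` gives the classical Student pooled-variance test with
    df = n_a + n_b - 2; ``equal_var=False`` selects Welch's test
    (recommended when group variances may differ, but the pooled test is the
    default here to match the study's stated analysis).
    """
    a, b = list(group_a), list(group_b)
    if len(a) < 2 or len(b) < 2:
        return TTestResult(testable=False, alpha=alpha, reason="n < 2 in a group")
    res = _sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df: float = len(a) + len(b) - 2
    else:
        df = float(res.df)
    p = float(res.pvalue)
    return TTestResult(
        testable=True,
        t=float(res.statistic),
        df=df,
        p=p,
        significant=p < alpha,
        alpha=alpha,
    )


def summarize_group(
    values: Iterable[float],
    drug: str = "",
    genotype: str = "",
    treatment: str | None = None,
) -> GroupSummary:
    """mean, SD (ddof=1) and SEM of one group; a single-value group reports
    SD = 0 with a flag rather than NaN."""
    vals = list(values)
    if not vals:
        raise InvalidInputError(
            f"empty group for {drug!r}/{genotype!r}/{treatment!r}"
        )
    n = len(vals)
    mean = sum(vals) / n
    if n == 1:
        return GroupSummary(drug, genotype, treatment, 1, mean, 0.0, 0.0, True)
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    return GroupSummary(drug, genotype, treatment, n, mean, sd, sd / math.sqrt(n))


def blocker_ratio_table(
    summaries: Sequence[GroupSummary],
) -> list[RatioEntry]:
    """Ratios of mean Kp with blocker over mean Kp in untreated controls.

    ``summaries`` mixes control groups (``treatment`` None/empty) and blocker
    groups for the same drug x genotype.  Entries whose control group is
    missing are skipped with a warning; no variance is propagated.
    """
    controls: dict[tuple[str, str], GroupSummary] = {}
    for s in summaries:
        if not s.treatment:
            controls[(s.drug, s.genotype)] = s
    out: list[RatioEntry] = []
    for s in summaries:
        if not s.treatment:
            continue
        control = controls.get((s.drug, s.genotype))
        if control is None:
            logger.warning(
                "no control group for %s/%s; skipping blocker ratio for %r",
                s.drug,
                s.genotype,
                s.treatment,
            )
            continue
        if control.mean <= 0:
            logger.warning(
                "control mean Kp <= 0 for %s/%s; skipping ratio", s.drug, s.genotype
            )
            continue
        out.append(RatioEntry(s.drug, s.genotype, s.treatment, s.mean / control.mean))
    return out


def significance_stars(p: float | None) -> str:
    """Figure-legend convention: ``*`` for p < 0.05, ``**`` for p < 0.01."""
    if p is None:
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
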