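"""Presentation layer: table-style rounding and report formatting.

Rounded values appear only here; every computation upstream keeps full
precision.  The partition-table convention is three decimal places for values
below 1 and three significant figures otherwise, matching the source table's
printed precision.  Censored proteomics cells print as ``U.L.Q.(< loq)``.
"""

from __future__ import annotations

import math

from .qtap import FoldChange, FoldKind, ProteinExpression

__all__ = [
    "round_sig",
    "round_kpuu_table",
    "format_mean_sem",
    "format_ulq",
    "format_expression_cell",
    "format_fold",
]


def round_sig(x: float, n: int = 3) -> float:
    """Round to ``n`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, n - 1 - int(math.floor(math.log10(abs(x)))))


def round_kpuu_table(x: float) -> float:
    """Partition-table rounding: 3 decimals below 1, else 3 significant figures."""
    if abs(x) < 1:
        return round(x, 3)
    return round_sig(x, 3)


def format_mean_sem(mean: float, sem: float, sig: int = 3) -> str:
    return f"{round_sig(mean, sig):g} ± {round_sig(sem, 2):g}"


def format_ulq(loq: float) -> str:
    return f"U.L.Q.(< {round_sig(loq, 3):g})"


def format_expression_cell(e: ProteinExpression) -> str:
    """One proteomics table cell: ``mean ± SEM`` or ``U.L.Q.(< loq)``."""
    if e.expressed:
        return format_mean_sem(e.level, e.sem or 0.0)
    return format_ulq(e.loq)


def format_fold(fc: FoldChange, sig: int = 3) -> str:
    if fc.kind is FoldKind.UNDEFINED:
        return "n.d. (both U.L.Q.)"
    value = f"{round_sig(fc.value, sig):g}"
    if fc.kind is FoldKind.LOWER_BOUND:
        return f"> {value}"
    if fc.kind is FoldKind.UPPER_BOUND:
        return f"< {value}"
    return value
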