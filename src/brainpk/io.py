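"""CSV schema readers and validation for the pipeline's input tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .binding import DialysisRecord, SliceAssayRecord
from .distribution import ConcentrationRecord, Genotype
from .exceptions import SchemaError
from .qtap import N_TRANSITION_SETS, ProbeSet, TransitionMeasurement

__all__ = [
    "Finding",
    "read_concentrations",
    "read_dialysis",
    "read_slices",
    "read_srm_transitions",
    "validate_table",
    "SCHEMAS",
]


@dataclass(frozen=True)
class Finding:
    """One validation finding: severity is ``error`` or ``warning``."""

    file: str
    severity: str
    message: str
    row: int | None = None

    def __str__(self) -> str:
        loc = f" [row {self.row}]" if self.row is not None else ""
        return f"{self.file}{loc}: {self.severity}: {self.message}"


SCHEMAS: dict[str, list[str]] = {
    "concentrations": [
        "animal_id",
        "genotype",
        "drug",
        "treatment",
        "c_plasma_ng_ml",
        "c_brain_homog_ng_ml",
        "homogenate_dilution",
    ],
    "dialysis": [
        "drug",
        "replicate_id",
        "c_buffer_side_ng_ml",
        "c_plasma_side_ng_ml",
        "incubation_h",
    ],
    "slices": [
        "drug",
        "slice_id",
        "slice_weight_g",
        "c_buffer_final_ng_ml",
        "c_slice_homog_ng_ml",
        "slice_dilution",
        "end_ph",
        "ldh_release_fraction",
    ],
    "srm_transitions": [
        "molecule",
        "peptide_probe",
        "transition_id",
        "run_id",
        "group",
        "area_analyte",
        "area_is",
        "is_amount_fmol",
        "protein_injected_ug",
        "rt_match",
    ],
}


def _load(path: str | Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{Path(path).name}: missing required column(s) {', '.join(missing)}"
        )
    return df


def read_concentrations(path: str | Path) -> list[ConcentrationRecord]:
    df = _load(path, "concentrations")
    records = []
    for row in df.itertuples():
        treatment = getattr(row, "treatment", None)
        if pd.isna(treatment) or treatment == "":
            treatment = None
        records.append(
            ConcentrationRecord(
                animal_id=str(row.animal_id),
                genotype=Genotype(row.genotype),
                drug=str(row.drug),
                treatment=treatment,
                c_plasma=float(row.c_plasma_ng_ml),
                c_brain_homogenate=float(row.c_brain_homog_ng_ml),
                homogenate_dilution=float(row.homogenate_dilution),
            )
        )
    return records


def read_dialysis(path: str | Path) -> list[DialysisRecord]:
    df = _load(path, "dialysis")
    records = []
    for row in df.itertuples():
        genotype = getattr(row, "genotype", None)
        if genotype is not None and (pd.isna(genotype) or genotype == ""):
            genotype = None
        records.append(
            DialysisRecord(
                drug=str(row.drug),
                replicate_id=str(row.replicate_id),
                c_buffer_side=float(row.c_buffer_side_ng_ml),
                c_plasma_side=float(row.c_plasma_side_ng_ml),
                incubation_h=float(row.incubation_h),
                genotype=str(genotype) if genotype is not None else None,
            )
        )
    return records


def read_slices(path: str | Path) -> list[SliceAssayRecord]:
    df = _load(path, "slices")
    return [
        SliceAssayRecord(
            drug=str(row.drug),
            slice_id=str(row.slice_id),
            slice_weight=float(row.slice_weight_g),
            c_buffer_final=float(row.c_buffer_final_ng_ml),
            c_slice_homog=float(row.c_slice_homog_ng_ml),
            slice_dilution=float(row.slice_dilution),
            end_ph=float(row.end_ph),
            ldh_release_fraction=float(row.ldh_release_fraction),
        )
        for row in df.itertuples()
    ]


def read_srm_transitions(
    path: str | Path,
) -> dict[tuple[str, str], list[TransitionMeasurement]]:
    """Transitions keyed by (molecule, group)."""
    df = _load(path, "srm_transitions")
    out: dict[tuple[str, str], list[TransitionMeasurement]] = {}
    for row in df.itertuples():
        m = TransitionMeasurement(
            molecule=str(row.molecule),
            peptide_probe=ProbeSet(row.peptide_probe),
            transition_id=str(row.transition_id),
            run_id=str(row.run_id),
            area_analyte=float(row.area_analyte),
            area_is=float(row.area_is),
            is_amount=float(row.is_amount_fmol),
            protein_injected=float(row.protein_injected_ug),
            rt_match=bool(row.rt_match),
        )
        out.setdefault((m.molecule, str(row.group)), []).append(m)
    return out


def validate_table(path: str | Path, kind: str) -> list[Finding]:
    """Schema, units and invariant checks for one table; returns findings."""
    name = Path(path).name
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        return [Finding(name, "error", f"unreadable file: {exc}")]
    except Exception as exc:  # malformed CSV
        return [Finding(name, "error", f"unparseable CSV: {exc}")]
    findings: list[Finding] = []
    for col in SCHEMAS[kind]:
        if col not in df.columns:
            findings.append(Finding(name, "error", f"missing column {col!r}"))
    if findings:
        return findings

    def check_nonneg(col: str) -> None:
        bad = df.index[pd.to_numeric(df[col], errors="coerce") < 0]
        for i in bad:
            findings.append(
                Finding(name, "error", f"negative value in {col!r}", int(i))
            )

    if kind == "concentrations":
        check_nonneg("c_plasma_ng_ml")
        check_nonneg("c_brain_homog_ng_ml")
        for i in df.index[df["homogenate_dilution"] < 1]:
            findings.append(
                Finding(name, "error", "homogenate_dilution < 1", int(i))
            )
        bad_geno = set(df["genotype"]) - {g.value for g in Genotype}
        if bad_geno:
            findings.append(
                Finding(name, "error", f"unknown genotype(s): {sorted(bad_geno)}")
            )
    elif kind == "dialysis":
        check_nonneg("c_buffer_side_ng_ml")
        check_nonneg("c_plasma_side_ng_ml")
    elif kind == "slices":
        for i in df.index[df["slice_weight_g"] <= 0]:
            findings.append(Finding(name, "error", "nonpositive slice weight", int(i)))
        bad = df.index[
            (df["ldh_release_fraction"] < 0) | (df["ldh_release_fraction"] > 1)
        ]
        for i in bad:
            findings.append(
                Finding(name, "error", "ldh_release_fraction outside [0, 1]", int(i))
            )
    elif kind == "srm_transitions":
        check_nonneg("area_analyte")
        check_nonneg("area_is")
        counts = df.groupby(["molecule", "group"])["transition_id"].nunique()
        for (mol, grp), n in counts.items():
            if n != N_TRANSITION_SETS:
                findings.append(
                    Finding(
                        name,
                        "error",
                        f"molecule {mol!r} in group {grp!r} has {n} transition "
                        f"sets; exactly {N_TRANSITION_SETS} required",
                    )
                )
    else:
        raise SchemaError(f"unknown table kind {kind!r}")
    return findings
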