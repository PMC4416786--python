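"""End-to-end orchestration: validation, assays, distribution, proteomics,
report emission.

Outputs are plain-text TSV reports mirroring the study's table layouts (a
partition table with Kp / Vu,brain / fu / Kp,uu, a blocker-ratio table, a
protein-expression table with ``U.L.Q.(< x)`` cells and significance stars)
plus a machine-readable ``results.json``.  Reports are byte-identical across
reruns of the same inputs and configuration; timestamps live only in the run
log, which also records a configuration hash and input checksums for
provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as bio
from .binding import FuPlasmaResult, VuBrainResult, compute_fu_plasma, compute_vu_brain
from .config import RunConfig
from .distribution import (
    DistributionResult,
    VascularParams,
    analyze_animal,
    compute_kpuu,
)
from .exceptions import BrainPKError, SchemaError
from .qtap import (
    ExpressionStatus,
    ProteinExpression,
    assess_positivity,
    compare_expression_groups,
    fold_change,
    quantify_transition,
    summarize_expression,
)
from .report import (
    format_expression_cell,
    format_fold,
    round_kpuu_table,
    round_sig,
)
from .stats import (
    GroupSummary,
    blocker_ratio_table,
    significance_stars,
    summarize_group,
    ttest_unpaired,
)

__all__ = ["PipelineResult", "validate_inputs", "run_pipeline"]

logger = logging.getLogger(__name__)

#: Cross-molecule fold comparisons of interest: (mol_a, group_a, mol_b, group_b)
DEFAULT_FOLD_COMPARISONS = (
    ("Mdr1a", "C57BL6_WT", "hMDR1", "HMDR1"),
    ("Mdr1a", "C57BL6_WT", "Mdr1a", "HMDR1"),
    ("Mdr1a", "HMDR1", "hMDR1", "HMDR1"),
)


@dataclass
class PipelineResult:
    fu: dict[tuple[str, str | None], FuPlasmaResult] = field(default_factory=dict)
    vu: dict[str, VuBrainResult] = field(default_factory=dict)
    animals: list[DistributionResult] = field(default_factory=list)
    group_summaries: list[GroupSummary] = field(default_factory=list)
    partition_table: pd.DataFrame | None = None
    ratio_table: pd.DataFrame | None = None
    expression: dict[tuple[str, str], ProteinExpression] = field(default_factory=dict)
    expression_table: pd.DataFrame | None = None
    folds: list = field(default_factory=list)
    n_tests: int = 0


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def validate_inputs(config: RunConfig) -> list[bio.Finding]:
    """Schema/units/invariant findings across all configured input files."""
    findings: list[bio.Finding] = []
    for attr, kind in (
        ("concentrations", "concentrations"),
        ("dialysis", "dialysis"),
        ("slices", "slices"),
        ("srm_transitions", "srm_transitions"),
    ):
        path = getattr(config, attr)
        if path is None:
            continue
        if not Path(path).exists():
            findings.append(bio.Finding(str(path), "error", "file not found"))
            continue
        findings.extend(bio.validate_table(path, kind))
    return findings


def _fu_lookup(
    fu: dict[tuple[str, str | None], FuPlasmaResult], drug: str, genotype: str
) -> FuPlasmaResult:
    res = fu.get((drug, genotype)) or fu.get((drug, None))
    if res is None:
        raise BrainPKError(f"no fu,plasma assay available for drug {drug!r}")
    return res


def run_binding(config: RunConfig, result: PipelineResult) -> None:
    if config.dialysis:
        by_assay: dict[tuple[str, str | None], list] = defaultdict(list)
        for rec in bio.read_dialysis(config.dialysis):
            by_assay[(rec.drug, rec.genotype)].append(rec)
        for key, records in sorted(by_assay.items(), key=str):
            result.fu[key] = compute_fu_plasma(records)
    if config.slices:
        by_drug: dict[str, list] = defaultdict(list)
        for srec in bio.read_slices(config.slices):
            by_drug[srec.drug].append(srec)
        for drug, records in sorted(by_drug.items()):
            result.vu[drug] = compute_vu_brain(
                records,
                v_film=config.qc.v_film_ml_g,
                ldh_threshold=config.qc.ldh_threshold,
            )


def run_distribution(config: RunConfig, result: PipelineResult) -> None:
    if not config.concentrations:
        return
    params = VascularParams(
        config.vascular.v_water_ml_g, config.vascular.v_protein_ml_g
    )
    records = bio.read_concentrations(config.concentrations)
    for rec in records:
        fu = _fu_lookup(result.fu, rec.drug, rec.genotype.value).fu_mean
        vu = result.vu[rec.drug].vu_mean
        result.animals.append(analyze_animal(rec, vu, fu, params))

    # group summaries on Kp (residual-blood corrected)
    groups: dict[tuple[str, str, str | None], list[float]] = defaultdict(list)
    for a in result.animals:
        groups[(a.drug, a.genotype.value, a.treatment)].append(a.kp)
    for (drug, genotype, treatment), values in sorted(groups.items(), key=str):
        result.group_summaries.append(
            summarize_group(values, drug, genotype, treatment)
        )

    # partition table (control animals): group-mean Kp with the assay
    # constants, Kp,uu formed from the group-mean Kp
    rows = []
    for s in result.group_summaries:
        if s.treatment:
            continue
        fu = _fu_lookup(result.fu, s.drug, s.genotype).fu_mean
        vu = result.vu[s.drug].vu_mean
        rows.append(
            {
                "drug": s.drug,
                "genotype": s.genotype,
                "n": s.n,
                "kp": s.mean,
                "kp_sd": s.sd,
                "v_u_brain": vu,
                "f_u_plasma": fu,
                "kpuu": compute_kpuu(s.mean, vu, fu),
            }
        )
    result.partition_table = pd.DataFrame(rows)

    ratios = blocker_ratio_table(result.group_summaries)
    result.ratio_table = pd.DataFrame(
        [
            {"drug": r.drug, "genotype": r.genotype, "blocker": r.blocker,
             "kp_ratio": r.ratio}
            for r in ratios
        ]
    )


def run_qtap(config: RunConfig, result: PipelineResult) -> None:
    if not config.srm_transitions:
        return
    by_key = bio.read_srm_transitions(config.srm_transitions)
    pools: dict[tuple[str, str], list[float]] = {}
    for (molecule, group), measurements in sorted(by_key.items()):
        loq = config.loq_table.get(f"{molecule}|{group}")
        if loq is None:
            loq = config.loq.fallback_fmol_ug
            if loq is None:
                raise SchemaError(
                    f"no LOQ configured for {molecule!r} in group {group!r}"
                )
        per_transition: dict[str, list[tuple[float, bool]]] = defaultdict(list)
        for m in measurements:
            amount = quantify_transition(m)
            if amount is None:
                logger.warning(
                    "excluded %s/%s/%s: internal standard area is 0",
                    m.molecule, m.transition_id, m.run_id,
                )
                continue
            per_transition[m.transition_id].append((amount, m.rt_match))
        sets = []
        for tid in sorted(per_transition):
            vals = per_transition[tid]
            mean_amount = sum(v for v, _ in vals) / len(vals)
            rt_all = all(rt for _, rt in vals)
            sets.append((mean_amount, rt_all, loq))
        expressed, positive = assess_positivity(sets)
        if expressed:
            # pool = all runs of the positive transition sets
            pool = []
            for tid in sorted(per_transition):
                vals = per_transition[tid]
                if _transition_positive(vals, loq):
                    pool.extend(v for v, _ in vals)
            pools[(molecule, group)] = pool
            result.expression[(molecule, group)] = summarize_expression(
                molecule, group, pool, positive, loq
            )
        else:
            result.expression[(molecule, group)] = ProteinExpression(
                molecule=molecule,
                group=group,
                status=ExpressionStatus.ULQ,
                loq=loq,
                positive_count=positive,
            )

    # per-molecule cross-group significance on pooled technical values
    comparisons: dict[str, object] = {}
    molecules = sorted({m for m, _ in result.expression})
    groups = sorted({g for _, g in result.expression})
    if len(groups) == 2:
        g_a, g_b = groups
        for molecule in molecules:
            comparisons[molecule] = compare_expression_groups(
                molecule,
                pools.get((molecule, g_a)),
                pools.get((molecule, g_b)),
                alpha=config.stats.alpha_expression,
            )
        result.n_tests += sum(1 for c in comparisons.values() if c.testable)

    rows = []
    for molecule in molecules:
        row: dict[str, object] = {"molecule": molecule}
        for group in groups:
            e = result.expression.get((molecule, group))
            row[group] = format_expression_cell(e) if e else ""
        comp = comparisons.get(molecule)
        if comp is not None and getattr(comp, "testable", False):
            row["signif"] = "*" if comp.significant else ""
            row["p"] = round_sig(comp.p, 3)
        else:
            row["signif"] = ""
            row["p"] = ""
        rows.append(row)
    result.expression_table = pd.DataFrame(rows)

    for mol_a, grp_a, mol_b, grp_b in DEFAULT_FOLD_COMPARISONS:
        a = result.expression.get((mol_a, grp_a))
        b = result.expression.get((mol_b, grp_b))
        if a is not None and b is not None:
            result.folds.append(fold_change(a, b))


def _transition_positive(vals: list[tuple[float, bool]], loq: float) -> bool:
    mean_amount = sum(v for v, _ in vals) / len(vals)
    return all(rt for _, rt in vals) and mean_amount >= loq


def _write_reports(config: RunConfig, result: PipelineResult, out: Path) -> None:
    if result.partition_table is not None and not result.partition_table.empty:
        t = result.partition_table.copy()
        t["kp"] = t["kp"].map(lambda x: round_sig(x, 3))
        t["kpuu"] = t["kpuu"].map(round_kpuu_table)
        t["f_u_plasma"] = t["f_u_plasma"].map(lambda x: round_sig(x, 3))
        t["v_u_brain"] = t["v_u_brain"].map(lambda x: round_sig(x, 3))
        t.drop(columns=["kp_sd"]).to_csv(out / "partition_table.tsv", sep="\t", index=False)
    if result.ratio_table is not None and not result.ratio_table.empty:
        t = result.ratio_table.copy()
        t["kp_ratio"] = t["kp_ratio"].map(lambda x: round_sig(x, 3))
        t.to_csv(out / "blocker_ratio_table.tsv", sep="\t", index=False)
    if result.expression_table is not None and not result.expression_table.empty:
        result.expression_table.to_csv(
            out / "expression_table.tsv", sep="\t", index=False
        )
    if result.vu:
        qc_rows = []
        for drug, vres in sorted(result.vu.items()):
            for slice_id, qc in sorted(vres.qc.items()):
                qc_rows.append(
                    {
                        "drug": drug,
                        "slice_id": slice_id,
                        "passed": qc.passed,
                        "reasons": "; ".join(qc.reasons),
                    }
                )
        pd.DataFrame(qc_rows).to_csv(out / "slice_qc.tsv", sep="\t", index=False)
    if result.folds:
        pd.DataFrame(
            [
                {
                    "numerator": f.numerator,
                    "denominator": f.denominator,
                    "kind": f.kind.value,
                    "fold": format_fold(f),
                }
                for f in result.folds
            ]
        ).to_csv(out / "fold_changes.tsv", sep="\t", index=False)


def _results_json(result: PipelineResult) -> dict:
    payload: dict = {
        "fu_plasma": {
            f"{d}|{g or ''}": {"mean": r.fu_mean, "sd": r.fu_sd, "n": r.n}
            for (d, g), r in sorted(result.fu.items(), key=str)
        },
        "vu_brain": {
            d: {"mean": r.vu_mean, "n_pass": r.n_pass, "n_fail": r.n_fail}
            for d, r in sorted(result.vu.items())
        },
        "animals": [
            {
                "animal_id": a.animal_id,
                "drug": a.drug,
                "genotype": a.genotype.value,
                "treatment": a.treatment,
                "kp": a.kp,
                "kpuu": a.kpuu,
                "a_brain": a.a_brain,
                "clamped": a.clamped,
            }
            for a in result.animals
        ],
        "expression": {
            f"{m}|{g}": {
                "status": e.status.value,
                "level": e.level,
                "sem": e.sem,
                "loq": e.loq,
                "n_values": e.n_values,
                "positive_count": e.positive_count,
            }
            for (m, g), e in sorted(result.expression.items())
        },
        "n_significance_tests": result.n_tests,
    }
    if result.partition_table is not None:
        payload["partition_table"] = result.partition_table.to_dict("records")
    if result.ratio_table is not None:
        payload["blocker_ratios"] = result.ratio_table.to_dict("records")
    if result.folds:
        payload["fold_changes"] = [
            {
                "numerator": f.numerator,
                "denominator": f.denominator,
                "kind": f.kind.value,
                "value": f.value,
            }
            for f in result.folds
        ]
    return payload


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Validate, run every configured stage, and emit the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="a")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("brainpk")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        cfg_hash = hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True).encode()
        ).hexdigest()
        logger.info("config hash %s", cfg_hash)
        for attr in ("concentrations", "dialysis", "slices", "srm_transitions"):
            path = getattr(config, attr)
            if path and Path(path).exists():
                logger.info("input %s sha256 %s", path, _sha256(path))
        findings = validate_inputs(config)
        errors = [f for f in findings if f.severity == "error"]
        if errors:
            for f in errors:
                logger.error("%s", f)
            raise SchemaError(
                "input validation failed:\n" + "\n".join(str(f) for f in errors)
            )
        result = PipelineResult()
        run_binding(config, result)
        run_distribution(config, result)
        run_qtap(config, result)
        _write_reports(config, result, out)
        (out / "results.json").write_text(
            json.dumps(_results_json(result), indent=2, sort_keys=True)
        )
        logger.info("pipeline complete; reports in %s", out)
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
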