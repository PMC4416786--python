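"""Synthetic cohort generator for the partitioning / proteomics pipeline.

Emulates the four experiment kinds end to end so the analysis chain is
exercisable and parameter-recoverable without any external data:

* in vivo cohorts — per-animal plasma and brain-homogenate concentrations
  produced by the forward model of the distribution equations:
  ``Cu,plasma = fu * Cplasma``; ``Cu,brain = Kp,uu * Cu,plasma``;
  ``Abrain = Cu,brain * Vu,brain``;
  ``Cbrain,h = Abrain * (1 - Vwater) + Veff * Cplasma`` (then divided by the
  homogenate dilution).  With zero noise the analysis inverts this exactly.
* equilibrium dialysis — buffer side carries the unbound concentration,
  plasma side the total.
* brain slices — slice uptake ``A_slice = (Vu,brain + v_film) * Cbuffer``;
  a configurable fraction of slices is generated non-viable (low pH) with a
  grossly inflated concentration to exercise QC exclusion.
* SRM/MRM transitions — 4 transition sets x 3 runs per peptide probe with
  species-selective probes (human-specific probes see no mouse signal and
  vice versa; the common probe sums both); molecules below their LOQ emit
  noise-level areas without a retention-time match.

All measurement noise is multiplicative lognormal (mean 1, CV-parameterised),
matching nonnegative, right-skewed assay data.  A single global seed is
expanded into independent named substreams so adding one generator never
perturbs another's output; a fixed seed yields byte-identical CSV files.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distribution import Genotype, VascularParams
from .exceptions import InvalidInputError
from .qtap import ProbeSet

__all__ = [
    "NoiseModel",
    "DrugGroupTruth",
    "Probe",
    "CohortTruth",
    "default_truth",
    "generate_cohort",
    "generate_dialysis",
    "generate_slices",
    "generate_srm",
    "generate_all",
]

CSV_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class NoiseModel:
    """Lognormal CVs per assay (0 = noise-free).

    Defaults: 10% for in vivo concentrations and slice assays (bioanalysis
    plus biological scatter), 5% for equilibrium dialysis (replicate
    agreement typical of that assay), 10% for SRM/MRM peak areas.
    """

    cv_concentration: float = 0.10
    cv_dialysis: float = 0.05
    cv_slice: float = 0.10
    cv_srm: float = 0.10


@dataclass(frozen=True)
class DrugGroupTruth:
    """Ground truth for one drug x genotype group."""

    kpuu: float
    v_u_brain: float  # ml/g
    f_u_plasma: float
    c_plasma: float  # ng/ml typical total plasma level

    def __post_init__(self) -> None:
        for name in ("kpuu", "v_u_brain", "f_u_plasma", "c_plasma"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"truth {name} must be positive")


@dataclass(frozen=True)
class Probe:
    """A monitored peptide probe: which proteins its signal sums over."""

    molecule: str  # label under which results are reported
    probe_set: ProbeSet
    targets: tuple[str, ...]  # protein truth keys the probe responds to


@dataclass(frozen=True)
class CohortTruth:
    """Full ground-truth record for one synthetic study."""

    drugs: dict[tuple[str, str], DrugGroupTruth]  # (drug, genotype) ->
    vascular: VascularParams = field(default_factory=VascularParams)
    noise: NoiseModel = field(default_factory=NoiseModel)
    proteins: dict[tuple[str, str], float] = field(default_factory=dict)
    probes: tuple[Probe, ...] = ()
    loq: dict[tuple[str, str], float] = field(default_factory=dict)
    homogenate_dilution: float = 5.0
    slice_dilution: float = 10.0
    slice_buffer_ng_ml: float = 100.0
    v_film: float = 0.0
    is_amount_fmol: float = 500.0
    protein_injected_ug: float = 33.3
    seed: int = 0

    def to_json(self) -> str:
        def _key(d: dict) -> dict:
            return {"|".join(k): v for k, v in d.items()}

        payload = {
            "drugs": _key(
                {k: dataclasses.asdict(v) for k, v in self.drugs.items()}
            ),
            "vascular": dataclasses.asdict(self.vascular),
            "noise": dataclasses.asdict(self.noise),
            "proteins": _key(self.proteins),
            "probes": [dataclasses.asdict(p) for p in self.probes],
            "loq": _key(self.loq),
            "homogenate_dilution": self.homogenate_dilution,
            "slice_dilution": self.slice_dilution,
            "slice_buffer_ng_ml": self.slice_buffer_ng_ml,
            "v_film": self.v_film,
            "is_amount_fmol": self.is_amount_fmol,
            "protein_injected_ug": self.protein_injected_ug,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent named substream of the global seed."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


def _lognoise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal factors with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


# --- default scenario ------------------------------------------------------

# Measured partitioning constants for the two strains with printed summary
# values; Kp,uu truths are the unrounded ratios Kp / (Vu,brain * fu) so the
# default scenario's report reproduces the printed cells after rounding.
_TABLE1_LIKE = {
    # drug: (kp_wt, kp_hmdr1, v_u_brain, fu_wt, fu_hmdr1, plasma ng/ml)
    "digoxin": (0.05, 0.11, 44.8, 0.594, 0.607, 50.0),
    "verapamil": (0.6, 9.0, 48.2, 0.115, 0.117, 100.0),
    "docetaxel": (0.09, 0.13, 789.0, 0.053, 0.052, 500.0),
    "oxycodone": (4.8, 7.7, 3.75, 0.681, 0.681, 150.0),
}

# Knockout-over-wild-type Kp fold increases used to extend the default
# scenario to the FVB / knockout pair (efflux abolished raises brain levels).
_KO_FOLD = {"digoxin": 20.0, "verapamil": 30.0, "docetaxel": 4.0, "oxycodone": 1.6}

# Capillary expression truths (fmol/ug protein) per underlying protein and
# strain; the humanised strain expresses a little human MDR1 plus residual
# mouse Mdr1a, the wild type only Mdr1a.
_PROTEIN_TRUTH = {
    ("MDR1", "C57BL6_WT"): 0.0,
    ("MDR1", "HMDR1"): 0.355,
    ("Mdr1a", "C57BL6_WT"): 22.3,
    ("Mdr1a", "HMDR1"): 2.45,
    ("Mdr1b", "C57BL6_WT"): 0.0,
    ("Mdr1b", "HMDR1"): 0.0,
}

_DEFAULT_PROBES = (
    Probe("hMDR1", ProbeSet.HUMAN_SPECIFIC, ("MDR1",)),
    Probe("Mdr1a", ProbeSet.MOUSE_SPECIFIC, ("Mdr1a",)),
    Probe("Mdr1b", ProbeSet.MOUSE_SPECIFIC, ("Mdr1b",)),
    Probe("MDR1_Mdr1a_common", ProbeSet.COMMON, ("MDR1", "Mdr1a")),
)

_DEFAULT_LOQ = {
    ("hMDR1", "C57BL6_WT"): 0.112,
    ("hMDR1", "HMDR1"): 0.110,
    ("Mdr1a", "C57BL6_WT"): 0.100,
    ("Mdr1a", "HMDR1"): 0.100,
    ("Mdr1b", "C57BL6_WT"): 0.136,
    ("Mdr1b", "HMDR1"): 0.134,
    ("MDR1_Mdr1a_common", "C57BL6_WT"): 0.100,
    ("MDR1_Mdr1a_common", "HMDR1"): 0.100,
}


def default_truth(seed: int = 0, noise: NoiseModel | None = None) -> CohortTruth:
    """Default scenario mirroring the study's printed summary constants."""
    drugs: dict[tuple[str, str], DrugGroupTruth] = {}
    for drug, (kp_wt, kp_h, vu, fu_wt, fu_h, cp) in _TABLE1_LIKE.items():
        drugs[(drug, Genotype.C57BL6_WT.value)] = DrugGroupTruth(
            kpuu=kp_wt / (vu * fu_wt), v_u_brain=vu, f_u_plasma=fu_wt, c_plasma=cp
        )
        drugs[(drug, Genotype.HMDR1.value)] = DrugGroupTruth(
            kpuu=kp_h / (vu * fu_h), v_u_brain=vu, f_u_plasma=fu_h, c_plasma=cp
        )
        # FVB wild type assumed comparable to the other wild-type strain;
        # knockout scales Kp (hence Kp,uu) by the efflux fold.
        drugs[(drug, Genotype.FVB_WT.value)] = DrugGroupTruth(
            kpuu=kp_wt / (vu * fu_wt), v_u_brain=vu, f_u_plasma=fu_wt, c_plasma=cp
        )
        drugs[(drug, Genotype.MDR1A1B_KO.value)] = DrugGroupTruth(
            kpuu=kp_wt * _KO_FOLD[drug] / (vu * fu_wt),
            v_u_brain=vu,
            f_u_plasma=fu_wt,
            c_plasma=cp,
        )
    return CohortTruth(
        drugs=drugs,
        noise=noise or NoiseModel(),
        proteins=dict(_PROTEIN_TRUTH),
        probes=_DEFAULT_PROBES,
        loq=dict(_DEFAULT_LOQ),
        seed=seed,
    )


# --- generators ------------------------------------------------------------


def generate_cohort(truth: CohortTruth, n_per_group: int = 5) -> pd.DataFrame:
    """Per-animal concentration table (``concentrations.csv`` content)."""
    rng = _rng(truth.seed, "cohort")
    rows = []
    vw = truth.vascular.v_water
    for (drug, genotype), g in sorted(truth.drugs.items()):
        v_eff = g.f_u_plasma * vw + (1 - g.f_u_plasma) * truth.vascular.v_protein
        noise_p = _lognoise(rng, truth.noise.cv_concentration, n_per_group)
        noise_b = _lognoise(rng, truth.noise.cv_concentration, n_per_group)
        for i in range(n_per_group):
            cu_plasma = g.f_u_plasma * g.c_plasma
            a_brain = g.kpuu * cu_plasma * g.v_u_brain
            c_brain_h = a_brain * (1 - vw) + v_eff * g.c_plasma
            rows.append(
                {
                    "animal_id": f"{drug}-{genotype}-{i + 1:02d}",
                    "genotype": genotype,
                    "drug": drug,
                    "treatment": "",
                    "c_plasma_ng_ml": g.c_plasma * noise_p[i],
                    "c_brain_homog_ng_ml": c_brain_h
                    / truth.homogenate_dilution
                    * noise_b[i],
                    "homogenate_dilution": truth.homogenate_dilution,
                }
            )
    return pd.DataFrame(rows)


def generate_dialysis(truth: CohortTruth, replicates: int = 3) -> pd.DataFrame:
    """Equilibrium-dialysis table (``dialysis.csv`` content)."""
    rng = _rng(truth.seed, "dialysis")
    rows = []
    seen: set[tuple[str, str]] = set()
    for (drug, genotype), g in sorted(truth.drugs.items()):
        # one dialysis assay per (drug, strain-specific fu); strains sharing
        # an fu truth still get their own replicate set, as in the bench work
        if (drug, genotype) in seen:
            continue
        seen.add((drug, genotype))
        noise_b = _lognoise(rng, truth.noise.cv_dialysis, replicates)
        noise_p = _lognoise(rng, truth.noise.cv_dialysis, replicates)
        cu = g.f_u_plasma * g.c_plasma
        for i in range(replicates):
            rows.append(
                {
                    "drug": drug,
                    "genotype": genotype,
                    "replicate_id": f"{drug}-{genotype}-r{i + 1}",
                    "c_buffer_side_ng_ml": cu * noise_b[i],
                    "c_plasma_side_ng_ml": g.c_plasma * noise_p[i],
                    "incubation_h": 6.0,
                }
            )
    return pd.DataFrame(rows)


def generate_slices(
    truth: CohortTruth, n_slices: int = 6, fail_fraction: float = 0.0
) -> pd.DataFrame:
    """Brain-slice table (``slices.csv`` content).

    The slice assay is run once per drug (tissue from wild-type animals);
    ``fail_fraction`` of the slices are generated non-viable — low pH, high
    LDH release and a 100x inflated homogenate concentration — so that QC
    exclusion is observable downstream.
    """
    if not (0 <= fail_fraction <= 1):
        raise InvalidInputError("fail_fraction must be within [0, 1]")
    rng = _rng(truth.seed, "slices")
    rows = []
    drugs = sorted({drug for drug, _ in truth.drugs})
    wt = Genotype.C57BL6_WT.value
    n_fail = int(round(fail_fraction * n_slices))
    for drug in drugs:
        g = truth.drugs.get((drug, wt)) or next(
            v for (d, _), v in sorted(truth.drugs.items()) if d == drug
        )
        noise_s = _lognoise(rng, truth.noise.cv_slice, n_slices)
        noise_b = _lognoise(rng, truth.noise.cv_slice, n_slices)
        weights = 0.02 + 0.004 * rng.random(n_slices)  # g, ~300 um slices
        for i in range(n_slices):
            c_buffer = truth.slice_buffer_ng_ml
            a_slice = (g.v_u_brain + truth.v_film) * c_buffer
            failing = i < n_fail
            c_homog = a_slice / truth.slice_dilution * noise_s[i]
            rows.append(
                {
                    "drug": drug,
                    "slice_id": f"{drug}-s{i + 1}",
                    "slice_weight_g": weights[i],
                    "c_buffer_final_ng_ml": c_buffer * noise_b[i],
                    "c_slice_homog_ng_ml": c_homog * (100.0 if failing else 1.0),
                    "slice_dilution": truth.slice_dilution,
                    "end_ph": 7.10 if failing else 7.40,
                    "ldh_release_fraction": 0.60 if failing else 0.05,
                }
            )
    return pd.DataFrame(rows)


def generate_srm(truth: CohortTruth, n_runs: int = 3) -> pd.DataFrame:
    """SRM/MRM transition table (``srm_transitions.csv`` content).

    Probe selectivity: each probe's analyte signal is the sum of its target
    proteins' expression in that strain.  A probe whose summed truth is below
    its LOQ emits low noise-level areas with no retention-time match.
    """
    rng = _rng(truth.seed, "srm")
    rows = []
    area_is_nominal = 1.0e5
    groups = sorted({g for _, g in truth.proteins})
    for probe in truth.probes:
        for group in groups:
            amount_true = sum(
                truth.proteins.get((t, group), 0.0) for t in probe.targets
            )
            loq = truth.loq.get((probe.molecule, group), 0.0)
            detectable = amount_true >= loq and amount_true > 0
            for t in range(1, 5):
                for r in range(1, n_runs + 1):
                    area_is = area_is_nominal * _lognoise(
                        rng, truth.noise.cv_srm, 1
                    )[0]
                    if detectable:
                        amount = amount_true * _lognoise(rng, truth.noise.cv_srm, 1)[0]
                        rt_match = True
                    else:
                        # background chemical noise well under the LOQ
                        amount = (
                            loq / 10.0 * rng.random() if loq > 0 else 0.0
                        )
                        rt_match = False
                    area_analyte = (
                        amount
                        * truth.protein_injected_ug
                        / truth.is_amount_fmol
                        * area_is
                    )
                    rows.append(
                        {
                            "molecule": probe.molecule,
                            "peptide_probe": probe.probe_set.value,
                            "transition_id": f"Q1Q3-{t}",
                            "run_id": f"run{r}",
                            "group": group,
                            "area_analyte": area_analyte,
                            "area_is": area_is,
                            "is_amount_fmol": truth.is_amount_fmol,
                            "protein_injected_ug": truth.protein_injected_ug,
                            "rt_match": rt_match,
                        }
                    )
    return pd.DataFrame(rows)


def generate_all(
    truth: CohortTruth,
    out_dir: str | Path,
    n_per_group: int = 5,
    dialysis_replicates: int = 3,
    n_slices: int = 6,
    fail_fraction: float = 0.0,
) -> dict[str, Path]:
    """Write the four input CSVs plus ``truth.json`` into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "concentrations.csv": generate_cohort(truth, n_per_group),
        "dialysis.csv": generate_dialysis(truth, dialysis_replicates),
        "slices.csv": generate_slices(truth, n_slices, fail_fraction),
        "srm_transitions.csv": generate_srm(truth),
    }
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
        paths[name] = path
    truth_path = out / "truth.json"
    truth_path.write_text(truth.to_json())
    paths["truth.json"] = truth_path
    return paths
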