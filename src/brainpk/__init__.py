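"""brainpk — brain-to-plasma drug partitioning and targeted proteomics.

Computes the total (Kp) and unbound (Kp,uu) brain-to-plasma partition
coefficients with residual-blood correction, processes the supporting
equilibrium-dialysis and brain-slice assays (fu,plasma, Vu,brain) with
viability QC, quantifies transporter protein expression from SRM/MRM
transition tables with ULQ censoring, and simulates complete synthetic
cohorts for parameter-recovery testing.
"""

from importlib import resources as _resources

import pandas as _pd

from .binding import (
    DialysisRecord,
    FuPlasmaResult,
    SliceAssayRecord,
    VuBrainResult,
    compute_fu_plasma,
    compute_vu_brain,
    qc_slice,
)
from .config import RunConfig
from .distribution import (
    ConcentrationRecord,
    DistributionResult,
    Genotype,
    VascularParams,
    analyze_animal,
    compute_kp,
    compute_kpuu,
    correct_residual_blood,
    effective_plasma_space,
    kpuu_table,
)
from .exceptions import (
    AssayFailureError,
    BrainPKError,
    InvalidInputError,
    QCFailureError,
    SchemaError,
)
from .pipeline import PipelineResult, run_pipeline, validate_inputs
from .qtap import (
    ExpressionStatus,
    FoldChange,
    FoldKind,
    ProbeSet,
    ProteinExpression,
    TransitionMeasurement,
    assess_positivity,
    compare_expression_groups,
    compute_loq,
    fold_change,
    quantify_transition,
    summarize_expression,
)
from .report import round_kpuu_table, round_sig
from .simulate import (
    CohortTruth,
    DrugGroupTruth,
    NoiseModel,
    default_truth,
    generate_all,
    generate_cohort,
    generate_dialysis,
    generate_slices,
    generate_srm,
)
from .stats import (
    GroupSummary,
    RatioEntry,
    TTestResult,
    blocker_ratio_table,
    significance_stars,
    summarize_group,
    ttest_unpaired,
)

__version__ = "0.1.0"


def load_partition_inputs() -> _pd.DataFrame:
    """Packaged per-group partitioning constants (Kp, Vu,brain, fu,plasma)
    for the two-strain, four-drug reference scenario."""
    with _resources.files("brainpk.data").joinpath("partition_inputs.csv").open() as fh:
        return _pd.read_csv(fh)
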