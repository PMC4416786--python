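"""Absolute transporter quantification from SRM/MRM transitions with censoring.

Generates a noise-free synthetic transition table for the efflux-pump probes
(human-specific, mouse-specific and common peptides), quantifies each
molecule per strain, and prints the censoring-aware fold differences between
mouse Mdr1a and human MDR1 expression.
"""

import tempfile
from pathlib import Path

from brainpk.config import RunConfig
from brainpk.pipeline import run_pipeline
from brainpk.report import format_expression_cell, format_fold
from brainpk.simulate import NoiseModel, default_truth, generate_all

tmp = Path(tempfile.mkdtemp())
truth = default_truth(seed=1, noise=NoiseModel(0, 0, 0, 0))
paths = generate_all(truth, tmp)
cfg = RunConfig(
    srm_transitions=str(paths["srm_transitions.csv"]),
    loq_table={f"{m}|{g}": v for (m, g), v in truth.loq.items()},
    out_dir=str(tmp / "out"),
)
res = run_pipeline(cfg)

for (molecule, group), expr in sorted(res.expression.items()):
    print(f"{molecule:18s} {group:10s} {format_expression_cell(expr)}")
print()
for fc in res.folds:
    print(f"{fc.numerator} / {fc.denominator}: {format_fold(fc)}-fold")
print()
print(
    "The humanized strain expresses ~63-fold less human MDR1 than wild-type\n"
    "mouse Mdr1a, plus residual Mdr1a (~9-fold below wild type); Mdr1b stays\n"
    "under its limit of quantification in both strains (U.L.Q. cells)."
)
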