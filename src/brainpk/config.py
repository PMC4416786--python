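"""Run configuration with lossless YAML round-tripping."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field

__all__ = ["VascularConfig", "LoqConfig", "QCConfig", "StatsConfig", "RunConfig"]


class VascularConfig(BaseModel):
    """Apparent vascular spaces (ml/g brain) for the residual-blood correction.

    Literature constants, not measured in-study; defaults follow the commonly
    used rat-brain estimates (plasma water 10.3 ul/g, plasma proteins
    8.0 ul/g)."""

    v_water_ml_g: float = 0.0103
    v_protein_ml_g: float = 0.0080


class LoqConfig(BaseModel):
    """Limit-of-quantification rule: k x SD of blank-equivalent amounts."""

    k_noise: float = 3.0
    fallback_fmol_ug: float | None = 0.1  # used when blanks are insufficient


class QCConfig(BaseModel):
    ldh_threshold: float = 0.25
    v_film_ml_g: float = 0.0  # adherent surface-fluid correction for slices


class StatsConfig(BaseModel):
    equal_var: bool = True  # Student's pooled-variance t-test; False = Welch
    alpha: float = 0.05
    alpha_expression: float = 0.01  # proteomics-table significance convention


class RunConfig(BaseModel):
    """Everything a pipeline run needs; round-trips losslessly through YAML."""

    concentrations: str | None = None
    dialysis: str | None = None
    slices: str | None = None
    srm_transitions: str | None = None
    loq_table: dict[str, float] = Field(default_factory=dict)  # "molecule|group"
    vascular: VascularConfig = Field(default_factory=VascularConfig)
    loq: LoqConfig = Field(default_factory=LoqConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
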