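"""Run configuration with schema validation and paper-derived defaults.

Every threshold the pipeline uses is a named, auditable key: the DE
thresholds per compartment (immune 0.25 / 0.1, neuron 0.8 / 0.25), the
adjusted-p cutoff, the minimum-cell and saturation constants of the
communication stage, and the per-injury peak-hypersensitivity timepoints
T_max (zymosan 4 h, incision 24 h, UV burn 48 h).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

VALID_CONDITIONS = {"zymosan", "incision", "uv_burn", "contralateral"}
VALID_TIMEPOINTS = {4, 24, 48}


class RunConfig(BaseModel):
    """Validated configuration for an end-to-end run."""

    out_dir: str = "nimx_run"
    seed: int = 0

    # knowledge-base inputs; all None -> synthetic fixture snapshot
    omnipath: Optional[str] = None
    cpdb: Optional[str] = None
    enzymes: Optional[str] = None
    channels: Optional[str] = None
    sif: Optional[str] = None
    statements: Optional[str] = None
    orthologs: Optional[str] = None

    # expression inputs; None -> synthetic dataset
    expr_dir: Optional[str] = None
    neurons: Optional[str] = None
    neurons_n_cells: Optional[str] = None

    # thresholds
    immune_log2fc_min: float = 0.25
    immune_min_pct: float = 0.10
    neuron_log2fc_min: float = 0.80
    neuron_min_pct: float = 0.25
    alpha: float = 0.05
    min_cells: int = 10
    mito_max: float = 0.05
    kh: float = Field(0.5, gt=0)
    trim: float = Field(0.25, ge=0, lt=0.5)
    n_perm: int = Field(100, ge=20)
    de_min_cells: int = 3

    divenn_cell_type: str = "Cx3cr1hi Macs"
    t_max: dict = Field(default_factory=lambda: {"zymosan": 4, "incision": 24, "uv_burn": 48})

    @field_validator("t_max")
    @classmethod
    def _check_t_max(cls, value: dict) -> dict:
        for cond, tp in value.items():
            if cond not in VALID_CONDITIONS - {"contralateral"}:
                raise ValueError(f"t_max: unknown condition label {cond!r}")
            if int(tp) not in VALID_TIMEPOINTS:
                raise ValueError(f"t_max: unknown timepoint {tp!r} for {cond!r}")
        return {c: int(t) for c, t in value.items()}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True, default_flow_style=False)
        )

    def kb_paths_given(self) -> bool:
        paths = [self.omnipath, self.cpdb, self.enzymes, self.channels, self.sif,
                 self.statements, self.orthologs]
        if any(paths) and not all(paths):
            raise ValueError("either provide all knowledge-base paths or none")
        return all(paths)
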