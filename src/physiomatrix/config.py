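"""Analysis configuration.

A single pydantic model collects every tunable of the pipeline: phase
resolution of the physio-matrix, respiratory peak detection window, GAM
basis dimensions and smoothing policy, plateau detection parameters and
empty-bin handling.  Defaults follow the resolutions used for the clinical
acquisitions this pipeline was designed around (40 respiratory x 10 cardiac
phases, 800 ms belt peak window, 8-point plateau fit at 5% slope).
"""

from __future__ import annotations

import json
import re
from typing import Literal, Optional, Tuple

from pydantic import BaseModel, Field, field_validator


class AnalysisConfig(BaseModel):
    """All pipeline tunables with validated defaults."""

    # phase binning
    n_resp_phases: int = Field(40, ge=1)
    n_cardiac_phases: int = Field(10, ge=1)

    # respiratory onset detection
    belt_window_s: float = Field(0.8, gt=0.0)

    # physio-matrix handling
    empty_bin_policy: Literal["error", "gam-impute"] = "error"
    coverage_warn_fraction: float = Field(0.2, ge=0.0, le=1.0)

    # GAM decomposition
    basis_dim_resp: int = Field(20, ge=4)
    basis_dim_cardiac: int = Field(8, ge=4)
    basis_dim_interaction: Tuple[int, int] = (8, 5)
    smoothing: str = "gcv"  # "gcv" or "fixed:<value>"
    fit_level: Literal["matrix", "samples"] = "matrix"
    weight_by_counts: bool = False

    # resting-state plateau
    plateau_fit_points: int = Field(8, ge=3)
    plateau_slope_fraction: float = Field(0.05, gt=0.0)
    plateau_reference: Literal["pairwise", "global"] = "pairwise"
    plateau_min_run: int = Field(2, ge=1)

    # body surface area indexing (optional)
    bsa_m2: Optional[float] = Field(None, gt=0.0)

    @field_validator("smoothing")
    @classmethod
    def _check_smoothing(cls, v: str) -> str:
        if v == "gcv" or re.fullmatch(r"fixed:[0-9.eE+-]+", v):
            return v
        raise ValueError(
            "smoothing must be 'gcv' or 'fixed:<lambda>', got " + repr(v)
        )

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def fixed_lambda(self) -> Optional[float]:
        """Return the fixed smoothing parameter, or None under GCV."""
        if self.smoothing.startswith("fixed:"):
            return float(self.smoothing.split(":", 1)[1])
        return None
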