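"""Physio-matrix construction and gated volume analysis.

The physio-matrix is an ``n_i x n_j`` grid of flow values indexed by
respiratory phase i (rows, i = 0 at the inspiration-to-expiration
transition) and cardiac phase j (columns, j = 0 at the R-wave).  Every bin
holds the arithmetic mean of the real-time flow samples that fell in that
phase combination.

Net flow volume per cardiac cycle integrates the matrix over both phase
axes and normalizes by the respiratory cycle length:

    V_net = sum_ij P_ij * dt_i * dt_j / (dt_i * n_i) = sum_ij P_ij * dt_j / n_i

where dt_i, dt_j are the respiratory and cardiac phase intervals.
Retrograde volume sums only the negative flow entries in the same
expression.  Exclusive ECG or respiratory gating is simulated by first
collapsing the matrix to its cardiac marginal P^c_j = sum_i P_ij or
respiratory marginal P^r_i = sum_j P_ij and then summing the negative
marginal entries.  Because the marginals are plain sums, the retrograde
marginal terms are rescaled by the same dt_j / n_i factor, so replacing
"negative entries" by "all entries" reproduces V_net exactly in every mode;
fractions are therefore identical whether marginals are defined as sums or
means.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    CoverageWarning,
    EmptyBinError,
    MatrixBuildError,
    ParameterError,
    UndefinedMetricError,
)
from .signals import CycleSegmentation, FlowSampleSeries, PhaseAssignments

GATING_MODES = ("simultaneous", "ecg", "resp")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PhysioMatrix:
    """Bin-averaged flow grid with phase-interval metadata.

    ``values`` holds NaN in empty bins; ``counts`` gives samples per bin.
    ``delta_t_i`` (``delta_t_j``) is the respiratory (cardiac) phase interval,
    i.e. the mean cycle period divided by the number of phases.
    """

    values: np.ndarray
    counts: np.ndarray
    delta_t_i: float
    delta_t_j: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.values.shape != self.counts.shape or self.values.ndim != 2:
            raise ParameterError("values and counts must share a 2-D shape")
        if self.delta_t_i <= 0 or self.delta_t_j <= 0:
            raise ParameterError("phase intervals must be positive")

    @property
    def n_i(self) -> int:
        return self.values.shape[0]

    @property
    def n_j(self) -> int:
        return self.values.shape[1]

    @property
    def empty_mask(self) -> np.ndarray:
        return self.counts == 0

    @property
    def occupancy(self) -> float:
        """Fraction of bins holding at least one sample."""
        return float(np.mean(~self.empty_mask))

    def empty_bins(self):
        return [tuple(ij) for ij in np.argwhere(self.empty_mask)]

    def filled(self, surface: np.ndarray) -> "PhysioMatrix":
        """Return a copy with empty bins imputed from ``surface``."""
        vals = np.where(self.empty_mask, surface, self.values)
        return PhysioMatrix(vals, np.maximum(self.counts, 1), self.delta_t_i, self.delta_t_j)

    # -- serialization ------------------------------------------------------
    def to_csv(self, grid_path, sidecar_path=None) -> None:
        df = pd.DataFrame(
            self.values,
            index=[f"resp_{i}" for i in range(self.n_i)],
            columns=[f"card_{j}" for j in range(self.n_j)],
        )
        df.to_csv(grid_path)
        if sidecar_path is not None:
            meta = {
                "delta_t_i_s": self.delta_t_i,
                "delta_t_j_s": self.delta_t_j,
                "counts": self.counts.tolist(),
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1)


@dataclass(frozen=True)
class GatedMarginals:
    """Cardiac and respiratory marginal sums of the physio-matrix."""

    cardiac_marginal: np.ndarray  # P^c_j = sum_i P_ij, length n_j
    respiratory_marginal: np.ndarray  # P^r_i = sum_j P_ij, length n_i


@dataclass
class VolumeReport:
    """Net and retrograde volumes (ml per cardiac cycle) and fractions (%).

    Retrograde volumes are signed (<= 0); fractions are reported as positive
    magnitudes in ``fractions_pct`` and signed in the JSON export, since both
    conventions are in clinical use.  When a body surface area is given the
    indexed volumes (ml/m2) are included as well.
    """

    net_ml: float
    retro_ml: Dict[str, float]
    fractions_pct: Dict[str, float]
    bsa_m2: Optional[float] = None

    def indexed(self, key: str) -> Optional[float]:
        if self.bsa_m2 is None:
            return None
        value = self.net_ml if key == "net" else self.retro_ml[key]
        return value / self.bsa_m2

    def to_dict(self) -> dict:
        out = {"net_ml": self.net_ml, "bsa_m2": self.bsa_m2}
        for mode in GATING_MODES:
            out[f"retro_ml_{mode}"] = self.retro_ml[mode]
            out[f"retro_pct_{mode}"] = -self.fractions_pct[mode]  # signed
        if self.bsa_m2 is not None:
            out["net_ml_per_m2"] = self.net_ml / self.bsa_m2
            for mode in GATING_MODES:
                out[f"retro_ml_per_m2_{mode}"] = self.retro_ml[mode] / self.bsa_m2
        return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_matrix(
    samples: FlowSampleSeries,
    assignments: PhaseAssignments,
    seg: CycleSegmentation,
    coverage_warn_fraction: float = 0.2,
) -> PhysioMatrix:
    """Average phase-indexed samples into the physio-matrix.

    Bins that receive more than one flow measurement hold the arithmetic
    mean of their samples; bins that receive none are NaN with count 0.
    """
    n_i, n_j = assignments.n_i, assignments.n_j
    valid = assignments.valid
    if not np.any(valid):
        raise MatrixBuildError("every sample fell outside the complete cycles")
    ri = assignments.resp_index[valid]
    cj = assignments.cardiac_index[valid]
    flows = samples.flows[valid]

    sums = np.zeros((n_i, n_j))
    counts = np.zeros((n_i, n_j), dtype=int)
    np.add.at(sums, (ri, cj), flows)
    np.add.at(counts, (ri, cj), 1)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    empty_frac = 1.0 - np.mean(counts > 0)
    if empty_frac > coverage_warn_fraction:
        warnings.warn(
            f"{empty_frac:.1%} of physio-matrix bins are empty "
            f"(limit {coverage_warn_fraction:.0%}); consider a longer "
            f"acquisition or fewer phases",
            CoverageWarning,
            stacklevel=2,
        )
    return PhysioMatrix(
        values,
        counts,
        delta_t_i=seg.mean_respiratory_period / n_i,
        delta_t_j=seg.mean_cardiac_period / n_j,
    )


def _require_full(M: PhysioMatrix) -> None:
    if np.any(M.empty_mask):
        raise EmptyBinError(M.empty_bins())


def marginals(M: PhysioMatrix) -> GatedMarginals:
    """Marginal sums simulating exclusive ECG / respiratory gating."""
    _require_full(M)
    return GatedMarginals(
        cardiac_marginal=M.values.sum(axis=0),
        respiratory_marginal=M.values.sum(axis=1),
    )


def net_flow_volume(M: PhysioMatrix, bsa_m2: Optional[float] = None) -> float:
    """Net flow volume per cardiac cycle (ml, or ml/m2 when BSA given)."""
    _require_full(M)
    v = float(M.values.sum() * M.delta_t_j / M.n_i)
    return v / bsa_m2 if bsa_m2 else v


def retrograde_volume(
    M: PhysioMatrix, mode: str = "simultaneous", bsa_m2: Optional[float] = None
) -> float:
    """Retrograde flow volume (<= 0) per cardiac cycle under a gating mode.

    ``simultaneous`` sums the matrix's negative entries; ``ecg`` / ``resp``
    first collapse to the cardiac / respiratory marginal and then sum that
    marginal's negative entries, emulating what an exclusively gated
    acquisition would measure.
    """
    if mode not in GATING_MODES:
        raise ParameterError(f"unknown gating mode {mode!r}; use {GATING_MODES}")
    _require_full(M)
    if mode == "simultaneous":
        entries = M.values[M.values < 0]
    elif mode == "ecg":
        pc = M.values.sum(axis=0)
        entries = pc[pc < 0]
    else:
        pr = M.values.sum(axis=1)
        entries = pr[pr < 0]
    v = float(entries.sum() * M.delta_t_j / M.n_i)
    return v / bsa_m2 if bsa_m2 else v


def retrograde_fraction(retro_ml: float, net_ml: float) -> float:
    """Retrograde volume as a positive percentage of net volume."""
    if net_ml == 0:
        raise UndefinedMetricError("retrograde fraction undefined for zero net volume")
    return 100.0 * abs(retro_ml) / net_ml


def volume_report(M: PhysioMatrix, bsa_m2: Optional[float] = None) -> VolumeReport:
    """Net volume plus retrograde volume and fraction for all gating modes."""
    net = net_flow_volume(M)
    retro = {mode: retrograde_volume(M, mode) for mode in GATING_MODES}
    frac = {mode: retrograde_fraction(retro[mode], net) for mode in GATING_MODES}
    return VolumeReport(net_ml=net, retro_ml=retro, fractions_pct=frac, bsa_m2=bsa_m2)


def respiratory_rebin_error(
    samples: FlowSampleSeries,
    assignments: PhaseAssignments,
    phase_counts: Sequence[int],
    reference: int = 50,
) -> Dict[int, float]:
    """Amplitude error of the respiratory flow waveform at coarser binnings.

    The respiratory waveform at resolution n is the mean flow per respiratory
    phase bin (averaging over the cardiac cycle), rebuilt from the raw samples
    via their continuous respiratory phase fraction.  The error at n is
    ``1 - A(n) / A(reference)`` with A the max-min waveform amplitude.
    """
    if reference < max(phase_counts):
        raise ParameterError("reference resolution must be >= every phase count")
    valid = assignments.valid
    frac = assignments.resp_frac[valid]
    flows = samples.flows[valid]

    def waveform(n: int) -> np.ndarray:
        idx = np.minimum((n * frac).astype(int), n - 1)
        sums = np.bincount(idx, weights=flows, minlength=n)
        counts = np.bincount(idx, minlength=n)
        if n == reference and np.any(counts == 0):
            raise CoverageError(
                f"empty respiratory bins at reference resolution {reference}"
            )
        with np.errstate(invalid="ignore"):
            w = sums / counts
        return w[counts > 0]

    ref_wave = waveform(reference)
    a_ref = float(ref_wave.max() - ref_wave.min())
    errors: Dict[int, float] = {}
    for n in phase_counts:
        w = waveform(int(n))
        a = float(w.max() - w.min())
        errors[int(n)] = 1.0 - a / a_ref if a_ref != 0 else 0.0
    return errors
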