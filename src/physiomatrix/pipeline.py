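"""End-to-end per-subject analysis.

Chains the pipeline in acquisition order: synchronize the flow series onto
the monitoring clock, detect respiratory onsets, segment both cycle types,
assign phases, build the physio-matrix, compute gated volumes, fit the
functional-ANOVA decomposition, derive pulsatility metrics, and attempt the
resting-state partition of net flow.  The result is a flat, JSON-serializable
:class:`SubjectSummary`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import AnalysisConfig
from .errors import PhysioMatrixError
from .gam import GAMDecomposition, fit_gam, pulsatility_metrics
from .matrix import (
    PhysioMatrix,
    build_matrix,
    net_flow_volume,
    retrograde_fraction,
    retrograde_volume,
    volume_report,
)
from .resting import detect_plateau, partition_net_flow
from .signals import (
    FlowSampleSeries,
    PhysioRecord,
    assign_phases,
    detect_respiratory_onsets,
    segment_cycles,
    synchronize,
)

log = logging.getLogger("physiomatrix")


@dataclass
class SubjectSummary:
    """Per-subject results: volumes, amplitudes, significance, plateau."""

    volumes: dict
    pulsatility: dict
    p_values: dict
    plateau: dict
    counts: dict

    def to_dict(self) -> dict:
        return {
            "volumes": self.volumes,
            "pulsatility": self.pulsatility,
            "p_values": self.p_values,
            "plateau": self.plateau,
            "counts": self.counts,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SubjectSummary":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            volumes=d["volumes"],
            pulsatility=d["pulsatility"],
            p_values=d["p_values"],
            plateau=d["plateau"],
            counts=d["counts"],
        )


@dataclass
class PipelineResult:
    """Full intermediate state of one pipeline run (not serialized)."""

    summary: SubjectSummary
    matrix: PhysioMatrix
    fit: GAMDecomposition
    assignments: object
    segmentation: object


class PipelineStageError(PhysioMatrixError):
    def __init__(self, stage, exc):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")


def run_pipeline(
    samples: FlowSampleSeries,
    record: PhysioRecord,
    config: Optional[AnalysisConfig] = None,
) -> PipelineResult:
    """Run the complete per-subject analysis; deterministic given inputs."""
    config = config or AnalysisConfig()
    stage = "synchronize"
    try:
        synced = synchronize(record, samples)
        log.info("synchronized %d samples, scan onset %.3f s",
                 len(synced.times), record.scan_onset)

        stage = "detect_respiratory_onsets"
        onsets = detect_respiratory_onsets(record, config.belt_window_s)
        log.info("detected %d respiratory onsets (window %.3f s)",
                 len(onsets), config.belt_window_s)

        stage = "segment_cycles"
        span = (float(synced.times[0]), float(synced.times[-1]) + synced.dt)
        seg = segment_cycles(onsets, record.r_wave_times, span)
        log.info("segmented %d cardiac / %d respiratory cycles "
                 "(mean periods %.3f / %.3f s)",
                 len(seg.cardiac_cycles), len(seg.respiratory_cycles),
                 seg.mean_cardiac_period, seg.mean_respiratory_period)

        stage = "assign_phases"
        assignments = assign_phases(synced, seg, config.n_resp_phases,
                                    config.n_cardiac_phases)
        log.info("assigned phases; invalid fraction %.2f%%",
                 100 * assignments.invalid_fraction)

        stage = "build_matrix"
        M = build_matrix(synced, assignments, seg,
                         config.coverage_warn_fraction)
        log.info("physio-matrix %dx%d, occupancy %.1f%%",
                 M.n_i, M.n_j, 100 * M.occupancy)

        stage = "fit_gam"
        fit = fit_gam(M, config, samples=synced, assignments=assignments)
        log.info("GAM fit: Q=%.2f ml/s, edf=%s", fit.Q,
                 {k: round(v, 2) for k, v in fit.edf.items()})

        stage = "volumes"
        if np.any(M.empty_mask):
            if config.empty_bin_policy == "gam-impute":
                M_full = M.filled(fit.surface)
            else:
                M_full = M  # net_flow_volume will raise EmptyBinError
        else:
            M_full = M
        volumes = volume_report(M_full, config.bsa_m2)

        stage = "pulsatility"
        pulsatility = pulsatility_metrics(fit)

        stage = "resting_state"
        plateau = detect_plateau(
            fit.Q + fit.R,
            M.delta_t_i,
            config.plateau_fit_points,
            config.plateau_slope_fraction,
            config.plateau_reference,
            config.plateau_min_run,
        )
        plateau = partition_net_flow(fit, plateau)
        if plateau.found:
            log.info("plateau at phases %s, respiratory share %.1f%%",
                     plateau.phase_range.tolist(),
                     plateau.respiratory_percent_of_net or 0.0)
        else:
            log.info("no respiratory resting-state plateau located")
    except PhysioMatrixError as exc:
        raise PipelineStageError(stage, exc) from exc

    summary = SubjectSummary(
        volumes=volumes.to_dict(),
        pulsatility=pulsatility.to_dict(),
        p_values=dict(fit.p_values),
        plateau=plateau.to_dict(),
        counts={
            "n_samples": len(samples.times),
            "n_valid": int(np.sum(assignments.valid)),
            "invalid_fraction": assignments.invalid_fraction,
            "occupancy": M.occupancy,
            "n_cardiac_cycles": len(seg.cardiac_cycles),
            "n_respiratory_cycles": len(seg.respiratory_cycles),
        },
    )
    return PipelineResult(summary=summary, matrix=M, fit=fit,
                          assignments=assignments, segmentation=seg)


def analyze_files(flow_csv, pmu_csv, events_csv,
                  config: Optional[AnalysisConfig] = None) -> PipelineResult:
    """File-based entry point used by the command line interface."""
    samples = FlowSampleSeries.from_csv(flow_csv)
    record = PhysioRecord.from_csv(pmu_csv, events_csv)
    return run_pipeline(samples, record, config)
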