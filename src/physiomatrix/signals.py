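"""Physiological signal handling.

Parses and synchronizes the real-time flow series with the scanner's
physiological monitoring record (respiratory belt curve sampled at 2 ms plus
R-wave event times), detects respiratory cycle onsets as belt-curve maxima
(the inspiration-to-expiration transition), segments both cycle types, and
assigns every flow sample a (respiratory, cardiac) phase index pair.

Phase convention: within each individual cycle the phase is the elapsed-time
fraction of *that* cycle, discretized into equidistant bins, so heart- and
breathing-rate variability does not smear the phase axes.  Samples that fall
before the first or after the last complete cycle of either kind are flagged
invalid and dropped from all downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d

from .errors import (
    InputError,
    ParameterError,
    SegmentationError,
    SynchronizationWarning,
)

_TIME_TOL_S = 1e-6  # tolerance on uniform sample spacing


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowSampleSeries:
    """Timestamped flow values from a real-time acquisition.

    times
        Seconds from scan onset, uniformly spaced (dynamic-scan resolution,
        typically 48 ms).
    flows
        Signed flow in ml/s; positive is antegrade venous return, negative
        is retrograde (liver-ward) flow.
    """

    times: np.ndarray
    flows: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        flows = np.asarray(self.flows, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "flows", flows)
        if times.ndim != 1 or flows.ndim != 1 or len(times) != len(flows):
            raise InputError("times and flows must be 1-D and equally long")
        if len(times) < 2:
            raise InputError("a flow series needs at least 2 samples")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise InputError("sample times must be strictly increasing")
        if np.ptp(steps) > _TIME_TOL_S:
            raise InputError(
                f"sample spacing not uniform within {_TIME_TOL_S} s "
                f"(spread {np.ptp(steps):.3g} s)"
            )

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return float(np.mean(np.diff(self.times)))

    def shifted(self, offset: float) -> "FlowSampleSeries":
        return FlowSampleSeries(self.times + offset, self.flows)

    @classmethod
    def from_csv(cls, path) -> "FlowSampleSeries":
        df = pd.read_csv(path)
        try:
            return cls(df["time_s"].to_numpy(), df["flow_ml_per_s"].to_numpy())
        except KeyError as exc:
            raise InputError(f"flow CSV missing column {exc}") from exc

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "flow_ml_per_s": self.flows}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class PhysioRecord:
    """Respiratory belt curve, R-wave events and the scan-onset marker.

    All times are seconds on the monitoring unit's clock.  The belt is
    uniformly sampled (2 ms for the scanner this pipeline was built for);
    R-wave peak times are taken as given events, no ECG waveform processing
    happens here.
    """

    belt_times: np.ndarray
    belt_values: np.ndarray
    r_wave_times: np.ndarray
    scan_onset: float

    def __post_init__(self):
        bt = np.asarray(self.belt_times, dtype=float)
        bv = np.asarray(self.belt_values, dtype=float)
        rw = np.asarray(self.r_wave_times, dtype=float)
        object.__setattr__(self, "belt_times", bt)
        object.__setattr__(self, "belt_values", bv)
        object.__setattr__(self, "r_wave_times", rw)
        if bt.ndim != 1 or len(bt) != len(bv):
            raise InputError("belt_times and belt_values must match in length")
        if len(bt) >= 2:
            steps = np.diff(bt)
            if np.any(steps <= 0) or np.ptp(steps) > _TIME_TOL_S:
                raise InputError("belt record must be uniformly sampled")
        if len(rw) >= 2 and np.any(np.diff(rw) <= 0):
            raise InputError("R-wave times must be strictly increasing")
        if len(bt) and not (bt[0] <= self.scan_onset <= bt[-1]):
            raise InputError("scan onset lies outside the belt record span")

    @property
    def belt_dt(self) -> float:
        return float(np.mean(np.diff(self.belt_times)))

    @property
    def span(self) -> tuple:
        return float(self.belt_times[0]), float(self.belt_times[-1])

    @classmethod
    def from_csv(cls, pmu_path, events_path) -> "PhysioRecord":
        pmu = pd.read_csv(pmu_path)
        ev = pd.read_csv(events_path)
        try:
            bt = pmu["time_s"].to_numpy()
            bv = pmu["belt_au"].to_numpy()
            kinds = ev["event"].astype(str)
            times = ev["time_s"].to_numpy(dtype=float)
        except KeyError as exc:
            raise InputError(f"PMU/events CSV missing column {exc}") from exc
        rwaves = np.sort(times[kinds == "RWAVE"])
        onsets = times[kinds == "SCAN_ONSET"]
        if len(onsets) != 1:
            raise InputError(
                f"expected exactly one SCAN_ONSET event, found {len(onsets)}"
            )
        return cls(bt, bv, rwaves, float(onsets[0]))

    def to_csv(self, pmu_path, events_path) -> None:
        pd.DataFrame({"time_s": self.belt_times, "belt_au": self.belt_values}).to_csv(
            pmu_path, index=False
        )
        ev = pd.DataFrame(
            {
                "time_s": np.concatenate([[self.scan_onset], self.r_wave_times]),
                "event": ["SCAN_ONSET"] + ["RWAVE"] * len(self.r_wave_times),
            }
        )
        ev.to_csv(events_path, index=False)


@dataclass(frozen=True)
class CycleSegmentation:
    """Contiguous cardiac and respiratory cycles on the record clock.

    Each cycle is a half-open ``[start, end)`` interval; cardiac cycles start
    at an R-wave peak, respiratory cycles at the inspiration-to-expiration
    transition (belt maximum).
    """

    cardiac_cycles: np.ndarray  # (n, 2)
    respiratory_cycles: np.ndarray  # (m, 2)

    def __post_init__(self):
        for name in ("cardiac_cycles", "respiratory_cycles"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(-1, 2)
            object.__setattr__(self, name, arr)
            if len(arr):
                if np.any(arr[:, 1] <= arr[:, 0]):
                    raise SegmentationError(f"{name}: non-positive period")
                if len(arr) > 1 and not np.allclose(
                    arr[:-1, 1], arr[1:, 0], rtol=0, atol=_TIME_TOL_S
                ):
                    raise SegmentationError(f"{name}: cycles not contiguous")

    @property
    def mean_cardiac_period(self) -> float:
        return float(np.mean(np.diff(self.cardiac_cycles, axis=1)))

    @property
    def mean_respiratory_period(self) -> float:
        return float(np.mean(np.diff(self.respiratory_cycles, axis=1)))


@dataclass
class PhaseAssignments:
    """Vectorized per-sample phase assignment.

    ``resp_index``/``cardiac_index`` are bin indices in ``[0, n)``;
    ``resp_frac``/``cardiac_frac`` are the continuous elapsed-time fractions
    of the enclosing cycle; ``valid`` is False for samples outside any
    complete cycle (their indices are set to -1).
    """

    resp_index: np.ndarray
    cardiac_index: np.ndarray
    resp_frac: np.ndarray
    cardiac_frac: np.ndarray
    valid: np.ndarray
    n_i: int
    n_j: int

    @property
    def invalid_fraction(self) -> float:
        return float(1.0 - np.mean(self.valid))

    def __len__(self) -> int:
        return len(self.valid)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def detect_respiratory_onsets(
    record: PhysioRecord, window: float = 0.8
) -> np.ndarray:
    """Detect respiratory cycle onsets as local maxima of the belt curve.

    A belt sample is an onset when it is the maximum of the centered sliding
    window of the given length (default 800 ms, long enough to extend beyond
    plateaus at the peak yet shorter than any respiratory cycle).  Runs of
    equal-valued window maxima (plateaus) are resolved to the plateau
    midpoint.  Returns onset times sorted ascending.
    """
    if len(record.belt_times) == 0:
        raise InputError("belt record is empty")
    if window <= 0:
        raise ParameterError("window must be positive")
    lo, hi = record.span
    if window >= hi - lo:
        raise ParameterError(
            f"window {window} s must be shorter than the record span "
            f"{hi - lo:.3f} s"
        )

    dt = record.belt_dt
    half = max(1, int(round(0.5 * window / dt)))
    size = 2 * half + 1
    values = record.belt_values
    wmax = maximum_filter1d(values, size=size, mode="nearest")
    is_max = values >= wmax
    # ignore candidates whose window sticks out of the record
    is_max[:half] = False
    is_max[len(values) - half:] = False

    onsets: List[float] = []
    idx = np.flatnonzero(is_max)
    if len(idx) == 0:
        return np.array([])
    # group contiguous candidate runs with equal value -> plateau midpoint
    run_start = idx[0]
    prev = idx[0]
    for k in idx[1:]:
        contiguous = k == prev + 1 and values[k] == values[prev]
        if not contiguous:
            mid = (run_start + prev) // 2
            onsets.append(record.belt_times[mid])
            run_start = k
        prev = k
    mid = (run_start + prev) // 2
    onsets.append(record.belt_times[mid])
    return np.array(sorted(onsets))


def segment_cycles(
    onsets: Sequence[float],
    r_waves: Sequence[float],
    span: tuple,
) -> CycleSegmentation:
    """Pair consecutive events into cycles, trimmed to the acquisition span.

    Only events inside ``span = [start, end)`` contribute; partial cycles at
    the boundary are excluded, so samples outside all complete cycles will be
    flagged invalid downstream.
    """
    start, end = span

    def _inside(events, kind):
        ev = np.asarray(events, dtype=float)
        ev = ev[(ev >= start) & (ev < end)]
        if len(ev) < 2:
            raise SegmentationError(
                f"need at least 2 {kind} events inside span [{start}, {end}), "
                f"found {len(ev)}"
            )
        return np.sort(ev)

    rw = _inside(r_waves, "R-wave")
    on = _inside(onsets, "respiratory-onset")
    cardiac = np.column_stack([rw[:-1], rw[1:]])
    resp = np.column_stack([on[:-1], on[1:]])
    return CycleSegmentation(cardiac, resp)


def _locate(times: np.ndarray, cycles: np.ndarray, n_bins: int):
    """Fractional position and bin index of each time in its cycle."""
    starts = cycles[:, 0]
    ends = cycles[:, 1]
    pos = np.searchsorted(starts, times, side="right") - 1
    inside = (pos >= 0) & (times < ends[np.clip(pos, 0, len(ends) - 1)])
    pos_c = np.clip(pos, 0, len(starts) - 1)
    frac = (times - starts[pos_c]) / (ends[pos_c] - starts[pos_c])
    frac = np.clip(frac, 0.0, np.nextafter(1.0, 0.0))
    idx = np.minimum((n_bins * frac).astype(int), n_bins - 1)
    return frac, idx, inside


def assign_phases(
    samples: FlowSampleSeries,
    seg: CycleSegmentation,
    n_i: int = 40,
    n_j: int = 10,
) -> PhaseAssignments:
    """Assign each flow sample a (respiratory, cardiac) phase index pair.

    For a sample at time t inside cardiac cycle [a, b) the cardiac index is
    ``floor(n_j * (t - a) / (b - a))`` clamped to ``n_j - 1``; the respiratory
    index is computed analogously from the enclosing respiratory cycle.
    Samples outside any complete cycle of either kind are flagged invalid.
    """
    if n_i < 1 or n_j < 1:
        raise ParameterError("phase counts must be at least 1")
    t = samples.times
    rfrac, ridx, rin = _locate(t, seg.respiratory_cycles, n_i)
    cfrac, cidx, cin = _locate(t, seg.cardiac_cycles, n_j)
    valid = rin & cin
    ridx = np.where(valid, ridx, -1)
    cidx = np.where(valid, cidx, -1)
    return PhaseAssignments(
        resp_index=ridx,
        cardiac_index=cidx,
        resp_frac=rfrac,
        cardiac_frac=cfrac,
        valid=valid,
        n_i=n_i,
        n_j=n_j,
    )


def synchronize(record: PhysioRecord, samples: FlowSampleSeries) -> FlowSampleSeries:
    """Shift sample times onto the monitoring-unit clock via the scan onset."""
    shifted = samples.shifted(record.scan_onset)
    lo, hi = record.span
    outside = (shifted.times < lo) | (shifted.times > hi)
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} synchronized samples fall outside the "
            f"belt record span and will be flagged invalid",
            SynchronizationWarning,
            stacklevel=2,
        )
    return shifted
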