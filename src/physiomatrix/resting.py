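"""Respiratory resting-state plateau detection and net-flow partition.

During the respiratory resting state the intrathoracic pressure is
atmospheric, so the cardiac-phase-averaged flow over that plateau estimates
the purely cardiac contribution to net venous return; the respiratory
contribution is the remainder Q - cardiac.  The plateau is searched on the
cardiac-averaged respiratory waveform Q + R_i from the functional-ANOVA fit:
for every cyclic window of ``fit_points`` consecutive phases a least-squares
slope is computed, and window centers whose absolute slope stays below
``slope_fraction`` of a reference slope qualify.  The reference slope is the
mean over adjacent local-extremum pairs of |flow difference| / |time
separation| (a "global" variant, amplitude over mean extremum spacing, is
available).  The plateau is the longest contiguous cyclic run of qualifying
centers.

Waveforms with no local extrema (constant flow) leave the reference
undefined; the full phase range is then returned with a degenerate-reference
flag.  Subjects whose waveform nowhere flattens below the threshold get
``found = False`` and the partition is skipped - respiration-to-net-flow
contributions cannot be determined for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ParameterError
from .gam import GAMDecomposition


@dataclass
class PlateauResult:
    """Detected plateau and the net-flow partition derived from it."""

    found: bool
    phase_range: np.ndarray  # respiratory phase indices of the plateau
    plateau_flow: Optional[float]  # ml/s, cardiac-phase-averaged
    degenerate_reference: bool = False
    cardiac_net_contribution: Optional[float] = None
    respiratory_net_contribution: Optional[float] = None
    respiratory_percent_of_net: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "plateau_found": self.found,
            "plateau_phase_range": np.asarray(self.phase_range).tolist(),
            "plateau_flow_ml_s": self.plateau_flow,
            "degenerate_reference": self.degenerate_reference,
            "cardiac_net_contribution_ml_s": self.cardiac_net_contribution,
            "respiratory_net_contribution_ml_s": self.respiratory_net_contribution,
            "respiratory_percent_of_net": self.respiratory_percent_of_net,
        }


def _cyclic_local_extrema(w: np.ndarray) -> np.ndarray:
    """Indices of strict local extrema of a cyclic sequence.

    Flat stretches are handled by carrying the last non-zero slope sign
    forward, so a plateau bounded by a rise and a fall counts once.
    """
    n = len(w)
    d = np.roll(w, -1) - w  # d[k] = w[k+1] - w[k] (cyclic)
    signs = np.sign(d)
    # forward-fill zero signs cyclically
    nz = np.flatnonzero(signs)
    if len(nz) == 0:
        return np.array([], dtype=int)
    filled = signs.copy()
    last = signs[nz[-1]]
    for k in range(n):
        if filled[k] == 0:
            filled[k] = last
        else:
            last = filled[k]
    prev = np.roll(filled, 1)
    return np.flatnonzero(prev != filled)


def detect_plateau(
    resp_waveform: np.ndarray,
    delta_t_i: float,
    fit_points: int = 8,
    slope_fraction: float = 0.05,
    reference: str = "pairwise",
    min_run: int = 2,
) -> PlateauResult:
    """Locate the respiratory resting-state plateau on a cyclic waveform.

    ``min_run`` is the minimum number of consecutive qualifying window
    positions for a plateau to count: the least-squares slope also vanishes
    in the single window centered on a smooth waveform extremum, and such an
    isolated zero-slope point is a turning point, not a resting state.
    """
    w = np.asarray(resp_waveform, dtype=float)
    n = len(w)
    if fit_points > n:
        raise ParameterError(
            f"fit_points {fit_points} exceeds the waveform length {n}"
        )
    if reference not in ("pairwise", "global"):
        raise ParameterError("reference must be 'pairwise' or 'global'")

    ext = _cyclic_local_extrema(w)
    if len(ext) == 0:
        return PlateauResult(
            found=True,
            phase_range=np.arange(n),
            plateau_flow=float(np.mean(w)),
            degenerate_reference=True,
        )

    # reference slope from adjacent extremum pairs (cyclic neighbours)
    nxt = np.roll(ext, -1)
    dflow = np.abs(w[nxt] - w[ext])
    dtime = ((nxt - ext) % n) * delta_t_i
    dtime[dtime == 0] = n * delta_t_i
    if reference == "pairwise":
        ref_slope = float(np.mean(dflow / dtime))
    else:
        ref_slope = float((w.max() - w.min()) / np.mean(dtime))
    if ref_slope == 0:
        return PlateauResult(
            found=True,
            phase_range=np.arange(n),
            plateau_flow=float(np.mean(w)),
            degenerate_reference=True,
        )

    # least-squares slope of every cyclic window of fit_points phases
    x = (np.arange(fit_points) - (fit_points - 1) / 2.0) * delta_t_i
    denom = float(np.sum(x * x))
    centers = np.empty(n, dtype=int)
    slopes = np.empty(n)
    for s in range(n):
        idx = (s + np.arange(fit_points)) % n
        slopes[s] = float(np.dot(x, w[idx])) / denom
        centers[s] = (s + fit_points // 2) % n
    qualifies = np.abs(slopes) < slope_fraction * ref_slope

    # longest contiguous cyclic run of qualifying window starts
    q2 = np.concatenate([qualifies, qualifies])
    best_len, best_start, run = 0, 0, 0
    for k in range(2 * n):
        if q2[k]:
            run += 1
            if run > best_len:
                best_len, best_start = run, k - run + 1
        else:
            run = 0
    best_len = min(best_len, n)
    if best_len < min_run:
        return PlateauResult(found=False, phase_range=np.array([], dtype=int),
                             plateau_flow=None)
    starts = (best_start + np.arange(best_len)) % n
    phase_range = np.unique(centers[starts])
    # restore cyclic ordering of the run's centers
    first = centers[starts[0]]
    phase_range = (first + np.arange(len(phase_range))) % n
    return PlateauResult(
        found=True,
        phase_range=phase_range,
        plateau_flow=float(np.mean(w[phase_range])),
    )


def partition_net_flow(
    fit: GAMDecomposition, plateau: PlateauResult
) -> PlateauResult:
    """Split net flow Q into cardiac and respiratory contributions.

    The cardiac contribution is the cardiac-phase-averaged flow (Q + R_i)
    averaged over the plateau phases; the respiratory contribution is the
    remainder, so the two always sum to Q exactly.
    """
    if not plateau.found:
        return plateau
    waveform = fit.Q + fit.R
    cardiac = float(np.mean(waveform[plateau.phase_range]))
    respiratory = fit.Q - cardiac
    percent = 100.0 * respiratory / fit.Q if fit.Q != 0 else None
    return replace(
        plateau,
        plateau_flow=cardiac,
        cardiac_net_contribution=cardiac,
        respiratory_net_contribution=respiratory,
        respiratory_percent_of_net=percent,
    )
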