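"""Synthetic physiological subjects with known ground truth.

Generates the exact statistical structure the analysis assumes: a flow
surface Q + R(phi_r) + E(phi_c) + I(phi_r, phi_c) sampled at the real-time
acquisition rate (48 ms, 8000 dynamics by default) under heart- and
breathing-rate jitter, plus the matching monitoring record (2 ms belt curve
whose maxima mark the respiratory onsets, R-wave events, scan-onset marker)
and additive Gaussian noise.

Two presets encode the two circulation types studied:

``fontan``
    Respiration-dominated venous return: a deep, narrow flow downdip at the
    beginning of expiration (retrograde across the whole cardiac cycle), an
    exactly flat resting plateau, and a narrow inspiratory peak (15% of the
    respiratory cycle).  Cardiac pulsatility is a smooth low-amplitude wave.
``normal``
    Cardiac-dominated triphasic venous return: two antegrade peaks (atrial
    and ventricular filling) and a downward deflection at atrial contraction
    deep enough to be retrograde across the whole respiratory cycle, with a
    smooth plateau-free respiratory wave.

The waveform shapes are stylized so that the gating signatures are
unambiguous: in the ``fontan`` preset every negative flow value lies at
early-expiration respiratory phases (so only respiratory gating can see the
retrograde flow), in the ``normal`` preset every negative value lies at the
atrial-contraction cardiac phase (so only ECG gating can).  Amplitudes,
rates and net flow levels default to the cohort means of the clinical study
this pipeline mirrors.

Components are built from raised-cosine bumps and sinusoids and centered
analytically, so R and E integrate to exactly zero over one period and the
separable interaction is doubly centered - the same identifiability
constraints the functional-ANOVA fit enforces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional

import numpy as np

from .errors import ParameterError
from .signals import FlowSampleSeries, PhysioRecord

_FINE = np.linspace(0.0, 1.0, 4096, endpoint=False) + 0.5 / 4096


def _raised_cosine(phi: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-height periodic raised-cosine bump of the given full width."""
    u = ((np.asarray(phi) - center + 0.5) % 1.0) - 0.5
    out = np.zeros_like(u, dtype=float)
    m = np.abs(u) < width / 2.0
    out[m] = 0.5 * (1.0 + np.cos(2.0 * np.pi * u[m] / width))
    return out


class _Shape:
    """Zero-mean periodic waveform scaled to a prescribed max-min amplitude.

    ``bumps`` is a list of (sign*height, center, width) raised cosines whose
    mean is the analytic sum of height*width/2; ``harmonics`` is a list of
    (amp, k, phase) sine terms, mean zero by construction.
    """

    def __init__(self, bumps=(), harmonics=(), amplitude=1.0):
        self.bumps = list(bumps)
        self.harmonics = list(harmonics)
        raw_fine = self._raw(_FINE)
        span = float(raw_fine.max() - raw_fine.min())
        if span <= 0:
            raise ParameterError("waveform shape must be non-constant")
        self.scale = amplitude / span
        self.offset = sum(h * w / 2.0 for h, _, w in self.bumps)
        self.amplitude = amplitude

    def _raw(self, phi):
        phi = np.asarray(phi, dtype=float)
        out = np.zeros_like(phi)
        for h, c, w in self.bumps:
            out += h * _raised_cosine(phi, c, w)
        for a, k, p in self.harmonics:
            out += a * np.sin(2.0 * np.pi * k * phi + p)
        return out

    def __call__(self, phi):
        return self.scale * (self._raw(phi) - self.offset)

    def normalized(self, phi):
        """Shape rescaled to unit maximum absolute value (for interactions)."""
        vals = self(_FINE)
        return self(phi) / float(np.max(np.abs(vals)))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESETS: Dict[str, dict] = {
    "fontan": {
        "heart_rate": 80.1,
        "resp_rate": 21.8,
        "cardiac_amplitude": 20.7,
        "respiratory_amplitude": 52.1,
        "interaction_amplitude": 11.8,
        "Q": 21.6,
        "bsa": 1.1,
        "noise_sd": 5.0,
        "jitter_cv": 0.05,
        "n_samples": 8000,
        "sample_dt": 0.048,
        "resp_shape": {
            "bumps": [(-1.0, 0.10, 0.20), (0.2, 0.85, 0.15)],
            "harmonics": [],
        },
        "cardiac_shape": {
            "bumps": [],
            "harmonics": [(1.0, 1, -0.5), (0.25, 2, 0.8)],
        },
    },
    "normal": {
        "heart_rate": 78.9,
        "resp_rate": 17.9,
        "cardiac_amplitude": 79.3,
        "respiratory_amplitude": 26.4,
        "interaction_amplitude": 36.1,
        "Q": 35.1,
        "bsa": 1.4,
        "noise_sd": 5.0,
        "jitter_cv": 0.05,
        "n_samples": 8000,
        "sample_dt": 0.048,
        "resp_shape": {
            "bumps": [],
            "harmonics": [(1.0, 1, -1.95), (0.15, 2, 0.4)],
        },
        "cardiac_shape": {
            "bumps": [(0.45, 0.15, 0.20), (0.45, 0.55, 0.20), (-1.0, 0.87, 0.24)],
            "harmonics": [],
        },
    },
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SubjectTruth:
    """Ground-truth generative parameters and component waveforms."""

    preset: str
    Q_true: float
    heart_rate: float  # beats per minute
    resp_rate: float  # breaths per minute
    cardiac_amplitude: float  # ml/s, max-min of E_true
    respiratory_amplitude: float  # ml/s, max-min of R_true
    interaction_amplitude: float  # ml/s, max-min of I_true
    noise_sd: float  # ml/s
    jitter_cv: float  # coefficient of variation of cycle periods
    seed: int
    bsa: float  # m2
    R_true: Callable = field(repr=False, default=None)
    E_true: Callable = field(repr=False, default=None)
    I_true: Callable = field(repr=False, default=None)

    def flow(self, resp_phase, cardiac_phase):
        """Noise-free flow surface at the given phase fractions."""
        return (
            self.Q_true
            + self.R_true(resp_phase)
            + self.E_true(cardiac_phase)
            + self.I_true(resp_phase, cardiac_phase)
        )

    def components_on_grid(self, n_i: int = 40, n_j: int = 10):
        """R, E, I evaluated at the native phase-grid midpoints."""
        gr = (np.arange(n_i) + 0.5) / n_i
        gc = (np.arange(n_j) + 0.5) / n_j
        return (
            self.R_true(gr),
            self.E_true(gc),
            self.I_true(gr[:, None], gc[None, :]),
        )

    @property
    def resp_to_cardiac_ratio(self) -> float:
        return self.respiratory_amplitude / self.cardiac_amplitude


@dataclass
class SyntheticSubject:
    """A generated subject: acquisition, monitoring record and truth.

    ``resp_phase``/``cardiac_phase`` are the exact phase fractions of every
    flow sample and ``noise`` the drawn residuals, so each sample value can
    be replayed exactly as truth surface + residual.
    """

    samples: FlowSampleSeries
    record: PhysioRecord
    truth: SubjectTruth
    resp_phase: np.ndarray = field(repr=False, default=None)
    cardiac_phase: np.ndarray = field(repr=False, default=None)
    noise: np.ndarray = field(repr=False, default=None)
    resp_onset_times: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_cycle_starts(rng, mean_period, cv, t_start, t_end):
    """Event times of consecutive cycles covering [t_start, t_end]."""
    if cv > 0:
        sigma = float(np.sqrt(np.log1p(cv**2)))
        mu = float(np.log(mean_period)) - 0.5 * sigma**2
    n_est = int(np.ceil((t_end - t_start) / mean_period)) + 8
    starts = [t_start + rng.uniform(0, mean_period)]
    while starts[-1] < t_end:
        if cv > 0:
            period = float(rng.lognormal(mu, sigma))
        else:
            period = mean_period
        starts.append(starts[-1] + period)
        if len(starts) > 10 * n_est:  # safety against degenerate draws
            raise ParameterError("cycle generation did not terminate")
    return np.array(starts)


def _phase_of(times, starts):
    """Piecewise-linear phase fraction of each time within its cycle."""
    pos = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(starts) - 2)
    return (times - starts[pos]) / (starts[pos + 1] - starts[pos])


def _build_truth(preset: str, params: dict, seed: int) -> SubjectTruth:
    r_spec = params["resp_shape"]
    e_spec = params["cardiac_shape"]
    R = _Shape(r_spec["bumps"], r_spec["harmonics"],
               amplitude=params["respiratory_amplitude"])
    E = _Shape(e_spec["bumps"], e_spec["harmonics"],
               amplitude=params["cardiac_amplitude"])

    # separable interaction: product of unit-normalized centered marginals,
    # rescaled so its max-min amplitude matches the requested value
    prod = R.normalized(_FINE)[:, None] * E.normalized(_FINE[::16])[None, :]
    span = float(prod.max() - prod.min())
    c_i = params["interaction_amplitude"] / span if span > 0 else 0.0

    def I_func(pr, pc, _c=c_i, _R=R, _E=E):
        return _c * _R.normalized(pr) * _E.normalized(pc)

    return SubjectTruth(
        preset=preset,
        Q_true=params["Q"],
        heart_rate=params["heart_rate"],
        resp_rate=params["resp_rate"],
        cardiac_amplitude=params["cardiac_amplitude"],
        respiratory_amplitude=params["respiratory_amplitude"],
        interaction_amplitude=params["interaction_amplitude"],
        noise_sd=params["noise_sd"],
        jitter_cv=params["jitter_cv"],
        seed=seed,
        bsa=params["bsa"],
        R_true=R,
        E_true=E,
        I_true=I_func,
    )


def generate_subject(
    preset: str = "fontan",
    overrides: Optional[dict] = None,
    seed: int = 0,
    scan_onset: float = 15.0,
    belt_dt: float = 0.002,
) -> SyntheticSubject:
    """Generate one synthetic subject.

    ``overrides`` may replace any preset parameter (rates, amplitudes, Q,
    noise_sd, jitter_cv, n_samples, sample_dt, bsa, shape recipes).
    """
    if preset not in PRESETS:
        raise ParameterError(f"unknown preset {preset!r}; use {tuple(PRESETS)}")
    params = {**PRESETS[preset]}
    if overrides:
        unknown = set(overrides) - set(params)
        if unknown:
            raise ParameterError(f"unknown override(s): {sorted(unknown)}")
        params.update(overrides)
    for key in ("heart_rate", "resp_rate", "cardiac_amplitude",
                "respiratory_amplitude"):
        if params[key] <= 0:
            raise ParameterError(f"{key} must be positive, got {params[key]}")
    if params["noise_sd"] < 0 or params["jitter_cv"] < 0:
        raise ParameterError("noise_sd and jitter_cv must be non-negative")

    rng = np.random.default_rng(seed)
    truth = _build_truth(preset, params, seed)

    n = int(params["n_samples"])
    dt = float(params["sample_dt"])
    duration = n * dt
    record_end = scan_onset + duration + 10.0

    t_c = 60.0 / params["heart_rate"]
    t_r = 60.0 / params["resp_rate"]
    cv = params["jitter_cv"]
    # event trains start before the record so phases are defined everywhere
    card_starts = _draw_cycle_starts(rng, t_c, cv, -2.0 * t_c, record_end + t_c)
    resp_starts = _draw_cycle_starts(rng, t_r, cv, -2.0 * t_r, record_end + t_r)

    sample_times_pmu = scan_onset + dt * np.arange(n)
    phi_r = _phase_of(sample_times_pmu, resp_starts)
    phi_c = _phase_of(sample_times_pmu, card_starts)
    noise = rng.normal(0.0, params["noise_sd"], size=n) if params["noise_sd"] > 0 \
        else np.zeros(n)
    flows = truth.flow(phi_r, phi_c) + noise

    belt_times = np.arange(0.0, record_end, belt_dt)
    belt_values = np.cos(2.0 * np.pi * _phase_of(belt_times, resp_starts))

    r_waves = card_starts[(card_starts >= 0) & (card_starts <= record_end)]
    record = PhysioRecord(belt_times, belt_values, r_waves, scan_onset)
    samples = FlowSampleSeries(dt * np.arange(n), flows)
    return SyntheticSubject(
        samples=samples,
        record=record,
        truth=truth,
        resp_phase=phi_r,
        cardiac_phase=phi_c,
        noise=noise,
        resp_onset_times=resp_starts[(resp_starts >= 0) & (resp_starts <= record_end)],
    )


# between-subject standard deviations used by generate_cohort; amplitude
# variability enters through the cardiac amplitude and the respiratory-to-
# cardiac ratio, which are what the study reports as separating the groups
COHORT_SD: Dict[str, dict] = {
    "fontan": {"heart_rate": 11.0, "resp_rate": 4.3, "cardiac_amplitude": 8.2,
               "ratio": 1.58, "interaction_amplitude": 9.2, "Q_cv": 0.3,
               "bsa": 0.4},
    "normal": {"heart_rate": 15.1, "resp_rate": 5.7, "cardiac_amplitude": 45.8,
               "ratio": 0.18, "interaction_amplitude": 13.3, "Q_cv": 0.3,
               "bsa": 0.6},
}

# reported group ranges of the amplitude ratio; subject draws are truncated
# to them, mirroring the non-overlap between the two circulations
_RATIO_MEAN_RANGE = {"fontan": (2.83, 1.01, 6.72), "normal": (0.40, 0.16, 0.71)}


def _truncated_normal(rng, mean, sd, lo, hi=np.inf):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_cohort(
    n: int,
    preset: str = "fontan",
    between_subject_sd: Optional[dict] = None,
    seed: int = 0,
) -> List[SyntheticSubject]:
    """Generate a cohort with between-subject parameter variability.

    Heart rate, breathing rate, cardiac amplitude, amplitude ratio,
    interaction amplitude, net flow level and BSA are drawn per subject
    around the preset means (truncated to positive / reported ranges); the
    respiratory amplitude is ratio * cardiac amplitude, preserving the
    group-specific pulsatility structure.  Subject seeds derive
    deterministically from the cohort seed.
    """
    if n < 1:
        raise ParameterError("cohort size must be at least 1")
    if preset not in PRESETS:
        raise ParameterError(f"unknown preset {preset!r}")
    sd = {**COHORT_SD[preset], **(between_subject_sd or {})}
    base = PRESETS[preset]
    rng = np.random.default_rng(seed)
    ratio_mean, ratio_lo, ratio_hi = _RATIO_MEAN_RANGE[preset]

    subjects = []
    for _ in range(n):
        a_c = _truncated_normal(rng, base["cardiac_amplitude"],
                                sd["cardiac_amplitude"],
                                0.25 * base["cardiac_amplitude"])
        ratio = _truncated_normal(rng, ratio_mean, sd["ratio"], ratio_lo, ratio_hi)
        overrides = {
            "heart_rate": _truncated_normal(rng, base["heart_rate"],
                                            sd["heart_rate"], 40.0, 140.0),
            "resp_rate": _truncated_normal(rng, base["resp_rate"],
                                           sd["resp_rate"], 8.0, 40.0),
            "cardiac_amplitude": a_c,
            "respiratory_amplitude": ratio * a_c,
            "interaction_amplitude": _truncated_normal(
                rng, base["interaction_amplitude"], sd["interaction_amplitude"],
                1.0),
            "Q": _truncated_normal(rng, base["Q"], sd["Q_cv"] * base["Q"],
                                   0.3 * base["Q"]),
            "bsa": _truncated_normal(rng, base["bsa"], sd["bsa"], 0.4),
        }
        child_seed = int(rng.integers(0, 2**31 - 1))
        subjects.append(generate_subject(preset, overrides, seed=child_seed))
    return subjects
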