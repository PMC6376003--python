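"""Cohort-level comparison of subject summaries.

Rank-based tests only, as appropriate for the small clinical group sizes
this pipeline mirrors: Mann-Whitney U between groups for each metric,
Wilcoxon signed rank within each group for respiratory vs cardiac
amplitude, and Spearman's rho for the association of the respiratory-to-
cardiac amplitude ratio with the simultaneous retrograde flow fraction.
Exact small-sample null distributions are used wherever ties permit; all
tests are two-sided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError
from .pipeline import SubjectSummary

#: metric name -> extraction path inside a SubjectSummary
_METRICS = {
    "resp_to_cardiac_ratio": ("pulsatility", "resp_to_cardiac_ratio"),
    "cardiac_amplitude_ml_s": ("pulsatility", "cardiac_amplitude_ml_s"),
    "respiratory_amplitude_ml_s": ("pulsatility", "respiratory_amplitude_ml_s"),
    "net_ml": ("volumes", "net_ml"),
    "retro_pct_simultaneous": ("volumes", "retro_pct_simultaneous"),
    "retro_pct_ecg": ("volumes", "retro_pct_ecg"),
    "retro_pct_resp": ("volumes", "retro_pct_resp"),
}


def _extract(summaries: Sequence[SubjectSummary], metric: str) -> np.ndarray:
    section, key = _METRICS[metric]
    return np.array([getattr(s, section)[key] for s in summaries], dtype=float)


def _exact_if_possible(x: np.ndarray, y: np.ndarray) -> str:
    pooled = np.concatenate([x, y])
    return "exact" if len(np.unique(pooled)) == len(pooled) else "auto"


@dataclass
class CohortComparison:
    """Group descriptives and between/within-group test results."""

    group_labels: tuple
    n: Dict[str, int]
    means: Dict[str, Dict[str, float]]
    sds: Dict[str, Dict[str, float]]
    mannwhitney_p: Dict[str, float]
    wilcoxon_amplitudes_p: Dict[str, Optional[float]]
    spearman: Dict[str, Dict[str, Optional[float]]]
    skipped: List[str]

    def to_dict(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "n": self.n,
            "means": self.means,
            "sds": self.sds,
            "mannwhitney_p": self.mannwhitney_p,
            "wilcoxon_amplitudes_p": self.wilcoxon_amplitudes_p,
            "spearman": self.spearman,
            "skipped": self.skipped,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def compare_cohorts(
    summaries_a: Sequence[SubjectSummary],
    summaries_b: Sequence[SubjectSummary],
    labels: tuple = ("A", "B"),
) -> CohortComparison:
    """Compare two groups of subject summaries with rank statistics."""
    if len(summaries_a) < 3 or len(summaries_b) < 3:
        raise ParameterError("need at least 3 subjects per group for testing")
    groups = {labels[0]: summaries_a, labels[1]: summaries_b}
    means, sds = {}, {}
    for label, grp in groups.items():
        means[label] = {m: float(np.mean(_extract(grp, m))) for m in _METRICS}
        sds[label] = {m: float(np.std(_extract(grp, m), ddof=1)) for m in _METRICS}

    skipped: List[str] = []
    mw: Dict[str, float] = {}
    for metric in _METRICS:
        x = _extract(summaries_a, metric)
        y = _extract(summaries_b, metric)
        if np.ptp(np.concatenate([x, y])) == 0:
            skipped.append(f"mannwhitney:{metric} (all values equal)")
            continue
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method=_exact_if_possible(x, y))
        mw[metric] = float(res.pvalue)

    wsr: Dict[str, Optional[float]] = {}
    for label, grp in groups.items():
        a_r = _extract(grp, "respiratory_amplitude_ml_s")
        a_c = _extract(grp, "cardiac_amplitude_ml_s")
        diffs = a_r - a_c
        if np.all(diffs == 0):
            wsr[label] = None
            skipped.append(f"wilcoxon:{label} (all differences zero)")
            continue
        method = "exact" if len(np.unique(np.abs(diffs[diffs != 0]))) == np.sum(diffs != 0) else "auto"
        res = stats.wilcoxon(a_r, a_c, alternative="two-sided", method=method)
        wsr[label] = float(res.pvalue)

    rho: Dict[str, Dict[str, Optional[float]]] = {}
    for label, grp in groups.items():
        x = _extract(grp, "resp_to_cardiac_ratio")
        y = -_extract(grp, "retro_pct_simultaneous")  # positive magnitude
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho[label] = {"rho": None, "p": None}
            skipped.append(f"spearman:{label} (degenerate)")
            continue
        res = stats.spearmanr(x, y)
        rho[label] = {"rho": float(res.statistic), "p": float(res.pvalue)}

    return CohortComparison(
        group_labels=labels,
        n={labels[0]: len(summaries_a), labels[1]: len(summaries_b)},
        means=means,
        sds=sds,
        mannwhitney_p=mw,
        wilcoxon_amplitudes_p=wsr,
        spearman=rho,
        skipped=skipped,
    )
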