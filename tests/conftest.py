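"""Shared fixtures: synthetic subjects and their full pipeline results.

The heavy objects (default 8000-sample subjects and their analyses) are
session-scoped so the acceptance checks and unit tests reuse one run each.
"""

import numpy as np
import pytest

from physiomatrix import AnalysisConfig, generate_subject, run_pipeline


@pytest.fixture(scope="session")
def fontan_subject():
    return generate_subject("fontan", seed=42)


@pytest.fixture(scope="session")
def fontan_result(fontan_subject):
    return run_pipeline(fontan_subject.samples, fontan_subject.record)


@pytest.fixture(scope="session")
def normal_subject():
    return generate_subject("normal", seed=42)


@pytest.fixture(scope="session")
def normal_result(normal_subject):
    return run_pipeline(normal_subject.samples, normal_subject.record)


@pytest.fixture(scope="session")
def noise_free_fontan():
    return generate_subject("fontan", {"noise_sd": 0.0, "jitter_cv": 0.0}, seed=42)


@pytest.fixture(scope="session")
def noise_free_fontan_result(noise_free_fontan):
    return run_pipeline(noise_free_fontan.samples, noise_free_fontan.record)


def assert_decomposition_invariants(fit, rel=1e-6, surface_rel=1e-9):
    """Centering and exactness contracts every functional-ANOVA fit obeys."""
    scale_r = max(np.ptp(fit.R), 1e-12)
    scale_e = max(np.ptp(fit.E), 1e-12)
    assert abs(fit.R.sum()) <= rel * scale_r * len(fit.R)
    assert abs(fit.E.sum()) <= rel * scale_e * len(fit.E)
    scale_i = max(np.ptp(fit.I), 1e-12)
    assert np.max(np.abs(fit.I.sum(axis=0))) <= rel * scale_i * fit.I.shape[0]
    assert np.max(np.abs(fit.I.sum(axis=1))) <= rel * scale_i * fit.I.shape[1]
    # reconstruction: surface property is defined as the exact sum
    recon = fit.Q + fit.R[:, None] + fit.E[None, :] + fit.I
    rng = max(np.ptp(recon), 1e-12)
    assert np.max(np.abs(fit.surface - recon)) <= surface_rel * rng
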