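"""Shared fixtures: simulated studies and their fitted bundles.

Session scope keeps the expensive end-to-end objects (simulation +
conditional-logistic fit) shared across test modules.
"""

import numpy as np
import pandas as pd
import pytest

from coldpm.basis import build_crossbasis
from coldpm.casecrossover import DayCovariates, build_design
from coldpm.clogit import conditional_logistic_fit
from coldpm.pipeline import AnalysisConfig, run_analysis
from coldpm.scenarios import (modification_recovery_config,
                              overall_recovery_config, pct_recovery_config)
from coldpm.synthetic import simulate_study


@pytest.fixture(scope="session")
def overall_study():
    """Six-season study, cold effect only (true OR 1.83, gamma = 0)."""
    return simulate_study(overall_recovery_config(seed=42))


@pytest.fixture(scope="session")
def overall_bundle(overall_study):
    s = overall_study
    return run_analysis(s.deaths, s.exposures, AnalysisConfig(pollutant="pm1"))


@pytest.fixture(scope="session")
def modified_study():
    """Study with PM1 modification: OR 1.60 at P10, 2.20 at P90."""
    return simulate_study(modification_recovery_config(seed=43, pollutant="pm1"))


@pytest.fixture(scope="session")
def modified_bundle(modified_study):
    s = modified_study
    return run_analysis(s.deaths, s.exposures, AnalysisConfig(pollutant="pm1"))


@pytest.fixture(scope="session")
def small_study():
    """Cheap study for structural tests (3 seasons, 80 deaths/day)."""
    cfg = pct_recovery_config(seed=7, pollutant="pm1")
    from dataclasses import replace
    return simulate_study(replace(cfg, n_seasons=3, baseline_rate=80.0))


@pytest.fixture(scope="session")
def small_fit(small_study):
    s = small_study
    exp = s.exposures.set_index("date")
    cb = build_crossbasis(exp["temp_c"], s.spec)
    dc = DayCovariates.assemble(exp, cb, "pm1")
    design = build_design(s.deaths, dc)
    return design, conditional_logistic_fit(design)


def toy_design(X, y, strata, weights=None, colnames=None):
    """Minimal design-table stand-in for direct clogit calls."""

    class _D:
        pass

    d = _D()
    d.X = np.asarray(X, float)
    d.y = np.asarray(y, float)
    d.stratum_ids = np.asarray(strata)
    d.weights = np.ones(len(d.y)) if weights is None else np.asarray(weights, float)
    d.colnames = colnames
    return d


@pytest.fixture
def make_toy_design():
    return toy_design
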