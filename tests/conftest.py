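"""Shared fixtures: small hand-built sessions and one reusable synthetic cohort.

The full 100-unit cohort and its analysis are expensive (a few seconds), so
they are computed once per test session and shared by the recovery,
population and acceptance tests.
"""

import numpy as np
import pytest

from kinencode import AnalysisConfig, analyze_session, build_kinematics
from kinencode.session_io import (SessionBundle, SessionEvents,
                                  TrackingSeries, UnitRecording)
from kinencode.synthetic_data import TaskSpec, generate_cohort, simulate_task_session

COHORT_SEED = 11


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def tiny_bundle():
    """A minimal valid 2-unit, 10-trial session built by hand."""
    t = np.arange(0.0, 120.0, 1.0 / 30.0)
    x = 20.0 + 5.0 * np.sin(0.2 * t)
    y = 25.0 + 4.0 * np.cos(0.15 * t)
    tracking = TrackingSeries(t, x, y)
    cues = 5.0 + 11.0 * np.arange(10)
    events = SessionEvents(cues, cues + 2.1, ["sucrose"] * 10)
    units = [
        UnitRecording("u0", np.sort(np.random.default_rng(0).uniform(0, 119, 300)),
                      hemisphere="left", mean_rate=2.5, spike_width_fwhm=1.1,
                      putative_class="DA"),
        UnitRecording("u1", np.sort(np.random.default_rng(1).uniform(0, 119, 2000)),
                      hemisphere="right", mean_rate=16.7, spike_width_fwhm=0.25,
                      putative_class="GABA"),
    ]
    return SessionBundle(tracking, events, units, provenance={"origin": "fixture"})


@pytest.fixture(scope="session")
def fast_session():
    """One simulated fast-profile task session (shared, read-only)."""
    return simulate_task_session(TaskSpec.fast(), seed=123)


@pytest.fixture(scope="session")
def cohort():
    """Seeded 100-unit cohort on the fast task profile, with ground truth."""
    bundle, session, specs = generate_cohort(n_units=100, seed=COHORT_SEED,
                                             task=TaskSpec.fast())
    return bundle, session, specs


@pytest.fixture(scope="session")
def cohort_analysis(cohort):
    """Full-pipeline analysis of the shared cohort."""
    bundle, _session, _specs = cohort
    results, report, kinset = analyze_session(bundle, AnalysisConfig())
    return results, report, kinset


@pytest.fixture(scope="session")
def fast_kinset(fast_session):
    return build_kinematics(fast_session.tracking)
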