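"""Shared fixtures.

The expensive closed-loop objects (default stochastic model, the seeded
100-patient virtual trials) are session-scoped: the safety audit, the
comparative-protocol checks and the acceptance suite all read the same
runs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from neoglyc import (
    BGMeasurement,
    CohortSpec,
    FitConfig,
    GlucoseInputProfile,
    InsulinSchedule,
    ModelParameters,
    NutritionEntry,
    NutritionSchedule,
    PatientRecord,
    PatientState,
    SITrace,
    generate_cohort,
    run_virtual_trial,
    simulate,
)
from neoglyc.cohort import default_stochastic_model
from neoglyc.model import steady_state_glucose, steady_state_insulin

TRIAL_SEED = 2025
COHORT_SEED = 1
STOCH_SEED = 777


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def stochastic_model():
    return default_stochastic_model(seed=STOCH_SEED, n_patients=50)


@pytest.fixture(scope="session")
def longterm_spec() -> CohortSpec:
    return CohortSpec(n=100, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def longterm_cohort(longterm_spec):
    return generate_cohort(longterm_spec)


@pytest.fixture(scope="session")
def model_trial(longterm_cohort, longterm_spec, stochastic_model):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_virtual_trial(
            longterm_cohort, longterm_spec, "model_based",
            stochastic_model=stochastic_model, seed=TRIAL_SEED,
        )


@pytest.fixture(scope="session")
def scale_trial(longterm_cohort, longterm_spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_virtual_trial(
            longterm_cohort, longterm_spec, "sliding_scale", seed=TRIAL_SEED,
        )


def make_steady_record(
    params: ModelParameters,
    si,
    rate: float = 0.005,
    p_mg_kg_min: float = 7.9,
    duration_min: float = 720.0,
    interval_min: float = 120.0,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
    patient_id: str = "fixture",
) -> tuple[PatientRecord, FitConfig]:
    """Record generated by simulate() from the metabolic steady state.

    ``si`` may be a constant or an SITrace; the initial state is the
    steady state of the *initial* SI value, so the trajectory is exact for
    constant SI and quasi-steady for slowly varying SI.
    """
    si0 = si if np.isscalar(si) else float(si.value_at(si.span[0]))
    g0 = steady_state_glucose(params, si0, rate, p_mg_kg_min)
    i0, q0 = steady_state_insulin(params, rate)
    insulin = InsulinSchedule([0.0], [rate])
    profile = GlucoseInputProfile.constant(p_mg_kg_min)
    res = simulate(PatientState(0.0, g0, i0, q0), params, si, insulin, profile,
                   duration_min, step=interval_min)
    values = res.G.copy()
    if noise_cv > 0:
        values = np.clip(values * (1.0 + noise_cv * rng.standard_normal(values.size)),
                         0.6, 49.0)
    meas = [BGMeasurement(float(t), float(g)) for t, g in zip(res.t, values)]
    # weight 1 kg and 10% dextrose sized so the profile reproduces P exactly
    nutrition = NutritionSchedule([NutritionEntry(
        0.0, duration_min + 240.0, 10.0, p_mg_kg_min * 60.0 / 100.0, 0.0, 0.0, 0.0
    )])
    record = PatientRecord(patient_id, 1.0, meas, insulin, nutrition)
    fit_cfg = FitConfig(initial_plasma_insulin=i0, initial_interstitial_insulin=q0)
    return record, fit_cfg


@pytest.fixture()
def steady_record(params):
    return make_steady_record(params, si=1.5e-3)


def random_walk_pairs(n_pairs: int, seed: int, walk_sigma: float = 0.12,
                      level_sigma: float = 0.557, median: float = 1.73e-3,
                      hours: int = 72) -> np.ndarray:
    """Hourly (SI_n, SI_{n+1}) pairs from a geometric random walk."""
    rng = np.random.default_rng(seed)
    xs = []
    total = 0
    while total < n_pairs:
        x0 = median * np.exp(level_sigma * rng.standard_normal())
        ln = np.log(x0) + np.concatenate(
            [[0.0], np.cumsum(walk_sigma * rng.standard_normal(hours))])
        si = np.exp(ln)
        xs.append(np.column_stack([si[:-1], si[1:]]))
        total += hours
    return np.concatenate(xs)[:n_pairs]
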