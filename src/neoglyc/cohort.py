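"""Synthetic VLBW cohort generation and closed-loop virtual trials.

Virtual patients emulate the insulin-treated very-low-birthweight
population: lognormal birthweights (median 760 g), an initial insulin
sensitivity drawn from a lognormal whose median and IQR match clinical
per-patient summaries, and hour-to-hour evolution as a geometric random
walk (sigma 0.12/hr) calibrated so the 90 % range of per-patient median SI
spans at least ten-fold across the default long-term cohort.  Nutrition
combines 10-12.5 % parenteral dextrose sized to a per-patient glucose
infusion rate, an expressed-breast-milk ramp, and an optional 5 % dextrose
drug-carrier infusion.  Enrolment requires an initial BG of at least
10 mmol/L.

``run_virtual_trial`` replays a dosing protocol (model-based or sliding
scale) in closed loop: at each scheduled measurement a noisy BG sample is
drawn from the simulated true state, insulin sensitivity is re-identified
from observations only (the controller never sees the true SI trajectory),
the protocol picks the infusion rate, and the truth is advanced to the
next measurement.  Outputs are observable PatientRecords plus a true-SI
sidecar for evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .controller import (
    SLIDING_SCALE_START_RATE,
    ControllerConfig,
    DoseRecommendation,
    recommend_rate,
    select_horizon,
    sliding_scale_rate,
)
from .exceptions import ValidationError
from .identify import BGMeasurement, FitConfig, SIInterval, SITrace, fit_interval_si
from .model import (
    GlucoseInputProfile,
    InsulinSchedule,
    ModelParameters,
    NutritionEntry,
    NutritionSchedule,
    PatientState,
    insulin_state_path,
    simulate,
    total_glucose_input,
)
from .stochastic import StochasticSIModel
from .units import GLUCOSE_MOLAR_MASS

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "VirtualPatient",
    "PatientTrialResult",
    "generate_cohort",
    "run_virtual_trial",
    "default_stochastic_model",
    "short_term_spec",
]

Protocol = Literal["model_based", "sliding_scale"]

#: Physiologic support bounds for the simulated SI random walk, L/(mU.min).
#: Wide enough that they rarely bind: tight bounds would compress the
#: cohort's sensitivity spread below its >= 10-fold calibration constraint.
SI_WALK_BOUNDS = (1e-5, 5e-2)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort generator settings.  Defaults are the long-term preset
    (several-day trials, 2-4 h sampling, mixed arterial/capillary sites)."""

    n: int = 100
    seed: int = 0
    duration_h: float = 72.0
    # weight: lognormal, median kg / ln-sd from the 601-925 g IQR
    weight_median: float = 0.760
    weight_sigma: float = 0.32
    # initial SI: lognormal, median / ln-sd from the 1.25-2.65e-3 IQR
    si_median: float = 1.73e-3
    si_sigma: float = 0.557
    si_walk_sigma: float = 0.12        # per hour, ln scale
    # per-patient slow drift (ln scale per hour): distinguishes persistent
    # divergence of patient condition from hour-to-hour volatility and
    # completes the calibration of the >= 10-fold cohort sensitivity spread
    si_drift_sigma: float = 0.015
    # enrolment BG: lognormal, median / ln-sd from the 9.4-13.4 IQR,
    # truncated at the enrolment threshold
    initial_bg_median: float = 11.4
    initial_bg_sigma: float = 0.263
    enrolment_bg: float = 10.0
    # nutrition: per-patient glucose infusion rate and EBM targets
    gir_median: float = 7.9            # mg/kg/min
    gir_sigma: float = 0.313
    ebm_median: float = 15.8           # mL/kg/day
    ebm_sigma: float = 2.15
    ebm_max: float = 60.0
    dextrose_concentrations: tuple = (10.0, 12.5)
    carrier_fraction: float = 0.3
    carrier_conc_pct: float = 5.0
    carrier_flow_ml_hr: float = 0.5
    # measurement scheduling and observation noise
    meas_interval_h: tuple = (2.0, 4.0)
    max_meas_per_day: int | None = None
    extra_meas_per_day: float = 0.5    # blood-gas overlay (Poisson rate)
    arterial_fraction: float = 0.27
    bg_cv_arterial: float = 0.02
    bg_cv_capillary: float = 0.05
    enforce_spread: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("cohort size must be >= 1")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("weight_median", "si_median", "initial_bg_median",
                     "gir_median", "duration_h"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"CohortSpec.{name} must be > 0")
        if self.enforce_spread and self.si_sigma <= 0 and self.si_walk_sigma <= 0:
            raise ValidationError(
                "degenerate spec: zero SI variance cannot reproduce the "
                "cohort sensitivity spread (set enforce_spread=False to allow)"
            )


def short_term_spec(**overrides) -> CohortSpec:
    """Short-term preset: 24 h, 1-3 h sampling capped at 12/day, arterial
    sampling, initial SI matching the short-term per-patient summaries."""
    base = dict(
        duration_h=24.0, meas_interval_h=(1.0, 3.0), max_meas_per_day=12,
        arterial_fraction=1.0, si_median=1.28e-3, si_sigma=1.0,
    )
    base.update(overrides)
    return CohortSpec(**base)


@dataclass
class VirtualPatient:
    patient_id: str
    weight_kg: float
    si_trace: SITrace          # true hourly insulin-sensitivity trajectory
    nutrition: NutritionSchedule
    initial_bg: float

    def __post_init__(self) -> None:
        if np.any(self.si_trace.values <= 0):
            raise ValidationError("true SI must be > 0 throughout")


def _lognormal(rng, median, sigma):
    return float(median * np.exp(sigma * rng.standard_normal()))


def generate_cohort(spec: CohortSpec) -> list[VirtualPatient]:
    """Deterministically generate ``spec.n`` virtual patients from the seed."""
    children = np.random.SeedSequence(spec.seed).spawn(spec.n)
    n_hours = int(np.ceil(spec.duration_h))
    patients = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        weight = float(np.clip(_lognormal(rng, spec.weight_median, spec.weight_sigma),
                               0.4, 1.5))

        si0 = _lognormal(rng, spec.si_median, spec.si_sigma)
        drift = spec.si_drift_sigma * rng.standard_normal()
        steps = drift + spec.si_walk_sigma * rng.standard_normal(n_hours - 1)
        ln_si = np.log(si0) + np.concatenate([[0.0], np.cumsum(steps)])
        si = np.clip(np.exp(ln_si), *SI_WALK_BOUNDS)

        bg0 = _lognormal(rng, spec.initial_bg_median, spec.initial_bg_sigma)
        for _ in range(200):
            if bg0 >= spec.enrolment_bg:
                break
            bg0 = _lognormal(rng, spec.initial_bg_median, spec.initial_bg_sigma)
        bg0 = max(bg0, spec.enrolment_bg)

        conc = float(rng.choice(spec.dextrose_concentrations))
        gir = _lognormal(rng, spec.gir_median, spec.gir_sigma)
        dex_flow = gir * weight * 60.0 / (conc * 10.0)
        ebm_target = float(np.clip(_lognormal(rng, spec.ebm_median, spec.ebm_sigma),
                                   0.0, spec.ebm_max))
        has_carrier = rng.uniform() < spec.carrier_fraction

        # hourly entries; extended past the trial end so end-of-trial
        # forecasts (up to 4 h ahead) see a defined glucose input
        entries = []
        for h in range(n_hours + 4):
            frac = min(1.0, h / max(n_hours - 1, 1))
            entries.append(NutritionEntry(
                start=60.0 * h, end=60.0 * (h + 1),
                dex_conc_pct=conc, dex_flow_ml_hr=dex_flow,
                ebm_ml_kg_day=ebm_target * frac,
                carrier_conc_pct=spec.carrier_conc_pct if has_carrier else 0.0,
                carrier_flow_ml_hr=spec.carrier_flow_ml_hr if has_carrier else 0.0,
            ))

        patients.append(VirtualPatient(
            patient_id=f"vp{i:03d}",
            weight_kg=weight,
            si_trace=SITrace.from_hourly(si),
            nutrition=NutritionSchedule(entries),
            initial_bg=bg0,
        ))
    return patients


def _measurement_times(spec: CohortSpec, rng) -> np.ndarray:
    """Scheduled measurements plus the Poisson blood-gas overlay."""
    end = spec.duration_h * 60.0
    times = [0.0]
    while True:
        dt = rng.uniform(*spec.meas_interval_h) * 60.0
        if spec.max_meas_per_day is not None:
            dt = max(dt, 24.0 * 60.0 / spec.max_meas_per_day)
        t = times[-1] + dt
        if t >= end - 30.0:
            break
        times.append(t)
    n_extra = rng.poisson(spec.extra_meas_per_day * spec.duration_h / 24.0)
    extras = rng.uniform(30.0, end - 30.0, size=n_extra)
    merged = np.sort(np.concatenate([times, extras]))
    keep = [merged[0]]
    for t in merged[1:]:
        if t - keep[-1] >= 15.0:    # no second stick within 15 min
            keep.append(t)
    return np.asarray(keep)


@dataclass
class PatientTrialResult:
    """One patient's virtual-trial output.

    ``record`` holds only observable quantities; ``true_si`` is the
    evaluation sidecar the controller never saw.
    """

    patient_id: str
    record: "PatientRecord"
    true_si: SITrace
    true_bg_hourly: np.ndarray
    recommendations: list[tuple[float, DoseRecommendation]]
    fitted_si: SITrace | None = None
    failed: bool = False
    error: str = ""


def run_virtual_trial(
    patients: list[VirtualPatient],
    spec: CohortSpec,
    protocol: Protocol,
    stochastic_model: StochasticSIModel | None = None,
    params: ModelParameters | None = None,
    controller_config: ControllerConfig | None = None,
    fit_config: FitConfig | None = None,
    seed: int | None = None,
) -> list[PatientTrialResult]:
    """Closed-loop virtual trial of a dosing protocol.

    Per-patient failures are logged and flagged without aborting the
    cohort.  Identical inputs and seed give bitwise-identical output.
    """
    if protocol == "model_based" and stochastic_model is None:
        raise ValidationError("model_based protocol requires a stochastic model")
    if protocol not in ("model_based", "sliding_scale"):
        raise ValidationError(f"unknown protocol {protocol!r}")
    params = params or ModelParameters()
    controller_config = controller_config or ControllerConfig()
    fit_config = fit_config or FitConfig()
    if seed is None:
        seed = spec.seed + 1

    children = np.random.SeedSequence(seed).spawn(len(patients))
    results = []
    for patient, child in zip(patients, children):
        rng = np.random.default_rng(child)
        try:
            results.append(_run_one(
                patient, spec, protocol, stochastic_model, params,
                controller_config, fit_config, rng,
            ))
        except Exception as err:  # noqa: BLE001 — per-patient isolation
            logger.warning("virtual trial failed for %s: %s", patient.patient_id, err)
            results.append(PatientTrialResult(
                patient_id=patient.patient_id,
                record=None, true_si=patient.si_trace,
                true_bg_hourly=np.array([]), recommendations=[],
                failed=True, error=str(err),
            ))
    return results


def _run_one(patient, spec, protocol, model, params, ctrl_cfg, fit_cfg, rng):
    from .records import PatientRecord  # local import: records imports this layer's deps

    end = spec.duration_h * 60.0
    glucose = total_glucose_input(patient.nutrition, patient.weight_kg)
    meas_times = _measurement_times(spec, rng)

    truth = PatientState(0.0, patient.initial_bg, 0.0, 0.0)
    ins_times: list[float] = []
    ins_rates: list[float] = []
    observations: list[BGMeasurement] = []
    fitted: list[SIInterval] = []
    recs: list[tuple[float, DoseRecommendation]] = []
    true_hourly_t: list[float] = [0.0]
    true_hourly_g: list[float] = [truth.G]

    I_obs = Q_obs = 0.0          # controller-side insulin states (observable)
    si_now = fit_cfg.si_initial
    current_rate = SLIDING_SCALE_START_RATE
    prev_obs: BGMeasurement | None = None

    for k, tk in enumerate(meas_times):
        # -- observe ---------------------------------------------------------
        if k == 0:
            bg_obs, site = truth.G, "arterial"    # the enrolment measurement
        else:
            site = "arterial" if rng.uniform() < spec.arterial_fraction else "capillary"
            cv = spec.bg_cv_arterial if site == "arterial" else spec.bg_cv_capillary
            bg_obs = float(np.clip(truth.G * (1.0 + cv * rng.standard_normal()),
                                   0.6, 49.0))
        obs = BGMeasurement(tk, bg_obs, site)
        observations.append(obs)

        # -- identify from observations only ---------------------------------
        if k > 0:
            schedule = InsulinSchedule(ins_times, ins_rates)
            t_grid, I_path, Q_grid = insulin_state_path(
                params, schedule, prev_obs.t, tk, I_obs, Q_obs, dt=fit_cfg.quad_dt
            )
            kappa = (np.asarray(glucose.total_at(t_grid)) + params.EGPnet) / (
                GLUCOSE_MOLAR_MASS * params.Vg
            )
            si_fit, residual, flag, _ = fit_interval_si(
                params, prev_obs.value, bg_obs, t_grid, Q_grid, kappa, si_now, fit_cfg
            )
            fitted.append(SIInterval(prev_obs.t, tk, si_fit, residual, flag))
            si_now = si_fit
            I_obs, Q_obs = float(I_path[-1]), float(Q_grid[-1])

        # -- dose -------------------------------------------------------------
        t_next = meas_times[k + 1] if k + 1 < meas_times.size else end
        if protocol == "model_based":
            horizon = select_horizon(t_next - tk, ctrl_cfg.horizon_choices)
            rec = recommend_rate(
                PatientState(tk, bg_obs, I_obs, Q_obs), params, model, si_now,
                glucose, horizon, ctrl_cfg, rng=rng,
            )
            rate = rec.rate
            recs.append((tk, rec))
        else:
            rate = sliding_scale_rate(bg_obs, current_rate)
        current_rate = rate
        ins_times.append(tk)
        ins_rates.append(rate)

        # -- advance the truth -------------------------------------------------
        schedule = InsulinSchedule(ins_times, ins_rates)
        res = simulate(truth, params, patient.si_trace, schedule, glucose,
                       duration=t_next - tk, step=30.0)
        # record true BG at integer hours for evaluation
        hours = np.arange(np.floor(tk / 60.0) + 1, np.floor(t_next / 60.0) + 1) * 60.0
        hours = hours[(hours > tk) & (hours <= t_next)]
        for h in hours:
            true_hourly_t.append(h)
            true_hourly_g.append(float(np.interp(h, res.t, res.G)))
        truth = res.state_at_end()
        prev_obs = obs

    record = PatientRecord(
        patient_id=patient.patient_id,
        weight_kg=patient.weight_kg,
        measurements=observations,
        insulin=InsulinSchedule(ins_times, ins_rates),
        nutrition=patient.nutrition,
        metadata={"protocol": protocol, "duration_h": spec.duration_h},
    )
    return PatientTrialResult(
        patient_id=patient.patient_id,
        record=record,
        true_si=patient.si_trace,
        true_bg_hourly=np.column_stack([true_hourly_t, true_hourly_g]),
        recommendations=recs,
        fitted_si=SITrace(fitted) if fitted else None,
    )


def default_stochastic_model(
    seed: int, n_patients: int = 50, duration_h: float = 72.0
) -> StochasticSIModel:
    """Stochastic SI model trained on a documented synthetic cohort.

    The clinical retrospective SI database is not public; the shipped
    default pools hourly transitions from the synthetic long-term cohort
    generator, which is calibrated to the published cohort summaries.
    """
    spec = CohortSpec(n=n_patients, seed=seed, duration_h=duration_h)
    patients = generate_cohort(spec)
    return StochasticSIModel.from_traces([p.si_trace for p in patients])
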