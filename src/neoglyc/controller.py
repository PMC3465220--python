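"""Safety-constrained model-predictive insulin dosing.

After every blood-glucose measurement the controller sweeps candidate
infusion rates from 0 to the 0.5 U/kg/hr safety cap, forecasts the BG
percentile band at the time of the next planned measurement (1-4 h ahead),
selects the rate whose median forecast lands closest to the target
setpoint (ties broken toward the lower, more conservative rate), and then
reduces the selection to the largest rate whose forecast 5th-percentile BG
stays above the hypoglycemia safety floor of 4 mmol/L.  A retrospective
sliding-scale comparator and the pump dilution arithmetic (0.25 U/kg/mL
standard neonatal dilution) live here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .model import GlucoseInputProfile, ModelParameters, PatientState, forecast_glucose
from .stochastic import ALLOWED_HORIZONS, ForecastBand, StochasticSIModel
from .units import INSULIN_DILUTION_U_PER_KG_PER_ML, MAX_INSULIN_RATE

logger = logging.getLogger(__name__)

__all__ = [
    "ControllerConfig",
    "DoseRecommendation",
    "recommend_rate",
    "pump_flow",
    "insulin_solution_concentration",
    "sliding_scale_rate",
    "select_horizon",
    "SLIDING_SCALE_START_RATE",
]

#: Sliding-scale starting rate (0.2 mL/hr at the standard dilution).
SLIDING_SCALE_START_RATE = 0.05


@dataclass(frozen=True)
class ControllerConfig:
    """Dosing targets, safety constraints and sweep resolution."""

    band_low: float = 4.0          # mmol/L
    band_high: float = 7.0         # mmol/L
    setpoint: float = 5.5          # mmol/L (band midpoint)
    safety_percentile: float = 5.0
    safety_floor: float = 4.0      # mmol/L; forecast p5 must exceed this
    max_rate: float = MAX_INSULIN_RATE   # U/kg/hr
    rate_step: float = 0.005       # candidate grid resolution (U/kg/hr)
    horizon_choices: tuple = ALLOWED_HORIZONS
    n_forecast_paths: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.setpoint < self.band_high:
            raise ValidationError("require 0 < band_low < setpoint < band_high")
        if self.max_rate <= 0 or self.rate_step <= 0:
            raise ValidationError("max_rate and rate_step must be > 0")

    def candidates(self) -> np.ndarray:
        n = int(round(self.max_rate / self.rate_step))
        return self.rate_step * np.arange(n + 1)


@dataclass(frozen=True)
class DoseRecommendation:
    rate: float                   # U/kg/hr
    pump_flow_ml_hr: float
    forecast: ForecastBand
    cap_applied: bool = False
    safety_reduced: bool = False
    below_band_stop: bool = False

    def to_dict(self) -> dict:
        return {
            "rate_U_kg_hr": self.rate,
            "pump_flow_mL_hr": round(self.pump_flow_ml_hr, 2),
            "forecast": self.forecast.to_dict(),
            "flags": {
                "cap_applied": self.cap_applied,
                "safety_reduced": self.safety_reduced,
                "below_band_stop": self.below_band_stop,
            },
        }


def pump_flow(rate_u_kg_hr: float) -> float:
    """Pump flow (mL/hr) for a charted rate at the standard 0.25 U/kg/mL
    dilution; weight-independent because the dilution is [5 x weight] U in
    20 mL."""
    if rate_u_kg_hr < 0:
        raise ValidationError("insulin rate must be >= 0")
    return rate_u_kg_hr / INSULIN_DILUTION_U_PER_KG_PER_ML


def insulin_solution_concentration(weight_kg: float) -> tuple[float, float]:
    """(U/kg/mL, U/mL) of the standard dilution [5 x weight] U in 20 mL."""
    if not np.isfinite(weight_kg) or weight_kg <= 0:
        raise ValidationError("weight must be strictly positive")
    per_kg = 5.0 * weight_kg / 20.0 / weight_kg
    return per_kg, per_kg * weight_kg


def sliding_scale_rate(bg_mmol_l: float, current_rate: float) -> float:
    """Retrospective sliding-scale comparator.

    BG > 20 -> 0.1; 15-20 -> 0.075; 10-15 (excl. 15) -> 0.05; BG < 5 ->
    stop; the unprinted 5-10 band holds the current rate (clinician
    discretion in the source protocol; a hold is the neutral reading).
    Rates in U/kg/hr.
    """
    if bg_mmol_l <= 0:
        raise ValidationError("BG must be > 0")
    if current_rate < 0:
        raise ValidationError("current rate must be >= 0")
    if bg_mmol_l > 20:
        return 0.1
    if bg_mmol_l >= 15:
        return 0.075
    if bg_mmol_l >= 10:
        return 0.05
    if bg_mmol_l < 5:
        return 0.0
    return current_rate


def select_horizon(minutes_to_next_measurement: float,
                   choices=ALLOWED_HORIZONS) -> float:
    """Forecast horizon: time to the next planned measurement, rounded to
    whole hours and clamped to the 1-4 h range."""
    h = 60.0 * round(minutes_to_next_measurement / 60.0)
    return float(np.clip(h, min(choices), max(choices)))


def recommend_rate(
    state: PatientState,
    params: ModelParameters,
    model: StochasticSIModel,
    si_now: float,
    glucose: GlucoseInputProfile,
    horizon: float,
    config: ControllerConfig | None = None,
    rng=None,
) -> DoseRecommendation:
    """Select the insulin infusion rate after a BG measurement.

    Sweeps candidate rates {0, step, ..., max}; the median-forecast-closest-
    to-setpoint candidate wins (ties toward the lower rate), then the
    selection is reduced to the largest rate whose forecast 5th-percentile
    BG exceeds the safety floor.  Current BG below the target band stops
    insulin outright.  The SI percentile forecast is drawn once and shared
    across candidates, so the sweep is deterministic given the rng seed.
    """
    config = config or ControllerConfig()
    if si_now < 0:
        raise ValidationError("si_now must be >= 0")
    if horizon not in config.horizon_choices:
        raise ValidationError(f"horizon must be one of {config.horizon_choices}")

    if si_now == 0.0:
        # identification clamps SI at zero for insulin-resistant intervals;
        # condition the forecast at the smallest sensitivity the stochastic
        # model has seen (the most-resistant assumption it supports)
        si_now = float(model.support[0])
        logger.info("SI at zero clamp; conditioning at support edge %.3g", si_now)
    si_q = model.si_percentiles(si_now, (5.0, 50.0, 95.0), horizon,
                                n_paths=config.n_forecast_paths, rng=rng)
    candidates = config.candidates()
    # rows: SI p95 (-> BG p5), SI p50 (-> BG p50), SI p5 (-> BG p95)
    g = forecast_glucose(
        state.G, state.I, state.Q, params,
        si_values=np.array([si_q[2], si_q[1], si_q[0]]),
        rates=candidates, glucose=glucose, t0=state.t, horizon=horizon,
    )
    bg_p5, bg_p50, bg_p95 = g[0], g[1], g[2]

    def band_at(idx: int) -> ForecastBand:
        lo = float(min(bg_p5[idx], bg_p50[idx]))
        hi = float(max(bg_p95[idx], bg_p50[idx]))
        return ForecastBand(horizon=horizon, bg=(lo, float(bg_p50[idx]), hi),
                            si=(float(si_q[0]), float(si_q[1]), float(si_q[2])))

    if state.G < config.band_low:
        logger.info("BG %.2f below band; insulin stopped", state.G)
        return DoseRecommendation(0.0, 0.0, band_at(0), below_band_stop=True)

    sel = int(np.argmin(np.abs(bg_p50 - config.setpoint)))  # first argmin = lower rate

    feasible = bg_p5 > config.safety_floor
    if not feasible.any():
        logger.info("no candidate satisfies forecast p5 > %.1f; insulin stopped",
                    config.safety_floor)
        return DoseRecommendation(0.0, 0.0, band_at(0), safety_reduced=True)

    max_safe = int(np.max(np.nonzero(feasible)[0]))
    final = min(sel, max_safe)
    rate = float(candidates[final])
    safety_reduced = final < sel
    cap_applied = final == candidates.size - 1
    if safety_reduced:
        logger.info("safety reduction: %.3f -> %.3f U/kg/hr",
                    candidates[sel], rate)
    return DoseRecommendation(
        rate=rate,
        pump_flow_ml_hr=pump_flow(rate),
        forecast=band_at(final),
        cap_applied=cap_applied,
        safety_reduced=safety_reduced,
    )
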