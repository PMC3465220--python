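"""Glucose-insulin compartment model for premature neonates.

The model has three states: blood glucose G (mmol/L), plasma insulin I
(mU/L) and interstitial (remote-compartment) insulin Q (mU/L).  Insulin
acts on glucose disposal from the remote compartment with a
patient-specific, time-varying gain SI (the insulin sensitivity,
L/(mU.min)) — the quantity the whole control system identifies, forecasts
and doses against:

    dG/dt = -pG*G - SI*G*Q/(1 + alphaG*Q) + (P(t) + EGPnet)/(180.16*Vg)
    dI/dt = -nI*I/(1 + alphaI*I) + (u_ex(t)*1000/60 + uEn)/Vi
    dQ/dt = kIQ*(I - Q)

with P(t) the total exogenous glucose appearance (mg/kg/min, summed over
parenteral dextrose, enteral breast-milk carbohydrate and drug-carrier
dextrose), u_ex the insulin infusion (U/kg/hr), and EGPnet the net
endogenous glucose balance (hepatic production minus insulin-independent
CNS uptake, mg/kg/min).  Insulin clearance saturates through alphaI and
insulin action may saturate through alphaG.  All schedules are
piecewise-constant on right-open intervals, matching infusion-pump
semantics; the time base is minutes from enrolment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import IntegrationError, NoSteadyStateError, ValidationError
from .units import (
    EBM_CARB_MG_PER_ML,
    GLUCOSE_MOLAR_MASS,
    MAX_INSULIN_RATE,
    MG_PER_ML_PER_PCT,
    MINUTES_PER_DAY,
    MINUTES_PER_HOUR,
    MU_PER_MIN_PER_U_HR,
)

__all__ = [
    "ModelParameters",
    "PatientState",
    "NutritionEntry",
    "NutritionSchedule",
    "InsulinSchedule",
    "GlucoseInputProfile",
    "total_glucose_input",
    "simulate",
    "steady_state_glucose",
    "steady_state_insulin",
    "forecast_glucose",
    "insulin_state_path",
    "SimulationResult",
]


@dataclass(frozen=True)
class ModelParameters:
    """Compartment-model constants (per-kg formulation).

    Defaults are physiologically plausible neonatal magnitudes and are
    configuration, not ground truth: every property the package asserts is
    robust to the particular values.
    """

    pG: float = 0.003        # endogenous glucose clearance (1/min)
    alphaG: float = 0.0      # insulin-effect saturation (L/mU)
    nI: float = 0.16         # plasma insulin clearance (1/min)
    alphaI: float = 1.7e-3   # insulin-clearance saturation (L/mU)
    kIQ: float = 0.0542      # plasma->interstitial transfer (1/min)
    Vg: float = 0.6          # glucose distribution volume (L/kg)
    Vi: float = 0.045        # insulin distribution volume (L/kg)
    EGPnet: float = 2.8      # net endogenous glucose balance (mg/kg/min)
    uEn: float = 0.0         # basal endogenous insulin secretion (mU/kg/min)

    def __post_init__(self) -> None:
        for name in ("pG", "nI", "kIQ", "Vg", "Vi"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValidationError(f"ModelParameters.{name} must be strictly positive")
        for name in ("alphaG", "alphaI", "EGPnet", "uEn"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValidationError(f"ModelParameters.{name} must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown model parameters: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PatientState:
    """Instantaneous model state at time t (minutes from enrolment)."""

    t: float
    G: float          # blood glucose (mmol/L)
    I: float = 0.0    # plasma insulin (mU/L)
    Q: float = 0.0    # interstitial insulin (mU/L)

    def __post_init__(self) -> None:
        if not np.isfinite(self.G) or self.G <= 0:
            raise ValidationError("PatientState.G must be finite and > 0")
        if self.I < 0 or self.Q < 0:
            raise ValidationError("PatientState insulin states must be >= 0")


@dataclass(frozen=True)
class NutritionEntry:
    start: float                 # min
    end: float                   # min
    dex_conc_pct: float = 0.0    # parenteral dextrose concentration (% w/v)
    dex_flow_ml_hr: float = 0.0  # parenteral flow (mL/hr)
    ebm_ml_kg_day: float = 0.0   # expressed breast milk (mL/kg/day)
    carrier_conc_pct: float = 0.0
    carrier_flow_ml_hr: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("NutritionEntry end must exceed start")
        for name in ("dex_conc_pct", "carrier_conc_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 50:
                raise ValidationError(f"{name} must lie in [0, 50] %")
        for name in ("dex_flow_ml_hr", "ebm_ml_kg_day", "carrier_flow_ml_hr"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class NutritionSchedule:
    """Ordered, non-overlapping nutrition intervals."""

    entries: list[NutritionEntry]

    def __post_init__(self) -> None:
        self.entries = [
            e if isinstance(e, NutritionEntry) else NutritionEntry(*e) for e in self.entries
        ]
        for prev, nxt in zip(self.entries, self.entries[1:]):
            if nxt.start < prev.end:
                raise ValidationError("nutrition intervals must be ordered and non-overlapping")

    @property
    def span(self) -> tuple[float, float]:
        if not self.entries:
            return (0.0, 0.0)
        return (self.entries[0].start, self.entries[-1].end)


@dataclass
class InsulinSchedule:
    """Piecewise-constant insulin infusion rates on right-open intervals.

    ``rates[i]`` applies on [times[i], times[i+1]); the final rate extends
    indefinitely.  Rate 0 applies before ``times[0]``.
    """

    times: np.ndarray
    rates: np.ndarray

    def __init__(self, times: Sequence[float], rates: Sequence[float]):
        self.times = np.asarray(times, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.rates.shape:
            raise ValidationError("insulin schedule times/rates must be 1-D and equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("insulin schedule times must be strictly increasing")
        if np.any(self.rates < 0) or np.any(self.rates > MAX_INSULIN_RATE + 1e-12):
            raise ValidationError(
                f"insulin rates must lie in [0, {MAX_INSULIN_RATE}] U/kg/hr"
            )

    def rate_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.rates[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)

    def with_change(self, t: float, rate: float) -> "InsulinSchedule":
        """Return a new schedule with ``rate`` applying from time ``t``."""
        keep = self.times < t
        return InsulinSchedule(
            np.append(self.times[keep], t), np.append(self.rates[keep], rate)
        )


@dataclass
class GlucoseInputProfile:
    """Total exogenous glucose appearance rate P(t) as a step function.

    ``starts[i]`` opens segment i (right-open); the last segment extends
    indefinitely; P = 0 before ``starts[0]``.  The per-source breakdown
    (parenteral, EBM, carrier) sums exactly to the total.
    """

    starts: np.ndarray
    parenteral: np.ndarray   # mg/kg/min
    ebm: np.ndarray          # mg/kg/min
    carrier: np.ndarray      # mg/kg/min

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        for name in ("parenteral", "ebm", "carrier"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.starts.shape:
                raise ValidationError("glucose profile component shape mismatch")
            if np.any(arr < 0):
                raise ValidationError(f"glucose input component {name} must be >= 0")
        if self.starts.size == 0:
            raise ValidationError("glucose profile needs at least one segment")
        if np.any(np.diff(self.starts) <= 0):
            raise ValidationError("glucose profile starts must be strictly increasing")

    @property
    def total(self) -> np.ndarray:
        return self.parenteral + self.ebm + self.carrier

    def _index(self, t) -> np.ndarray:
        return np.searchsorted(self.starts, np.asarray(t, dtype=float), side="right") - 1

    def total_at(self, t):
        idx = self._index(t)
        out = np.where(idx >= 0, self.total[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)

    def components_at(self, t) -> dict[str, np.ndarray]:
        idx = self._index(t)

        def pick(arr):
            out = np.where(idx >= 0, arr[np.clip(idx, 0, None)], 0.0)
            return out if out.ndim else float(out)

        return {"parenteral": pick(self.parenteral), "ebm": pick(self.ebm),
                "carrier": pick(self.carrier)}

    @classmethod
    def constant(cls, p_mg_kg_min: float, t0: float = 0.0) -> "GlucoseInputProfile":
        return cls(np.array([t0]), np.array([float(p_mg_kg_min)]),
                   np.zeros(1), np.zeros(1))


def total_glucose_input(
    nutrition: NutritionSchedule,
    weight_kg: float,
    ebm_carb_mg_per_ml: float = EBM_CARB_MG_PER_ML,
) -> GlucoseInputProfile:
    """Convert a nutrition schedule into a glucose appearance profile.

    Parenteral and drug-carrier dextrose: conc % x 10 mg/mL x flow mL/hr
    / weight / 60 -> mg/kg/min.  Expressed breast milk: mL/kg/day x
    carbohydrate mg/mL / 1440 -> mg/kg/min.  Gaps between nutrition
    entries contribute zero.
    """
    if not np.isfinite(weight_kg) or weight_kg <= 0:
        raise ValidationError("weight must be strictly positive")
    if not nutrition.entries:
        raise ValidationError("empty nutrition schedule")

    starts, par, ebm, car = [], [], [], []

    def push(t, p, e, c):
        if starts and starts[-1] == t:
            par[-1], ebm[-1], car[-1] = p, e, c
            return
        starts.append(t)
        par.append(p)
        ebm.append(e)
        car.append(c)

    for entry in nutrition.entries:
        p = entry.dex_conc_pct * MG_PER_ML_PER_PCT * entry.dex_flow_ml_hr / weight_kg / MINUTES_PER_HOUR
        e = entry.ebm_ml_kg_day * ebm_carb_mg_per_ml / MINUTES_PER_DAY
        c = entry.carrier_conc_pct * MG_PER_ML_PER_PCT * entry.carrier_flow_ml_hr / weight_kg / MINUTES_PER_HOUR
        push(entry.start, p, e, c)
        push(entry.end, 0.0, 0.0, 0.0)

    return GlucoseInputProfile(np.array(starts), np.array(par), np.array(ebm), np.array(car))


# ---------------------------------------------------------------------------
# forward simulation


@dataclass
class SimulationResult:
    """Trajectory of PatientState on a regular output grid."""

    t: np.ndarray
    G: np.ndarray
    I: np.ndarray
    Q: np.ndarray

    def state_at_end(self) -> PatientState:
        return PatientState(float(self.t[-1]), float(self.G[-1]),
                            float(self.I[-1]), float(self.Q[-1]))

    def states(self) -> list[PatientState]:
        return [PatientState(float(t), float(g), float(i), float(q))
                for t, g, i, q in zip(self.t, self.G, self.I, self.Q)]

    def plot(self, ax=None):
        """Plot G with insulin compartments on a twin axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t / 60.0, self.G, label="BG (mmol/L)")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("BG (mmol/L)")
        ax2 = ax.twinx()
        ax2.plot(self.t / 60.0, self.Q, color="C1", alpha=0.6, label="Q (mU/L)")
        ax2.set_ylabel("interstitial insulin (mU/L)")
        return ax


class _SILookup:
    """Normalize a constant or SITrace-like object into value/edges access."""

    def __init__(self, si, t0: float, t1: float):
        if np.isscalar(si):
            if si < 0:
                raise ValidationError("constant SI must be >= 0")
            self._const = float(si)
            self.edges = np.array([])
        else:
            self._const = None
            lo, hi = si.span
            if lo > t0 + 1e-9 or hi < t1 - 1e-9:
                raise ValidationError(
                    f"SI trace covers [{lo}, {hi}] but horizon is [{t0}, {t1}]"
                )
            self._trace = si
            self.edges = np.asarray(si.edges, dtype=float)

    def value_at(self, t: float) -> float:
        if self._const is not None:
            return self._const
        return float(self._trace.value_at(t))


def _rhs(t, y, p: ModelParameters, si_val: float, u: float, P: float):
    G, I, Q = y
    Qp = max(Q, 0.0)
    Ip = max(I, 0.0)
    dG = (-p.pG * G - si_val * G * Qp / (1.0 + p.alphaG * Qp)
          + (P + p.EGPnet) / (GLUCOSE_MOLAR_MASS * p.Vg))
    dI = -p.nI * Ip / (1.0 + p.alphaI * Ip) + (u * MU_PER_MIN_PER_U_HR + p.uEn) / p.Vi
    dQ = p.kIQ * (Ip - Qp)
    return (dG, dI, dQ)


def simulate(
    state0: PatientState,
    params: ModelParameters,
    si,
    insulin: InsulinSchedule,
    glucose: GlucoseInputProfile,
    duration: float,
    step: float = 1.0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> SimulationResult:
    """Integrate the compartment model over ``duration`` minutes.

    ``si`` is a constant (L/(mU.min)) or an SITrace covering the horizon.
    Integration is adaptive (LSODA, mildly stiff at high nI) and segmented
    at every discontinuity of the piecewise-constant inputs so the
    integrator never steps across a jump.  Output states are reported at
    t0, t0+step, ..., t0+duration.  States are clamped at zero with a
    warning if the integrator undershoots.
    """
    if duration <= 0 or step <= 0:
        raise ValidationError("duration and step must be > 0")
    t0 = state0.t
    t_end = t0 + duration
    lookup = _SILookup(si, t0, t_end)

    out_t = float(t0) + float(step) * np.arange(int(round(duration / step)) + 1,
                                                dtype=float)
    out_t = out_t[out_t <= t_end + 1e-9]
    if out_t[-1] < t_end - 1e-9:
        out_t = np.append(out_t, t_end)

    breaks = np.concatenate([
        [t0, t_end],
        insulin.times,
        glucose.starts,
        lookup.edges,
    ])
    breaks = np.unique(breaks[(breaks > t0 + 1e-9) & (breaks < t_end - 1e-9)])
    if breaks.size:
        # merge breakpoints closer than 1e-9 min: zero-length segments from
        # floating-point coincidences make LSODA reject the span
        breaks = breaks[np.concatenate([[True], np.diff(breaks) > 1e-9])]
    seg_edges = np.concatenate([[t0], breaks, [t_end]])

    y = np.array([state0.G, state0.I, state0.Q], dtype=float)
    G_out = np.empty_like(out_t)
    I_out = np.empty_like(out_t)
    Q_out = np.empty_like(out_t)
    G_out[0], I_out[0], Q_out[0] = y

    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        mid = 0.5 * (a + b)
        si_val = lookup.value_at(mid)
        u = float(insulin.rate_at(mid))
        P = float(glucose.total_at(mid))
        sol = solve_ivp(
            _rhs, (a, b), y, method="LSODA", rtol=rtol, atol=atol,
            dense_output=True, args=(params, si_val, u, P),
        )
        if not sol.success:
            raise IntegrationError(f"integration failed on [{a}, {b}]: {sol.message}")
        mask = (out_t > a + 1e-12) & (out_t <= b + 1e-12)
        if mask.any():
            vals = sol.sol(np.clip(out_t[mask], a, b))
            G_out[mask], I_out[mask], Q_out[mask] = vals
        y = sol.y[:, -1]
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state at t={b}: {y}")

    for name, arr in (("G", G_out), ("I", I_out), ("Q", Q_out)):
        if not np.all(np.isfinite(arr)):
            raise IntegrationError(f"non-finite {name} in simulation output")
        neg = arr < 0
        if neg.any():
            if arr[neg].min() < -1e-7:
                warnings.warn(
                    f"simulated {name} undershot zero (min {arr[neg].min():.3g}); clamped",
                    RuntimeWarning,
                    stacklevel=2,
                )
            np.clip(arr, 0.0, None, out=arr)

    return SimulationResult(out_t, G_out, I_out, Q_out)


# ---------------------------------------------------------------------------
# steady states


def steady_state_insulin(
    params: ModelParameters, rate_u_kg_hr: float
) -> tuple[float, float]:
    """Steady-state (I*, Q*) for a constant infusion rate.

    Solves nI*I/(1+alphaI*I) = c with c the total insulin appearance
    (mU/L/min).  Raises NoSteadyStateError when the saturating clearance
    cannot match the input (c >= nI/alphaI).
    """
    if rate_u_kg_hr < 0:
        raise ValidationError("insulin rate must be >= 0")
    c = (rate_u_kg_hr * MU_PER_MIN_PER_U_HR + params.uEn) / params.Vi
    if c == 0:
        return (0.0, 0.0)
    denom = params.nI - c * params.alphaI
    if denom <= 0:
        raise NoSteadyStateError(
            "insulin input exceeds saturating clearance capacity; no steady state"
        )
    i_star = c / denom
    return (i_star, i_star)


def steady_state_glucose(
    params: ModelParameters,
    si: float,
    rate_u_kg_hr: float,
    p_mg_kg_min: float,
) -> float:
    """Glucose steady state G* with I, Q at their own steady states.

    G* = (P + EGPnet) / (180.16 * Vg * (pG + SI*Q*/(1+alphaG*Q*))).
    """
    if si < 0 or p_mg_kg_min < 0:
        raise ValidationError("SI and P must be >= 0")
    _, q_star = steady_state_insulin(params, rate_u_kg_hr)
    clearance = params.pG + si * q_star / (1.0 + params.alphaG * q_star)
    if clearance <= 0:
        raise NoSteadyStateError("total glucose clearance is zero; no positive root")
    return (p_mg_kg_min + params.EGPnet) / (GLUCOSE_MOLAR_MASS * params.Vg * clearance)


# ---------------------------------------------------------------------------
# fast fixed-grid paths used by identification and the dosing sweep


def insulin_state_path(
    params: ModelParameters,
    insulin: InsulinSchedule,
    t_start: float,
    t_end: float,
    I0: float = 0.0,
    Q0: float = 0.0,
    dt: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the insulin cascade (independent of G and SI) on a fixed
    grid with classical RK4, segmenting at schedule changes.

    Returns (t, I, Q) with t spanning [t_start, t_end]; grid spacing is at
    most ``dt`` and every schedule breakpoint is a grid node.
    """
    if t_end <= t_start:
        raise ValidationError("t_end must exceed t_start")
    breaks = insulin.times[(insulin.times > t_start) & (insulin.times < t_end)]
    edges = np.concatenate([[t_start], breaks, [t_end]])

    ts = [np.array([t_start])]
    for a, b in zip(edges[:-1], edges[1:]):
        n = max(1, int(np.ceil((b - a) / dt)))
        ts.append(a + (b - a) * (np.arange(1, n + 1) / n))
    t = np.concatenate(ts)

    I = np.empty_like(t)
    Q = np.empty_like(t)
    I[0], Q[0] = I0, Q0

    ci = params.nI
    ai = params.alphaI
    kq = params.kIQ

    def f(i, q, c):
        di = -ci * i / (1.0 + ai * i) + c
        dq = kq * (i - q)
        return di, dq

    for k in range(t.size - 1):
        h = t[k + 1] - t[k]
        u = float(insulin.rate_at(0.5 * (t[k] + t[k + 1])))
        c = (u * MU_PER_MIN_PER_U_HR + params.uEn) / params.Vi
        i0, q0 = I[k], Q[k]
        k1i, k1q = f(i0, q0, c)
        k2i, k2q = f(i0 + 0.5 * h * k1i, q0 + 0.5 * h * k1q, c)
        k3i, k3q = f(i0 + 0.5 * h * k2i, q0 + 0.5 * h * k2q, c)
        k4i, k4q = f(i0 + h * k3i, q0 + h * k3q, c)
        I[k + 1] = i0 + h / 6.0 * (k1i + 2 * k2i + 2 * k3i + k4i)
        Q[k + 1] = q0 + h / 6.0 * (k1q + 2 * k2q + 2 * k3q + k4q)

    return t, np.clip(I, 0.0, None), np.clip(Q, 0.0, None)


def forecast_glucose(
    G0: float,
    I0: float,
    Q0: float,
    params: ModelParameters,
    si_values: np.ndarray,
    rates: np.ndarray,
    glucose: GlucoseInputProfile,
    t0: float,
    horizon: float,
    dt: float = 0.5,
    return_path: bool = False,
):
    """Glucose at ``t0 + horizon`` for a grid of SI values x candidate
    constant insulin rates.

    Exploits the model structure: the insulin cascade is independent of G
    and SI, so (I, Q) is integrated once per candidate rate (vectorized
    RK4), and the G equation — linear in G for fixed SI — is solved with an
    exponential (integrating-factor) scheme that is unconditionally stable
    and keeps G positive.

    ``si_values`` may be shape (n_si,) for SI held constant over the
    horizon, or (n_si, n_t) for SI given at every grid node (Monte-Carlo
    paths).  Returns array (n_si, n_rates), or (n_si, n_rates, n_t) with
    ``return_path``.
    """
    si_values = np.atleast_1d(np.asarray(si_values, dtype=float))
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates < 0):
        raise ValidationError("candidate insulin rates must be >= 0")
    if np.any(si_values < 0):
        raise ValidationError("SI values must be >= 0")
    n_steps = max(1, int(round(horizon / dt)))
    t = t0 + horizon * np.arange(n_steps + 1) / n_steps
    h = horizon / n_steps

    # vectorized RK4 for the insulin cascade, one column per candidate rate
    c = (rates * MU_PER_MIN_PER_U_HR + params.uEn) / params.Vi
    I = np.full(rates.shape, float(I0))
    Q = np.full(rates.shape, float(Q0))
    Qpath = np.empty((rates.size, n_steps + 1))
    Qpath[:, 0] = Q
    ci, ai, kq = params.nI, params.alphaI, params.kIQ

    def f(i, q):
        return (-ci * i / (1.0 + ai * i) + c, kq * (i - q))

    for k in range(n_steps):
        k1i, k1q = f(I, Q)
        k2i, k2q = f(I + 0.5 * h * k1i, Q + 0.5 * h * k1q)
        k3i, k3q = f(I + 0.5 * h * k2i, Q + 0.5 * h * k2q)
        k4i, k4q = f(I + h * k3i, Q + h * k3q)
        I = I + h / 6.0 * (k1i + 2 * k2i + 2 * k3i + k4i)
        Q = Q + h / 6.0 * (k1q + 2 * k2q + 2 * k3q + k4q)
        Qpath[:, k + 1] = Q

    np.clip(Qpath, 0.0, None, out=Qpath)
    qeff = Qpath / (1.0 + params.alphaG * Qpath)          # (n_rates, n_t)
    kappa = (np.asarray(glucose.total_at(t)) + params.EGPnet) / (
        GLUCOSE_MOLAR_MASS * params.Vg
    )                                                     # (n_t,)

    if si_values.ndim == 1:
        a = params.pG + si_values[:, None, None] * qeff[None, :, :]
    else:
        if si_values.shape[1] != n_steps + 1:
            raise ValidationError("SI path must be given at every grid node")
        a = params.pG + si_values[:, None, :] * qeff[None, :, :]

    # exponential per-step update: G_{k+1} = e^{-dA}(G_k + h/2 kappa_k) + h/2 kappa_{k+1}
    G = np.full(a.shape[:2], float(G0))
    if return_path:
        Gpath = np.empty(a.shape)
        Gpath[..., 0] = G
    for k in range(n_steps):
        dA = 0.5 * h * (a[..., k] + a[..., k + 1])
        G = np.exp(-dA) * (G + 0.5 * h * kappa[k]) + 0.5 * h * kappa[k + 1]
        if return_path:
            Gpath[..., k + 1] = G

    return Gpath if return_path else G
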