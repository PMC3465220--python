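"""Stochastic insulin-sensitivity transition model and forecast bands.

Hourly transition pairs (SI_n, SI_{n+1}) pooled across patients define an
empirical conditional distribution of next-hour insulin sensitivity given
the current value.  The estimator uses product-Gaussian kernels on the
(log level, log hourly ratio) plane:

    x_i = ln SI_n,   r_i = ln(SI_{n+1} / SI_n)

with a Silverman bandwidth on each of those marginals.  Working in the
level x ratio parametrization (rather than level x level) matters: the
hour-to-hour conditional spread of SI is an order of magnitude smaller
than the between-patient spread of SI levels, so bandwidths set on the
level marginals would inflate the forecast bands well past their nominal
coverage.  The ratio marginal has exactly the conditional scale, and the
conditioning kernel on ln SI_n still captures any dependence of glycemic
volatility on the sensitivity level.

Conditional CDFs are tabulated on a (level grid x ratio grid) matrix;
percentile lookups interpolate this table, one-hour forecasts read it
directly, and multi-hour forecasts iterate hourly transitions by seeded
Monte-Carlo.  Blood-glucose bands use the monotone coupling of BG with SI:
the q-th BG percentile is obtained by simulating with the (100-q)-th SI
percentile held constant over the horizon (more sensitivity, more glucose
disposal, lower glucose).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import InsufficientDataError, ValidationError
from .model import (
    GlucoseInputProfile,
    ModelParameters,
    PatientState,
    forecast_glucose,
)

__all__ = ["StochasticSIModel", "ForecastBand", "forecast_si", "forecast_bg",
           "ALLOWED_HORIZONS"]

ALLOWED_HORIZONS = (60.0, 120.0, 180.0, 240.0)

MIN_TRANSITION_PAIRS = 50

SCHEMA_VERSION = 1


def _silverman(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a 1-D Gaussian KDE."""
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        scale = sd
    return 0.9 * scale * n ** (-0.2)


@dataclass(frozen=True)
class ForecastBand:
    """Percentile envelope of a forecast at a given horizon."""

    horizon: float                        # min
    bg: tuple[float, float, float]        # (p5, p50, p95) mmol/L
    si: tuple[float, float, float]        # (p5, p50, p95) L/(mU.min)

    def __post_init__(self) -> None:
        if not (self.bg[0] <= self.bg[1] + 1e-12 and self.bg[1] <= self.bg[2] + 1e-12):
            raise ValidationError(f"BG percentiles not ordered: {self.bg}")
        if not (self.si[0] <= self.si[1] + 1e-15 and self.si[1] <= self.si[2] + 1e-15):
            raise ValidationError(f"SI percentiles not ordered: {self.si}")

    def to_dict(self) -> dict:
        return {
            "horizon_min": self.horizon,
            "bg_mmol_L": {"p5": self.bg[0], "p50": self.bg[1], "p95": self.bg[2]},
            "si_L_per_mU_min": {"p5": self.si[0], "p50": self.si[1], "p95": self.si[2]},
        }


class StochasticSIModel:
    """Kernel-estimated conditional distribution of next-hour SI."""

    def __init__(
        self,
        pairs: np.ndarray,
        bandwidth_scale: float = 1.0,
        n_level_grid: int = 120,
        n_ratio_grid: int = 120,
    ):
        pairs = np.asarray(pairs, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValidationError("pairs must have shape (n, 2)")
        if pairs.shape[0] < MIN_TRANSITION_PAIRS:
            raise InsufficientDataError(
                f"need >= {MIN_TRANSITION_PAIRS} hourly transition pairs; got "
                f"{pairs.shape[0]} — augment with synthetic cohort traces"
            )
        if np.any(pairs <= 0):
            raise ValidationError("SI transition pairs must be strictly positive")
        self.pairs = pairs
        self.bandwidth_scale = float(bandwidth_scale)
        self._n_level_grid = int(n_level_grid)
        self._n_ratio_grid = int(n_ratio_grid)
        self._build()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_pairs(cls, pairs, **kwargs) -> "StochasticSIModel":
        return cls(np.asarray(pairs, dtype=float), **kwargs)

    @classmethod
    def from_traces(cls, traces: Sequence, **kwargs) -> "StochasticSIModel":
        """Pool hourly transition pairs from SITrace-like objects."""
        xs, ys = [], []
        for tr in traces:
            hourly = np.asarray(tr.hourly_values() if hasattr(tr, "hourly_values") else tr,
                                dtype=float)
            if hourly.size >= 2:
                xs.append(hourly[:-1])
                ys.append(hourly[1:])
        if not xs:
            raise InsufficientDataError("no hourly transition pairs in traces")
        pairs = np.column_stack([np.concatenate(xs), np.concatenate(ys)])
        pairs = pairs[(pairs > 0).all(axis=1)]
        return cls(pairs, **kwargs)

    def _build(self) -> None:
        lx = np.log(self.pairs[:, 0])
        lr = np.log(self.pairs[:, 1] / self.pairs[:, 0])
        self._lx, self._lr = lx, lr

        self.h_level = max(_silverman(lx) * self.bandwidth_scale, 1e-9)
        self.h_ratio = max(_silverman(lr) * self.bandwidth_scale, 1e-9)
        self.degenerate = float(np.std(lr)) < 1e-12

        self.level_grid = np.linspace(lx.min(), lx.max(), self._n_level_grid)

        span_lo = lr.min() - 8.0 * self.h_ratio
        span_hi = lr.max() + 8.0 * self.h_ratio
        # keep the grid fine relative to the kernel so quadrature is exact
        n_r = int(max(self._n_ratio_grid,
                      min(2000, np.ceil((span_hi - span_lo) / (0.5 * self.h_ratio)))))
        self.ratio_grid = np.linspace(span_lo, span_hi, n_r)

        # conditional density/CDF of the log-ratio on the level grid
        w = np.exp(-0.5 * ((self.level_grid[:, None] - lx[None, :]) / self.h_level) ** 2)
        w /= w.sum(axis=1, keepdims=True)
        kern = np.exp(-0.5 * ((self.ratio_grid[:, None] - lr[None, :]) / self.h_ratio) ** 2)
        kern /= np.sqrt(2.0 * np.pi) * self.h_ratio
        dens = w @ kern.T                                   # (n_level, n_ratio)

        from scipy.integrate import cumulative_trapezoid

        cdf = cumulative_trapezoid(dens, self.ratio_grid, axis=1, initial=0.0)
        self._norm = cdf[:, -1].copy()
        cdf /= cdf[:, -1][:, None]
        self._cdf = cdf
        self._dens = dens / self._norm[:, None]

    # -- introspection / invariants ----------------------------------------

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    @property
    def support(self) -> tuple[float, float]:
        """Observed SI conditioning range."""
        return (float(np.exp(self._lx.min())), float(np.exp(self._lx.max())))

    def conditional_density(self, si_now: float, si_next: np.ndarray) -> np.ndarray:
        """Conditional density p(SI_{n+1} | SI_n) evaluated at ``si_next``."""
        si_next = np.asarray(si_next, dtype=float)
        row = self._row(si_now, self._dens)
        lr = np.log(si_next / si_now)
        d_lr = np.interp(lr, self.ratio_grid, row, left=0.0, right=0.0)
        return d_lr / si_next   # change of variables ln-ratio -> level

    def normalization(self, si_now: float) -> float:
        """Integral of the conditional density over its support (=1)."""
        row = self._row(si_now, self._dens)
        return float(np.trapezoid(row, self.ratio_grid))

    # -- lookup -------------------------------------------------------------

    def _row(self, si_now: float, table: np.ndarray) -> np.ndarray:
        if si_now <= 0:
            raise ValidationError("si_now must be > 0")
        lx = np.log(si_now)
        lo, hi = self.level_grid[0], self.level_grid[-1]
        if lx < lo - 1e-12 or lx > hi + 1e-12:
            warnings.warn(
                f"SI {si_now:.3g} outside model support {self.support}; "
                "conditioning at nearest support edge",
                RuntimeWarning,
                stacklevel=3,
            )
            lx = np.clip(lx, lo, hi)
        j = np.searchsorted(self.level_grid, lx)
        j = int(np.clip(j, 1, self.level_grid.size - 1))
        f = (lx - self.level_grid[j - 1]) / (self.level_grid[j] - self.level_grid[j - 1])
        return (1.0 - f) * table[j - 1] + f * table[j]

    def percentiles_1h(self, si_now: float, percentiles: Sequence[float]) -> np.ndarray:
        """SI percentiles one transition ahead, read from the conditional CDF."""
        cdf = self._row(si_now, self._cdf)
        q = np.asarray(percentiles, dtype=float) / 100.0
        lr_q = np.interp(q, cdf, self.ratio_grid)
        return si_now * np.exp(lr_q)

    def sample_step(self, si: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One hourly transition, inverse-CDF sampled per path (vectorized)."""
        si = np.asarray(si, dtype=float)
        lx = np.clip(np.log(si), self.level_grid[0], self.level_grid[-1])
        j = np.clip(np.searchsorted(self.level_grid, lx), 1, self.level_grid.size - 1)
        f = (lx - self.level_grid[j - 1]) / (self.level_grid[j] - self.level_grid[j - 1])
        cdf = (1.0 - f[:, None]) * self._cdf[j - 1] + f[:, None] * self._cdf[j]
        u = rng.uniform(size=si.size)
        k = np.clip((cdf < u[:, None]).sum(axis=1), 1, self.ratio_grid.size - 1)
        rows = np.arange(si.size)
        c0, c1 = cdf[rows, k - 1], cdf[rows, k]
        frac = np.where(c1 > c0, (u - c0) / np.where(c1 > c0, c1 - c0, 1.0), 0.0)
        lr = self.ratio_grid[k - 1] + frac * (self.ratio_grid[k] - self.ratio_grid[k - 1])
        return si * np.exp(lr)

    def si_percentiles(
        self,
        si_now: float,
        percentiles: Sequence[float],
        horizon: float,
        n_paths: int = 1000,
        rng: np.random.Generator | int | None = None,
    ) -> np.ndarray:
        """SI percentiles ``horizon`` minutes ahead.

        One hour reads the conditional CDF directly; longer horizons
        iterate hourly transitions with seeded Monte-Carlo (``n_paths``).
        """
        if horizon not in ALLOWED_HORIZONS:
            raise ValidationError(f"horizon must be one of {ALLOWED_HORIZONS} min")
        steps = int(round(horizon / 60.0))
        if steps == 1:
            return self.percentiles_1h(si_now, percentiles)
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        si = np.full(n_paths, float(si_now))
        for _ in range(steps):
            si = self.sample_step(si, rng)
        return np.percentile(si, np.asarray(percentiles, dtype=float))

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Persist as JSON (pairs + bandwidth/grid settings; the tables are
        rebuilt deterministically on load)."""
        payload = {
            "schema_version": SCHEMA_VERSION,
            "kind": "neoglyc-stochastic-si-model",
            "bandwidth_scale": self.bandwidth_scale,
            "n_level_grid": self._n_level_grid,
            "n_ratio_grid": self._n_ratio_grid,
            "pairs": self.pairs.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "StochasticSIModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("kind") != "neoglyc-stochastic-si-model":
            raise ValidationError(f"{path} is not a stochastic SI model archive")
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported schema version {payload.get('schema_version')}"
            )
        return cls(
            np.asarray(payload["pairs"], dtype=float),
            bandwidth_scale=payload["bandwidth_scale"],
            n_level_grid=payload["n_level_grid"],
            n_ratio_grid=payload["n_ratio_grid"],
        )

    def __repr__(self) -> str:
        lo, hi = self.support
        return (f"StochasticSIModel({self.n_pairs} pairs, support "
                f"[{lo:.2e}, {hi:.2e}] L/(mU.min))")


def forecast_si(
    model: StochasticSIModel,
    si_now: float,
    horizon: float,
    percentiles: Sequence[float] = (5.0, 50.0, 95.0),
    n_paths: int = 1000,
    rng=None,
) -> np.ndarray:
    """Functional wrapper around :meth:`StochasticSIModel.si_percentiles`."""
    return model.si_percentiles(si_now, percentiles, horizon, n_paths=n_paths, rng=rng)


def forecast_bg(
    state: PatientState,
    params: ModelParameters,
    model: StochasticSIModel,
    si_now: float,
    rate_u_kg_hr: float,
    glucose: GlucoseInputProfile,
    horizon: float,
    n_paths: int = 1000,
    rng=None,
) -> ForecastBand:
    """Percentile band of BG at the horizon for one candidate insulin rate.

    BG percentile q is simulated with the (100-q)-th SI percentile held
    constant over the horizon (monotone coupling); the band therefore
    collapses to the deterministic endpoint when the SI distribution is
    degenerate.
    """
    si_q = model.si_percentiles(si_now, (5.0, 50.0, 95.0), horizon,
                                n_paths=n_paths, rng=rng)
    # BG p5 <- SI p95, BG p50 <- SI p50, BG p95 <- SI p5
    g = forecast_glucose(
        state.G, state.I, state.Q, params,
        si_values=np.array([si_q[2], si_q[1], si_q[0]]),
        rates=np.array([rate_u_kg_hr]),
        glucose=glucose, t0=state.t, horizon=horizon,
    )[:, 0]
    bg = (float(min(g[0], g[1])), float(g[1]), float(max(g[1], g[2])))
    return ForecastBand(horizon=horizon, bg=bg,
                        si=(float(si_q[0]), float(si_q[1]), float(si_q[2])))
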