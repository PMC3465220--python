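"""Cohort evaluation metrics for glycemic-control trials.

Measurements are resampled to hourly estimates by linear interpolation, so
time-in-band percentages are comparable across cohorts with different
measurement frequencies.  Band conventions (fixed so comparisons are
internally consistent): printed bands are closed on both endpoints
([4.0, 7.0], [4.0, 8.0] mmol/L), exceedance and hypoglycemia thresholds are
strict (> 10, < 4, < 3, < 2.7 mmol/L), and medians/IQRs use linear
interpolation between order statistics.  Whole-cohort percentages pool the
hourly values across patients (duration-weighted); per-patient summaries
are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError
from .identify import BGMeasurement, SITrace

__all__ = [
    "BandStatistics",
    "TrialSummary",
    "CohortComparison",
    "hourly_resample",
    "band_statistics",
    "si_spread",
    "compare_cohorts",
    "summarize_trial",
]

HYPO_THRESHOLD = 2.7   # mmol/L
HYPER_THRESHOLD = 10.0


def hourly_resample(measurements) -> tuple[np.ndarray, np.ndarray]:
    """Hourly BG estimates by linear interpolation between measurements.

    Accepts a sequence of BGMeasurement or (t_min, value) pairs.  Returns
    (hours_min, values) at integer hours h with t_first < h <= t_last; no
    extrapolation beyond either end.
    """
    if len(measurements) < 2:
        raise InsufficientDataError("hourly resampling needs >= 2 measurements")
    if isinstance(measurements[0], BGMeasurement):
        t = np.array([m.t for m in measurements], dtype=float)
        v = np.array([m.value for m in measurements], dtype=float)
    else:
        arr = np.asarray(measurements, dtype=float)
        t, v = arr[:, 0], arr[:, 1]
    if np.any(np.diff(t) <= 0):
        raise ValidationError("measurement times must be strictly increasing")
    hours = np.arange(np.floor(t[0] / 60.0) + 1, np.floor(t[-1] / 60.0) + 1) * 60.0
    hours = hours[(hours > t[0]) & (hours <= t[-1])]
    return hours, np.interp(hours, t, v)


@dataclass(frozen=True)
class BandStatistics:
    """Band percentages and distribution summary of one hourly BG series."""

    n_hours: int
    median: float
    iqr: tuple[float, float]
    pct_in_4_7: float
    pct_in_4_8: float
    pct_gt_10: float
    pct_lt_4: float
    pct_lt_3: float
    pct_lt_2_7: float

    def __post_init__(self) -> None:
        pcts = [self.pct_in_4_7, self.pct_in_4_8, self.pct_gt_10,
                self.pct_lt_4, self.pct_lt_3, self.pct_lt_2_7]
        if any(not 0 <= p <= 100 for p in pcts):
            raise ValidationError("band percentages must lie in [0, 100]")
        if self.pct_in_4_7 > self.pct_in_4_8 + 1e-9:
            raise ValidationError("band nesting violated: %4-7 > %4-8")
        if not self.pct_lt_2_7 <= self.pct_lt_3 + 1e-9 <= self.pct_lt_4 + 2e-9:
            raise ValidationError("hypoglycemia nesting violated")

    def to_dict(self) -> dict:
        return {
            "n_hours": self.n_hours,
            "bg_median_mmol_L": self.median,
            "bg_iqr_mmol_L": list(self.iqr),
            "pct_bg_4_0_to_7_0": self.pct_in_4_7,
            "pct_bg_4_0_to_8_0": self.pct_in_4_8,
            "pct_bg_gt_10": self.pct_gt_10,
            "pct_bg_lt_4_0": self.pct_lt_4,
            "pct_bg_lt_3_0": self.pct_lt_3,
            "pct_bg_lt_2_7": self.pct_lt_2_7,
        }


def band_statistics(values) -> BandStatistics:
    """Compute band percentages over an hourly BG series."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("empty series")
    pct = lambda mask: 100.0 * float(np.count_nonzero(mask)) / v.size  # noqa: E731
    return BandStatistics(
        n_hours=int(v.size),
        median=float(np.median(v)),
        iqr=(float(np.percentile(v, 25)), float(np.percentile(v, 75))),
        pct_in_4_7=pct((v >= 4.0) & (v <= 7.0)),
        pct_in_4_8=pct((v >= 4.0) & (v <= 8.0)),
        pct_gt_10=pct(v > HYPER_THRESHOLD),
        pct_lt_4=pct(v < 4.0),
        pct_lt_3=pct(v < 3.0),
        pct_lt_2_7=pct(v < HYPO_THRESHOLD),
    )


def si_spread(per_patient_median_si) -> float:
    """Ratio of the 95th to 5th percentile of per-patient median SI
    (the cohort's 90 % sensitivity-spread statistic)."""
    m = np.asarray(per_patient_median_si, dtype=float)
    if m.size < 2:
        raise InsufficientDataError("si_spread needs >= 2 patients")
    lo, hi = np.percentile(m, [5, 95])
    if lo <= 0:
        raise ValidationError("5th percentile of median SI is not positive")
    return float(hi / lo)


@dataclass
class TrialSummary:
    """Whole-cohort and per-patient trial metrics."""

    n_patients: int
    total_hours: float
    n_measurements: int
    pooled: BandStatistics
    insulin_median: float                   # U/kg/hr, pooled hourly
    insulin_iqr: tuple[float, float]
    glucose_rate_median: float              # mg/kg/min, pooled hourly
    meas_interval_median_h: float
    si_median: float | None
    si_iqr: tuple[float, float] | None
    si_spread_ratio: float | None
    per_patient: pd.DataFrame               # one row per patient
    hourly_series: list = field(default_factory=list, repr=False)
    hypo_event_hours: int = 0

    def to_dict(self) -> dict:
        out = {
            "n_patients": self.n_patients,
            "total_hours": self.total_hours,
            "n_bg_measurements": self.n_measurements,
            **self.pooled.to_dict(),
            "insulin_median_U_kg_hr": self.insulin_median,
            "insulin_iqr_U_kg_hr": list(self.insulin_iqr),
            "glucose_rate_median_mg_kg_min": self.glucose_rate_median,
            "meas_interval_median_h": self.meas_interval_median_h,
            "per_patient_medians": {
                c: float(self.per_patient[c].median()) for c in self.per_patient.columns
                if self.per_patient[c].dtype.kind == "f"
            },
        }
        if self.si_median is not None:
            out["si_median_L_per_mU_min"] = self.si_median
            out["si_iqr_L_per_mU_min"] = list(self.si_iqr)
            out["si_spread_90pct_range_ratio"] = self.si_spread_ratio
        return out

    def to_markdown(self) -> str:
        d = self.pooled
        rows = [
            ("Number of episodes", f"{self.n_patients}"),
            ("Total hours", f"{self.total_hours:.0f}"),
            ("Number of BG measurements", f"{self.n_measurements}"),
            ("BG median [IQR] (mmol/L)",
             f"{d.median:.1f} [{d.iqr[0]:.1f} - {d.iqr[1]:.1f}]"),
            ("% BG within 4.0 - 7.0 mmol/L", f"{d.pct_in_4_7:.1f}"),
            ("% BG within 4.0 - 8.0 mmol/L", f"{d.pct_in_4_8:.1f}"),
            ("% BG > 10 mmol/L", f"{d.pct_gt_10:.1f}"),
            ("% BG < 4.0 mmol/L", f"{d.pct_lt_4:.1f}"),
            ("% BG < 3.0 mmol/L", f"{d.pct_lt_3:.1f}"),
            ("% BG < 2.7 mmol/L", f"{d.pct_lt_2_7:.2f}"),
            ("Median insulin rate [IQR] (U/kg/hr)",
             f"{self.insulin_median:.3f} "
             f"[{self.insulin_iqr[0]:.3f} - {self.insulin_iqr[1]:.3f}]"),
            ("Median glucose rate (mg/kg/min)", f"{self.glucose_rate_median:.1f}"),
            ("Time between measurements (hours)", f"{self.meas_interval_median_h:.1f}"),
        ]
        if self.si_median is not None:
            rows.append(("Insulin sensitivity x 10^-3 (L/[mU.min])",
                         f"{self.si_median * 1e3:.2f} "
                         f"[{self.si_iqr[0] * 1e3:.2f} - {self.si_iqr[1] * 1e3:.2f}]"))
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"| {k.ljust(width)} | {v} |" for k, v in rows)


def summarize_trial(records, si_traces=None) -> TrialSummary:
    """Cohort metric suite over PatientRecords (or trial results).

    ``si_traces`` optionally supplies SI traces (true sidecars or fitted)
    for the sensitivity summary rows; pass None to omit them.
    """
    records = [r for r in records if r is not None]
    if not records:
        raise InsufficientDataError("empty cohort")

    hourly_series = []
    per_rows = []
    pooled_insulin = []
    pooled_glucose = []
    intervals = []
    si_medians = []
    n_meas = 0
    total_hours = 0.0

    for i, rec in enumerate(records):
        hours, values = hourly_resample(rec.measurements)
        hourly_series.append(values)
        n_meas += len(rec.measurements)
        span_h = (rec.bg_times[-1] - rec.bg_times[0]) / 60.0
        total_hours += span_h
        intervals.extend(np.diff(rec.bg_times) / 60.0)

        ins = np.asarray(rec.insulin.rate_at(hours))
        pooled_insulin.append(ins)
        profile = rec.glucose_profile()
        glu = np.asarray(profile.total_at(hours))
        pooled_glucose.append(glu)

        b = band_statistics(values)
        row = {"patient_id": rec.patient_id, "hours": span_h,
               "n_measurements": len(rec.measurements),
               "bg_median": b.median, "pct_in_4_7": b.pct_in_4_7,
               "pct_in_4_8": b.pct_in_4_8, "pct_gt_10": b.pct_gt_10,
               "pct_lt_4": b.pct_lt_4, "pct_lt_3": b.pct_lt_3,
               "pct_lt_2_7": b.pct_lt_2_7,
               "insulin_median": float(np.median(ins)),
               "glucose_rate_median": float(np.median(glu))}
        if si_traces is not None:
            tr = si_traces[i]
            si_med = float(np.median(tr.hourly_values()))
            si_medians.append(si_med)
            row["si_median"] = si_med
        per_rows.append(row)

    pooled_values = np.concatenate(hourly_series)
    pooled_ins = np.concatenate(pooled_insulin)
    pooled_glu = np.concatenate(pooled_glucose)
    pooled = band_statistics(pooled_values)

    si_median = si_iqr = spread = None
    if si_medians:
        all_si = np.concatenate([si_traces[i].hourly_values()
                                 for i in range(len(records))])
        si_median = float(np.median(all_si))
        si_iqr = (float(np.percentile(all_si, 25)), float(np.percentile(all_si, 75)))
        spread = si_spread(si_medians) if len(si_medians) >= 2 else None

    return TrialSummary(
        n_patients=len(records),
        total_hours=total_hours,
        n_measurements=n_meas,
        pooled=pooled,
        insulin_median=float(np.median(pooled_ins)),
        insulin_iqr=(float(np.percentile(pooled_ins, 25)),
                     float(np.percentile(pooled_ins, 75))),
        glucose_rate_median=float(np.median(pooled_glu)),
        meas_interval_median_h=float(np.median(intervals)),
        si_median=si_median,
        si_iqr=si_iqr,
        si_spread_ratio=spread,
        per_patient=pd.DataFrame(per_rows),
        hourly_series=hourly_series,
        hypo_event_hours=int(np.count_nonzero(pooled_values < HYPO_THRESHOLD)),
    )


@dataclass(frozen=True)
class CohortComparison:
    """Convenience wrappers around the standard cohort-comparison tests."""

    mannwhitney_u: float
    mannwhitney_p: float
    rank_biserial: float
    fisher_odds_ratio: float
    fisher_p: float
    chi2_stat: float
    chi2_p: float
    hypo_table: tuple
    band_table: tuple

    def to_dict(self) -> dict:
        return {
            "bg_mannwhitney": {"U": self.mannwhitney_u, "p": self.mannwhitney_p,
                               "rank_biserial": self.rank_biserial},
            "hypoglycemia_fisher": {"odds_ratio": self.fisher_odds_ratio,
                                    "p": self.fisher_p,
                                    "table": [list(r) for r in self.hypo_table]},
            "band_chi2": {"chi2": self.chi2_stat, "p": self.chi2_p,
                          "table": [list(r) for r in self.band_table]},
        }


def compare_cohorts(a: TrialSummary, b: TrialSummary) -> CohortComparison:
    """Mann-Whitney on pooled hourly BG, Fisher's exact on hypoglycemia
    event counts (< 2.7 mmol/L), chi-squared on 4-8 mmol/L band counts."""
    for s in (a, b):
        if not s.hourly_series:
            raise InsufficientDataError("cohort summary lacks raw hourly series")
    va = np.concatenate(a.hourly_series)
    vb = np.concatenate(b.hourly_series)

    mw = stats.mannwhitneyu(va, vb, alternative="two-sided")
    rank_biserial = 2.0 * mw.statistic / (va.size * vb.size) - 1.0

    hypo = ((int(np.count_nonzero(va < HYPO_THRESHOLD)),
             int(np.count_nonzero(va >= HYPO_THRESHOLD))),
            (int(np.count_nonzero(vb < HYPO_THRESHOLD)),
             int(np.count_nonzero(vb >= HYPO_THRESHOLD))))
    fisher = stats.fisher_exact(hypo)

    in_a = int(np.count_nonzero((va >= 4.0) & (va <= 8.0)))
    in_b = int(np.count_nonzero((vb >= 4.0) & (vb <= 8.0)))
    band = ((in_a, va.size - in_a), (in_b, vb.size - in_b))
    chi2 = stats.chi2_contingency(band)

    return CohortComparison(
        mannwhitney_u=float(mw.statistic), mannwhitney_p=float(mw.pvalue),
        rank_biserial=float(rank_biserial),
        fisher_odds_ratio=float(fisher[0]), fisher_p=float(fisher[1]),
        chi2_stat=float(chi2.statistic), chi2_p=float(chi2.pvalue),
        hypo_table=hypo, band_table=band,
    )
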