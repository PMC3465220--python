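"""Patient record container, CSV schemas, config and manifest I/O.

A patient record CSV has one row per charted event time with the mandatory
header::

    time_min,bg_mmol_L,site,insulin_U_kg_hr,dex_conc_pct,dex_flow_mL_hr,
    ebm_mL_kg_day,carrier_conc_pct,carrier_flow_mL_hr,weight_kg

``bg_mmol_L``/``site`` may be empty on rows that only change an infusion;
infusion columns are piecewise-constant from each row's time until the
next row (right-open intervals, pump semantics).  Weight is constant per
record.  Floats round-trip at 10 significant digits.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .controller import ControllerConfig
from .exceptions import ValidationError
from .identify import BGMeasurement, SITrace
from .model import (
    GlucoseInputProfile,
    InsulinSchedule,
    ModelParameters,
    NutritionEntry,
    NutritionSchedule,
    total_glucose_input,
)
from .units import MAX_INSULIN_RATE

__all__ = ["PatientRecord", "read_record", "write_record", "load_config",
           "write_manifest", "RECORD_COLUMNS"]

RECORD_COLUMNS = [
    "time_min", "bg_mmol_L", "site", "insulin_U_kg_hr", "dex_conc_pct",
    "dex_flow_mL_hr", "ebm_mL_kg_day", "carrier_conc_pct",
    "carrier_flow_mL_hr", "weight_kg",
]


@dataclass
class PatientRecord:
    """Full time-stamped clinical stream for one infant."""

    patient_id: str
    weight_kg: float
    measurements: list[BGMeasurement]
    insulin: InsulinSchedule
    nutrition: NutritionSchedule
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight_kg) or self.weight_kg <= 0:
            raise ValidationError("weight must be strictly positive")
        times = [m.t for m in self.measurements]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("BG measurement times must be strictly increasing")

    @property
    def bg_times(self) -> np.ndarray:
        return np.array([m.t for m in self.measurements])

    @property
    def bg_values(self) -> np.ndarray:
        return np.array([m.value for m in self.measurements])

    def glucose_profile(self, ebm_carb_mg_per_ml: float | None = None) -> GlucoseInputProfile:
        kwargs = {}
        if ebm_carb_mg_per_ml is not None:
            kwargs["ebm_carb_mg_per_ml"] = ebm_carb_mg_per_ml
        return total_glucose_input(self.nutrition, self.weight_kg, **kwargs)


def _event_times(record: PatientRecord) -> np.ndarray:
    times = set(float(m.t) for m in record.measurements)
    times.update(float(t) for t in record.insulin.times)
    entries = record.nutrition.entries
    for i, e in enumerate(entries):
        times.add(float(e.start))
        # the trailing end is not representable in the row schema (the last
        # row's infusions extend to the end of the record); interior ends
        # that open a gap need an explicit zero row
        if i + 1 < len(entries) and entries[i + 1].start > e.end:
            times.add(float(e.end))
    return np.array(sorted(times))


def write_record(record: PatientRecord, path) -> None:
    """Serialize a PatientRecord to the canonical CSV schema."""
    times = _event_times(record)
    meas = {m.t: m for m in record.measurements}

    def nutrition_at(t):
        for e in record.nutrition.entries:
            if e.start <= t < e.end:
                return e
        return NutritionEntry(t, t + 1.0)

    rows = []
    for t in times:
        m = meas.get(t)
        e = nutrition_at(t)
        rows.append({
            "time_min": t,
            "bg_mmol_L": m.value if m else np.nan,
            "site": m.site if m else "",
            "insulin_U_kg_hr": float(record.insulin.rate_at(t)),
            "dex_conc_pct": e.dex_conc_pct,
            "dex_flow_mL_hr": e.dex_flow_ml_hr,
            "ebm_mL_kg_day": e.ebm_ml_kg_day,
            "carrier_conc_pct": e.carrier_conc_pct,
            "carrier_flow_mL_hr": e.carrier_flow_ml_hr,
            "weight_kg": record.weight_kg,
        })
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


def read_record(path, patient_id: str | None = None) -> PatientRecord:
    """Parse and validate a patient record CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"site": "string"})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in RECORD_COLUMNS]
    if missing or extra:
        raise ValidationError(
            f"{path.name}: schema mismatch; missing columns {missing}, "
            f"unexpected columns {extra}"
        )
    if df.empty:
        raise ValidationError(f"{path.name}: empty record")

    t = df["time_min"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"{path.name}: time_min not strictly increasing at row {bad[0] + 3}"
        )

    weights = df["weight_kg"].to_numpy(dtype=float)
    if not np.allclose(weights, weights[0], rtol=0, atol=1e-12):
        raise ValidationError(f"{path.name}: weight must be constant per record")

    measurements = []
    for i, row in df.iterrows():
        if pd.notna(row["bg_mmol_L"]):
            site = row["site"] if pd.notna(row["site"]) and row["site"] else "arterial"
            try:
                measurements.append(BGMeasurement(float(row["time_min"]),
                                                  float(row["bg_mmol_L"]), str(site)))
            except ValidationError as err:
                raise ValidationError(f"{path.name}: row {i + 2}: {err}") from err

    rates = df["insulin_U_kg_hr"].to_numpy(dtype=float)
    over = np.nonzero(rates > MAX_INSULIN_RATE + 1e-12)[0]
    if over.size:
        raise ValidationError(
            f"{path.name}: row {over[0] + 2}: insulin rate {rates[over[0]]} exceeds "
            f"the {MAX_INSULIN_RATE} U/kg/hr cap"
        )
    neg = np.nonzero(rates < 0)[0]
    if neg.size:
        raise ValidationError(f"{path.name}: row {neg[0] + 2}: negative insulin rate")
    insulin = InsulinSchedule(t, rates)

    entries = []
    ends = np.append(t[1:], t[-1] + 24 * 60.0)   # last row extends one day
    for i, row in df.iterrows():
        try:
            entries.append(NutritionEntry(
                float(t[i]), float(ends[i]),
                float(row["dex_conc_pct"]), float(row["dex_flow_mL_hr"]),
                float(row["ebm_mL_kg_day"]), float(row["carrier_conc_pct"]),
                float(row["carrier_flow_mL_hr"]),
            ))
        except ValidationError as err:
            raise ValidationError(f"{path.name}: row {i + 2}: {err}") from err

    return PatientRecord(
        patient_id=patient_id or path.stem,
        weight_kg=float(weights[0]),
        measurements=measurements,
        insulin=insulin,
        nutrition=NutritionSchedule(entries),
    )


# ---------------------------------------------------------------------------
# config + manifest


def load_config(path) -> dict:
    """Load a YAML/JSON config with optional ``model`` and ``controller``
    blocks mirroring ModelParameters / ControllerConfig field names."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    out = dict(raw)
    if "model" in raw:
        out["model"] = ModelParameters.from_dict(raw["model"])
    if "controller" in raw:
        fields = set(ControllerConfig.__dataclass_fields__)
        unknown = set(raw["controller"]) - fields
        if unknown:
            raise ValidationError(f"unknown controller options: {sorted(unknown)}")
        block = dict(raw["controller"])
        if "horizon_choices" in block:
            block["horizon_choices"] = tuple(float(h) for h in block["horizon_choices"])
        out["controller"] = ControllerConfig(**block)
    return out


def _hash_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, inputs: list, seed, config_echo: dict | None = None) -> None:
    """Write a reproducibility manifest next to a command's outputs."""
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "inputs": {str(p): _hash_file(p) for p in inputs if Path(p).is_file()},
        "config": config_echo or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
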