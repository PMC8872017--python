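"""Synthetic ICU event tables with planted pre-sepsis dynamics.

Emits chart/lab/prescription event tables and a demographics table in the
same shape the cohort module expects from real extracts, together with the
ground truth used to validate downstream detection.  Sepsis patients carry

* a precursor drift in the four inflammatory-response features (heart rate,
  respiratory rate, temperature, white-cell count) that starts
  ``signal_lead_h`` hours before onset, ramps linearly toward the abnormal
  thresholds and is attenuated by ``signal_decay`` per hour of lead — so a
  window's predictive signal weakens as the prediction horizon grows;
* an intended abnormal run of at least 5 consecutive hours beginning at the
  planted onset, with all four features pushed past their thresholds;
* antibiotic prescription events near the planted infection time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import (
    ANTIBIOTICS,
    FEATURES,
    MIXED_UNIT_IDS,
    OTHER_DRUGS,
    FeatureSpec,
)

EVENT_COLUMNS = ["patient_id", "admission_id", "time", "feature_id", "value", "unit", "source"]

#: (abnormal threshold, in-run mean, in-run sd) per precursor feature
SIRS_PLANT = {
    "heart_rate": (90.0, 102.0, 4.0),
    "respiratory_rate": (20.0, 26.0, 2.0),
    "temperature": (38.0, 38.8, 0.3),
    "wbc": (12.0, 14.5, 1.0),
}

#: drift target as a fraction of the gap to the abnormal threshold; kept
#: below 1 so pre-onset hours rarely satisfy the abnormal criteria and the
#: planted onset remains the earliest qualifying run
DRIFT_CAP = {
    "heart_rate": 0.8,
    "respiratory_rate": 0.5,
    "temperature": 0.7,
    "wbc": 0.7,
}

#: fraction of ``signal_lead_h`` at which each feature's precursor starts;
#: the staggering makes the feature composition of a window encode its
#: distance to onset, not just the drift amplitude
SIRS_LEAD_FRACTION = {
    "heart_rate": 1.0,
    "respiratory_rate": 0.75,
    "temperature": 0.5,
    "wbc": 0.35,
}


class SynthConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    n_patients: int = 400
    mean_stay_h: float = 36.0
    sepsis_prevalence: float = 0.2
    signal_lead_h: float = 14.0
    signal_decay: float = 0.85
    missing_rate: float = 0.1
    unit_mix_rate: float = 0.15
    minor_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SynthConfigError("n_patients must be >= 1")
        if not 0.0 <= self.sepsis_prevalence <= 1.0:
            raise SynthConfigError("sepsis_prevalence must lie in [0, 1]")
        if self.signal_lead_h < 0:
            raise SynthConfigError("signal_lead_h must be >= 0")
        if not 0.0 < self.signal_decay <= 1.0:
            raise SynthConfigError("signal_decay must lie in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SynthConfigError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.unit_mix_rate <= 1.0:
            raise SynthConfigError("unit_mix_rate must lie in [0, 1]")
        if self.mean_stay_h < 14:
            raise SynthConfigError("mean_stay_h must be >= 14")


@dataclass
class GroundTruth:
    """Per-patient planted truth."""

    onset_time: dict[str, int] = field(default_factory=dict)
    infection_time: dict[str, int] = field(default_factory=dict)
    sirs_hours: dict[str, list[int]] = field(default_factory=dict)
    stay_hours: dict[str, int] = field(default_factory=dict)

    def sepsis_patients(self) -> list[str]:
        return sorted(self.onset_time)

    def to_json(self) -> str:
        return json.dumps(
            {
                "onset_time": self.onset_time,
                "infection_time": self.infection_time,
                "sirs_hours": self.sirs_hours,
                "stay_hours": self.stay_hours,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        doc = json.loads(text)
        return cls(
            onset_time={k: int(v) for k, v in doc["onset_time"].items()},
            infection_time={k: int(v) for k, v in doc["infection_time"].items()},
            sirs_hours={k: [int(h) for h in v] for k, v in doc["sirs_hours"].items()},
            stay_hours={k: int(v) for k, v in doc["stay_hours"].items()},
        )


def _drift_fraction(hours_to_onset: np.ndarray, lead: float, decay: float) -> np.ndarray:
    """Precursor strength in [0, 1]: ``decay ** d`` at ``d`` hours before
    onset, gated to the feature's lead window; zero outside (0, lead]."""
    d = np.asarray(hours_to_onset, dtype=np.float64)
    if lead <= 0:
        return np.zeros_like(d)
    active = (d > 0) & (d <= lead)
    return np.where(active, decay ** np.clip(d, 0.0, None), 0.0)


def _choose_source_id(
    spec: FeatureSpec, mixed: bool, rng: np.random.Generator
) -> tuple[str, str]:
    """Pick a source id (and its reporting unit) for one event."""
    mixed_ids = [sid for sid in spec.source_ids if sid in MIXED_UNIT_IDS]
    canon_ids = [sid for sid in spec.source_ids if sid not in MIXED_UNIT_IDS]
    if mixed and mixed_ids:
        sid = mixed_ids[int(rng.integers(0, len(mixed_ids)))]
        return sid, MIXED_UNIT_IDS[sid][1]
    pool = canon_ids or list(spec.source_ids)
    sid = pool[int(rng.integers(0, len(pool)))]
    unit = MIXED_UNIT_IDS[sid][1] if sid in MIXED_UNIT_IDS else spec.canonical_unit
    return sid, unit


def generate_cohort(
    config: SynthConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Generate event tables, demographics and ground truth.

    Returns ``(tables, demographics, truth)`` where ``tables`` holds the
    ``chartevents``, ``labevents`` and ``prescriptions`` frames.
    """
    from .catalog import default_catalog

    catalog = default_catalog()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    chart_rows: list[tuple] = []
    lab_rows: list[tuple] = []
    rx_rows: list[tuple] = []
    demo_rows: list[tuple] = []

    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        adm = f"A{p:05d}"
        minor = rng.random() < config.minor_rate
        age = int(rng.integers(14, 18)) if minor else int(rng.integers(18, 95))
        gender = "F" if rng.random() < 0.45 else "M"
        demo_rows.append((pid, adm, age, gender))

        stay = max(14, int(rng.poisson(config.mean_stay_h)))
        septic = (not minor) and rng.random() < config.sepsis_prevalence
        onset: int | None = None
        run_hours: list[int] = []
        if septic:
            onset = int(rng.integers(8, max(9, stay - 5)))
            run_len = 5 + int(rng.integers(0, 3))
            stay = max(stay, onset + run_len + 1)
            run_hours = list(range(onset, min(onset + run_len, stay)))
            infection = max(0, onset - int(rng.integers(0, 3)))
            truth.onset_time[pid] = onset
            truth.infection_time[pid] = infection
            truth.sirs_hours[pid] = run_hours
            # two antibiotic events so a single dropped record cannot erase
            # the infection evidence
            for _ in range(2):
                drug = ANTIBIOTICS[int(rng.integers(0, len(ANTIBIOTICS)))]
                t = infection + float(rng.uniform(0.0, 0.75))
                rx_rows.append((pid, adm, t, drug, float(rng.uniform(250, 2000)), "mg", "prescription"))
        truth.stay_hours[pid] = stay

        # occasional non-antibiotic prescriptions for everyone
        for _ in range(int(rng.integers(0, 3))):
            drug = OTHER_DRUGS[int(rng.integers(0, len(OTHER_DRUGS)))]
            t = float(rng.uniform(0, stay))
            rx_rows.append((pid, adm, t, drug, float(rng.uniform(5, 500)), "mg", "prescription"))
        # a few controls get antibiotics without any abnormal run
        if not septic and rng.random() < 0.08:
            drug = ANTIBIOTICS[int(rng.integers(0, len(ANTIBIOTICS)))]
            t = float(rng.uniform(0, stay))
            rx_rows.append((pid, adm, t, drug, float(rng.uniform(250, 2000)), "mg", "prescription"))

        hours = np.arange(stay)
        run_mask = np.zeros(stay, dtype=bool)
        if run_hours:
            run_mask[run_hours] = True
        hours_to_onset = (onset - hours.astype(float)) if onset is not None else None

        for spec in FEATURES:
            offset = rng.normal(0.0, spec.patient_sd)
            values = spec.baseline + offset + rng.normal(0.0, spec.noise_sd, size=stay)
            if spec.name in SIRS_PLANT:
                threshold, run_mean, run_sd = SIRS_PLANT[spec.name]
                if hours_to_onset is not None:
                    lead = config.signal_lead_h * SIRS_LEAD_FRACTION[spec.name]
                    drift = _drift_fraction(hours_to_onset, lead, config.signal_decay)
                    cap = DRIFT_CAP[spec.name]
                    values = values + cap * (threshold - spec.baseline) * drift
                if run_mask.any():
                    values[run_mask] = run_mean + rng.normal(0.0, run_sd, size=int(run_mask.sum()))
            values = np.maximum(values, 0.01)
            emitted = rng.random(stay) < spec.emit_rate
            if spec.name in SIRS_PLANT:
                emitted |= run_mask  # abnormal hours are always charted
            rows = chart_rows if spec.kind == "chart" else lab_rows
            for h in hours[emitted]:
                repeats = 2 if (run_mask[h] and spec.name in SIRS_PLANT) else 1
                for _ in range(repeats):
                    mixed = rng.random() < config.unit_mix_rate
                    sid, unit = _choose_source_id(spec, mixed, rng)
                    value = float(values[h])
                    if unit != spec.canonical_unit:
                        value = catalog.convert(spec.name, value, spec.canonical_unit, unit)
                    t = float(h) + float(rng.uniform(0.0, 0.75))
                    rows.append((pid, adm, t, sid, value, unit, spec.kind))

    chart = pd.DataFrame(chart_rows, columns=EVENT_COLUMNS)
    lab = pd.DataFrame(lab_rows, columns=EVENT_COLUMNS)
    rx = pd.DataFrame(rx_rows, columns=EVENT_COLUMNS)
    demographics = pd.DataFrame(demo_rows, columns=["patient_id", "admission_id", "age", "gender"])

    if config.missing_rate > 0:
        drop_seed = int(rng.integers(0, 2**31 - 1))
        chart = inject_missingness(chart, config.missing_rate, drop_seed)
        lab = inject_missingness(lab, config.missing_rate, drop_seed + 1)

    tables = {"chartevents": chart, "labevents": lab, "prescriptions": rx}
    return tables, demographics, truth


def inject_missingness(events: pd.DataFrame, missing_rate: float, seed: int) -> pd.DataFrame:
    """Drop each event independently with probability ``missing_rate``."""
    if not 0.0 <= missing_rate < 1.0:
        raise SynthConfigError("missing_rate must lie in [0, 1)")
    if missing_rate == 0.0:
        return events.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(len(events)) >= missing_rate
    return events.loc[keep].reset_index(drop=True)


def write_cohort(
    out_dir: str | Path,
    tables: dict[str, pd.DataFrame],
    demographics: pd.DataFrame,
    truth: GroundTruth,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in tables.items():
        frame.to_csv(out / f"{name}.csv", index=False)
    demographics.to_csv(out / "patients.csv", index=False)
    (out / "ground_truth.json").write_text(truth.to_json())


def read_cohort(in_dir: str | Path) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth | None]:
    src = Path(in_dir)
    tables = {
        name: pd.read_csv(src / f"{name}.csv", dtype={"patient_id": str, "admission_id": str, "feature_id": str})
        for name in ("chartevents", "labevents", "prescriptions")
    }
    demographics = pd.read_csv(src / "patients.csv", dtype={"patient_id": str, "admission_id": str})
    truth_path = src / "ground_truth.json"
    truth = GroundTruth.from_json(truth_path.read_text()) if truth_path.exists() else None
    return tables, demographics, truth
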