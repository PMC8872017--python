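"""The 40-feature catalog: canonical names, source ids, units, conversions.

Source ids follow the Chartevents/Labevents convention in which the same
clinical concept appears under several numeric ids (e.g. heart rate as both
211 and 220045, temperature in Fahrenheit under 678/223761 and in Celsius
under 676/223762).  Conversion rules are invertible affine maps
``canonical = a * value + b`` per (feature, unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    canonical_unit: str
    source_ids: tuple[str, ...]
    #: unit -> (a, b) with canonical = a * value + b; canonical unit implied (1, 0)
    conversions: dict[str, tuple[float, float]] = field(default_factory=dict)
    # synthetic-generation parameters
    baseline: float = 0.0
    patient_sd: float = 0.0
    noise_sd: float = 1.0
    kind: str = "lab"  # chart | lab
    emit_rate: float = 0.3  # per-hour emission probability


FAHRENHEIT = ("F", (5.0 / 9.0, -160.0 / 9.0))  # C = (F - 32) * 5/9

FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("heart_rate", "bpm", ("211", "220045"),
                baseline=75.0, patient_sd=1.5, noise_sd=2.0, kind="chart", emit_rate=0.97),
    FeatureSpec("temperature", "C", ("678", "223761", "676", "223762"),
                conversions={"F": FAHRENHEIT[1]},
                baseline=36.8, patient_sd=0.08, noise_sd=0.2, kind="chart", emit_rate=0.9),
    FeatureSpec("systolic_bp", "mmHg", ("51", "442", "455", "6701", "220179", "220050"),
                baseline=118.0, patient_sd=6.0, noise_sd=5.0, kind="chart", emit_rate=0.95),
    FeatureSpec("diastolic_bp", "mmHg", ("8368", "8441", "220180"),
                baseline=72.0, patient_sd=4.0, noise_sd=4.0, kind="chart", emit_rate=0.95),
    FeatureSpec("mean_arterial_pressure", "mmHg", ("456", "220052"),
                baseline=85.0, patient_sd=4.0, noise_sd=4.0, kind="chart", emit_rate=0.9),
    FeatureSpec("pulse_pressure", "mmHg", ("90001",),
                baseline=45.0, patient_sd=3.0, noise_sd=3.0, kind="chart", emit_rate=0.85),
    FeatureSpec("respiratory_rate", "cpm", ("618", "220210"),
                baseline=16.0, patient_sd=0.8, noise_sd=1.0, kind="chart", emit_rate=0.97),
    FeatureSpec("spo2", "%", ("50816", "220277"),
                baseline=97.0, patient_sd=0.8, noise_sd=0.8, kind="chart", emit_rate=0.95),
    FeatureSpec("gcs_verbal", "score", ("723", "223900"),
                baseline=4.6, patient_sd=0.2, noise_sd=0.3, kind="chart", emit_rate=0.5),
    FeatureSpec("gcs_motor", "score", ("454", "223901"),
                baseline=5.6, patient_sd=0.2, noise_sd=0.3, kind="chart", emit_rate=0.5),
    FeatureSpec("gcs_eye", "score", ("184", "220739"),
                baseline=3.6, patient_sd=0.2, noise_sd=0.3, kind="chart", emit_rate=0.5),
    FeatureSpec("urine_output", "mL", ("40055", "226559"),
                baseline=80.0, patient_sd=10.0, noise_sd=15.0, kind="chart", emit_rate=0.7),
    FeatureSpec("weight", "kg", ("763", "224639"),
                conversions={"lb": (0.45359237, 0.0), "g": (0.001, 0.0), "mg": (1e-6, 0.0)},
                baseline=78.0, patient_sd=12.0, noise_sd=0.3, kind="chart", emit_rate=0.15),
    FeatureSpec("wbc", "K/uL", ("51300", "51301"),
                baseline=8.0, patient_sd=0.4, noise_sd=0.65, emit_rate=0.5),
    FeatureSpec("ph", "units", ("50820",),
                baseline=7.4, patient_sd=0.02, noise_sd=0.03, emit_rate=0.35),
    FeatureSpec("pao2", "mmHg", ("50821",),
                baseline=95.0, patient_sd=6.0, noise_sd=7.0, emit_rate=0.35),
    FeatureSpec("fio2", "fraction", ("223835", "3420", "3422", "190"),
                conversions={"%": (0.01, 0.0)},
                baseline=0.35, patient_sd=0.03, noise_sd=0.03, kind="chart", emit_rate=0.5),
    FeatureSpec("paco2", "mmHg", ("50818",),
                baseline=40.0, patient_sd=2.0, noise_sd=2.5, emit_rate=0.35),
    FeatureSpec("blood_urea_nitrogen", "mg/dL", ("51006",),
                baseline=18.0, patient_sd=3.0, noise_sd=2.0, emit_rate=0.3),
    FeatureSpec("sodium", "mmol/L", ("50983", "50824"),
                baseline=139.0, patient_sd=1.5, noise_sd=1.5, emit_rate=0.3),
    FeatureSpec("potassium", "mmol/L", ("50971", "50822"),
                baseline=4.1, patient_sd=0.2, noise_sd=0.2, emit_rate=0.3),
    FeatureSpec("bicarbonate", "mmol/L", ("50882",),
                baseline=24.0, patient_sd=1.2, noise_sd=1.2, emit_rate=0.3),
    FeatureSpec("chloride", "mmol/L", ("50902", "50806"),
                baseline=103.0, patient_sd=1.5, noise_sd=1.5, emit_rate=0.3),
    FeatureSpec("anion_gap", "mmol/L", ("50868",),
                baseline=12.0, patient_sd=1.0, noise_sd=1.0, emit_rate=0.3),
    FeatureSpec("glucose", "mg/dL", ("50931", "50809"),
                conversions={"mmol/L": (18.0182, 0.0)},
                baseline=115.0, patient_sd=10.0, noise_sd=12.0, emit_rate=0.4),
    FeatureSpec("lactate", "mmol/L", ("50813",),
                baseline=1.4, patient_sd=0.2, noise_sd=0.25, emit_rate=0.3),
    FeatureSpec("creatinine", "mg/dL", ("50912",),
                baseline=1.0, patient_sd=0.15, noise_sd=0.1, emit_rate=0.3),
    FeatureSpec("bilirubin", "mg/dL", ("50885",),
                baseline=0.8, patient_sd=0.15, noise_sd=0.15, emit_rate=0.25),
    FeatureSpec("albumin", "g/dL", ("50862",),
                baseline=3.8, patient_sd=0.2, noise_sd=0.15, emit_rate=0.2),
    FeatureSpec("platelets", "K/uL", ("51265",),
                baseline=250.0, patient_sd=30.0, noise_sd=15.0, emit_rate=0.3),
    FeatureSpec("hematocrit", "%", ("51221", "50810"),
                baseline=36.0, patient_sd=2.0, noise_sd=1.2, emit_rate=0.3),
    FeatureSpec("hemoglobin", "g/dL", ("51222", "50811"),
                baseline=12.0, patient_sd=0.8, noise_sd=0.4, emit_rate=0.3),
    FeatureSpec("magnesium", "mg/dL", ("50960",),
                baseline=2.0, patient_sd=0.1, noise_sd=0.1, emit_rate=0.25),
    FeatureSpec("phosphate", "mg/dL", ("50970",),
                baseline=3.5, patient_sd=0.3, noise_sd=0.25, emit_rate=0.25),
    FeatureSpec("calcium", "mg/dL", ("50893",),
                baseline=9.0, patient_sd=0.3, noise_sd=0.25, emit_rate=0.25),
    FeatureSpec("ptt", "s", ("51275",),
                baseline=30.0, patient_sd=2.0, noise_sd=2.0, emit_rate=0.2),
    FeatureSpec("inr", "ratio", ("51237",),
                baseline=1.1, patient_sd=0.1, noise_sd=0.05, emit_rate=0.2),
    FeatureSpec("alt", "IU/L", ("50861",),
                baseline=28.0, patient_sd=5.0, noise_sd=3.0, emit_rate=0.2),
    FeatureSpec("ast", "IU/L", ("50878",),
                baseline=30.0, patient_sd=5.0, noise_sd=3.0, emit_rate=0.2),
    FeatureSpec("bands", "%", ("51144",),
                baseline=4.0, patient_sd=0.8, noise_sd=0.8, emit_rate=0.2),
)

FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURES)
N_FEATURES = len(FEATURES)
assert N_FEATURES == 40

#: source ids that report a non-canonical unit, and which unit
MIXED_UNIT_IDS: dict[str, tuple[str, str]] = {
    "678": ("temperature", "F"),
    "223761": ("temperature", "F"),
    "763": ("weight", "lb"),
    "3420": ("fio2", "%"),
    "3422": ("fio2", "%"),
    "190": ("fio2", "%"),
    "50809": ("glucose", "mmol/L"),
}

SIRS_FEATURES: tuple[str, ...] = ("temperature", "heart_rate", "respiratory_rate", "wbc")

ANTIBIOTICS: tuple[str, ...] = (
    "vancomycin",
    "ceftriaxone",
    "piperacillin-tazobactam",
    "cefepime",
    "meropenem",
    "levofloxacin",
    "azithromycin",
)

OTHER_DRUGS: tuple[str, ...] = ("acetaminophen", "insulin", "heparin", "furosemide")


class CatalogError(ValueError):
    pass


@dataclass
class FeatureCatalog:
    """Maps source feature ids to the 40 canonical features."""

    features: tuple[FeatureSpec, ...] = FEATURES

    def __post_init__(self) -> None:
        if not self.features:
            raise CatalogError("empty catalog")
        self.names: tuple[str, ...] = tuple(f.name for f in self.features)
        self.by_name: dict[str, FeatureSpec] = {f.name: f for f in self.features}
        self.id_to_name: dict[str, str] = {}
        for f in self.features:
            if not f.source_ids:
                raise CatalogError(f"feature {f.name} has no source ids")
            for sid in f.source_ids:
                self.id_to_name[sid] = f.name

    @property
    def n_features(self) -> int:
        return len(self.features)

    def column(self, name: str) -> int:
        return self.names.index(name)

    def to_canonical(self, name: str, value: float, unit: str) -> float:
        """Convert a value recorded in ``unit`` to the feature's canonical unit."""
        spec = self.by_name[name]
        if unit == spec.canonical_unit:
            return value
        if unit in spec.conversions:
            a, b = spec.conversions[unit]
            return a * value + b
        raise CatalogError(f"no conversion for {name} from unit {unit!r}")

    def convert(self, name: str, value: float, unit_from: str, unit_to: str) -> float:
        """Convert between any two known units of a feature via the canonical one."""
        canonical = self.to_canonical(name, value, unit_from)
        spec = self.by_name[name]
        if unit_to == spec.canonical_unit:
            return canonical
        if unit_to in spec.conversions:
            a, b = spec.conversions[unit_to]
            return (canonical - b) / a
        raise CatalogError(f"no conversion for {name} to unit {unit_to!r}")

    def known_units(self, name: str) -> set[str]:
        spec = self.by_name[name]
        return {spec.canonical_unit, *spec.conversions}


def default_catalog() -> FeatureCatalog:
    return FeatureCatalog()
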