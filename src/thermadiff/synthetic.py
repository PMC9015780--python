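"""Synthetic patient registries and per-minute bilateral temperature streams.

The generator produces streams with the statistical structure the analysis
assumes: socks record only while worn (ambient otherwise), both feet share
the baseline, circadian, and day-level drift terms (so the expected
contralateral differential is 0 absent injury), each sensor carries
independent per-minute noise, and injected injuries raise affected-foot
temperatures along a linear ramp that is then sustained.

Per-patient noise scale can be dispersed (lognormal, unit mean) via
``patient_noise_cv``; this is what gives the cohort-level spread of mean
differentials between patients while keeping every per-minute differential
zero-mean.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .stream_io import (
    FEET,
    FOOT_INDEX,
    LOCATIONS,
    LOCATION_INDEX,
    MINUTES_PER_DAY,
    PatientStream,
)

INJURY_TYPES = ("charcot", "ulcer", "osteomyelitis", "dvt", "blister")
#: archetypes that affect all 6 plantar sites
DIFFUSE_TYPES = frozenset({"osteomyelitis", "dvt", "charcot"})
DIAGNOSES = ("diabetes_t1", "diabetes_t2", "peripheral_artery_disease", "neuropathy")

REGISTRY_CSV_HEADER = [
    "patient_id", "age", "sex", "diagnoses", "cohort",
    "injury_type", "injury_foot", "injury_locations",
    "onset_day", "diagnosis_day", "peak_offset", "ramp_days",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the stream simulator. Temperatures in deg F, times in minutes."""

    n_study: int = 5
    n_control: int = 26
    days: int = 135
    wear_minutes_per_day_mean: float = 600.0
    wear_minutes_per_day_sd: float = 60.0
    baseline_temp_mean: float = 85.0
    baseline_temp_sd: float = 1.5
    bilateral_noise_sd: float = 0.8
    patient_noise_cv: float = 0.0
    circadian_amplitude: float = 1.5
    drift_sd: float = 0.3
    ambient_temp: float = 72.0
    seed: int = 0

    def __post_init__(self):
        if self.n_study < 0 or self.n_control < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if self.days <= 0:
            raise ConfigError("observation span must be positive")
        for name in ("wear_minutes_per_day_sd", "baseline_temp_sd",
                     "bilateral_noise_sd", "drift_sd", "patient_noise_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.wear_minutes_per_day_mean <= 0:
            raise ConfigError("wear_minutes_per_day_mean must be positive")
        if self.ambient_temp >= self.baseline_temp_mean:
            raise ConfigError("ambient_temp must be below baseline_temp_mean")


@dataclass(frozen=True)
class InjurySpec:
    """A unilateral inflammation event injected into one patient's stream."""

    injury_type: str
    foot: str
    locations: tuple[str, ...]
    onset_day: int
    diagnosis_day: int
    peak_offset: float
    ramp_days: int

    def __post_init__(self):
        if self.injury_type not in INJURY_TYPES:
            raise ConfigError(f"unknown injury type {self.injury_type!r}")
        if self.foot not in FEET:
            raise ConfigError(f"unknown foot {self.foot!r}")
        unknown = set(self.locations) - set(LOCATIONS)
        if unknown:
            raise ConfigError(f"unknown locations {sorted(unknown)}")
        if self.injury_type in DIFFUSE_TYPES and set(self.locations) != set(LOCATIONS):
            raise ConfigError(
                f"{self.injury_type} is diffuse and must affect all 6 locations"
            )
        if self.injury_type not in DIFFUSE_TYPES and not (1 <= len(self.locations) <= 2):
            raise ConfigError(f"{self.injury_type} is focal and must affect 1-2 locations")
        if not self.onset_day < self.diagnosis_day:
            raise ConfigError("onset_day must precede diagnosis_day")
        if self.peak_offset <= 0:
            raise ConfigError("peak_offset must be positive")
        if self.ramp_days < 0:
            raise ConfigError("ramp_days must be >= 0")

    def offset_on_day(self, day: int) -> float:
        """Temperature offset (deg F) added to affected sensors on ``day``."""
        if day < self.onset_day:
            return 0.0
        if self.ramp_days == 0:
            return self.peak_offset
        frac = min(1.0, (day - self.onset_day) / self.ramp_days)
        return self.peak_offset * frac


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: int
    sex: str
    diagnoses: frozenset[str]
    cohort: str
    injury: Optional[InjurySpec] = None

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ConfigError(f"unknown sex {self.sex!r}")
        if self.cohort not in ("study", "control"):
            raise ConfigError(f"unknown cohort {self.cohort!r}")
        unknown = set(self.diagnoses) - set(DIAGNOSES)
        if unknown:
            raise ConfigError(f"unknown diagnoses {sorted(unknown)}")
        if "neuropathy" not in self.diagnoses:
            raise ConfigError("peripheral neuropathy is an eligibility diagnosis")
        if (self.cohort == "study") != (self.injury is not None):
            raise ConfigError("study patients carry an injury; controls do not")


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    digest = hashlib.sha256(patient_id.encode()).digest()
    return np.random.default_rng([seed, int.from_bytes(digest[:8], "big")])


def simulate_patient_stream(
    patient: PatientRecord, config: GeneratorConfig
) -> PatientStream:
    """Simulate one patient's full-span stream (one record per minute).

    During worn intervals each sensor reads baseline + circadian + shared
    day-level drift + independent noise; both feet share every common term.
    Non-worn minutes read ambient with ``worn=False``. An injury, if
    present, adds a linear ramp (0 at ``onset_day`` to ``peak_offset`` at
    ``onset_day + ramp_days``, sustained thereafter) to the affected foot's
    affected locations.
    """
    injury = patient.injury
    if injury is not None and injury.diagnosis_day > config.days:
        raise ConfigError(
            f"injury diagnosis day {injury.diagnosis_day} outside the "
            f"{config.days}-day span"
        )
    rng = _patient_rng(config.seed, patient.patient_id)
    days, n = config.days, config.days * MINUTES_PER_DAY

    # one contiguous wear block per day, both socks together
    durations = np.rint(
        rng.normal(config.wear_minutes_per_day_mean, config.wear_minutes_per_day_sd, days)
    ).astype(np.int64)
    durations = np.clip(durations, 1, MINUTES_PER_DAY)
    starts = rng.integers(0, MINUTES_PER_DAY - durations + 1)

    phase = rng.uniform(0.0, 2.0 * np.pi)
    base = config.baseline_temp_mean + rng.normal(0.0, config.baseline_temp_sd, 6)
    drift = np.cumsum(rng.normal(0.0, config.drift_sd, days))
    if config.patient_noise_cv > 0:
        # unit-mean lognormal dispersion of the per-patient noise scale
        s = np.sqrt(np.log1p(config.patient_noise_cv**2))
        noise_sd = config.bilateral_noise_sd * rng.lognormal(-0.5 * s * s, s)
    else:
        noise_sd = config.bilateral_noise_sd

    worn_mask = np.zeros(n, dtype=bool)
    for d in range(days):
        lo = d * MINUTES_PER_DAY + starts[d]
        worn_mask[lo : lo + durations[d]] = True

    temps = np.full((n, 2, 6), config.ambient_temp, dtype=np.float64)
    idx = np.flatnonzero(worn_mask)
    day_of = idx // MINUTES_PER_DAY
    minute_of = idx % MINUTES_PER_DAY
    common = (
        base[None, :]
        + (
            config.circadian_amplitude
            * np.sin(2.0 * np.pi * minute_of / MINUTES_PER_DAY + phase)
            + drift[day_of]
        )[:, None]
    )
    for fi in range(2):
        temps[idx, fi, :] = common + rng.normal(0.0, noise_sd, (len(idx), 6))

    if injury is not None:
        offsets = np.array([injury.offset_on_day(d) for d in range(days)])
        fi = FOOT_INDEX[injury.foot]
        li = [LOCATION_INDEX[l] for l in injury.locations]
        add = offsets[day_of]
        for l in li:
            temps[idx, fi, l] += add
    np.clip(temps, 32.0, 120.0, out=temps)

    worn = np.zeros((n, 2), dtype=bool)
    worn[worn_mask] = True
    return PatientStream(
        patient_id=patient.patient_id,
        day=np.repeat(np.arange(days, dtype=np.int64), MINUTES_PER_DAY),
        minute=np.tile(np.arange(MINUTES_PER_DAY, dtype=np.int64), days),
        temps=temps,
        worn=worn,
    )


# ---------------------------------------------------------------------------
# default presets

_ALL = tuple(LOCATIONS)

#: study-cohort profiles: (age, sex, diagnoses) alongside each injury preset
DEFAULT_STUDY_PROFILES: tuple[tuple[int, str, tuple[str, ...]], ...] = (
    (68, "male", ("neuropathy", "diabetes_t1")),
    (75, "male", ("neuropathy", "diabetes_t2")),
    (61, "female", ("neuropathy", "peripheral_artery_disease")),
    (48, "male", ("neuropathy", "diabetes_t2")),
    (76, "male", ("neuropathy", "peripheral_artery_disease")),
)

#: control-cohort margins: fractions of the default 26-patient cohort
CONTROL_MARGINS = {"diabetes": 24 / 26, "pad": 5 / 26, "female": 9 / 26, "mean_age": 70.4}


def _preset_path() -> Path:
    return Path(str(resources.files("thermadiff") / "presets" / "default.yaml"))


def load_preset(path: str | Path | None = None) -> dict:
    """Load a scenario preset (generator + injuries + protocol constants)."""
    path = _preset_path() if path is None else Path(path)
    with open(path) as fh:
        return yaml.safe_load(fh)


def injury_from_dict(obj: Mapping) -> InjurySpec:
    locations = obj["locations"]
    if locations == "all":
        locations = _ALL
    return InjurySpec(
        injury_type=obj["injury_type"],
        foot=obj["foot"],
        locations=tuple(locations),
        onset_day=int(obj["onset_day"]),
        diagnosis_day=int(obj["diagnosis_day"]),
        peak_offset=float(obj["peak_offset"]),
        ramp_days=int(obj["ramp_days"]),
    )


def default_generator_config(seed: int | None = None) -> GeneratorConfig:
    """The calibrated generator preset shipped with the package."""
    preset = load_preset()
    cfg = GeneratorConfig(**preset["generator"])
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg


def default_injury_presets() -> list[InjurySpec]:
    """The five injury archetypes of the default study cohort."""
    return [injury_from_dict(obj) for obj in load_preset()["injuries"]]


# ---------------------------------------------------------------------------
# cohorts


def _control_ages(rng: np.random.Generator, n: int, mean_age: float) -> np.ndarray:
    """Integer ages whose mean matches ``mean_age`` to printed precision."""
    ages = np.clip(np.rint(rng.normal(mean_age, 9.0, n)), 40, 95).astype(np.int64)
    target = int(round(mean_age * n))
    while ages.sum() != target:
        i = int(rng.integers(n))
        step = 1 if ages.sum() < target else -1
        if 40 <= ages[i] + step <= 95:
            ages[i] += step
    return ages


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generate_cohorts(
    config: GeneratorConfig,
    presets: Optional[Sequence[InjurySpec]] = None,
    simulate_streams: bool = True,
) -> tuple[list[PatientRecord], dict[str, PatientStream]]:
    """Build the registry (study + control) and simulate every stream.

    With the default presets and default cohort sizes, study demographics
    use the five documented profiles verbatim and control margins are drawn
    to match the reference table (24/26 diabetic, 5/26 PAD, 9/26 female,
    mean age 70.4). Other sizes scale the margins proportionally.
    """
    if presets is None:
        presets = default_injury_presets()
    if config.n_study > 0 and not presets:
        raise ConfigError("study patients requested but no injury presets given")
    rng = np.random.default_rng([config.seed, 0x5EED])

    registry: list[PatientRecord] = []
    for i in range(config.n_study):
        preset = presets[i % len(presets)]
        if i < len(DEFAULT_STUDY_PROFILES) and len(presets) == len(DEFAULT_STUDY_PROFILES):
            age, sex, dx = DEFAULT_STUDY_PROFILES[i % len(DEFAULT_STUDY_PROFILES)]
        else:
            age = int(np.clip(round(rng.normal(66.0, 10.0)), 30, 95))
            sex = "female" if rng.random() < 0.2 else "male"
            dx = ("neuropathy", "diabetes_t2")
        registry.append(
            PatientRecord(
                patient_id=f"S{i + 1:02d}",
                age=age,
                sex=sex,
                diagnoses=frozenset(dx),
                cohort="study",
                injury=preset,
            )
        )

    n = config.n_control
    if n > 0:
        ages = _control_ages(rng, n, CONTROL_MARGINS["mean_age"])
        n_female = _round_half_up(CONTROL_MARGINS["female"] * n)
        n_diab = _round_half_up(CONTROL_MARGINS["diabetes"] * n)
        n_pad = _round_half_up(CONTROL_MARGINS["pad"] * n)
        sexes = np.array(["female"] * n_female + ["male"] * (n - n_female))
        rng.shuffle(sexes)
        diab_idx = set(rng.choice(n, size=n_diab, replace=False).tolist())
        pad_idx = set(rng.choice(n, size=n_pad, replace=False).tolist())
        for i in range(n):
            dx = {"neuropathy"}
            if i in diab_idx:
                dx.add("diabetes_t1" if rng.random() < 0.1 else "diabetes_t2")
            if i in pad_idx:
                dx.add("peripheral_artery_disease")
            registry.append(
                PatientRecord(
                    patient_id=f"C{i + 1:02d}",
                    age=int(ages[i]),
                    sex=str(sexes[i]),
                    diagnoses=frozenset(dx),
                    cohort="control",
                )
            )

    if not simulate_streams:
        return registry, {}
    streams = {p.patient_id: simulate_patient_stream(p, config) for p in registry}
    return registry, streams


def sample_null_patient_stats(
    n_patients: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    n_minutes: int = 900,
) -> np.ndarray:
    """Patient-level window statistics under the no-injury null, sampled directly.

    Equivalent in distribution to running the full stream pipeline on an
    uninjured patient: every common term cancels in the contralateral
    differential, leaving |N(0, 2*sd_p^2)| averaged over the window minutes,
    with sd_p the patient's (possibly dispersed) sensor noise scale.
    """
    if config.patient_noise_cv > 0:
        s = np.sqrt(np.log1p(config.patient_noise_cv**2))
        sd = config.bilateral_noise_sd * rng.lognormal(-0.5 * s * s, s, n_patients)
    else:
        sd = np.full(n_patients, config.bilateral_noise_sd)
    tau = sd * np.sqrt(2.0)
    deltas = np.abs(rng.normal(0.0, 1.0, (n_patients, n_minutes))) * tau[:, None]
    return deltas.mean(axis=1)


# ---------------------------------------------------------------------------
# registry IO


def write_registry(registry: Sequence[PatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REGISTRY_CSV_HEADER)
        for p in registry:
            inj = p.injury
            writer.writerow(
                [
                    p.patient_id,
                    p.age,
                    p.sex,
                    ";".join(sorted(p.diagnoses)),
                    p.cohort,
                    inj.injury_type if inj else "",
                    inj.foot if inj else "",
                    ";".join(inj.locations) if inj else "",
                    inj.onset_day if inj else "",
                    inj.diagnosis_day if inj else "",
                    inj.peak_offset if inj else "",
                    inj.ramp_days if inj else "",
                ]
            )


def read_registry(path: str | Path) -> list[PatientRecord]:
    registry = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or reader.fieldnames[:10] != REGISTRY_CSV_HEADER[:10]:
            raise ConfigError(f"bad registry header in {path}")
        for row in reader:
            injury = None
            if row["injury_type"]:
                injury = InjurySpec(
                    injury_type=row["injury_type"],
                    foot=row["injury_foot"],
                    locations=tuple(row["injury_locations"].split(";")),
                    onset_day=int(row["onset_day"]),
                    diagnosis_day=int(row["diagnosis_day"]),
                    peak_offset=float(row.get("peak_offset") or 1.0),
                    ramp_days=int(float(row.get("ramp_days") or 0)),
                )
            registry.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    age=int(row["age"]),
                    sex=row["sex"],
                    diagnoses=frozenset(row["diagnoses"].split(";")),
                    cohort=row["cohort"],
                    injury=injury,
                )
            )
    return registry
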