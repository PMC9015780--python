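"""Cohort-level comparison: summaries, Welch t from formula, demographics.

The unit of analysis is the patient: each contributes one scalar (the mean
absolute differential over their 900-minute analysis window), and the two
cohorts of scalars are compared with a Welch two-sample t test implemented
directly from the formula (the t distribution itself comes from scipy; the
statistic and Welch-Satterthwaite degrees of freedom do not). A pooled
minute-level mode is available behind a flag for users who want to see the
inflated-t behaviour of treating minutes as independent — it is labelled as
pseudo-replication in the report.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .differentials import minute_differentials, patient_window_statistic
from .errors import StatsError, WindowError
from .stream_io import PatientStream, filter_eligible
from .synthetic import PatientRecord
from .windows import extract_preinjury_window, sample_control_window


@dataclass(frozen=True)
class CohortSummary:
    cohort: str
    n: int
    mean: float
    sd: float
    values: tuple[float, ...]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_diff: float
    ci_low: float
    ci_high: float
    conf: float


def summarize_cohort(values: Sequence[float], cohort_label: str) -> CohortSummary:
    """Mean and sample SD (n-1 denominator) of per-patient statistics."""
    values = tuple(float(v) for v in values)
    n = len(values)
    if n == 0:
        raise StatsError(f"cohort {cohort_label!r} is empty")
    if n == 1:
        raise StatsError(
            f"cohort {cohort_label!r} has a single patient; sample SD undefined"
        )
    arr = np.asarray(values)
    return CohortSummary(
        cohort=cohort_label,
        n=n,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        values=values,
    )


def welch_t(a: Sequence[float], b: Sequence[float], conf: float = 0.95) -> WelchResult:
    """Welch two-sample t test, implemented from the formula.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom, a two-sided p from the t
    distribution, and CI = mean_diff +/- t_crit(df) * SE.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each sample needs at least 2 observations")
    if not (0 < conf < 1):
        raise ValueError("conf must be in (0, 1)")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sea, seb = va / na, vb / nb
    se2 = sea + seb
    if se2 == 0:
        raise StatsError("both sample variances are zero; Welch t undefined")
    mean_diff = float(a.mean() - b.mean())
    se = math.sqrt(se2)
    t = mean_diff / se
    df = se2**2 / (sea**2 / (na - 1) + seb**2 / (nb - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    t_crit = float(sps.t.ppf(0.5 + conf / 2.0, df))
    return WelchResult(
        t=float(t),
        df=float(df),
        p=p,
        mean_diff=mean_diff,
        ci_low=mean_diff - t_crit * se,
        ci_high=mean_diff + t_crit * se,
        conf=conf,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def demographics_table(registry: Sequence[PatientRecord]) -> dict:
    """Per-cohort n, mean age, sex counts, and diagnosis counts with percentages.

    Percentages are 100 * count / cohort n, rounded half away from zero to
    the nearest integer. 'diabetes' pools type 1 and type 2.
    """
    out: dict = {}
    for cohort in ("study", "control"):
        members = [p for p in registry if p.cohort == cohort]
        n = len(members)
        if n == 0:
            raise StatsError(f"cohort {cohort!r} is empty")
        diabetes = sum(
            1 for p in members if p.diagnoses & {"diabetes_t1", "diabetes_t2"}
        )
        pad = sum(1 for p in members if "peripheral_artery_disease" in p.diagnoses)
        out[cohort] = {
            "n": n,
            "mean_age": round(sum(p.age for p in members) / n, 1),
            "sex": {
                "female": sum(1 for p in members if p.sex == "female"),
                "male": sum(1 for p in members if p.sex == "male"),
            },
            "diagnoses": {
                "diabetes": {"count": diabetes, "pct": _round_half_away(100 * diabetes / n)},
                "peripheral_artery_disease": {
                    "count": pad,
                    "pct": _round_half_away(100 * pad / n),
                },
            },
        }
    return out


def format_demographics(table: Mapping) -> str:
    """Human-readable demographics table, one criterion per line."""
    lines = [f"{'Criteria':<28}" + "".join(f"{c:>16}" for c in table)]
    lines.append(f"{'n':<28}" + "".join(f"{table[c]['n']:>16}" for c in table))
    lines.append(
        f"{'Average age (years)':<28}"
        + "".join(f"{table[c]['mean_age']:>16}" for c in table)
    )
    for sex in ("female", "male"):
        lines.append(
            f"{'Sex: ' + sex:<28}" + "".join(f"{table[c]['sex'][sex]:>16}" for c in table)
        )
    for dx, label in (
        ("diabetes", "Diabetes"),
        ("peripheral_artery_disease", "Peripheral artery disease"),
    ):
        lines.append(
            f"{label:<28}"
            + "".join(
                f"{table[c]['diagnoses'][dx]['count']} ({table[c]['diagnoses'][dx]['pct']})".rjust(16)
                for c in table
            )
        )
    return "\n".join(lines)


def _window_seed(seed: int, patient_id: str) -> int:
    digest = hashlib.sha256(f"{seed}:{patient_id}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


def run_cohort_comparison(
    registry: Sequence[PatientRecord],
    streams: Mapping[str, PatientStream],
    seed: int = 0,
    window_days: int = 15,
    minutes_budget: int = 900,
    min_wear_days: int = 50,
    min_minutes_per_day: int = 30,
    conf: float = 0.95,
    unit: str = "patient",
    per_day_quota: Optional[int] = None,
    method: str = "pooled",
) -> dict:
    """End-to-end cohort comparison, fully reproducible from (inputs, seed).

    Pipeline: eligibility filter -> per-patient analysis window (pre-injury
    for injured patients, seeded random span for controls) -> per-patient
    window statistic -> cohort summaries -> Welch t. Returns a
    JSON-serializable report.
    """
    if unit not in ("patient", "minute"):
        raise ValueError(f"unknown analysis unit {unit!r}")
    eligible = filter_eligible(
        list(registry), streams, min_wear_days=min_wear_days,
        min_minutes_per_day=min_minutes_per_day,
    )

    per_patient: dict[str, dict] = {}
    pooled: dict[str, list[float]] = {"study": [], "control": []}
    stats_by_cohort: dict[str, list[float]] = {"study": [], "control": []}
    for patient in eligible:
        stream = streams[patient.patient_id]
        wseed = _window_seed(seed, patient.patient_id)
        if patient.cohort == "study":
            window = extract_preinjury_window(
                stream, patient.injury.diagnosis_day,
                minutes_budget=minutes_budget, days=window_days,
                seed=wseed, per_day_quota=per_day_quota,
            )
        else:
            window = sample_control_window(
                stream, minutes_budget=minutes_budget, days=window_days,
                seed=wseed, per_day_quota=per_day_quota,
            )
        diffs = minute_differentials(stream)
        stat = patient_window_statistic(diffs, window, method=method)
        stats_by_cohort[patient.cohort].append(stat)
        if unit == "minute":
            keys = {d * 1440 + m for d, m in window.minutes}
            row_key = diffs["day"].to_numpy() * 1440 + diffs["minute"].to_numpy()
            pooled[patient.cohort].extend(
                diffs["abs_delta"].to_numpy()[np.isin(row_key, list(keys))].tolist()
            )
        per_patient[patient.patient_id] = {
            "cohort": patient.cohort,
            "window": {
                "label": window.label,
                "start_day": window.start_day,
                "end_day": window.end_day,
                "n_minutes": len(window.minutes),
            },
            "statistic_f": round(stat, 6),
        }

    summaries = {
        c: summarize_cohort(v, c) for c, v in stats_by_cohort.items() if len(v) >= 2
    }
    report: dict = {
        "seed": seed,
        "unit": unit,
        "method": method,
        "parameters": {
            "window_days": window_days,
            "minutes_budget": minutes_budget,
            "min_wear_days": min_wear_days,
            "min_minutes_per_day": min_minutes_per_day,
            "conf": conf,
        },
        "n_registry": len(registry),
        "n_eligible": len(eligible),
        "per_patient": per_patient,
        "cohorts": {
            c: {
                "n": s.n,
                "mean_f": round(s.mean, 6),
                "sd_f": round(s.sd, 6),
                "values_f": [round(v, 6) for v in s.values],
            }
            for c, s in summaries.items()
        },
    }
    try:
        report["demographics"] = demographics_table(registry)
    except StatsError as exc:
        report["demographics"] = {"unavailable": str(exc)}
    if unit == "minute":
        a, b = pooled["study"], pooled["control"]
        test_a, test_b = a, b
        report["pseudo_replication_warning"] = (
            "minute-level pooling treats correlated minutes as independent "
            "observations and inflates the t statistic"
        )
    else:
        test_a = stats_by_cohort["study"]
        test_b = stats_by_cohort["control"]
    if len(test_a) >= 2 and len(test_b) >= 2:
        try:
            w = welch_t(test_a, test_b, conf=conf)
            report["welch"] = {k: round(v, 6) for k, v in asdict(w).items()}
        except StatsError as exc:
            report["welch"] = {"degenerate": str(exc)}
    else:
        report["welch"] = {"degenerate": "need >= 2 patients per cohort"}
    return report


def report_json(report: Mapping) -> str:
    """Canonical JSON rendering (stable byte-for-byte under a fixed seed)."""
    return json.dumps(report, sort_keys=True, indent=2)
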