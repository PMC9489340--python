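"""Cohort data model: patient/follow-up records, delimited-text I/O, derived
echocardiographic indices, covariate categorization and the baseline
two-group comparison table with automatic test dispatch.

Derived left-ventricular mass uses the Devereux-corrected formula; body
surface area uses a linear height/weight formula; LVMI = LVM / BSA.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .states import CVE, NYHA_STATES, encode_state, parse_nyha, parse_state

__all__ = [
    "DomainError",
    "SchemaError",
    "ConfigError",
    "EchoIndices",
    "PatientRecord",
    "FollowUpRecord",
    "compute_lvm",
    "compute_bsa",
    "compute_lvmi",
    "compute_bmi",
    "categorize_covariates",
    "baseline_table",
    "read_cohort",
    "write_cohort",
    "patients_frame",
    "followup_frame",
    "load_thresholds",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_VARIABLE_SPEC",
]


class DomainError(ValueError):
    """An input value outside the mathematical/clinical domain of a formula."""


class SchemaError(ValueError):
    """A malformed input file (missing columns, bad values); carries row context."""


class ConfigError(ValueError):
    """An invalid configuration entry (e.g. unknown variable name)."""


COMORBIDITY_FLAGS = (
    "hypertension",
    "coronary_artery_disease",
    "arrhythmia",
    "heart_valve_disease",
    "diabetes",
    "renal_insufficiency",
)
MEDICATION_FLAGS = ("diuretics", "acei_arb", "beta_blocker", "mra")
LAB_NAMES = ("hb", "cr", "tg", "ldl_c", "hs_crp", "nt_probnp", "hcy", "k", "na", "cl", "mg")
ARMS = ("integrative", "conventional")

PATIENT_COLUMNS = (
    ("patient_id", "arm", "age", "gender", "height_cm", "weight_kg")
    + COMORBIDITY_FLAGS
    + MEDICATION_FLAGS
    + ("smoking",)
    + LAB_NAMES
    + ("lvef", "lvidd_cm", "pwtd_cm", "swtd_cm")
    + ("nyha_admission", "nyha_discharge", "died_in_hospital", "hospital_days", "entry_month")
)
FOLLOWUP_COLUMNS = ("patient_id", "month", "state", "censored")

# Plausibility gate for the end-diastolic diameter in centimetres; values
# outside suggest millimetre input.
LVIDD_PLAUSIBLE_CM = (2.0, 9.0)


# ---------------------------------------------------------------------------
# derived indices
# ---------------------------------------------------------------------------

def compute_lvm(lvidd_cm: float, pwtd_cm: float, swtd_cm: float) -> float:
    """Left ventricular mass (g) from end-diastolic dimensions in cm.

    LVM = 0.8 * 1.04 * ((LVIDd + PWTd + SWTd)^3 - LVIDd^3) + 0.6
    """
    for name, v in (("lvidd_cm", lvidd_cm), ("pwtd_cm", pwtd_cm), ("swtd_cm", swtd_cm)):
        if not v > 0:
            raise DomainError(f"{name} must be > 0, got {v}")
    return 0.8 * 1.04 * ((lvidd_cm + pwtd_cm + swtd_cm) ** 3 - lvidd_cm**3) + 0.6


def compute_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) = 0.0061*height + 0.0128*weight - 0.1529."""
    if not height_cm > 0:
        raise DomainError(f"height_cm must be > 0, got {height_cm}")
    if not weight_kg > 0:
        raise DomainError(f"weight_kg must be > 0, got {weight_kg}")
    bsa = 0.0061 * height_cm + 0.0128 * weight_kg - 0.1529
    if not bsa > 0:
        raise DomainError(f"computed BSA {bsa:.4f} m^2 is non-positive")
    return bsa


def compute_lvmi(lvm_g: float, bsa_m2: float) -> float:
    """Left ventricular mass index (g/m^2) = LVM / BSA."""
    if not bsa_m2 > 0:
        raise DomainError(f"bsa_m2 must be > 0, got {bsa_m2}")
    return lvm_g / bsa_m2


def compute_bmi(height_cm: float, weight_kg: float) -> float:
    """Body mass index (kg/m^2)."""
    if not height_cm > 0:
        raise DomainError(f"height_cm must be > 0, got {height_cm}")
    return weight_kg / (height_cm / 100.0) ** 2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EchoIndices:
    """Echocardiographic measurements plus the derived LVM/BSA/LVMI triple."""

    lvef: float
    lvidd_cm: float
    pwtd_cm: float
    swtd_cm: float
    lvm: float
    bsa: float
    lvmi: float

    @classmethod
    def from_measurements(
        cls,
        lvef: float,
        lvidd_cm: float,
        pwtd_cm: float,
        swtd_cm: float,
        height_cm: float,
        weight_kg: float,
        check_plausible: bool = True,
    ) -> "EchoIndices":
        if not 0 < lvef <= 100:
            raise DomainError(f"lvef must be in (0, 100], got {lvef}")
        if check_plausible and not (LVIDD_PLAUSIBLE_CM[0] <= lvidd_cm <= LVIDD_PLAUSIBLE_CM[1]):
            raise DomainError(
                f"lvidd_cm {lvidd_cm} outside plausible range {LVIDD_PLAUSIBLE_CM} cm; "
                "if dimensions are in mm pass units='mm' or disable the gate"
            )
        lvm = compute_lvm(lvidd_cm, pwtd_cm, swtd_cm)
        bsa = compute_bsa(height_cm, weight_kg)
        return cls(lvef, lvidd_cm, pwtd_cm, swtd_cm, lvm, bsa, compute_lvmi(lvm, bsa))


@dataclass(frozen=True)
class PatientRecord:
    """One patient's baseline covariates, arm label and discharge state."""

    patient_id: str
    arm: str
    age: float
    gender: str  # "male" | "female"
    height_cm: float
    weight_kg: float
    comorbidities: Mapping[str, bool]
    medications: Mapping[str, bool]
    smoking: bool
    labs: Mapping[str, float | None]
    echo: EchoIndices
    nyha_admission: str  # "I".."IV"
    nyha_discharge: str | None  # None when died_in_hospital
    died_in_hospital: bool
    hospital_days: float
    entry_month: int

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise DomainError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if not 18 <= self.age <= 75:
            raise DomainError(f"age must be in [18, 75], got {self.age}")
        if self.gender not in ("male", "female"):
            raise DomainError(f"gender must be male/female, got {self.gender!r}")
        if self.hospital_days < 0:
            raise DomainError("hospital_days must be >= 0")
        if self.nyha_admission not in NYHA_STATES:
            raise DomainError(f"nyha_admission must be a NYHA class, got {self.nyha_admission!r}")
        if self.died_in_hospital:
            if self.nyha_discharge is not None:
                raise DomainError("died_in_hospital patients must have no discharge class")
        elif self.nyha_discharge not in NYHA_STATES:
            raise DomainError(f"nyha_discharge must be a NYHA class, got {self.nyha_discharge!r}")

    @property
    def bmi(self) -> float:
        return compute_bmi(self.height_cm, self.weight_kg)


@dataclass(frozen=True)
class FollowUpRecord:
    """One patient-visit on the 6-month grid; ``censored`` marks the last
    visit of a patient who left observation event-free."""

    patient_id: str
    month: int
    state: str  # "I".."IV" | "CVE"
    censored: bool

    def __post_init__(self) -> None:
        if self.month % 6 != 0 or not 6 <= self.month <= 36:
            raise DomainError(
                f"visit month must be a multiple of 6 in [6, 36], got {self.month}"
            )
        if self.state not in NYHA_STATES + (CVE,):
            raise DomainError(f"invalid state {self.state!r}")


def validate_followups(followups: Iterable[FollowUpRecord]) -> None:
    """Check per-patient schedule invariants: strictly increasing months and
    no observation after the first CVE."""
    last_month: dict[str, int] = {}
    absorbed: set[str] = set()
    for rec in followups:
        if rec.patient_id in absorbed:
            raise SchemaError(f"patient {rec.patient_id}: record after first CVE")
        if rec.patient_id in last_month and rec.month <= last_month[rec.patient_id]:
            raise SchemaError(
                f"patient {rec.patient_id}: months not strictly increasing at {rec.month}"
            )
        last_month[rec.patient_id] = rec.month
        if rec.state == CVE:
            absorbed.add(rec.patient_id)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _flag(token: str, column: str, line: int) -> bool:
    tok = str(token).strip()
    if tok not in ("0", "1"):
        raise SchemaError(f"line {line}: column {column} must be 0/1, got {token!r}")
    return tok == "1"


def _parse_patient_row(row: Mapping[str, str], line: int, units: str) -> PatientRecord:
    try:
        died = _flag(row["died_in_hospital"], "died_in_hospital", line)
        labs = {}
        for lab in LAB_NAMES:
            tok = row[lab].strip()
            labs[lab] = float(tok) if tok else None
        scale = 0.1 if units == "mm" else 1.0
        echo = EchoIndices.from_measurements(
            float(row["lvef"]),
            float(row["lvidd_cm"]) * scale,
            float(row["pwtd_cm"]) * scale,
            float(row["swtd_cm"]) * scale,
            float(row["height_cm"]),
            float(row["weight_kg"]),
        )
        discharge_tok = row["nyha_discharge"].strip()
        if died:
            if discharge_tok not in ("", "0"):
                raise SchemaError(
                    f"line {line}: died_in_hospital=1 requires nyha_discharge 0"
                )
            discharge = None
        else:
            discharge = parse_nyha(discharge_tok)
        return PatientRecord(
            patient_id=row["patient_id"].strip(),
            arm=row["arm"].strip(),
            age=float(row["age"]),
            gender=row["gender"].strip(),
            height_cm=float(row["height_cm"]),
            weight_kg=float(row["weight_kg"]),
            comorbidities={k: _flag(row[k], k, line) for k in COMORBIDITY_FLAGS},
            medications={k: _flag(row[k], k, line) for k in MEDICATION_FLAGS},
            smoking=_flag(row["smoking"], "smoking", line),
            labs=labs,
            echo=echo,
            nyha_admission=parse_nyha(row["nyha_admission"]),
            nyha_discharge=discharge,
            died_in_hospital=died,
            hospital_days=float(row["hospital_days"]),
            entry_month=int(row["entry_month"]),
        )
    except SchemaError:
        raise
    except (ValueError, KeyError) as exc:
        raise SchemaError(f"line {line}: {exc}") from exc


def read_cohort(
    patients_path: str | Path,
    followup_path: str | Path | None = None,
    units: str = "cm",
) -> tuple[list[PatientRecord], list[FollowUpRecord]]:
    """Read patients.csv (and optionally followup.csv).

    Malformed rows raise :class:`SchemaError` identifying the line number;
    the echo plausibility gate rejects millimetre-looking dimensions unless
    ``units='mm'`` is given (values are then converted to cm).
    """
    if units not in ("cm", "mm"):
        raise ConfigError(f"units must be 'cm' or 'mm', got {units!r}")
    patients: list[PatientRecord] = []
    with open(patients_path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(PATIENT_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(f"patients file missing columns: {sorted(missing)}")
        for line, row in enumerate(reader, start=2):
            patients.append(_parse_patient_row(row, line, units))

    followups: list[FollowUpRecord] = []
    if followup_path is not None:
        with open(followup_path, newline="") as fh:
            reader = csv.DictReader(fh)
            missing = set(FOLLOWUP_COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise SchemaError(f"followup file missing columns: {sorted(missing)}")
            known = {p.patient_id for p in patients}
            for line, row in enumerate(reader, start=2):
                try:
                    rec = FollowUpRecord(
                        patient_id=row["patient_id"].strip(),
                        month=int(row["month"]),
                        state=parse_state(row["state"]),
                        censored=_flag(row["censored"], "censored", line),
                    )
                except (DomainError, ValueError) as exc:
                    raise SchemaError(f"line {line}: {exc}") from exc
                if rec.patient_id not in known:
                    raise SchemaError(
                        f"line {line}: unknown patient_id {rec.patient_id!r}"
                    )
                followups.append(rec)
        validate_followups(followups)
    return patients, followups


def write_cohort(
    patients: Sequence[PatientRecord],
    followups: Sequence[FollowUpRecord],
    patients_path: str | Path,
    followup_path: str | Path,
) -> None:
    """Write patients.csv / followup.csv; round-trips through read_cohort."""
    with open(patients_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PATIENT_COLUMNS)
        for p in patients:
            row = [p.patient_id, p.arm, repr(float(p.age)), p.gender,
                   repr(float(p.height_cm)), repr(float(p.weight_kg))]
            row += [int(p.comorbidities[k]) for k in COMORBIDITY_FLAGS]
            row += [int(p.medications[k]) for k in MEDICATION_FLAGS]
            row.append(int(p.smoking))
            row += ["" if p.labs.get(k) is None else repr(float(p.labs[k])) for k in LAB_NAMES]
            row += [repr(float(p.echo.lvef)), repr(float(p.echo.lvidd_cm)),
                    repr(float(p.echo.pwtd_cm)), repr(float(p.echo.swtd_cm))]
            row.append(NYHA_STATES.index(p.nyha_admission) + 1)
            row.append(0 if p.died_in_hospital else NYHA_STATES.index(p.nyha_discharge) + 1)
            row.append(int(p.died_in_hospital))
            row.append(repr(float(p.hospital_days)))
            row.append(p.entry_month)
            writer.writerow(row)
    with open(followup_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FOLLOWUP_COLUMNS)
        for r in followups:
            writer.writerow([r.patient_id, r.month, encode_state(r.state), int(r.censored)])


def patients_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flat analysis DataFrame with derived bmi/lvm/bsa/lvmi columns."""
    rows = []
    for p in patients:
        row: dict[str, object] = {
            "patient_id": p.patient_id,
            "arm": p.arm,
            "age": p.age,
            "gender": p.gender,
            "height_cm": p.height_cm,
            "weight_kg": p.weight_kg,
            "bmi": p.bmi,
            **{k: int(v) for k, v in p.comorbidities.items()},
            **{k: int(v) for k, v in p.medications.items()},
            "smoking": int(p.smoking),
            **{k: (np.nan if v is None else v) for k, v in p.labs.items()},
            "lvef": p.echo.lvef,
            "lvidd_cm": p.echo.lvidd_cm,
            "pwtd_cm": p.echo.pwtd_cm,
            "swtd_cm": p.echo.swtd_cm,
            "lvm": p.echo.lvm,
            "bsa": p.echo.bsa,
            "lvmi": p.echo.lvmi,
            "nyha_admission": p.nyha_admission,
            "nyha_discharge": p.nyha_discharge,
            "died_in_hospital": int(p.died_in_hospital),
            "hospital_days": p.hospital_days,
            "entry_month": p.entry_month,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def followup_frame(followups: Sequence[FollowUpRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"patient_id": r.patient_id, "month": r.month, "state": r.state,
             "censored": int(r.censored)}
            for r in followups
        ]
    )


# ---------------------------------------------------------------------------
# covariate categorization
# ---------------------------------------------------------------------------

# Clinically conventional defaults; these cut-points are package defaults and
# are NOT taken from any specific study (override via thresholds.yaml).
DEFAULT_THRESHOLDS: dict[str, list[float]] = {
    "ldl_c": [3.4],
    "hcy": [15.0],
    "hs_crp": [3.0],
    "nt_probnp": [1500.0],
    "cr": [97.0],
    "k": [3.5, 5.5],
    "na": [135.0, 145.0],
    "cl": [96.0, 106.0],
    "mg": [0.75, 1.02],
    "lvef": [40.0, 50.0],
    "lvmi": [115.0],
}

_BIN_LABELS = {1: ["low", "high"], 2: ["low", "medium", "high"]}


def _bin_labels(n_cuts: int) -> list[str]:
    return _BIN_LABELS.get(n_cuts, [f"bin{i}" for i in range(n_cuts + 1)])


def load_thresholds(path: str | Path) -> dict[str, list[float]]:
    """Load a YAML mapping of variable name -> ordered cut-points."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("thresholds file must be a mapping of name -> cut-points")
    out: dict[str, list[float]] = {}
    for name, cuts in raw.items():
        cuts = [float(c) for c in (cuts if isinstance(cuts, (list, tuple)) else [cuts])]
        if sorted(cuts) != cuts:
            raise ConfigError(f"cut-points for {name!r} must be sorted ascending")
        out[str(name)] = cuts
    return out


def categorize_covariates(
    frame: pd.DataFrame, thresholds: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """Add a categorical companion column ``<var>_cat`` per configured variable.

    Binning is the half-open partition (-inf, c1), [c1, c2), ..., [ck, inf):
    a value exactly at a cut-point falls in the bin whose lower edge it is.
    """
    out = frame.copy()
    for name, cuts in thresholds.items():
        if name not in frame.columns:
            raise ConfigError(f"unknown variable {name!r} in thresholds config")
        cuts = [float(c) for c in cuts]
        if sorted(cuts) != cuts or len(set(cuts)) != len(cuts):
            raise ConfigError(f"cut-points for {name!r} must be strictly ascending")
        labels = _bin_labels(len(cuts))
        idx = np.searchsorted(cuts, frame[name].to_numpy(dtype=float), side="right")
        cat = pd.Series(
            pd.Categorical.from_codes(
                np.where(frame[name].isna(), -1, idx), categories=labels
            ),
            index=frame.index,
        )
        out[f"{name}_cat"] = cat
    return out


# ---------------------------------------------------------------------------
# baseline comparison table
# ---------------------------------------------------------------------------

# Test dispatch mirrors the conventional presentation for this kind of
# cohort: skewed labs are declared non-normal, all other continuous
# variables normal, flags/classes are counts.
DEFAULT_VARIABLE_SPEC: list[tuple[str, str]] = (
    [("age", "normal"), ("gender", "count"), ("weight_kg", "normal"), ("bmi", "normal")]
    + [(m, "count") for m in MEDICATION_FLAGS]
    + [(c, "count") for c in COMORBIDITY_FLAGS]
    + [("smoking", "count"), ("hb", "normal"), ("cr", "nonnormal"), ("tg", "normal"),
       ("ldl_c", "normal"), ("hs_crp", "nonnormal"), ("nt_probnp", "nonnormal"),
       ("hcy", "normal"), ("k", "normal"), ("na", "normal"), ("cl", "normal"),
       ("mg", "normal"), ("lvef", "normal"), ("lvmi", "normal"),
       ("nyha_admission", "count"), ("hospital_days", "normal")]
)

_VALID_KINDS = ("normal", "nonnormal", "count")


def _continuous_row(
    name: str, kind: str, a: np.ndarray, b: np.ndarray
) -> dict[str, object]:
    if len(a) < 2 or len(b) < 2:
        return {
            "variable": name, "test": "untestable", "statistic": np.nan, "p": np.nan,
            "summary_integrative": "n/a", "summary_conventional": "n/a",
            "note": "fewer than 2 observations in an arm",
        }
    if kind == "normal":
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        summaries = [f"{x.mean():.2f} ± {x.std(ddof=1):.2f}" for x in (a, b)]
        test = "t-test"
    else:
        stat, p = stats.kruskal(a, b)
        summaries = [
            f"{np.median(x):.2f} ({np.percentile(x, 25):.2f}, {np.percentile(x, 75):.2f})"
            for x in (a, b)
        ]
        test = "kruskal-wallis"
    return {
        "variable": name, "test": test, "statistic": float(stat), "p": float(p),
        "summary_integrative": summaries[0], "summary_conventional": summaries[1],
        "note": "",
    }


def _count_row(name: str, a: pd.Series, b: pd.Series, yates: bool) -> dict[str, object]:
    levels = sorted(set(a.dropna().unique()) | set(b.dropna().unique()), key=str)
    table = np.array(
        [[int((a == lv).sum()) for lv in levels], [int((b == lv).sum()) for lv in levels]]
    )
    # drop all-zero columns (levels absent from both arms cannot occur here)
    if table.shape[1] < 2 or table.sum() == 0:
        return {
            "variable": name, "test": "untestable", "statistic": np.nan, "p": np.nan,
            "summary_integrative": "n/a", "summary_conventional": "n/a",
            "note": "fewer than 2 observed levels",
        }
    correction = yates and table.shape == (2, 2)
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    if (table == table[0]).all():  # identical rows -> no difference by construction
        stat, p = 0.0, 1.0

    def _summary(counts: np.ndarray) -> str:
        n = counts.sum()
        return "; ".join(
            f"{lv}: {c} ({100 * c / n:.1f})" for lv, c in zip(levels, counts)
        )

    return {
        "variable": name, "test": "chi-square", "statistic": float(stat), "p": float(p),
        "summary_integrative": _summary(table[0]), "summary_conventional": _summary(table[1]),
        "note": "yates" if correction else "",
    }


def baseline_table(
    frame: pd.DataFrame,
    variable_spec: Sequence[tuple[str, str]] | None = None,
    yates: bool = False,
) -> pd.DataFrame:
    """Two-arm comparison table with automatic test dispatch.

    Continuous variables declared ``normal`` get mean +/- SD and a two-sample
    t-test; ``nonnormal`` get median (Q1, Q3) and Kruskal-Wallis; ``count``
    variables get n (%) and a chi-square test on the contingency table.
    Missing values are dropped variable-wise (complete-case per row).
    """
    spec = list(variable_spec) if variable_spec is not None else list(DEFAULT_VARIABLE_SPEC)
    if "arm" not in frame.columns:
        raise SchemaError("cohort frame must contain an 'arm' column")
    arms = set(frame["arm"].unique())
    if not {"integrative", "conventional"} <= arms:
        raise SchemaError(f"cohort must contain both arms, found {sorted(arms)}")
    ga = frame[frame["arm"] == "integrative"]
    gb = frame[frame["arm"] == "conventional"]

    rows = []
    for name, kind in spec:
        if kind not in _VALID_KINDS:
            raise ConfigError(f"variable {name!r}: kind must be one of {_VALID_KINDS}")
        if name not in frame.columns:
            raise ConfigError(f"unknown variable {name!r} in variable spec")
        if kind == "count":
            rows.append(_count_row(name, ga[name], gb[name], yates))
        else:
            a = ga[name].dropna().to_numpy(dtype=float)
            b = gb[name].dropna().to_numpy(dtype=float)
            rows.append(_continuous_row(name, kind, a, b))
    return pd.DataFrame(rows)
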