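"""Synthetic two-arm heart-failure cohort generator.

Covariates are drawn per-arm from configurable distributions (normal,
log-normal parameterized by median/quartiles, Bernoulli, categorical);
follow-up uses staggered entry on a 6-month visit grid (6-36 months of
observation); NYHA trajectories evolve under true per-arm transition
matrices; the absorbing CVE can be driven either by the transition matrix
("matrix" mode) or by a piecewise-constant proportional-hazards clock with
an elevated early rate ("hazard" mode, for testing the survival stage
against a known hazard ratio). A truth ledger records every latent quantity
for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort import EchoIndices, FollowUpRecord, PatientRecord
from .states import CVE, CVE_INDEX, N_STATES, NYHA_STATES, STATES, state_index

__all__ = [
    "ParameterError",
    "TruthParams",
    "TruthLedger",
    "generate_cohort",
    "sample_trajectory",
    "sample_size_check",
    "SampleSizeReport",
    "DEFAULT_COVARIATES",
    "DEFAULT_TRANSITIONS",
    "DEFAULT_DISCHARGE",
]

_Z75 = 0.6744897501960817  # standard-normal upper quartile


class ParameterError(ValueError):
    """Invalid generator parameters."""


# Per-arm covariate targets. Normal entries are (mean, sd); "lognormal"
# entries are (median, q1, q3) matched by quantiles; "bernoulli" is a
# proportion; "categorical" is a probability vector. "bounds" triggers
# rejection resampling (used only where a hard validity range exists).
DEFAULT_COVARIATES: dict[str, dict] = {
    "age": {"dist": "normal", "integrative": (63.98, 10.44), "conventional": (60.85, 11.25),
            "bounds": (18.0, 75.0)},
    "gender_male": {"dist": "bernoulli", "integrative": 0.591, "conventional": 0.662},
    "weight_kg": {"dist": "normal", "integrative": (71.55, 14.62), "conventional": (71.62, 14.59),
                  "bounds": (30.0, 160.0)},
    "bmi": {"dist": "normal", "integrative": (25.48, 4.35), "conventional": (25.17, 3.94),
            "bounds": (13.0, 55.0)},
    "diuretics": {"dist": "bernoulli", "integrative": 0.829, "conventional": 0.808},
    "acei_arb": {"dist": "bernoulli", "integrative": 0.646, "conventional": 0.723},
    "beta_blocker": {"dist": "bernoulli", "integrative": 0.790, "conventional": 0.850},
    "mra": {"dist": "bernoulli", "integrative": 0.713, "conventional": 0.634},
    "hypertension": {"dist": "bernoulli", "integrative": 0.674, "conventional": 0.653},
    "coronary_artery_disease": {"dist": "bernoulli", "integrative": 0.541, "conventional": 0.629},
    "arrhythmia": {"dist": "bernoulli", "integrative": 0.331, "conventional": 0.376},
    "heart_valve_disease": {"dist": "bernoulli", "integrative": 0.105, "conventional": 0.117},
    "diabetes": {"dist": "bernoulli", "integrative": 0.586, "conventional": 0.507},
    "renal_insufficiency": {"dist": "bernoulli", "integrative": 0.420, "conventional": 0.211},
    "smoking": {"dist": "bernoulli", "integrative": 0.348, "conventional": 0.413},
    "hb": {"dist": "normal", "integrative": (127.48, 23.89), "conventional": (129.91, 25.19)},
    "cr": {"dist": "lognormal", "integrative": (92.30, 72.50, 130.30),
           "conventional": (83.90, 69.30, 107.43)},
    "tg": {"dist": "normal", "integrative": (1.67, 0.78), "conventional": (1.63, 1.04)},
    "ldl_c": {"dist": "normal", "integrative": (2.41, 0.80), "conventional": (2.42, 0.91)},
    "hs_crp": {"dist": "lognormal", "integrative": (6.71, 2.13, 14.54),
               "conventional": (3.00, 1.20, 11.61)},
    "nt_probnp": {"dist": "lognormal", "integrative": (2455.00, 625.00, 7400.50),
                  "conventional": (1520.00, 452.00, 3594.00)},
    "hcy": {"dist": "normal", "integrative": (17.98, 8.50), "conventional": (17.64, 13.26)},
    "k": {"dist": "normal", "integrative": (4.06, 0.51), "conventional": (4.04, 0.48)},
    "na": {"dist": "normal", "integrative": (139.69, 3.24), "conventional": (139.26, 3.12)},
    "cl": {"dist": "normal", "integrative": (103.14, 8.07), "conventional": (103.67, 4.21)},
    "mg": {"dist": "normal", "integrative": (0.88, 0.11), "conventional": (0.89, 0.10)},
    "lvef": {"dist": "normal", "integrative": (47.45, 15.03), "conventional": (49.36, 14.09),
             "bounds": (5.0, 80.0)},
    # echo dimensions are not tabulated targets; means chosen so the derived
    # mass index lands near the tabulated per-arm LVMI means
    "lvidd_cm": {"dist": "normal", "integrative": (5.44, 0.70), "conventional": (5.32, 0.70),
                 "bounds": (2.5, 8.5)},
    "pwtd_cm": {"dist": "normal", "integrative": (1.00, 0.12), "conventional": (1.00, 0.12),
                "bounds": (0.5, 1.8)},
    "swtd_cm": {"dist": "normal", "integrative": (1.00, 0.12), "conventional": (1.00, 0.12),
                "bounds": (0.5, 1.8)},
    "nyha_admission": {"dist": "categorical", "integrative": (0.0, 0.105, 0.403, 0.492),
                       "conventional": (0.0, 0.127, 0.545, 0.328)},
    "hospital_days": {"dist": "normal", "integrative": (9.76, 4.10), "conventional": (8.43, 4.77),
                      "bounds": (0.0, 60.0)},
}

# True per-arm 6-month dynamics (synthetic defaults, qualitatively ordered:
# the integrative arm improves more and absorbs less per cycle).
DEFAULT_TRANSITIONS: dict[str, list[list[float]]] = {
    "integrative": [
        [0.70, 0.15, 0.05, 0.00, 0.10],
        [0.10, 0.55, 0.15, 0.02, 0.18],
        [0.05, 0.20, 0.40, 0.08, 0.27],
        [0.02, 0.10, 0.25, 0.23, 0.40],
        [0.00, 0.00, 0.00, 0.00, 1.00],
    ],
    "conventional": [
        [0.60, 0.20, 0.05, 0.00, 0.15],
        [0.05, 0.50, 0.18, 0.02, 0.25],
        [0.02, 0.15, 0.40, 0.08, 0.35],
        [0.01, 0.05, 0.20, 0.24, 0.50],
        [0.00, 0.00, 0.00, 0.00, 1.00],
    ],
}

DEFAULT_DISCHARGE: dict[str, tuple[float, ...]] = {
    "integrative": (0.05, 0.35, 0.40, 0.20),
    "conventional": (0.03, 0.30, 0.47, 0.20),
}


@dataclass(frozen=True)
class TruthParams:
    """Complete generating truth for one synthetic cohort."""

    n_per_arm: tuple[int, int] = (181, 213)
    covariate_specs: Mapping[str, dict] = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    true_hr: float = 0.322
    baseline_hazard: tuple[float, float] = (0.075, 0.025)  # monthly, [0,6) and [6,inf)
    true_transition: Mapping[str, Sequence[Sequence[float]]] = field(
        default_factory=lambda: {k: [row[:] for row in v] for k, v in DEFAULT_TRANSITIONS.items()}
    )
    discharge_distribution: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_DISCHARGE)
    )
    entry_window: int = 30
    cve_mode: str = "matrix"  # "matrix" | "hazard"
    annual_dropout: float = 0.10
    inhospital_death_rate: Mapping[str, float] = field(
        default_factory=lambda: {"integrative": 2.0 / 181.0, "conventional": 0.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_arm) != 2 or any(int(n) < 1 for n in self.n_per_arm):
            raise ParameterError(f"n_per_arm must be two integers >= 1, got {self.n_per_arm}")
        if not self.true_hr > 0:
            raise ParameterError("true_hr must be > 0")
        early, late = self.baseline_hazard
        if not (early > 0 and late > 0):
            raise ParameterError("baseline hazard rates must be > 0")
        if self.cve_mode not in ("matrix", "hazard"):
            raise ParameterError(f"cve_mode must be 'matrix' or 'hazard', got {self.cve_mode!r}")
        if not 0 <= self.annual_dropout < 1:
            raise ParameterError("annual_dropout must be in [0, 1)")
        if not 1 <= self.entry_window <= 30:
            raise ParameterError("entry_window must be in [1, 30] months")
        for arm in ("integrative", "conventional"):
            m = np.asarray(self.true_transition[arm], dtype=float)
            if m.shape != (N_STATES, N_STATES):
                raise ParameterError(f"{arm} transition matrix must be {N_STATES}x{N_STATES}")
            if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-12, rtol=0):
                raise ParameterError(f"{arm} transition matrix is not row-stochastic")
            unit = np.zeros(N_STATES)
            unit[CVE_INDEX] = 1.0
            if not np.allclose(m[CVE_INDEX], unit):
                raise ParameterError(f"{arm} transition matrix: CVE row must be absorbing")
            d = np.asarray(self.discharge_distribution[arm], dtype=float)
            if d.shape != (len(NYHA_STATES),) or (d < 0).any() or abs(d.sum() - 1) > 1e-9:
                raise ParameterError(f"{arm} discharge distribution must sum to 1 over NYHA I-IV")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "TruthParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        kwargs = dict(raw)
        if "n_per_arm" in kwargs:
            kwargs["n_per_arm"] = tuple(int(n) for n in kwargs["n_per_arm"])
        if "baseline_hazard" in kwargs:
            kwargs["baseline_hazard"] = tuple(float(x) for x in kwargs["baseline_hazard"])
        if "covariate_specs" in kwargs:
            merged = {k: dict(v) for k, v in DEFAULT_COVARIATES.items()}
            for name, spec in kwargs["covariate_specs"].items():
                merged.setdefault(name, {}).update(spec)
            kwargs["covariate_specs"] = merged
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TruthParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_transition"] = {k: np.asarray(v).tolist() for k, v in d["true_transition"].items()}
        d["discharge_distribution"] = {
            k: list(map(float, v)) for k, v in d["discharge_distribution"].items()
        }
        return d


@dataclass
class TruthLedger:
    """Latent truth behind an emitted cohort (one entry per patient)."""

    params: dict
    seed: int
    patients: list[dict]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"params": self.params, "seed": self.seed, "patients": self.patients},
                      fh, indent=1)

    def frame(self):
        import pandas as pd

        return pd.DataFrame(self.patients)


@dataclass(frozen=True)
class SampleSizeReport:
    n_events: int
    n_covariates: int
    events_per_variable: float
    threshold: float
    passed: bool


def sample_size_check(
    n_events: int, n_covariates: int, threshold: float = 10.0
) -> SampleSizeReport:
    """Events-per-variable adequacy check (the 10-events-per-variable rule)."""
    if n_events < 0 or n_covariates < 0:
        raise ParameterError("counts must be non-negative")
    epv = math.inf if n_covariates == 0 else n_events / n_covariates
    return SampleSizeReport(n_events, n_covariates, epv, threshold, epv >= threshold)


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sampled normal restricted to [lo, hi]."""
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise ParameterError(
        f"truncated normal({mean}, {sd}) on [{lo}, {hi}] failed to converge"
    )


def _lognormal_from_quartiles(
    rng: np.random.Generator, median: float, q1: float, q3: float, size: int
) -> np.ndarray:
    if not 0 < q1 < median < q3:
        raise ParameterError(f"need 0 < q1 < median < q3, got ({median}, {q1}, {q3})")
    mu = math.log(median)
    sigma = (math.log(q3) - math.log(q1)) / (2 * _Z75)
    return rng.lognormal(mu, sigma, size)


def _draw(rng: np.random.Generator, spec: dict, arm: str, n: int) -> np.ndarray:
    dist = spec["dist"]
    par = spec[arm]
    if dist == "normal":
        if "bounds" in spec:
            lo, hi = spec["bounds"]
            return _truncated_normal(rng, par[0], par[1], lo, hi, n)
        return rng.normal(par[0], par[1], n)
    if dist == "lognormal":
        return _lognormal_from_quartiles(rng, *par, n)
    if dist == "bernoulli":
        return (rng.random(n) < float(par)).astype(int)
    if dist == "categorical":
        p = np.asarray(par, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ParameterError("categorical probabilities must sum to 1")
        return rng.choice(len(p), size=n, p=p)
    raise ParameterError(f"unknown distribution {dist!r}")


def sample_trajectory(
    start: str,
    matrix: Sequence[Sequence[float]] | np.ndarray,
    n_cycles: int,
    rng: np.random.Generator,
) -> list[str]:
    """One state path of up to ``n_cycles`` transitions; stops once absorbed."""
    i = state_index(start)
    if i == CVE_INDEX:
        raise ParameterError("start state must be non-absorbing")
    p = np.asarray(matrix, dtype=float)
    cum = p.cumsum(axis=1)
    path = [start]
    for _ in range(n_cycles):
        i = int(np.searchsorted(cum[i], rng.random(), side="right"))
        i = min(i, N_STATES - 1)
        path.append(STATES[i])
        if i == CVE_INDEX:
            break
    return path


def _sample_paths(
    starts: np.ndarray, matrix: np.ndarray, n_cycles: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized path sampling: (n, n_cycles+1) integer state array."""
    cum = np.asarray(matrix, dtype=float).cumsum(axis=1)
    n = len(starts)
    paths = np.empty((n, n_cycles + 1), dtype=np.int64)
    paths[:, 0] = starts
    cur = starts.copy()
    for k in range(1, n_cycles + 1):
        u = rng.random(n)
        cur = np.minimum((cum[cur] < u[:, None]).sum(axis=1), N_STATES - 1)
        paths[:, k] = cur
    return paths


def _piecewise_exp_times(
    rng: np.random.Generator, rate_early: float, rate_late: float, mult: float, n: int
) -> np.ndarray:
    """Event times under a two-piece constant hazard with break at month 6."""
    e = rng.exponential(1.0, n)
    r0, r1 = rate_early * mult, rate_late * mult
    cut = r0 * 6.0
    return np.where(e < cut, e / r0, 6.0 + (e - cut) / r1)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_MAX_MONTH = 36
_CYCLES = _MAX_MONTH // 6


def _strip_cve_column(matrix: np.ndarray) -> np.ndarray:
    """Renormalized NYHA-only dynamics for hazard mode (matrix never absorbs)."""
    m = np.asarray(matrix, dtype=float).copy()
    m[:, CVE_INDEX] = 0.0
    sums = m.sum(axis=1, keepdims=True)
    if (sums[:CVE_INDEX] <= 0).any():
        raise ParameterError("a NYHA row transitions to CVE with probability 1; "
                             "cannot strip the CVE column in hazard mode")
    m[:CVE_INDEX] /= sums[:CVE_INDEX]
    m[CVE_INDEX] = 0.0
    m[CVE_INDEX, CVE_INDEX] = 1.0
    return m


def generate_cohort(
    params: TruthParams,
) -> tuple[list[PatientRecord], list[FollowUpRecord], TruthLedger]:
    """Generate one synthetic cohort plus its truth ledger.

    Randomness flows from ``params.seed`` through named substreams so each
    stage (covariates, entry, trajectories, event clock, dropout) is
    independently reproducible.
    """
    ss = np.random.SeedSequence(params.seed)
    streams = {
        name: np.random.Generator(np.random.PCG64(child))
        for name, child in zip(
            ("covariates", "entry", "trajectories", "hazard", "censoring", "inhospital"),
            ss.spawn(6),
        )
    }

    patients: list[PatientRecord] = []
    followups: list[FollowUpRecord] = []
    ledger_rows: list[dict] = []

    for arm, n_arm, prefix in (
        ("integrative", int(params.n_per_arm[0]), "int"),
        ("conventional", int(params.n_per_arm[1]), "con"),
    ):
        rng_cov = streams["covariates"]
        cov = {name: _draw(rng_cov, spec, arm, n_arm)
               for name, spec in params.covariate_specs.items()}
        height = 100.0 * np.sqrt(cov["weight_kg"] / cov["bmi"])

        entry = streams["entry"].integers(0, params.entry_window + 1, n_arm)
        max_fu = np.maximum(6, ((_MAX_MONTH - entry) // 6) * 6)

        died = streams["inhospital"].random(n_arm) < float(
            params.inhospital_death_rate.get(arm, 0.0)
        )

        d_dist = np.asarray(params.discharge_distribution[arm], dtype=float)
        discharge = streams["trajectories"].choice(len(NYHA_STATES), size=n_arm, p=d_dist)

        true_p = np.asarray(params.true_transition[arm], dtype=float)
        if params.cve_mode == "hazard":
            path_matrix = _strip_cve_column(true_p)
            mult = params.true_hr if arm == "integrative" else 1.0
            cve_time = _piecewise_exp_times(
                streams["hazard"], *params.baseline_hazard, mult, n_arm
            )
        else:
            path_matrix = true_p
            # keep the hazard stream aligned across modes for reproducibility
            cve_time = np.full(n_arm, np.inf)
            streams["hazard"].exponential(1.0, n_arm)
        paths = _sample_paths(discharge, path_matrix, _CYCLES, streams["trajectories"])

        if params.annual_dropout > 0:
            monthly = -math.log(1.0 - params.annual_dropout) / 12.0
            drop_time = streams["censoring"].exponential(1.0 / monthly, n_arm)
        else:
            drop_time = np.full(n_arm, np.inf)
            streams["censoring"].exponential(1.0, n_arm)

        for i in range(n_arm):
            pid = f"{prefix}-{i + 1:05d}"
            echo = EchoIndices.from_measurements(
                lvef=float(cov["lvef"][i]),
                lvidd_cm=float(cov["lvidd_cm"][i]),
                pwtd_cm=float(cov["pwtd_cm"][i]),
                swtd_cm=float(cov["swtd_cm"][i]),
                height_cm=float(height[i]),
                weight_kg=float(cov["weight_kg"][i]),
            )
            nyha_adm = NYHA_STATES[int(cov["nyha_admission"][i])]
            rec = PatientRecord(
                patient_id=pid,
                arm=arm,
                age=float(cov["age"][i]),
                gender="male" if cov["gender_male"][i] else "female",
                height_cm=float(height[i]),
                weight_kg=float(cov["weight_kg"][i]),
                comorbidities={k: bool(cov[k][i]) for k in (
                    "hypertension", "coronary_artery_disease", "arrhythmia",
                    "heart_valve_disease", "diabetes", "renal_insufficiency")},
                medications={k: bool(cov[k][i]) for k in (
                    "diuretics", "acei_arb", "beta_blocker", "mra")},
                smoking=bool(cov["smoking"][i]),
                labs={k: float(cov[k][i]) for k in (
                    "hb", "cr", "tg", "ldl_c", "hs_crp", "nt_probnp", "hcy",
                    "k", "na", "cl", "mg")},
                echo=echo,
                nyha_admission=nyha_adm,
                nyha_discharge=None if died[i] else NYHA_STATES[int(discharge[i])],
                died_in_hospital=bool(died[i]),
                hospital_days=float(cov["hospital_days"][i]),
                entry_month=int(entry[i]),
            )
            patients.append(rec)

            row = {
                "patient_id": pid,
                "arm": arm,
                "entry_month": int(entry[i]),
                "max_followup_month": int(max_fu[i]),
                "died_in_hospital": bool(died[i]),
                "discharge_state": None if died[i] else NYHA_STATES[int(discharge[i])],
                "latent_path": [STATES[s] for s in paths[i]],
                "latent_cve_time": None if not np.isfinite(cve_time[i]) else float(cve_time[i]),
                "latent_dropout_time": None if not np.isfinite(drop_time[i]) else float(drop_time[i]),
                "event": False,
                "event_month": None,
                "last_visit_month": None,
            }

            if died[i]:
                ledger_rows.append(row)
                continue

            # last scheduled visit: dropout floored to the grid (never below
            # the guaranteed first visit), capped by staggered entry
            drop_grid = max(6, 6 * int(drop_time[i] // 6)) if np.isfinite(drop_time[i]) else _MAX_MONTH
            last_visit = int(min(max_fu[i], drop_grid))

            if params.cve_mode == "hazard":
                cve_month = 6 * math.ceil(cve_time[i] / 6.0)
            else:
                in_cve = paths[i] == CVE_INDEX
                cve_month = 6 * int(in_cve.argmax()) if in_cve.any() else math.inf

            emitted = []
            for k in range(1, _CYCLES + 1):
                month = 6 * k
                if month > last_visit:
                    break
                if month >= cve_month:
                    emitted.append(FollowUpRecord(pid, month, CVE, censored=False))
                    row["event"] = True
                    row["event_month"] = month
                    break
                emitted.append(FollowUpRecord(pid, month, STATES[paths[i, k]], censored=False))
            if emitted and not row["event"]:
                emitted[-1] = dataclasses.replace(emitted[-1], censored=True)
            row["last_visit_month"] = emitted[-1].month if emitted else None
            followups.extend(emitted)
            ledger_rows.append(row)

    ledger = TruthLedger(params=params.to_jsonable(), seed=params.seed, patients=ledger_rows)
    return patients, followups, ledger
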