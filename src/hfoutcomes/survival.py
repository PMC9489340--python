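"""Survival pipeline: Kaplan-Meier tables, log-rank comparison, nested Cox
proportional-hazards tiers, discrimination metrics (Harrell C, IPCW
time-dependent ROC) and stratified subgroup sensitivity analysis.

Event time is the visit month of the first recorded CVE; CVE-free patients
are censored at their last observed visit. Cox models use Efron tie
handling (the 6-month visit grid produces heavily tied times).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times

from .cohort import FollowUpRecord, PatientRecord, patients_frame
from .states import CVE

__all__ = [
    "SeparationError",
    "ConvergenceFailure",
    "SurvivalDataset",
    "CoxResult",
    "KMTable",
    "RocResult",
    "TIER_COVARIATES",
    "make_survival_dataset",
    "km_fit",
    "cox_fit",
    "time_dependent_roc",
    "subgroup_analysis",
    "default_strata",
    "relative_risk_reduction",
]


class SeparationError(ValueError):
    """Degenerate design: a model column is constant or perfectly separates."""


class ConvergenceFailure(RuntimeError):
    """The partial-likelihood optimizer failed to converge."""


_LAB_COVARIATES = ("hb", "cr", "tg", "ldl_c", "hs_crp", "nt_probnp", "hcy", "k", "na", "cl", "mg")

# Nested adjustment tiers: I demographics; II adds anthropometry, therapy
# background, history and baseline functional class; III adds the
# continuous laboratory and echocardiographic variables.
TIER_COVARIATES: dict[str, tuple[str, ...]] = {
    "I": ("age", "gender_male"),
    "II": ("age", "gender_male", "bmi",
           "diuretics", "acei_arb", "beta_blocker", "mra",
           "hypertension", "coronary_artery_disease", "arrhythmia",
           "heart_valve_disease", "diabetes", "renal_insufficiency", "smoking",
           "nyha_III", "nyha_IV"),
    "III": ("age", "gender_male", "bmi",
            "diuretics", "acei_arb", "beta_blocker", "mra",
            "hypertension", "coronary_artery_disease", "arrhythmia",
            "heart_valve_disease", "diabetes", "renal_insufficiency", "smoking",
            "nyha_III", "nyha_IV") + _LAB_COVARIATES + ("lvef", "lvmi"),
}


@dataclass
class SurvivalDataset:
    """Per-patient time/event/arm plus tier-dependent model covariates.

    ``frame`` holds the model matrix (time, event, arm_integrative and the
    tier's covariates); ``raw`` keeps the aligned full patient frame for
    stratification.
    """

    frame: pd.DataFrame
    raw: pd.DataFrame
    tier: str
    covariates: tuple[str, ...]
    n_excluded: int = 0


@dataclass(frozen=True)
class CoxResult:
    tier: str
    hr: float
    ci95: tuple[float, float]
    p: float
    covariates: tuple[str, ...]
    n: int
    n_events: int
    minus2loglik: float
    omnibus_chi2: float
    omnibus_p: float
    c_statistic: float
    coefficients: pd.DataFrame = field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class KMTable:
    per_arm: dict
    curves: pd.DataFrame = field(repr=False)
    logrank_chi2: float | None
    logrank_p: float | None
    rmst_horizon: float


@dataclass(frozen=True)
class RocResult:
    auc: float
    horizon: float
    n_cases: int
    n_controls: int
    curve: pd.DataFrame = field(repr=False)


def relative_risk_reduction(hr: float) -> float:
    """Percent risk reduction implied by a hazard ratio: (1 - HR) * 100."""
    if not hr > 0:
        raise ValueError("hazard ratio must be > 0")
    return (1.0 - hr) * 100.0


def make_survival_dataset(
    followups: Sequence[FollowUpRecord],
    patients: Sequence[PatientRecord],
    tier: str = "III",
) -> SurvivalDataset:
    """Collapse follow-up records into one row per patient.

    Event time = month of the first CVE record; otherwise censoring at the
    last observed visit. Patients with zero visits (e.g. in-hospital deaths)
    are excluded with a counted warning.
    """
    if tier not in TIER_COVARIATES:
        raise ValueError(f"tier must be one of {sorted(TIER_COVARIATES)}, got {tier!r}")
    known = {p.patient_id for p in patients}
    first_cve: dict[str, int] = {}
    last_visit: dict[str, int] = {}
    for rec in followups:
        if rec.patient_id not in known:
            raise ValueError(f"follow-up for unknown patient {rec.patient_id!r}")
        last_visit[rec.patient_id] = max(last_visit.get(rec.patient_id, 0), rec.month)
        if rec.state == CVE and rec.patient_id not in first_cve:
            first_cve[rec.patient_id] = rec.month

    raw = patients_frame(patients).set_index("patient_id")
    observed = [p.patient_id for p in patients if p.patient_id in last_visit]
    n_excluded = len(patients) - len(observed)
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} patient(s) with no follow-up visits",
                      stacklevel=2)
    raw = raw.loc[observed]

    frame = pd.DataFrame(index=raw.index)
    frame["time"] = [
        float(first_cve.get(pid, last_visit[pid])) for pid in frame.index
    ]
    frame["event"] = [int(pid in first_cve) for pid in frame.index]
    frame["arm_integrative"] = (raw["arm"] == "integrative").astype(int)

    model = raw.copy()
    model["gender_male"] = (raw["gender"] == "male").astype(int)
    model["nyha_III"] = (raw["nyha_admission"] == "III").astype(int)
    model["nyha_IV"] = (raw["nyha_admission"] == "IV").astype(int)
    covs = TIER_COVARIATES[tier]
    for c in covs:
        frame[c] = model[c].astype(float)
    return SurvivalDataset(frame=frame, raw=raw, tier=tier,
                           covariates=covs, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def restricted_mean(km: KaplanMeierFitter, tau: float) -> tuple[float, float]:
    """RMST to ``tau`` and its variance, in closed form for the KM step
    function (area under the step curve; Klein-style variance
    ``sum A(t_j)^2 d_j / (n_j (n_j - d_j))`` over event times)."""
    sf = km.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t <= tau
    t, s = t[keep], s[keep]
    if len(t) == 0 or t[0] > 0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    edges = np.concatenate([t, [tau]])
    widths = np.diff(edges)
    rmst = float((s * widths).sum())

    et = km.event_table
    ev_t = et.index.to_numpy(dtype=float)
    d = et["observed"].to_numpy(dtype=float)
    n = et["at_risk"].to_numpy(dtype=float)
    mask = (d > 0) & (ev_t <= tau) & (n > d)
    var = 0.0
    for tj, dj, nj in zip(ev_t[mask], d[mask], n[mask]):
        # area under S from tj to tau
        a = float((s[t >= tj] * widths[t >= tj]).sum())
        var += a * a * dj / (nj * (nj - dj))
    return rmst, var


def km_fit(ds: SurvivalDataset) -> KMTable:
    """Product-limit estimates per arm with Greenwood CIs, restricted mean
    survival to the largest observed time, Brookmeyer-Crowley-style median
    CIs, and the two-arm log-rank test."""
    f = ds.frame
    if int(f["event"].sum()) < 1:
        raise ValueError("need at least one event to fit survival curves")
    horizon = float(f["time"].max())
    per_arm: dict[str, dict] = {}
    curves = []
    groups = {
        "all": f,
        "integrative": f[f["arm_integrative"] == 1],
        "conventional": f[f["arm_integrative"] == 0],
    }
    for label, g in groups.items():
        if len(g) == 0:
            continue
        km = KaplanMeierFitter(label=label)
        km.fit(g["time"], g["event"])
        rmst, var = restricted_mean(km, horizon)
        se = float(np.sqrt(max(var, 0.0)))
        median = float(km.median_survival_time_)
        med_ci = median_survival_times(km.confidence_interval_)
        per_arm[label] = {
            "n": int(len(g)),
            "n_events": int(g["event"].sum()),
            "rmst": float(rmst),
            "rmst_ci": (float(rmst - 1.959963984540054 * se),
                        float(rmst + 1.959963984540054 * se)),
            "median": median,
            "median_ci": (float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1])),
        }
        step = km.survival_function_.reset_index()
        step.columns = ["time", "survival"]
        ci = km.confidence_interval_.reset_index(drop=True)
        step["ci_lower"] = ci.iloc[:, 0].to_numpy()
        step["ci_upper"] = ci.iloc[:, 1].to_numpy()
        step["arm"] = label
        curves.append(step)

    both = {"integrative", "conventional"} <= set(per_arm)
    if both:
        a = groups["integrative"]
        b = groups["conventional"]
        lr = logrank_test(a["time"], b["time"], a["event"], b["event"])
        chi2, p = float(lr.test_statistic), float(lr.p_value)
    else:
        chi2 = p = None
    return KMTable(per_arm=per_arm, curves=pd.concat(curves, ignore_index=True),
                   logrank_chi2=chi2, logrank_p=p, rmst_horizon=horizon)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def cox_fit(
    ds: SurvivalDataset,
    tier: str | None = None,
    penalizer: float = 0.0,
    events_per_variable_threshold: float = 10.0,
) -> CoxResult:
    """Proportional-hazards fit (Efron ties) returning the treatment hazard
    ratio with Wald 95% CI, -2 log-likelihood, the likelihood-ratio omnibus
    chi-square and Harrell's C on the fitted risk scores.

    Violating the events-per-variable heuristic only warns. Constant model
    columns raise :class:`SeparationError`; optimizer failure raises
    :class:`ConvergenceFailure` carrying the underlying trace.
    """
    tier = tier or ds.tier
    f = ds.frame
    model_cols = ["arm_integrative"] + [c for c in ds.covariates]
    for c in model_cols:
        if f[c].nunique() <= 1:
            raise SeparationError(f"model column {c!r} is constant across patients")
    n_events = int(f["event"].sum())
    epv = n_events / len(model_cols)
    if epv < events_per_variable_threshold:
        warnings.warn(
            f"{n_events} events for {len(model_cols)} covariates "
            f"({epv:.1f} per variable; guideline is {events_per_variable_threshold:g})",
            stacklevel=2,
        )
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(f[["time", "event"] + model_cols], duration_col="time",
                    event_col="event")
    except _LLConvergenceError as exc:
        raise ConvergenceFailure(f"Cox model did not converge: {exc}") from exc

    summ = cph.summary
    row = summ.loc["arm_integrative"]
    lrt = cph.log_likelihood_ratio_test()
    return CoxResult(
        tier=tier,
        hr=float(row["exp(coef)"]),
        ci95=(float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"])),
        p=float(row["p"]),
        covariates=tuple(model_cols),
        n=int(len(f)),
        n_events=n_events,
        minus2loglik=float(-2.0 * cph.log_likelihood_),
        omnibus_chi2=float(lrt.test_statistic),
        omnibus_p=float(lrt.p_value),
        c_statistic=float(cph.concordance_index_),
        coefficients=summ,
    )


# ---------------------------------------------------------------------------
# time-dependent ROC (cumulative cases / dynamic controls, IPCW)
# ---------------------------------------------------------------------------

def _censoring_survival(times: np.ndarray, events: np.ndarray):
    """KM of the censoring distribution, evaluated left-continuously."""
    km = KaplanMeierFitter()
    km.fit(times, 1 - events)
    grid = km.survival_function_.index.to_numpy(dtype=float)
    surv = km.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    def g_minus(t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(grid, np.asarray(t, dtype=float), side="left") - 1
        return np.where(idx < 0, 1.0, surv[np.clip(idx, 0, len(surv) - 1)])

    return g_minus


def time_dependent_roc(
    ds: SurvivalDataset, risk_scores: Sequence[float], horizon: float
) -> RocResult:
    """Cumulative/dynamic AUC at ``horizon`` with inverse-probability-of-
    censoring weights (cases weighted by 1/G(T-), controls by 1/G(horizon))."""
    f = ds.frame
    t = f["time"].to_numpy(dtype=float)
    e = f["event"].to_numpy(dtype=int)
    s = np.asarray(risk_scores, dtype=float)
    if len(s) != len(f):
        raise ValueError("risk_scores must align with the dataset rows")
    if horizon > t.max():
        raise ValueError(f"horizon {horizon} exceeds the maximum follow-up {t.max()}")
    case = (t <= horizon) & (e == 1)
    control = t > horizon
    if not case.any():
        raise ValueError(f"no events at or before horizon {horizon}")
    if not control.any():
        raise ValueError(f"no controls beyond horizon {horizon}")

    g = _censoring_survival(t, e)
    w_case = 1.0 / g(t[case])
    sc, ss_ = s[case], s[control]

    # weighted exceedance concordance
    order = np.argsort(ss_)
    ss_sorted = ss_[order]
    n_ctrl = len(ss_sorted)
    gt = np.searchsorted(ss_sorted, sc, side="left")        # controls < case score
    ge = np.searchsorted(ss_sorted, sc, side="right")       # controls <= case score
    conc = gt + 0.5 * (ge - gt)
    auc = float((w_case * conc).sum() / (w_case.sum() * n_ctrl))

    thresholds = np.unique(s)[::-1]
    tpr = [(w_case * (sc > c)).sum() / w_case.sum() for c in thresholds]
    fpr = [(ss_ > c).sum() / n_ctrl for c in thresholds]
    curve = pd.DataFrame({
        "threshold": np.concatenate([[np.inf], thresholds]),
        "fpr": np.concatenate([[0.0], fpr]),
        "tpr": np.concatenate([[0.0], tpr]),
    })
    return RocResult(auc=auc, horizon=float(horizon), n_cases=int(case.sum()),
                     n_controls=int(control.sum()), curve=curve)


# ---------------------------------------------------------------------------
# subgroup sensitivity analysis
# ---------------------------------------------------------------------------

def default_strata(raw: pd.DataFrame, age_cut: float = 65.0) -> list[tuple[str, pd.Series]]:
    """Stratification mirroring the sensitivity analysis: age about the
    cohort cut-point, baseline NYHA class, renal insufficiency, coronary
    artery disease."""
    strata: list[tuple[str, pd.Series]] = [
        (f"age>={age_cut:g}", raw["age"] >= age_cut),
        (f"age<{age_cut:g}", raw["age"] < age_cut),
    ]
    for cls in ("II", "III", "IV"):
        strata.append((f"nyha_{cls}", raw["nyha_admission"] == cls))
    strata += [
        ("renal_insufficiency_yes", raw["renal_insufficiency"] == 1),
        ("renal_insufficiency_no", raw["renal_insufficiency"] == 0),
        ("coronary_artery_disease_yes", raw["coronary_artery_disease"] == 1),
        ("coronary_artery_disease_no", raw["coronary_artery_disease"] == 0),
    ]
    return strata


def subgroup_analysis(
    ds: SurvivalDataset,
    strata: Sequence[tuple[str, pd.Series]] | None = None,
    penalizer: float = 0.0,
    low_information_events: int = 5,
) -> pd.DataFrame:
    """Refit the dataset's Cox tier within each stratum.

    Strata without events get an n/a row; optimizer failures and degenerate
    designs are reported in the row instead of aborting the table. Strata
    with fewer than ``low_information_events`` events are flagged."""
    if strata is None:
        strata = default_strata(ds.raw)
    rows = []
    for label, mask in strata:
        mask = mask.reindex(ds.frame.index).fillna(False).astype(bool)
        if not mask.any():
            raise ValueError(f"stratum {label!r} is empty")
        sub_frame = ds.frame[mask]
        # drop covariates made constant by the stratification itself
        covs = tuple(c for c in ds.covariates if sub_frame[c].nunique() > 1)
        sub = SurvivalDataset(frame=sub_frame, raw=ds.raw[mask], tier=ds.tier,
                              covariates=covs)
        n_events = int(sub_frame["event"].sum())
        row = {
            "stratum": label,
            "n": int(mask.sum()),
            "n_integrative": int(sub_frame["arm_integrative"].sum()),
            "n_events": n_events,
            "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
            "note": "",
        }
        if n_events == 0:
            row["note"] = "no events"
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = cox_fit(sub, penalizer=penalizer)
                row.update(hr=res.hr, ci_low=res.ci95[0], ci_high=res.ci95[1], p=res.p)
            except (ConvergenceFailure, SeparationError) as exc:
                row["note"] = f"fit failed: {type(exc).__name__}"
        if 0 < n_events < low_information_events:
            row["note"] = (row["note"] + "; " if row["note"] else "") + "low information"
        rows.append(row)
    return pd.DataFrame(rows)
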