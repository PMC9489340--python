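"""Pipeline orchestration: staged runs (simulate -> baseline -> survival ->
markov), table rendering, manifest/checksum bookkeeping."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort as _cohort
from . import markov as _markov
from . import simulate as _simulate
from . import survival as _survival
from .states import CVE, NYHA_STATES, STATES

log = logging.getLogger("hfoutcomes")

__all__ = ["RunConfig", "StageFailure", "full_pipeline", "render_tables",
           "simulate_stage", "baseline_stage", "survival_stage", "markov_stage",
           "read_transition_counts"]


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    patients_path: Path | None = None
    followup_path: Path | None = None
    params_path: Path | None = None
    thresholds_path: Path | None = None
    transitions_path: Path | None = None
    tier: str = "III"
    cycles: int = 10
    zero_row_policy: str = "self"
    merge_small_cells: bool = False
    fmt: str = "csv"  # csv | markdown | json

    def validate(self) -> None:
        for name in ("patients_path", "followup_path", "params_path",
                     "thresholds_path", "transitions_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise _cohort.ConfigError(f"{name} does not exist: {p}")
        if self.fmt not in ("csv", "markdown", "json"):
            raise _cohort.ConfigError(f"unknown format {self.fmt!r}")
        if self.tier not in _survival.TIER_COVARIATES:
            raise _cohort.ConfigError(f"unknown tier {self.tier!r}")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # output location must not affect the config hash
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_frame(frame: pd.DataFrame, path: Path, fmt: str = "csv") -> Path:
    if fmt == "markdown":
        path = path.with_suffix(".md")
        cols = list(frame.columns)
        lines = ["| " + " | ".join(map(str, cols)) + " |",
                 "| " + " | ".join("---" for _ in cols) + " |"]
        for _, row in frame.iterrows():
            lines.append("| " + " | ".join(str(v) for v in row) + " |")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        path = path.with_suffix(".json")
        path.write_text(frame.to_json(orient="records", indent=1))
    else:
        frame.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate_stage(config: RunConfig) -> tuple[list, list, Path, Path]:
    params = (_simulate.TruthParams.from_yaml(config.params_path)
              if config.params_path else _simulate.TruthParams(seed=config.seed))
    if config.params_path and params.seed != config.seed:
        params = dataclasses.replace(params, seed=config.seed)
    patients, followups, ledger = _simulate.generate_cohort(params)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p_path, f_path = out / "patients.csv", out / "followup.csv"
    _cohort.write_cohort(patients, followups, p_path, f_path)
    ledger.to_json(out / "truth.json")
    return patients, followups, p_path, f_path


def baseline_stage(patients: Sequence, config: RunConfig) -> dict:
    frame = _cohort.patients_frame(patients)
    thresholds = (_cohort.load_thresholds(config.thresholds_path)
                  if config.thresholds_path else _cohort.DEFAULT_THRESHOLDS)
    frame = _cohort.categorize_covariates(frame, thresholds)
    table = _cohort.baseline_table(frame)
    out = Path(config.out_dir)
    path = _write_frame(table, out / "baseline_table.csv", config.fmt)
    return {"baseline_table": table, "baseline_path": path, "cohort_frame": frame}


def survival_stage(patients: Sequence, followups: Sequence, config: RunConfig) -> dict:
    out = Path(config.out_dir)
    datasets = {t: _survival.make_survival_dataset(followups, patients, tier=t)
                for t in ("I", "II", "III")}
    ds_main = datasets[config.tier]

    km = _survival.km_fit(ds_main)
    km_rows = []
    for label, d in km.per_arm.items():
        km_rows.append({
            "group": label, "n": d["n"], "n_events": d["n_events"],
            "rmst": d["rmst"], "rmst_ci_low": d["rmst_ci"][0], "rmst_ci_high": d["rmst_ci"][1],
            "median": d["median"], "median_ci_low": d["median_ci"][0],
            "median_ci_high": d["median_ci"][1],
            "logrank_chi2": km.logrank_chi2 if label == "all" else "",
            "logrank_p": km.logrank_p if label == "all" else "",
        })
    km_table = pd.DataFrame(km_rows)
    _write_frame(km_table, out / "km_table.csv", config.fmt)
    _write_frame(km.curves, out / "km_curves.csv", config.fmt)

    tiers: dict[str, _survival.CoxResult] = {}
    tier_order = ("I", "II", "III")
    for t in tier_order[: tier_order.index(config.tier) + 1]:
        tiers[t] = _survival.cox_fit(datasets[t])

    main = tiers[config.tier]
    lp = (ds_main.frame[list(main.covariates)].to_numpy(float)
          @ main.coefficients["coef"].to_numpy(float))
    horizon = 12.0
    try:
        roc = _survival.time_dependent_roc(ds_main, lp, horizon=horizon)
        _write_frame(roc.curve, out / "roc_curve.csv", config.fmt)
        roc_info = {"horizon": horizon, "auc": roc.auc,
                    "n_cases": roc.n_cases, "n_controls": roc.n_controls}
    except ValueError as exc:
        log.warning("time-dependent ROC unavailable: %s", exc)
        roc, roc_info = None, {"horizon": horizon, "auc": None, "reason": str(exc)}

    cox_payload = {
        t: {
            "hr": r.hr, "ci95": list(r.ci95), "p": r.p, "n": r.n,
            "n_events": r.n_events, "minus2loglik": r.minus2loglik,
            "omnibus_chi2": r.omnibus_chi2, "omnibus_p": r.omnibus_p,
            "c_statistic": r.c_statistic, "covariates": list(r.covariates),
        }
        for t, r in tiers.items()
    }
    (out / "cox_results.json").write_text(
        json.dumps({"tiers": cox_payload, "roc": roc_info, "seed": config.seed}, indent=1)
    )

    subgroups = _survival.subgroup_analysis(ds_main)
    _write_frame(subgroups, out / "subgroups.csv", config.fmt)
    return {"km": km, "km_table": km_table, "cox": tiers, "roc": roc,
            "subgroups": subgroups, "datasets": datasets}


def read_transition_counts(path: Path) -> dict[str, _markov.TransitionCounts]:
    """Read a pre-tabulated transition-count file.

    Columns: from_state, to_state, count and optionally arm. State tokens
    use the followup.csv encoding (1-4 or CVE)."""
    df = pd.read_csv(path)
    required = {"from_state", "to_state", "count"}
    if not required <= set(df.columns):
        raise _cohort.SchemaError(f"transitions file needs columns {sorted(required)}")
    if "arm" not in df.columns:
        df = df.assign(arm="all")
    out: dict[str, _markov.TransitionCounts] = {}
    from .states import parse_state, state_index

    for arm, g in df.groupby("arm"):
        c = np.zeros((len(STATES), len(STATES)), dtype=np.int64)
        for _, row in g.iterrows():
            i = state_index(parse_state(row["from_state"]))
            j = state_index(parse_state(row["to_state"]))
            c[i, j] += int(row["count"])
        out[str(arm)] = _markov.TransitionCounts(c)
    return out


def _markov_one_arm(counts: _markov.TransitionCounts, config: RunConfig,
                    observed_counts: dict | None, years=(1, 3, 5)) -> dict:
    _, matrix = _markov.estimate_transitions(counts, zero_row_policy=config.zero_row_policy)
    totals = counts.row_totals.astype(float)
    n0 = totals.sum()
    init = _markov.StateDistribution(totals / n0, cycle=0)
    preds = _markov.predict_at_years(init, matrix, years=years)
    gof = None
    if observed_counts is not None:
        gof = _markov.gof_test(preds[1], observed_counts,
                               merge_small_cells=config.merge_small_cells)
    return {"counts": counts, "matrix": matrix, "init": init, "n0": int(n0),
            "predictions": preds, "gof": gof}


def markov_stage(patients: Sequence | None, followups: Sequence | None,
                 config: RunConfig) -> dict:
    out = Path(config.out_dir)
    per_arm: dict[str, dict] = {}
    if config.transitions_path is not None:
        for arm, counts in read_transition_counts(Path(config.transitions_path)).items():
            obs = None
            if followups:
                arm_ids = {p.patient_id for p in patients if p.arm == arm}
                arm_fu = [r for r in followups if r.patient_id in arm_ids]
                if arm_fu:
                    obs, _ = _markov.observed_distribution(arm_fu, month=12)
            per_arm[arm] = _markov_one_arm(counts, config, obs)
    else:
        if not patients or not followups:
            raise _cohort.ConfigError("markov stage needs patients+followup or --transitions")
        for arm in ("integrative", "conventional"):
            arm_patients = [p for p in patients
                            if p.arm == arm and not p.died_in_hospital]
            if not arm_patients:
                continue
            ids = {p.patient_id for p in arm_patients}
            by_pid = {p.patient_id: p for p in arm_patients}
            arm_fu = [r for r in followups if r.patient_id in ids]
            pairs = [(by_pid[r.patient_id].nyha_discharge, r.state)
                     for r in arm_fu if r.month == 6]
            if not pairs:
                raise _markov.EstimationError(f"arm {arm!r} has no 6-month observations")
            obs, _ = _markov.observed_distribution(arm_fu, month=12)
            per_arm[arm] = _markov_one_arm(_markov.TransitionCounts.from_pairs(pairs), config, obs)

    # serialize
    mat_rows, pred_rows = [], []
    gof_payload, cmp_payload = {}, {}
    for arm, r in per_arm.items():
        for i, s_from in enumerate(STATES):
            mat_rows.append({"arm": arm, "from_state": s_from,
                             **{f"to_{s}": r["matrix"].probs[i, j]
                                for j, s in enumerate(STATES)},
                             "n_from": int(r["counts"].row_totals[i])})
        for year, dist in r["predictions"].items():
            pct = dist.as_percent()
            pred_rows.append({"arm": arm, "year": year, "cycle": dist.cycle,
                              **{s: pct[s] for s in STATES}})
        if r["gof"] is not None:
            g = r["gof"]
            gof_payload[arm] = {
                "statistic": g.statistic, "df": g.df, "p_value": g.p_value,
                "observed": g.observed.tolist(), "expected": g.expected.tolist(),
                "categories": list(g.categories),
                "small_cell_warnings": list(g.small_cell_warnings),
            }
    arms = list(per_arm)
    if len(arms) == 2:
        a, b = arms
        for year in (1, 3, 5):
            cmp_payload[str(year)] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in _markov.compare_arm_distributions(
                    per_arm[a]["predictions"][year], per_arm[b]["predictions"][year],
                    per_arm[a]["n0"], per_arm[b]["n0"]).items()
            }
    _write_frame(pd.DataFrame(mat_rows), out / "transition_matrix.csv", config.fmt)
    _write_frame(pd.DataFrame(pred_rows), out / "predictions.csv", config.fmt)
    (out / "gof.json").write_text(json.dumps(gof_payload, indent=1))
    (out / "arm_comparison.json").write_text(json.dumps(cmp_payload, indent=1))
    return {"per_arm": per_arm, "predictions_table": pd.DataFrame(pred_rows),
            "arm_comparison": cmp_payload, "gof": gof_payload}


# ---------------------------------------------------------------------------
# table rendering
# ---------------------------------------------------------------------------

def render_tables(bundle: dict, config: RunConfig) -> list[Path]:
    """Emit the six summary tables from the pipeline bundle.

    Missing stage outputs skip their table with a logged reason."""
    out = Path(config.out_dir) / "tables"
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "baseline_table" in bundle:
        written.append(_write_frame(bundle["baseline_table"], out / "table1_baseline.csv",
                                    config.fmt))
    else:
        log.warning("table1 skipped: baseline stage output missing")

    if "km_table" in bundle:
        written.append(_write_frame(bundle["km_table"], out / "table2_survival.csv",
                                    config.fmt))
    else:
        log.warning("table2 skipped: survival stage output missing")

    if "cox" in bundle:
        rows = []
        for t, r in bundle["cox"].items():
            rows.append({"model": f"Model {t}",
                         "integrative": f"{r.hr:.3f} ({r.ci95[0]:.3f}, {r.ci95[1]:.3f})",
                         "conventional": "1.00 (ref.)",
                         "p": f"{r.p:.3g}"})
        written.append(_write_frame(pd.DataFrame(rows), out / "table3_cox.csv", config.fmt))
    else:
        log.warning("table3 skipped: cox results missing")

    if "subgroups" in bundle:
        sg = bundle["subgroups"].copy()
        sg["hr_ci"] = sg.apply(
            lambda r: "n/a" if pd.isna(r["hr"])
            else f"{r['hr']:.3f} ({r['ci_low']:.3f}, {r['ci_high']:.3f})", axis=1)
        written.append(_write_frame(
            sg[["stratum", "n", "n_integrative", "n_events", "hr_ci", "p", "note"]],
            out / "table4_subgroups.csv", config.fmt))
    else:
        log.warning("table4 skipped: subgroup results missing")

    if "predictions_table" in bundle:
        pred = bundle["predictions_table"]
        rows = []
        for s in STATES:
            row: dict[str, object] = {"state": s}
            for _, r in pred.iterrows():
                row[f"{r['arm']}_y{int(r['year'])}"] = r[s]
            rows.append(row)
        t5 = pd.DataFrame(rows)
        written.append(_write_frame(t5, out / "table5_predictions.csv", config.fmt))

        gof = bundle.get("gof") or {}
        rows6 = []
        for arm, g in gof.items():
            pred1 = pred[(pred["arm"] == arm) & (pred["year"] == 1)]
            if pred1.empty:
                continue
            obs_total = sum(g["observed"])
            row = {"arm": arm}
            obs_by_cat = dict(zip(g["categories"], g["observed"]))
            for s in STATES:
                row[f"{s}_predicted"] = float(pred1.iloc[0][s])
                row[f"{s}_actual"] = _markov.percent_round(
                    obs_by_cat.get(s, 0.0) / obs_total) if obs_total else float("nan")
            row["gof_p"] = g["p_value"]
            rows6.append(row)
        if rows6:
            written.append(_write_frame(pd.DataFrame(rows6), out / "table6_gof.csv",
                                        config.fmt))
    else:
        log.warning("table5/6 skipped: markov stage output missing")
    return written


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def full_pipeline(config: RunConfig) -> dict:
    """Run every stage, render tables and write a checksum manifest.

    Identical config + seed reproduces byte-identical artifacts; a stage
    failure writes a ``failed/<stage>`` marker (partial outputs persist) and
    raises :class:`StageFailure`."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_jsonable(), indent=1, sort_keys=True)
    (out / "effective_config.json").write_text(cfg_json)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    log.info("run start: seed=%s config_hash=%s", config.seed, cfg_hash)

    bundle: dict = {}
    stage = "setup"
    timings: dict[str, float] = {}
    try:
        stage = "input"
        t0 = time.perf_counter()
        if config.patients_path is not None:
            patients, followups = _cohort.read_cohort(
                config.patients_path, config.followup_path)
        else:
            stage = "simulate"
            patients, followups, _, _ = simulate_stage(config)
        timings[stage] = time.perf_counter() - t0

        for stage, fn in (
            ("baseline", lambda: baseline_stage(patients, config)),
            ("survival", lambda: survival_stage(patients, followups, config)),
            ("markov", lambda: markov_stage(patients, followups, config)),
        ):
            t0 = time.perf_counter()
            bundle.update(fn())
            timings[stage] = time.perf_counter() - t0
            log.info("stage %s done in %.2fs", stage, timings[stage])

        stage = "render"
        render_tables(bundle, config)
    except Exception as exc:
        marker = out / "failed"
        marker.mkdir(exist_ok=True)
        (marker / stage).write_text(f"{type(exc).__name__}: {exc}\n")
        raise StageFailure(stage, exc) from exc

    artifacts = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json" and "failed" not in p.parts
    )
    manifest = {
        "seed": config.seed,
        "config_hash": cfg_hash,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "artifacts": [
            {"path": str(p.relative_to(out)), "sha256": _sha256(p)} for p in artifacts
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    log.info("run complete: %d artifacts", len(manifest["artifacts"]))
    return bundle
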