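# hfoutcomes

Analysis toolkit for two-arm heart-failure cohort studies: baseline
characterization with derived echocardiographic indices, a
Kaplan–Meier / log-rank / nested-Cox survival pipeline with subgroup
sensitivity checks, and an absorbing five-state discrete-time Markov cohort
model (NYHA classes I–IV plus a composite cardiovascular event, CVE) that
estimates 6-month transition probabilities from paired
discharge → 6-month observations, cycles them to 60 months, and validates
predictions with a chi-square goodness-of-fit test. A synthetic-cohort
generator with a full truth ledger stands in for confidential patient data.

## Modules

| module | contents |
| --- | --- |
| `hfoutcomes.cohort` | `PatientRecord` / `FollowUpRecord` / `EchoIndices`, CSV I/O with schema validation, Devereux LVM / BSA / LVMI, covariate categorization, baseline comparison table with automatic test dispatch (t-test / Kruskal–Wallis / chi-square) |
| `hfoutcomes.simulate` | `TruthParams` + `generate_cohort`: per-arm covariate distributions, staggered entry (6–36 months on a 6-month grid), NYHA trajectories from true transition matrices, CVE via the matrix or via a piecewise proportional-hazards clock with an elevated early rate; emits a `TruthLedger` of every latent quantity |
| `hfoutcomes.survival` | `make_survival_dataset`, KM with Greenwood CIs / RMST (closed-form Klein variance) / median CIs, log-rank, nested Cox tiers I–III (Efron ties, lifelines backend), Harrell C, IPCW time-dependent ROC, stratified subgroup analysis |
| `hfoutcomes.markov` | `estimate_transitions` (row-wise relative frequencies, configurable zero-row policy), `run_cohort` / `predict_at_years` (cycle = 6 months, year *y* = cycle 2*y*), `gof_test`, `compare_arm_distributions`, `observed_distribution` |
| `hfoutcomes.pipeline` / `hfoutcomes.cli` | staged orchestration, renderers for the six summary tables (baseline, survival, Cox tiers, subgroups, predictions, model validation), checksum manifest, click CLI |

## CLI

```bash
# synthetic cohort (patients.csv, followup.csv, truth.json)
hfoutcomes simulate --seed 1 --out out/sim

# individual stages
hfoutcomes baseline-table --patients out/sim/patients.csv --out out/base
hfoutcomes survival --patients out/sim/patients.csv \
    --followup out/sim/followup.csv --tier III --out out/surv
hfoutcomes markov --patients out/sim/patients.csv \
    --followup out/sim/followup.csv --cycles 10 --out out/markov

# pre-tabulated transition counts bypass estimation from follow-up data;
# the initial distribution defaults to the normalized row totals
hfoutcomes markov --transitions counts.csv --out out/markov

# everything, with rendered table analogues and a checksum manifest
hfoutcomes full-pipeline --seed 1 --out out/run
```

Exit codes: `0` success, `2` validation/configuration error, `3` stage
failure (a `failed/<stage>` marker is written and partial outputs persist).
All randomness flows from `--seed` through named substreams; identical
config + seed reproduces byte-identical artifacts.

Generator parameters are overridable via `--params params.yaml` (see
`hfoutcomes.simulate.TruthParams` fields); categorization cut-points via a
`thresholds.yaml` mapping variable → ordered cut-points. The built-in
cut-point defaults are clinically conventional values, not study-specific.

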