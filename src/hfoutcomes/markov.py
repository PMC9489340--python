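"""Absorbing five-state discrete-time cohort model.

States are NYHA classes I-IV plus the absorbing composite cardiovascular
event (CVE). Six-month transition probabilities are estimated as row-wise
relative frequencies of paired discharge -> 6-month observations; the cohort
model propagates a state distribution by repeated right-multiplication with
the transition matrix (one cycle = 6 months, 10 cycles = 60 months), and the
prediction is validated against the observed distribution with a chi-square
goodness-of-fit test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import FollowUpRecord
from .states import CVE, CVE_INDEX, N_STATES, STATES, state_index

__all__ = [
    "EstimationError",
    "TransitionCounts",
    "TransitionMatrix",
    "StateDistribution",
    "GofResult",
    "estimate_transitions",
    "run_cohort",
    "predict_at_years",
    "gof_test",
    "compare_arm_distributions",
    "observed_distribution",
    "percent_round",
]

_ROW_TOL = 1e-12
_DIST_TOL = 1e-9


class EstimationError(ValueError):
    """Raised when transition probabilities cannot be estimated."""


def percent_round(p: float, decimals: int = 1) -> float:
    """Probability -> percentage rounded half-up to ``decimals`` places."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(100.0 * p)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TransitionCounts:
    """5x5 matrix of paired-observation counts; rows index the source state."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_STATES, N_STATES):
            raise ValueError(f"counts must be {N_STATES}x{N_STATES}, got {c.shape}")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if c[CVE_INDEX].any():
            raise ValueError("no patient may start a transition pair in CVE")
        object.__setattr__(self, "counts", c.copy())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "TransitionCounts":
        c = np.zeros((N_STATES, N_STATES), dtype=np.int64)
        n = 0
        for start, end in pairs:
            i, j = state_index(start), state_index(end)
            if i == CVE_INDEX:
                raise ValueError("transition pair starts in the absorbing CVE state")
            c[i, j] += 1
            n += 1
        if n == 0:
            raise EstimationError("no transition pairs supplied")
        return cls(c)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 5x5 transition matrix with CVE absorbing."""

    probs: np.ndarray
    provenance: str = "specified"  # "estimated" | "specified"
    zero_rows: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_STATES, N_STATES):
            raise ValueError(f"matrix must be {N_STATES}x{N_STATES}, got {p.shape}")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        rows = p.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=_ROW_TOL, rtol=0):
            raise ValueError(f"rows must sum to 1 within {_ROW_TOL}; sums {rows}")
        absorbing = np.zeros(N_STATES)
        absorbing[CVE_INDEX] = 1.0
        if not np.array_equal(p[CVE_INDEX], absorbing):
            raise ValueError("CVE row must be the unit vector on CVE (absorbing)")
        object.__setattr__(self, "probs", p.copy())

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.probs, dtype=dtype)


@dataclass(frozen=True)
class StateDistribution:
    """Probability vector over the five states at one model cycle."""

    probs: np.ndarray
    cycle: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_STATES,):
            raise ValueError(f"distribution must have {N_STATES} entries")
        if (p < -_DIST_TOL).any() or (p > 1 + _DIST_TOL).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > _DIST_TOL:
            raise ValueError(f"distribution must sum to 1 within {_DIST_TOL}, got {p.sum()}")
        if self.cycle < 0:
            raise ValueError("cycle must be >= 0")
        object.__setattr__(self, "probs", p.copy())

    @property
    def months(self) -> int:
        return 6 * self.cycle

    @property
    def cve_mass(self) -> float:
        return float(self.probs[CVE_INDEX])

    def as_percent(self, decimals: int = 1) -> dict[str, float]:
        return {s: percent_round(float(p), decimals) for s, p in zip(STATES, self.probs)}


@dataclass(frozen=True)
class GofResult:
    """Chi-square goodness-of-fit of observed counts against a prediction."""

    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    categories: tuple[str, ...]
    small_cell_warnings: tuple[str, ...] = ()


def estimate_transitions(
    pairs: Iterable[tuple[str, str]] | TransitionCounts,
    zero_row_policy: str = "self",
) -> tuple[TransitionCounts, TransitionMatrix]:
    """Row-wise relative-frequency estimate of the 6-month transition matrix.

    ``P[i, j] = n[i, j] / n[i]`` for source states with observations. Source
    states never observed get a self-transition of 1 under the default
    ``"self"`` policy (never inventing unobserved moves) or a uniform row
    under ``"uniform"``; either way a warning is emitted. The CVE row is the
    absorbing unit vector by construction.
    """
    if zero_row_policy not in ("self", "uniform"):
        raise ValueError(f"unknown zero_row_policy {zero_row_policy!r}")
    counts = pairs if isinstance(pairs, TransitionCounts) else TransitionCounts.from_pairs(pairs)
    if counts.counts.sum() == 0:
        raise EstimationError("no transition pairs supplied")
    p = np.zeros((N_STATES, N_STATES), dtype=float)
    totals = counts.row_totals
    zero_rows = []
    for i in range(N_STATES):
        if i == CVE_INDEX:
            continue
        if totals[i] > 0:
            p[i] = counts.counts[i] / totals[i]
        else:
            zero_rows.append(i)
            if zero_row_policy == "self":
                p[i, i] = 1.0
            else:
                p[i] = 1.0 / N_STATES
    p[CVE_INDEX, CVE_INDEX] = 1.0
    if zero_rows:
        warnings.warn(
            "no observed transitions out of state(s) "
            + ", ".join(STATES[i] for i in zero_rows)
            + f"; applied zero-row policy {zero_row_policy!r}",
            stacklevel=2,
        )
    return counts, TransitionMatrix(p, provenance="estimated", zero_rows=tuple(zero_rows))


def run_cohort(
    init: StateDistribution | Sequence[float],
    matrix: TransitionMatrix | np.ndarray,
    n_cycles: int = 10,
) -> list[StateDistribution]:
    """Propagate the cohort distribution: ``v_{k+1} = v_k P`` for k cycles.

    Returns the full trajectory ``[v_0, ..., v_{n_cycles}]``; each element is
    validated (sums to 1, CVE mass non-decreasing)."""
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    if not isinstance(matrix, TransitionMatrix):
        matrix = TransitionMatrix(np.asarray(matrix, dtype=float))
    if not isinstance(init, StateDistribution):
        init = StateDistribution(np.asarray(init, dtype=float), cycle=0)
    out = [init]
    v = init.probs
    for k in range(1, n_cycles + 1):
        v = v @ matrix.probs
        v = v / v.sum()  # scrub accumulated round-off
        dist = StateDistribution(v, cycle=k)
        if dist.cve_mass < out[-1].cve_mass - _DIST_TOL:
            raise AssertionError("absorbing CVE mass decreased across a cycle")
        out.append(dist)
    return out


def predict_at_years(
    init: StateDistribution | Sequence[float],
    matrix: TransitionMatrix | np.ndarray,
    years: Sequence[int] = (1, 3, 5),
) -> dict[int, StateDistribution]:
    """State distributions after whole years of 6-month cycles (year y -> cycle 2y)."""
    years = list(years)
    for y in years:
        if int(y) != y or y < 0:
            raise ValueError(f"years must be non-negative integers, got {y}")
    n_cycles = 2 * max(years, default=0)
    traj = run_cohort(init, matrix, n_cycles=n_cycles)
    return {int(y): traj[2 * int(y)] for y in years}


def gof_test(
    predicted: StateDistribution | Sequence[float],
    observed_counts: Mapping[str, int] | Sequence[int],
    merge_small_cells: bool = False,
) -> GofResult:
    """Chi-square goodness-of-fit of observed state counts vs a predicted
    distribution.

    Categories with zero predicted probability and zero observations are
    dropped; zero-predicted categories with observations raise (the statistic
    would be infinite — merge categories instead). Expected counts below 5
    produce warnings; with ``merge_small_cells`` adjacent NYHA categories are
    pooled until all expected counts reach 5 (CVE is never merged away).
    """
    if isinstance(predicted, StateDistribution):
        probs = predicted.probs
    else:
        probs = np.asarray(predicted, dtype=float)
    if isinstance(observed_counts, Mapping):
        obs = np.array([float(observed_counts.get(s, 0)) for s in STATES])
    else:
        obs = np.asarray(observed_counts, dtype=float)
    if obs.shape != probs.shape:
        raise ValueError("observed counts and prediction must cover the same states")
    if (obs < 0).any():
        raise ValueError("observed counts must be non-negative")
    n = obs.sum()
    if n <= 0:
        raise ValueError("total observed count must be positive")

    cats = [[s] for s in STATES]
    p = probs.copy()
    o = obs.copy()
    zero_pred = p <= 0
    if (zero_pred & (o > 0)).any():
        bad = [STATES[i] for i in np.flatnonzero(zero_pred & (o > 0))]
        raise ValueError(
            f"states {bad} observed but predicted probability is 0; "
            "merge categories before testing"
        )
    keep = ~(zero_pred & (o == 0))
    p, o = p[keep], o[keep]
    cats = [c for c, k in zip(cats, keep) if k]

    if merge_small_cells:
        # pool adjacent NYHA cells (left to right) until expected >= 5
        while len(p) > 1 and (n * p[:-1] < 5).any():
            i = int(np.argmax(n * p[:-1] < 5))
            j = i + 1 if i + 1 < len(p) - 1 or cats[i + 1] != [CVE] else i - 1
            if j < 0 or cats[min(i, j)] == [CVE]:
                break
            lo, hi = min(i, j), max(i, j)
            p[lo] += p[hi]
            o[lo] += o[hi]
            cats[lo] = cats[lo] + cats[hi]
            p = np.delete(p, hi)
            o = np.delete(o, hi)
            del cats[hi]

    expected = n * p
    small = tuple(
        f"expected count {expected[i]:.2f} < 5 for {'+'.join(cats[i])}"
        for i in np.flatnonzero(expected < 5)
    )
    if len(p) < 2:
        raise ValueError("need at least two categories with positive prediction")
    statistic = float(((o - expected) ** 2 / expected).sum())
    df = len(p) - 1
    return GofResult(
        statistic=statistic,
        df=df,
        p_value=float(stats.chi2.sf(statistic, df)),
        observed=o,
        expected=expected,
        categories=tuple("+".join(c) for c in cats),
        small_cell_warnings=small,
    )


def compare_arm_distributions(
    dist_a: StateDistribution | Sequence[float],
    dist_b: StateDistribution | Sequence[float],
    n_a: int,
    n_b: int,
) -> dict[str, object]:
    """Chi-square homogeneity test on the 2x5 table of implied counts.

    Counts are ``round(n * p)`` per arm; all-zero state columns are merged
    out before testing. Returns statistic, df, p and the table used."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("cohort sizes must be positive")
    pa = dist_a.probs if isinstance(dist_a, StateDistribution) else np.asarray(dist_a, float)
    pb = dist_b.probs if isinstance(dist_b, StateDistribution) else np.asarray(dist_b, float)
    table = np.vstack([np.round(n_a * pa), np.round(n_b * pb)]).astype(int)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    kept_states = [s for s, k in zip(STATES, keep) if k]
    if table.shape[1] < 2:
        return {
            "statistic": 0.0, "df": 0, "p_value": 1.0, "table": table,
            "states": kept_states, "degenerate": True,
        }
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return {
        "statistic": float(stat), "df": int(df), "p_value": float(p),
        "table": table, "states": kept_states, "degenerate": False,
    }


def observed_distribution(
    followups: Sequence[FollowUpRecord], month: int
) -> tuple[dict[str, int], dict[str, float]]:
    """Observed state counts and proportions at a visit month.

    A patient contributes their recorded state at ``month``; a patient whose
    CVE occurred earlier is carried forward into CVE; patients censored
    before ``month`` (no record at or after it, no prior CVE) are excluded
    from the denominator."""
    if month % 6 != 0 or month < 6:
        raise ValueError(f"month must be on the 6-month visit grid, got {month}")
    at_month: dict[str, str] = {}
    prior_cve: set[str] = set()
    for rec in followups:
        if rec.month == month:
            at_month[rec.patient_id] = rec.state
        elif rec.month < month and rec.state == CVE:
            prior_cve.add(rec.patient_id)
    counts = {s: 0 for s in STATES}
    for state in at_month.values():
        counts[state] += 1
    for pid in prior_cve - set(at_month):
        counts[CVE] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no patient has a determinate state at month {month}")
    return counts, {s: c / total for s, c in counts.items()}
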