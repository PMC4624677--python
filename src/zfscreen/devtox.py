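"""Hatching and mortality statistics for developmental-toxicity cohorts.

A cohort table holds per-replicate counts of treated, hatched and dead
embryos at each scored day (3 and 5 dpf by default). Rates are computed as
the unweighted mean of replicate proportions with the SEM across replicates,
matching mean +- SEM reporting; treatment effects are tested with the
two-sided Fisher exact test on pooled 2x2 tables (replicates pooled;
group sizes here are small enough that the conditional exact test is the
appropriate choice over a normal-approximation z-test).

Hatching denominators use all treated embryos by default ("x% of the embryos
hatched"); pass ``alive_denominator=True`` to restrict to survivors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RateEstimate",
    "validate_cohort_table",
    "rate_estimate",
    "proportion_test",
    "treatment_report",
]

REQUIRED_COLUMNS = ("replicate", "condition", "day", "n_treated", "n_hatched", "n_dead")


@dataclass(frozen=True)
class RateEstimate:
    """Replicate-level mean +- SEM of an outcome rate, in percent."""

    mean_pct: float
    sem_pct: float
    n_replicates: int
    sem_defined: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_pct <= 100.0:
            raise ValueError("mean_pct must lie in [0, 100]")
        if self.sem_pct < 0:
            raise ValueError("sem_pct must be >= 0")


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check column presence and per-row count conservation.

    Every row must satisfy 0 <= n_hatched + n_dead <= n_treated; violating
    rows are reported with their indices and counts.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    t = table.copy()
    for c in ("n_treated", "n_hatched", "n_dead"):
        t[c] = t[c].astype(int)
    bad = t.index[
        (t.n_hatched < 0)
        | (t.n_dead < 0)
        | (t.n_hatched + t.n_dead > t.n_treated)
    ]
    if len(bad):
        lines = [
            f"  row {i}: treated={t.at[i, 'n_treated']} "
            f"hatched={t.at[i, 'n_hatched']} dead={t.at[i, 'n_dead']}"
            for i in bad[:10]
        ]
        raise ValueError(
            "cohort rows violate n_hatched + n_dead <= n_treated:\n"
            + "\n".join(lines)
        )
    return t


def _outcome_counts(
    rows: pd.DataFrame, outcome: str, alive_denominator: bool
) -> tuple[np.ndarray, np.ndarray]:
    if outcome == "hatched":
        success = rows.n_hatched.to_numpy()
        denom = (
            rows.n_treated.to_numpy() - rows.n_dead.to_numpy()
            if alive_denominator
            else rows.n_treated.to_numpy()
        )
    elif outcome == "dead":
        success = rows.n_dead.to_numpy()
        denom = rows.n_treated.to_numpy()
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    return success, denom


def rate_estimate(
    table: pd.DataFrame,
    condition: str,
    day: int,
    outcome: str = "hatched",
    alive_denominator: bool = False,
) -> RateEstimate:
    """Mean +- SEM (percent) of an outcome rate across replicates.

    With a single replicate the SEM is undefined; it is reported as 0 with
    ``sem_defined=False``.
    """
    t = validate_cohort_table(table)
    rows = t[(t.condition == condition) & (t.day == day)]
    if rows.empty:
        raise KeyError(f"no rows for condition {condition!r} at day {day}")
    success, denom = _outcome_counts(rows, outcome, alive_denominator)
    if np.any(denom <= 0):
        raise ValueError("zero denominator in a replicate")
    props = success / denom
    k = len(props)
    mean_pct = float(props.mean() * 100.0)
    if k > 1:
        sem_pct = float(props.std(ddof=1) / np.sqrt(k) * 100.0)
        return RateEstimate(mean_pct, sem_pct, k, sem_defined=True)
    return RateEstimate(mean_pct, 0.0, k, sem_defined=False)


def proportion_test(
    success_a: int, n_a: int, success_b: int, n_b: int, midp: bool = False
) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 outcome table.

    Returns (odds_ratio, p). The p-value sums hypergeometric probabilities of
    all tables with fixed margins whose probability does not exceed the
    observed table's; ``midp=True`` counts the observed probability with
    weight one half (mid-p variant). Invariant under swapping the groups and
    under swapping the success/failure labels.
    """
    for name, v in (("n_a", n_a), ("n_b", n_b)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    if not (0 <= success_a <= n_a and 0 <= success_b <= n_b):
        raise ValueError("successes must lie in [0, n]")
    table = [[success_a, n_a - success_a], [success_b, n_b - success_b]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    if midp:
        total_success = success_a + success_b
        n = n_a + n_b
        rv = stats.hypergeom(n, total_success, n_a)
        support = np.arange(max(0, total_success - n_b), min(n_a, total_success) + 1)
        pmf = rv.pmf(support)
        obs = rv.pmf(success_a)
        eps = obs * 1e-9
        p = float(pmf[pmf < obs - eps].sum() + 0.5 * pmf[np.abs(pmf - obs) <= eps].sum())
    return float(odds), float(min(p, 1.0))


def treatment_report(
    table: pd.DataFrame,
    control_label: str = "control",
    alpha: float = 0.05,
    alive_denominator: bool = False,
    midp: bool = False,
) -> pd.DataFrame:
    """Compare every non-control condition against control per day/outcome.

    For each (condition, day, outcome in {hatched, dead}) the report carries
    the replicate-level rate estimate, the control estimate, their
    difference, and the Fisher exact test on replicate-pooled counts.
    Returns an empty frame when only the control condition is present.
    """
    t = validate_cohort_table(table)
    if control_label not in set(t.condition):
        raise KeyError(f"control condition {control_label!r} not in table")
    rows = []
    conditions = [c for c in t.condition.unique() if c != control_label]
    for cond in conditions:
        for day in sorted(t[t.condition == cond].day.unique()):
            ctrl_rows = t[(t.condition == control_label) & (t.day == day)]
            if ctrl_rows.empty:
                raise KeyError(f"control has no rows at day {day}")
            cond_rows = t[(t.condition == cond) & (t.day == day)]
            for outcome in ("hatched", "dead"):
                est = rate_estimate(
                    t, cond, day, outcome, alive_denominator=alive_denominator
                )
                est_ctrl = rate_estimate(
                    t, control_label, day, outcome, alive_denominator=alive_denominator
                )
                sa, da = _outcome_counts(cond_rows, outcome, alive_denominator)
                sc, dc = _outcome_counts(ctrl_rows, outcome, alive_denominator)
                odds, p = proportion_test(
                    int(sa.sum()), int(da.sum()), int(sc.sum()), int(dc.sum()),
                    midp=midp,
                )
                rows.append(
                    {
                        "condition": cond,
                        "day": day,
                        "outcome": outcome,
                        "mean_pct": est.mean_pct,
                        "sem_pct": est.sem_pct,
                        "control_mean_pct": est_ctrl.mean_pct,
                        "control_sem_pct": est_ctrl.sem_pct,
                        "delta_pct": est.mean_pct - est_ctrl.mean_pct,
                        "odds_ratio": odds,
                        "p_value": p,
                        "significant": p < alpha,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "condition",
            "day",
            "outcome",
            "mean_pct",
            "sem_pct",
            "control_mean_pct",
            "control_sem_pct",
            "delta_pct",
            "odds_ratio",
            "p_value",
            "significant",
        ],
    )
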