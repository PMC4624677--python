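"""Dose-dependent rescue quantification and group comparisons.

Given per-animal behavioural metrics for a control group, a convulsant-
treated (PTZ) group and several anticonvulsant (VPA) dose groups, the rescue
fraction at a dose is

    R(d) = (M_ptz - M_d) / (M_ptz - M_ctrl),  clamped to [0, 1],

so R = 0 means no improvement over the PTZ baseline and R = 1 means full
return to the control mean. A two-parameter Hill curve
R(d) = d^h / (EC50^h + d^h) can be fitted to the empirical rescue curve.

Group comparisons default to the two-sided Mann-Whitney U test (locomotor
metrics are heavy-tailed); Welch's t-test is available via ``method``. Ties
are handled with mid-ranks and no continuity correction, so identical
samples give p = 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GroupMetrics",
    "RescueCurve",
    "rescue_fraction",
    "build_rescue_curve",
    "fit_hill",
    "compare_groups",
    "holm_correction",
]


@dataclass(frozen=True)
class GroupMetrics:
    """Per-animal values of one metric for one treatment arm."""

    label: str
    dose: float  # mmol/L; 0 for control and PTZ-only arms
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 2:
            raise ValueError("values must be 1-D with n >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class RescueCurve:
    doses: np.ndarray
    rescue_fractions: np.ndarray
    metric_name: str = "metric"

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        r = np.asarray(self.rescue_fractions, dtype=float)
        if d.shape != r.shape:
            raise ValueError("doses and rescue_fractions must align")
        if len(d) > 1 and np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any((r < 0) | (r > 1)):
            raise ValueError("rescue fractions must be clamped to [0, 1]")
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "rescue_fractions", r)


def rescue_fraction(mean_ctrl: float, mean_ptz: float, mean_dose: float) -> float:
    """Fractional return of a dose-group mean from the PTZ baseline to control.

    Affine-invariant: rescaling all three means by a common positive factor
    (or shifting all three) leaves the fraction unchanged.
    """
    if mean_ptz == mean_ctrl:
        raise ValueError(
            "PTZ and control means are equal: rescue baseline is undefined"
        )
    r = (mean_ptz - mean_dose) / (mean_ptz - mean_ctrl)
    return float(np.clip(r, 0.0, 1.0))


def build_rescue_curve(
    ctrl: GroupMetrics,
    ptz: GroupMetrics,
    dose_groups: Sequence[GroupMetrics],
    metric_name: str = "metric",
) -> RescueCurve:
    """Empirical rescue curve over the dose groups (sorted by dose)."""
    groups = sorted(dose_groups, key=lambda g: g.dose)
    doses = np.array([g.dose for g in groups], dtype=float)
    fracs = np.array(
        [rescue_fraction(ctrl.mean, ptz.mean, g.mean) for g in groups]
    )
    return RescueCurve(doses=doses, rescue_fractions=fracs, metric_name=metric_name)


def _hill(d: np.ndarray, ec50: float, h: float) -> np.ndarray:
    return d**h / (ec50**h + d**h)


def fit_hill(curve: RescueCurve) -> tuple[float, float, float]:
    """Least-squares 2-parameter Hill fit; returns (EC50, hill_slope, residual).

    EC50 is parameterised on a log scale for stability. The residual is the
    sum of squared deviations at the fitted parameters.
    """
    d = curve.doses
    r = curve.rescue_fractions
    if len(d) < 3:
        raise ValueError("need at least 3 doses")
    if np.ptp(r) == 0:
        raise ValueError("rescue fractions are all equal: Hill fit is degenerate")

    def loss(theta):
        ec50, h = np.exp(theta[0]), theta[1]
        return _hill(d, ec50, h) - r

    # start EC50 near the dose closest to half rescue
    i0 = int(np.argmin(np.abs(r - 0.5)))
    res = optimize.least_squares(
        loss, x0=[np.log(max(d[i0], 1e-6)), 1.5], method="lm", xtol=1e-14, ftol=1e-14
    )
    ec50 = float(np.exp(res.x[0]))
    h = float(res.x[1])
    residual = float(np.sum(res.fun**2))
    return ec50, h, residual


def compare_groups(a, b, method: str = "mann_whitney") -> tuple[float, float]:
    """Two-sided comparison of two groups of per-animal metric values.

    ``a`` and ``b`` may be :class:`GroupMetrics` or plain arrays.
    ``method`` is ``"mann_whitney"`` (default; exact when samples are small
    and tie-free, mid-rank normal approximation otherwise) or ``"welch"``.
    """
    va = np.asarray(a.values if isinstance(a, GroupMetrics) else a, dtype=float)
    vb = np.asarray(b.values if isinstance(b, GroupMetrics) else b, dtype=float)
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("each group needs n >= 2")
    if method == "mann_whitney":
        pooled = np.concatenate([va, vb])
        tie_free = len(np.unique(pooled)) == len(pooled)
        res = stats.mannwhitneyu(
            va,
            vb,
            alternative="two-sided",
            use_continuity=False,
            # exact null distribution when possible; the mid-rank normal
            # approximation (no continuity correction) when ties force it
            method="exact" if tie_free else "asymptotic",
        )
        return float(res.statistic), float(min(res.pvalue, 1.0))
    if method == "welch":
        if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
            raise ValueError(
                "both groups are constant and identical: Welch statistic is degenerate"
            )
        res = stats.ttest_ind(va, vb, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def holm_correction(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional multiplicity control)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
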