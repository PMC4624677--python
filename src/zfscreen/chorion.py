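"""Micropipette-aspiration stiffness analysis of the embryo chorion.

An aspiration recording pairs a stepped-pressure protocol with the measured
length of the membrane tongue drawn into the pipette, plus a shear-force time
trace. For an elastic membrane the pressure-length (P-L) relation is linear;
its slope, together with the pipette radius, yields the elastic moduli under
the classic half-space aspiration model

    E = 3 * phi * R_p * slope / (2 * pi),    G = E / (2 * (1 + nu)),

with shape factor ``phi`` (~2.1 for typical pipette wall geometry) and
Poisson ratio ``nu`` (0.5 for an incompressible membrane, giving
``G = phi * R_p * slope / (2 * pi)``). Membrane stiffening also shows up
kinematically as a shorter time to reach the peak of the shear-force trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rescue import compare_groups

__all__ = [
    "AspirationRecording",
    "PLFit",
    "StiffnessResult",
    "fit_pl_curve",
    "shear_modulus",
    "time_to_peak",
    "analyze_recording",
    "compare_stiffness",
    "PHI_DEFAULT",
    "POISSON_DEFAULT",
    "LINEARITY_THRESHOLD_DEFAULT",
]

PHI_DEFAULT = 2.1
POISSON_DEFAULT = 0.5
LINEARITY_THRESHOLD_DEFAULT = 0.98


@dataclass(frozen=True)
class AspirationRecording:
    """One embryo's aspiration data: P-L samples plus a force-time trace.

    Pressures in Pa (increasing aspiration steps), tongue lengths in m,
    force in arbitrary units (all force analysis is scale-invariant).
    """

    pressures: np.ndarray
    lengths: np.ndarray
    force_times: np.ndarray
    forces: np.ndarray
    pipette_radius: float

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures, dtype=float)
        l = np.asarray(self.lengths, dtype=float)
        if p.shape != l.shape:
            raise ValueError("pressures and lengths must align")
        if np.any(p < 0) or (len(p) > 1 and np.any(np.diff(p) <= 0)):
            raise ValueError("pressures must be >= 0 and strictly increasing")
        if np.any(l < 0):
            raise ValueError("lengths must be >= 0")
        t = np.asarray(self.force_times, dtype=float)
        if t.shape != np.asarray(self.forces, dtype=float).shape:
            raise ValueError("force_times and forces must align")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("force_times must be strictly increasing")
        if self.pipette_radius <= 0:
            raise ValueError("pipette_radius must be > 0")


@dataclass(frozen=True)
class PLFit:
    """Least-squares line through the P-L samples."""

    slope: float  # Pa / m
    intercept: float  # Pa
    r_squared: float
    linear_ok: bool


@dataclass(frozen=True)
class StiffnessResult:
    shear_modulus: float  # Pa
    time_to_peak: float  # ms
    fit: PLFit


def fit_pl_curve(
    rec: AspirationRecording,
    linearity_threshold: float = LINEARITY_THRESHOLD_DEFAULT,
) -> PLFit:
    """Ordinary least squares of pressure on tongue length.

    ``linear_ok`` flags whether r^2 reaches ``linearity_threshold``; a
    recording that fails the flag reflects non-elastic behaviour and should
    not be converted to a modulus.
    """
    p = np.asarray(rec.pressures, dtype=float)
    l = np.asarray(rec.lengths, dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 (P, L) samples")
    if np.ptp(l) == 0:
        raise ValueError("tongue lengths are constant: P-L fit is rank-deficient")
    res = stats.linregress(l, p)
    r2 = float(res.rvalue**2)
    return PLFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        linear_ok=bool(r2 >= linearity_threshold),
    )


def shear_modulus(
    fit: PLFit,
    pipette_radius: float,
    phi: float = PHI_DEFAULT,
    poisson: float = POISSON_DEFAULT,
) -> float:
    """Shear modulus (Pa) from the P-L slope via the half-space model."""
    if not fit.linear_ok:
        raise ValueError(
            "P-L fit is not linear (r^2 = "
            f"{fit.r_squared:.4f}); refusing to estimate a modulus"
        )
    if fit.slope < 0:
        raise ValueError("P-L slope must be >= 0")
    if pipette_radius <= 0:
        raise ValueError("pipette_radius must be > 0")
    if not 0.0 < poisson <= 0.5:
        raise ValueError("poisson must lie in (0, 0.5]")
    young = 3.0 * phi * pipette_radius * fit.slope / (2.0 * math.pi)
    return young / (2.0 * (1.0 + poisson))


def time_to_peak(
    force_times: np.ndarray,
    forces: np.ndarray,
    smoothing_window: int = 5,
    peak_fraction: float = 0.99,
) -> float:
    """Time (ms) from aspiration onset to the peak of the shear-force trace.

    The trace is smoothed with a centred moving average, then the first time
    at which it reaches ``peak_fraction`` of its maximum is returned. For a
    saturating-exponential rise F(t) = F_max (1 - exp(-t/tau)) recorded long
    enough that the trace saturates, this equals tau * ln(1/(1 - q)).
    """
    t = np.asarray(force_times, dtype=float)
    f = np.asarray(forces, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 force samples")
    if not 0.0 < peak_fraction <= 1.0:
        raise ValueError("peak_fraction must lie in (0, 1]")
    if smoothing_window > 1:
        w = int(smoothing_window)
        kern = np.ones(w) / w
        # centred mean with edge truncation (shorter window at the ends)
        f = np.convolve(f, kern, mode="same") / np.convolve(
            np.ones_like(f), kern, mode="same"
        )
    fmax = float(np.max(f))
    if fmax <= 0:
        raise ValueError("force trace has no positive peak")
    idx = int(np.argmax(f >= peak_fraction * fmax))
    return float(t[idx] * 1e3)


def analyze_recording(
    rec: AspirationRecording,
    phi: float = PHI_DEFAULT,
    poisson: float = POISSON_DEFAULT,
    linearity_threshold: float = LINEARITY_THRESHOLD_DEFAULT,
    smoothing_window: int = 5,
    peak_fraction: float = 0.99,
) -> StiffnessResult:
    """Full per-embryo analysis: P-L fit, modulus and time-to-peak."""
    fit = fit_pl_curve(rec, linearity_threshold=linearity_threshold)
    g = shear_modulus(fit, rec.pipette_radius, phi=phi, poisson=poisson)
    ttp = time_to_peak(
        rec.force_times,
        rec.forces,
        smoothing_window=smoothing_window,
        peak_fraction=peak_fraction,
    )
    return StiffnessResult(shear_modulus=g, time_to_peak=ttp, fit=fit)


def compare_stiffness(
    groups: list[tuple[str, list[StiffnessResult]]],
    metric: str = "shear_modulus",
    method: str = "mann_whitney",
):
    """Pairwise group comparisons of a stiffness metric.

    Returns a tidy :class:`pandas.DataFrame` with one row per ordered pair,
    symmetric in the two-sided p-value; self-comparisons give p = 1.
    """
    import pandas as pd

    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for label_a, res_a in groups:
        for label_b, res_b in groups:
            a = np.array([getattr(r, metric) for r in res_a], dtype=float)
            b = np.array([getattr(r, metric) for r in res_b], dtype=float)
            stat, p = compare_groups(a, b, method=method)
            rows.append(
                {
                    "group_a": label_a,
                    "group_b": label_b,
                    "mean_a": a.mean(),
                    "mean_b": b.mean(),
                    "statistic": stat,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
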