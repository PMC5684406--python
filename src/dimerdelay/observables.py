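"""Populations, coherence, steady-state limits and beating metrics.

Site populations are |c_n(t)|² and the inter-site coherence is the modulus
of the off-diagonal density-matrix element, |c₁*(t) c₂(t)|.  At destructive
feedback interference (e^{iφ} = −1) the system develops a trapped (dark)
component and the amplitude settles to the residual value 1/(1 + γ₀τ);
for any other phase it decays to zero.  Beating metrics quantify the
delay-induced population oscillations: dominant period, envelope decay rate
and oscillation count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dde import AmplitudeTrajectory
from .model import FeedbackCoupling

__all__ = [
    "ObservableSeries",
    "BeatingMetrics",
    "population",
    "coherence",
    "steady_state_amplitude",
    "beating_metrics",
    "decay_rate",
]


@dataclass
class ObservableSeries:
    """A labeled time series derived from a trajectory."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")

    def at(self, t):
        return np.interp(np.asarray(t, float), self.times, np.real(self.values))

    def to_csv(self, path, sidecar: bool = True) -> None:
        import json

        with open(path, "w", newline="") as fh:
            fh.write("t,value\n")
            np.savetxt(
                fh,
                np.column_stack([self.times, np.real(self.values)]),
                delimiter=",",
                fmt="%.17g",
            )
        if sidecar:
            with open(str(path) + ".meta.json", "w") as fh:
                json.dump({"label": self.label, **self.metadata}, fh, indent=2)


def population(traj: AmplitudeTrajectory, site: int = 0) -> ObservableSeries:
    """Site population |c_site(t)|²."""
    if not (0 <= site < traj.n_components):
        raise IndexError(
            f"site {site} out of range for a {traj.n_components}-component trajectory"
        )
    return ObservableSeries(
        times=traj.times,
        values=np.abs(traj.component(site)) ** 2,
        label=f"population[site {site + 1}]",
        metadata={"mode": traj.mode},
    )


def coherence(traj: AmplitudeTrajectory) -> ObservableSeries:
    """Inter-site coherence |c₁*(t) c₂(t)| (off-diagonal density element).

    Defined for two-component (dimer-mode) trajectories only; a scalar
    trajectory carries a single total amplitude with no site resolution.
    """
    if traj.n_components != 2:
        raise ValueError(
            "coherence needs a two-component trajectory; run the dimer "
            "cross-delay mode (solve_dimer_cross_delay) to resolve the sites"
        )
    return ObservableSeries(
        times=traj.times,
        values=np.abs(np.conj(traj.component(0)) * traj.component(1)),
        label="coherence |c1* c2|",
        metadata={"mode": traj.mode},
    )


def steady_state_amplitude(coupling: FeedbackCoupling, atol: float = 1e-12) -> float:
    """Long-time limit of |c(t)| for the undetuned model.

    Returns 1/(1 + γ₀τ) when the feedback interferes destructively
    (|1 + e^{iφ}| ≤ atol, i.e. φ = π), and 0 otherwise.  The limit is only
    established for δ₀ = 0; a detuned coupling is refused.
    """
    if coupling.delta0 != 0.0:
        raise ValueError("steady-state limit requires delta0 = 0")
    if abs(1.0 + np.exp(1j * coupling.phi)) <= atol:
        return 1.0 / (1.0 + coupling.gamma0 * coupling.tau)
    return 0.0


def _local_maxima(values: np.ndarray, tol: float = 1e-12):
    """Indices of strict local maxima; a flat plateau counts once (center)."""
    idx = []
    n = len(values)
    i = 1
    while i < n - 1:
        if values[i] - values[i - 1] > tol:
            j = i
            while j + 1 < n and abs(values[j + 1] - values[j]) <= tol:
                j += 1
            if j < n - 1 and values[j] - values[j + 1] > tol:
                idx.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.array(idx, dtype=int)


def _local_minima(values: np.ndarray, tol: float = 1e-12):
    return _local_maxima(-np.asarray(values), tol)


@dataclass
class BeatingMetrics:
    """Summary of population/coherence oscillations.

    ``beating`` is False (the "no beating" marker) when the series has too
    few extrema for a period estimate; the numeric fields are then None.
    """

    beating: bool
    period: Optional[float] = None  # fs, mean spacing of maxima
    envelope_rate: Optional[float] = None  # fs⁻¹, log-linear fit to maxima
    n_oscillations: int = 0  # maxima above the amplitude floor

    NO_BEATING = "no beating"


def beating_metrics(
    series: ObservableSeries, floor: float = 1e-4, tol: float = 1e-12
) -> BeatingMetrics:
    """Dominant period, envelope decay rate and count of oscillations.

    The period is the mean spacing of local maxima, the envelope rate the
    slope of a least-squares line through log(maxima), and the count the
    number of maxima above ``floor``.  A series with fewer than two maxima
    (or fewer than three extrema in total) gets the no-beating marker
    rather than an exception.
    """
    v = np.real(np.asarray(series.values, dtype=float))
    t = series.times
    maxima = _local_maxima(v, tol)
    minima = _local_minima(v, tol)
    if len(maxima) < 2 or len(maxima) + len(minima) < 3:
        return BeatingMetrics(beating=False)
    tm = t[maxima]
    vm = v[maxima]
    period = float(np.mean(np.diff(tm)))
    pos = vm > 0
    envelope_rate = None
    if pos.sum() >= 2:
        slope = np.polyfit(tm[pos], np.log(vm[pos]), 1)[0]
        envelope_rate = float(-slope)
    n_osc = int(np.sum(vm > floor))
    return BeatingMetrics(
        beating=True, period=period, envelope_rate=envelope_rate, n_oscillations=n_osc
    )


def decay_rate(series: ObservableSeries, tail_fraction: float = 0.25) -> float:
    """Late-time exponential decay rate fitted from the series tail.

    Fits log(values) against time over the trailing ``tail_fraction`` of the
    series (a plain least-squares line) and returns the negated slope in
    fs⁻¹.  For a population series this is 2·|Re s| of the dominant
    characteristic root once subdominant roots have died out.
    """
    v = np.real(np.asarray(series.values, dtype=float))
    t = series.times
    n0 = int(len(t) * (1.0 - tail_fraction))
    vv, tt = v[n0:], t[n0:]
    good = vv > 0
    if good.sum() < 2:
        raise ValueError("series tail has no positive values to fit")
    slope = np.polyfit(tt[good], np.log(vv[good]), 1)[0]
    return float(-slope)
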