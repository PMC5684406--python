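"""Feedback-coupling parameterization, spectral density and dissipation kernel.

An effective two-level system (the weak-excitation reduction of an excitonic
dimer) couples to a common phonon continuum at two points of a feedback loop.
The loop makes the system-bath coupling frequency-structured: an excitation
emitted into the bath revisits the system after a round-trip delay τ with an
accumulated phase φ.  The resulting spectral density is

    J(ω) = (γ₀/π) (1 + cos(ωτ + φ)),   ω > 0,

whose (two-sided) inverse Fourier transform is a three-delta dissipation
kernel with lags {−τ, 0, +τ} and weights {γ₀e^{−iφ}, 2γ₀, γ₀e^{iφ}} — the
memory structure that turns the amplitude equation of motion into a delay
differential equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FeedbackCoupling",
    "KernelWeights",
    "SpectralDensityCurve",
    "spectral_density",
    "coupling_coefficient",
    "kernel_weights",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class FeedbackCoupling:
    """Parameters of the delayed system-bath coupling.

    Parameters
    ----------
    gamma0 : float
        Coupling rate to the bath, fs⁻¹ (≥ 0).
    tau : float
        Feedback round-trip delay, fs (≥ 0).
    phi : float
        Feedback phase in radians (φ = 2φ₀, twice the one-way phase);
        stored reduced to [0, 2π).
    delta0 : float
        Detuning rate fs⁻¹ between the system transition and the rotating
        frame; zero in the undetuned model.
    omega0 : float
        Site transition rate fs⁻¹.  Informational only: it is absorbed by
        the rotating frame and never enters the dynamics.
    """

    gamma0: float
    tau: float
    phi: float = 0.0
    delta0: float = 0.0
    omega0: float = 0.0

    def __post_init__(self):
        for name in ("gamma0", "tau", "phi", "delta0", "omega0"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.gamma0 < 0:
            raise ValueError(f"gamma0 must be >= 0, got {self.gamma0}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        object.__setattr__(self, "phi", float(self.phi) % _TWO_PI)

    def replace(self, **kw) -> "FeedbackCoupling":
        return replace(self, **kw)

    def as_dict(self) -> dict:
        return {
            "gamma0": self.gamma0,
            "tau": self.tau,
            "phi": self.phi,
            "delta0": self.delta0,
            "omega0": self.omega0,
        }


def spectral_density(omega, coupling: FeedbackCoupling):
    """Feedback spectral density J(ω) = (γ₀/π)(1 + cos(ωτ + φ)) for ω > 0.

    The form is defined for positive frequencies only; non-positive input is
    a domain error.  Values are non-negative and bounded by 2γ₀/π.
    """
    om = np.asarray(omega, dtype=float)
    if np.any(om <= 0):
        raise ValueError("spectral density is defined for omega > 0 only")
    j = (coupling.gamma0 / math.pi) * (
        1.0 + np.cos(om * coupling.tau + coupling.phi)
    )
    # cos rounding can leave values at -1e-17; J is a density, clip to 0.
    j = np.clip(j, 0.0, None)
    return j if j.ndim else float(j)


def _two_sided_spectral_density(omega, coupling: FeedbackCoupling):
    """Formula extension of J(ω) to all ω (internal; Fourier-pair checks).

    Extending (γ₀/π)(1 + cos(ωτ + φ)) to the whole real line makes J and the
    three-delta dissipation kernel an exact Fourier pair.  Never exposed to
    users: the physical density is defined for ω > 0.
    """
    om = np.asarray(omega, dtype=float)
    return (coupling.gamma0 / math.pi) * (
        1.0 + np.cos(om * coupling.tau + coupling.phi)
    )


def coupling_coefficient(xi, omega_xi, M, coupling: FeedbackCoupling, phi0: float):
    """Discrete-mode coupling amplitude κ_ξ = √(2γ₀/M)·cos(ξ̄(ω_ξτ/2 + φ₀)).

    ``xi`` is the signed mode index (only its sign ξ̄ enters), ``omega_xi``
    the mode frequency in fs⁻¹, ``M`` the quantization time interval in fs
    (M → ∞ recovers the continuum density :func:`spectral_density`).
    """
    if M <= 0:
        raise ValueError(f"time interval M must be > 0, got {M}")
    sgn = np.sign(xi)
    amp = math.sqrt(2.0 * coupling.gamma0 / M)
    out = amp * np.cos(sgn * (np.asarray(omega_xi, float) * coupling.tau / 2.0 + phi0))
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class KernelWeights:
    """Lag/weight decomposition of the dissipation kernel.

    For the feedback coupling the kernel is three deltas,

        f(t − t′) = γ₀ e^{iφ} δ(t − τ − t′) + 2γ₀ δ(t − t′)
                    + γ₀ e^{−iφ} δ(t + τ − t′),

    stored as (lag, weight) pairs with lags (+τ, 0, −τ).  Only causal
    entries (lag ≥ 0) can contribute to the memory integral over [0, t];
    the lag-0 delta sits on the integration endpoint and carries half
    weight there.  ``conjugated=True`` swaps e^{iφ} ↔ e^{−iφ}, the sign
    convention under which the delayed term of the equation of motion
    carries e^{−iφ}; the two conventions coincide for φ ∈ {0, π}.
    """

    lags: tuple
    weights: tuple
    conjugated: bool = False

    def __post_init__(self):
        if len(self.lags) != len(self.weights):
            raise ValueError("lags and weights must have equal length")

    @property
    def causal(self) -> tuple:
        """Boolean flags: which entries have lag ≥ 0."""
        return tuple(lag >= 0 for lag in self.lags)

    def causal_entries(self):
        """(lag, weight) pairs with lag ≥ 0, endpoint convention untouched."""
        return [(l, w) for l, w in zip(self.lags, self.weights) if l >= 0]

    def weight_at(self, lag: float, atol: float = 1e-12) -> complex:
        for l, w in zip(self.lags, self.weights):
            if abs(l - lag) <= atol:
                return w
        raise KeyError(f"no kernel entry at lag {lag}")


def kernel_weights(coupling: FeedbackCoupling, conjugated: bool = False) -> KernelWeights:
    """Three-delta decomposition of the feedback dissipation kernel.

    Returns entries ordered [(+τ, γ₀e^{iφ}), (0, 2γ₀), (−τ, γ₀e^{−iφ})]
    (the printed spectral-density convention).  With ``conjugated=True`` the
    delayed-weight phases are conjugated, matching the sign the delayed term
    carries in the amplitude delay differential equation; the solvers use
    that convention throughout.
    """
    g0, tau, phi = coupling.gamma0, coupling.tau, coupling.phi
    eip = complex(math.cos(phi), math.sin(phi))
    w_plus, w_minus = (eip.conjugate(), eip) if conjugated else (eip, eip.conjugate())
    return KernelWeights(
        lags=(+tau, 0.0, -tau),
        weights=(g0 * w_plus, complex(2.0 * g0), g0 * w_minus),
        conjugated=conjugated,
    )


@dataclass(frozen=True)
class SpectralDensityCurve:
    """Sampled spectral density J(ω) on a frequency grid.

    ``omega`` is strictly increasing (fs⁻¹) and ``values`` non-negative.
    User-defined baths for the general multi-site engine are supplied in
    this form; the feedback density can be sampled into it via
    :meth:`from_coupling`.
    """

    omega: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        om = np.asarray(self.omega, dtype=float)
        va = np.asarray(self.values, dtype=float)
        if om.ndim != 1 or om.shape != va.shape:
            raise ValueError("omega and values must be 1-D arrays of equal length")
        if np.any(np.diff(om) <= 0):
            raise ValueError("omega grid must be strictly increasing")
        if np.any(va < 0):
            raise ValueError("spectral density values must be non-negative")
        object.__setattr__(self, "omega", om)
        object.__setattr__(self, "values", va)

    @classmethod
    def from_coupling(
        cls, coupling: FeedbackCoupling, omega: np.ndarray
    ) -> "SpectralDensityCurve":
        return cls(
            omega=np.asarray(omega, float),
            values=np.asarray(spectral_density(omega, coupling), float),
            label=f"feedback(gamma0={coupling.gamma0:g},tau={coupling.tau:g},phi={coupling.phi:g})",
        )

    def to_table(self, path) -> None:
        """Write a two-column delimited table (omega, J) with a header line."""
        np.savetxt(
            path,
            np.column_stack([self.omega, self.values]),
            header="omega_fs^-1\tJ",
            delimiter="\t",
            comments="# ",
        )

    @classmethod
    def from_table(cls, path, label: str = "") -> "SpectralDensityCurve":
        data = np.loadtxt(path)
        if data.ndim != 2 or data.shape[1] != 2:
            raise ValueError(f"expected a two-column table in {path}")
        return cls(omega=data[:, 0], values=data[:, 1], label=label)
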