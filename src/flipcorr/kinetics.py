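"""Single-compartment kinetics of hyperpolarization build-up and decay.

The nuclear polarization ``P`` is modelled as a single pool fed by a
polarization source (DNP microwave injection, SEOP, parahydrogen, ...)
and drained by relaxation::

    dP/dt = (A - P) * kW - kR * P

``A`` is the polarization capacity -- the ceiling of the process, set in
DNP by the thermal electron polarization -- ``kW`` the injection rate
constant and ``kR`` the relaxation rate constant.  The solution is
mono-exponential, which ties the model to the phenomenological form used
to fit experiments: a steady state ``P0 = A*kW/(kW+kR)`` approached with
time constant ``tau = 1/(kW+kR)``.  Setting ``kW = 0`` (microwave off)
leaves a pure exponential decay with ``tau_decay = 1/kR``.

All flip angles at the public boundary are in degrees; time units are an
opaque label ("a.u." or "s") that is carried through, never converted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.constants import Boltzmann, Planck

__all__ = [
    "GAMMA_E_OVER_GAMMA_1H",
    "RateParams",
    "PhenomParams",
    "ThermalContext",
    "params_from_observables",
    "observables_from_params",
    "polarization_at",
    "thermal_polarization",
    "electron_frequency",
    "enhancement_to_polarization",
    "polarization_to_enhancement",
    "apparent_params",
    "rf_relaxation_rate",
]

#: |gamma_e| / gamma_1H -- converts a 1H Larmor frequency into the
#: electron Larmor frequency at the same field.
GAMMA_E_OVER_GAMMA_1H = 658.21


@dataclass(frozen=True)
class RateParams:
    """Physical parameters of the rate equation dP/dt = (A-P)kW - kR*P.

    Parameters
    ----------
    A : float
        Polarization capacity, dimensionless fraction in (0, 1].
    kW : float
        Injection rate constant (1/time), >= 0.
    kR : float
        Relaxation rate constant (1/time), >= 0.  ``kW + kR`` must be
        positive, otherwise the model is degenerate (nothing evolves).
    """

    A: float
    kW: float
    kR: float

    def __post_init__(self) -> None:
        if not (0.0 < self.A <= 1.0):
            raise ValueError(f"capacity A must be in (0, 1], got {self.A}")
        if self.kW < 0.0 or self.kR < 0.0:
            raise ValueError(f"rate constants must be >= 0, got kW={self.kW}, kR={self.kR}")
        if self.kW + self.kR <= 0.0:
            raise ValueError("degenerate model: kW + kR must be > 0")

    @property
    def rate_sum(self) -> float:
        """Total rate kW + kR, the reciprocal build-up time constant."""
        return self.kW + self.kR


@dataclass(frozen=True)
class PhenomParams:
    """Phenomenological exponential parameters (steady state + time constant).

    ``mode`` distinguishes the build-up ansatz ``P0*(1 - exp(-t/tau))``
    from the decay ansatz ``P_init*exp(-t/tau)``; ``P_init`` is only
    meaningful for decays.
    """

    P0: float
    tau: float
    mode: str = "buildup"
    P_init: float | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0.0:
            raise ValueError(f"time constant must be > 0, got {self.tau}")
        if self.mode not in ("buildup", "decay"):
            raise ValueError(f"mode must be 'buildup' or 'decay', got {self.mode!r}")


@dataclass(frozen=True)
class ThermalContext:
    """Thermal-equilibrium bookkeeping for converting enhancements.

    The equilibrium polarization of a spin-1/2 species at Larmor
    frequency ``f`` and temperature ``T`` is ``tanh(h f / (2 kB T))``;
    the hyperpolarization enhancement is ``eps = P_hyp / P_eq``.
    """

    frequency: float  # Hz
    temperature: float  # K
    species: str = "electron"

    def __post_init__(self) -> None:
        if self.frequency <= 0.0:
            raise ValueError("frequency must be > 0")
        if self.temperature <= 0.0:
            raise ValueError("temperature must be > 0")

    @property
    def P_eq(self) -> float:
        return thermal_polarization(self.frequency, self.temperature)

    def enhancement(self, P_hyp: float) -> float:
        return polarization_to_enhancement(P_hyp, self.P_eq)

    def polarization(self, eps: float) -> float:
        return enhancement_to_polarization(eps, self.P_eq)


def params_from_observables(P0: float, tau: float, A: float = 1.0) -> RateParams:
    """Invert the observable pair (P0, tau) into rate constants.

    kW = P0 / (A * tau) and kR = (1 - P0/A) / tau.  Requires
    0 < P0 < A (a steady state at or above the capacity would force a
    negative relaxation rate) and tau > 0.
    """
    if tau <= 0.0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if not (0.0 < P0 < A):
        raise ValueError(
            f"steady-state polarization must satisfy 0 < P0 < A, got P0={P0}, A={A}"
        )
    kW = P0 / (A * tau)
    kR = (1.0 - P0 / A) / tau
    return RateParams(A=A, kW=kW, kR=kR)


def observables_from_params(r: RateParams) -> PhenomParams:
    """Steady state and build-up time constant of a rate-parameter set.

    P0 = A*kW/(kW+kR), tau = 1/(kW+kR).
    """
    k = r.rate_sum
    if k <= 0.0:
        raise ValueError("degenerate model: kW + kR must be > 0")
    return PhenomParams(P0=r.A * r.kW / k, tau=1.0 / k, mode="buildup")


def polarization_at(t, r: RateParams, P_init: float = 0.0):
    """Exact RF-free polarization at time(s) ``t``.

    General solution of the rate equation from an arbitrary start:
    ``P(t) = P0 + (P_init - P0) * exp(-(kW+kR) t)``.  Vectorized over
    ``t``; scalar in, scalar out.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("time must be >= 0")
    if not (0.0 <= P_init <= r.A):
        raise ValueError(f"P_init must be in [0, A], got {P_init}")
    obs = observables_from_params(r)
    out = obs.P0 + (P_init - obs.P0) * np.exp(-t_arr / obs.tau)
    return out if out.ndim else float(out)


def thermal_polarization(frequency: float, temperature: float) -> float:
    """Thermal-equilibrium polarization of a spin-1/2 species.

    ``P_eq = tanh(h*f / (2*kB*T))``.  For an electron at the field of a
    299 MHz 1H system (f ~ 197 GHz) and 3.3 K this gives 0.89.
    """
    if frequency <= 0.0 or temperature <= 0.0:
        raise ValueError("frequency and temperature must be > 0")
    return math.tanh(Planck * frequency / (2.0 * Boltzmann * temperature))


def electron_frequency(proton_frequency: float) -> float:
    """Electron Larmor frequency at the field of a given 1H frequency."""
    if proton_frequency <= 0.0:
        raise ValueError("frequency must be > 0")
    return proton_frequency * GAMMA_E_OVER_GAMMA_1H


def enhancement_to_polarization(eps: float, P_eq: float) -> float:
    """Absolute polarization from an enhancement: P = eps * P_eq."""
    if eps < 0.0:
        raise ValueError("enhancement must be >= 0")
    if not (0.0 < P_eq < 1.0):
        raise ValueError("P_eq must be in (0, 1)")
    return eps * P_eq


def polarization_to_enhancement(P: float, P_eq: float) -> float:
    """Enhancement from an absolute polarization: eps = P / P_eq."""
    if P < 0.0:
        raise ValueError("polarization must be >= 0")
    if not (0.0 < P_eq < 1.0):
        raise ValueError("P_eq must be in (0, 1)")
    return P / P_eq


def _check_scheme(theta: float, TR: float) -> None:
    if not (0.0 <= theta < 90.0):
        raise ValueError(f"flip angle must be in [0, 90) degrees, got {theta}")
    if TR <= 0.0:
        raise ValueError(f"repetition time must be > 0, got {TR}")


def apparent_params(r: RateParams, theta: float, TR: float) -> PhenomParams:
    """RF-perturbed (apparent) steady state and time constant.

    Sampling the polarization immediately before each pulse of a
    theta/TR readout train gives points that again lie exactly on a
    mono-exponential build-up, but with

    * ``tau' = 1 / (1/tau - ln(cos theta)/TR)`` -- the pulse train acts
      as an extra apparent relaxation channel of rate ``-ln(cos)/TR``;
    * ``P0' = P0 * (1 - E) / (1 - cos(theta)*E)`` with
      ``E = exp(-TR/tau)`` -- the pre-pulse fixed point of the
      evolve-then-pulse recurrence.

    At ``theta = 0`` both reduce to the unperturbed (P0, tau).
    """
    _check_scheme(theta, TR)
    obs = observables_from_params(r)
    if theta == 0.0:
        return obs
    c = math.cos(math.radians(theta))
    tau_app = 1.0 / (1.0 / obs.tau - math.log(c) / TR)
    E = math.exp(-TR / obs.tau)
    P0_app = obs.P0 * (1.0 - E) / (1.0 - c * E)
    return PhenomParams(P0=P0_app, tau=tau_app, mode="buildup")


def rf_relaxation_rate(theta: float, TR: float) -> float:
    """Apparent relaxation rate due to RF perturbations, sin(theta)/TR.

    A heuristic scale for how strongly a readout scheme depletes the
    polarization, used to order experiments by RF severity.
    """
    _check_scheme(theta, TR)
    return math.sin(math.radians(theta)) / TR
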