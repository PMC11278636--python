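"""Constitutive models, unit system and dimensionless groups.

The package models a micron-sized probe bead held by a ring-shaped ("halo")
optical trap and immersed in either a Newtonian solvent or a single-mode
Jeffreys fluid: a solvent dashpot of viscosity ``eta1`` in parallel with a
Maxwell element (spring ``G`` in series with a dashpot ``eta2``).  This module
holds the closed-form half of the physics — the complex modulus
``G*(omega) = G'(omega) + i G''(omega)`` of the models, the exponential
friction memory kernel of the Maxwell branch, the natural (dimensionless)
unit system of the trapped bead, and the Deborah-number bookkeeping — against
which the stochastic simulations are validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.constants import k as BOLTZMANN  # 1.380649e-23 J/K, SI exact

__all__ = [
    "BOLTZMANN",
    "JeffreysFluid",
    "ProbeParticle",
    "TrapGeometry",
    "UnitSystem",
    "DimensionlessGroups",
    "ComplexModulusCurve",
    "FeasibilityDiagnostics",
    "complex_modulus_jeffreys",
    "complex_modulus_newtonian",
    "memory_kernel",
    "memory_kernel_ft",
    "effective_stiffness",
    "unit_system",
    "dimensionless_groups",
    "feasibility_diagnostics",
]


def _require_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class JeffreysFluid:
    """Single-mode Jeffreys fluid: solvent dashpot in parallel with a Maxwell arm.

    Parameters
    ----------
    eta1 : float
        Solvent (background) viscosity in Pa·s. Must be positive.
    eta2 : float
        Viscosity of the Maxwell-branch dashpot in Pa·s. ``eta2 = 0``
        degenerates the model to a Newtonian fluid of viscosity ``eta1``.
    G : float
        Modulus of the Maxwell-branch spring in Pa. Required positive whenever
        ``eta2 > 0``; ignored (may be 0) in the Newtonian limit.
    """

    eta1: float
    eta2: float = 0.0
    G: float = 0.0

    def __post_init__(self) -> None:
        _require_positive("eta1", self.eta1)
        if self.eta2 < 0 or not np.isfinite(self.eta2):
            raise ValueError(f"eta2 must be >= 0, got {self.eta2!r}")
        if self.eta2 > 0:
            _require_positive("G (required when eta2 > 0)", self.G)

    @property
    def is_newtonian(self) -> bool:
        return self.eta2 == 0.0

    @property
    def tau2(self) -> float:
        """Maxwell relaxation time eta2/G (the fluid relaxation time tau)."""
        return 0.0 if self.is_newtonian else self.eta2 / self.G

    # Alias: the simulation sections of the physics use plain "tau".
    tau = tau2

    @property
    def tau1(self) -> float:
        """Solvent time constant eta1/G (zero in the Newtonian limit)."""
        return 0.0 if self.is_newtonian else self.eta1 / self.G

    @property
    def eta0(self) -> float:
        """Zero-shear viscosity eta1 + eta2."""
        return self.eta1 + self.eta2

    @classmethod
    def newtonian(cls, eta0: float) -> "JeffreysFluid":
        return cls(eta1=eta0, eta2=0.0, G=0.0)

    @classmethod
    def from_relaxation_time(cls, eta1: float, G: float, tau: float) -> "JeffreysFluid":
        """Build from (eta1, G, tau) with eta2 = G * tau."""
        return cls(eta1=eta1, eta2=G * tau, G=G)

    def to_dict(self) -> dict:
        return {"eta1": self.eta1, "eta2": self.eta2, "G": self.G}

    @classmethod
    def from_dict(cls, d: Mapping) -> "JeffreysFluid":
        return cls(eta1=float(d["eta1"]), eta2=float(d.get("eta2", 0.0)),
                   G=float(d.get("G", 0.0)))


@dataclass(frozen=True)
class ProbeParticle:
    """Spherical probe bead of radius ``radius_a`` at temperature ``temperature_T``."""

    radius_a: float
    temperature_T: float = 298.0

    def __post_init__(self) -> None:
        _require_positive("radius_a", self.radius_a)
        _require_positive("temperature_T", self.temperature_T)

    @property
    def kBT(self) -> float:
        return BOLTZMANN * self.temperature_T

    def friction(self, eta: float) -> float:
        """Stokes drag 6*pi*a*eta for a solvent of viscosity ``eta``."""
        _require_positive("eta", eta)
        return 6.0 * math.pi * self.radius_a * eta

    def to_dict(self) -> dict:
        return {"radius_a": self.radius_a, "temperature_T": self.temperature_T}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProbeParticle":
        return cls(radius_a=float(d["radius_a"]),
                   temperature_T=float(d.get("temperature_T", 298.0)))


@dataclass(frozen=True)
class TrapGeometry:
    """Toroidal trap: major radius R, radial/axial stiffnesses; azimuthal stiffness is zero.

    The trap attracts the bead to the circle of radius ``major_R`` in the
    z = 0 plane with stiffness ``kappa_r`` radially and ``kappa_z`` axially.
    The minor radius b of the thermally explored tube is not stored: it is the
    r.m.s. radial excursion, b = sqrt(kBT/kappa_r).
    """

    major_R: float
    kappa_r: float
    kappa_z: float

    def __post_init__(self) -> None:
        _require_positive("major_R", self.major_R)
        _require_positive("kappa_r", self.kappa_r)
        _require_positive("kappa_z", self.kappa_z)

    def minor_radius(self, particle: ProbeParticle) -> float:
        """Thermal minor radius b = sqrt(kBT / kappa_r)."""
        return math.sqrt(particle.kBT / self.kappa_r)

    def to_dict(self) -> dict:
        return {"major_R": self.major_R, "kappa_r": self.kappa_r,
                "kappa_z": self.kappa_z}

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrapGeometry":
        return cls(major_R=float(d["major_R"]), kappa_r=float(d["kappa_r"]),
                   kappa_z=float(d["kappa_z"]))


@dataclass(frozen=True)
class UnitSystem:
    """Natural units of the radially trapped bead.

    length_unit = sqrt(kBT/kappa_r) (r.m.s. radial excursion), time_unit =
    zeta0/kappa_r (inverse corner frequency of the radial trap in the pure
    solvent), friction_zeta0 = 6*pi*a*eta1.  All integration is done in these
    units; SI conversion happens only at the I/O boundary.
    """

    length_unit: float
    time_unit: float
    friction_zeta0: float
    kappa_r: float
    kBT: float

    # --- converters (SI <-> dimensionless) -------------------------------
    def length_to_hat(self, x_si: np.ndarray | float):
        return np.asarray(x_si) / self.length_unit

    def length_to_si(self, x_hat: np.ndarray | float):
        return np.asarray(x_hat) * self.length_unit

    def time_to_hat(self, t_si: np.ndarray | float):
        return np.asarray(t_si) / self.time_unit

    def time_to_si(self, t_hat: np.ndarray | float):
        return np.asarray(t_hat) * self.time_unit

    def omega_to_hat(self, w_si: np.ndarray | float):
        return np.asarray(w_si) * self.time_unit

    def omega_to_si(self, w_hat: np.ndarray | float):
        return np.asarray(w_hat) / self.time_unit

    @property
    def modulus_unit(self) -> float:
        """Natural modulus scale kappa_r/(6 pi a): converts dimensionless G* to Pa."""
        return self.kappa_r / (6.0 * math.pi * self._a)

    _a: float = field(default=float("nan"), repr=False)


def unit_system(kappa_r: float, fluid: JeffreysFluid,
                particle: ProbeParticle) -> UnitSystem:
    """Natural units of the compound trap+solvent system.

    length = sqrt(kBT/kappa_r), time = 6*pi*a*eta1/kappa_r.
    """
    _require_positive("kappa_r", kappa_r)
    zeta0 = particle.friction(fluid.eta1)
    return UnitSystem(
        length_unit=math.sqrt(particle.kBT / kappa_r),
        time_unit=zeta0 / kappa_r,
        friction_zeta0=zeta0,
        kappa_r=kappa_r,
        kBT=particle.kBT,
        _a=particle.radius_a,
    )


@dataclass(frozen=True)
class DimensionlessGroups:
    """The four dimensionless groups governing a halo-trapped bead in a Jeffreys fluid.

    De = tau * kappa_star / zeta0 compares the fluid relaxation time with the
    inverse corner frequency of the Maxwell-stiffness trap; De2 = tau *
    kappa_r / zeta0 = De * kappa_r / kappa_star is the analogue for the
    optical stiffness.  kappa_star = 6*pi*a*G is the Maxwell spring expressed
    as a trap-equivalent stiffness.
    """

    De: float
    De2: float
    kappa_star: float
    ratio_kstar_kr: float
    ratio_kz_kr: float

    def __post_init__(self) -> None:
        for name in ("De", "De2", "kappa_star", "ratio_kstar_kr", "ratio_kz_kr"):
            v = getattr(self, name)
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


def effective_stiffness(G: float, a: float) -> float:
    """Trap-equivalent stiffness of the Maxwell spring, kappa_star = 6*pi*a*G."""
    if G < 0:
        raise ValueError(f"G must be >= 0, got {G!r}")
    _require_positive("a", a)
    return 6.0 * math.pi * a * G


def dimensionless_groups(fluid: JeffreysFluid, particle: ProbeParticle,
                         geometry: TrapGeometry) -> DimensionlessGroups:
    """Deborah numbers and stiffness ratios for a fluid/particle/trap combination.

    For a Newtonian fluid (eta2 = 0) De = De2 = kappa_star = 0. The algebraic
    identity eta2 = De * eta1 holds by construction.
    """
    zeta0 = particle.friction(fluid.eta1)
    kstar = effective_stiffness(fluid.G if not fluid.is_newtonian else 0.0,
                                particle.radius_a)
    tau = fluid.tau2
    return DimensionlessGroups(
        De=tau * kstar / zeta0,
        De2=tau * geometry.kappa_r / zeta0,
        kappa_star=kstar,
        ratio_kstar_kr=kstar / geometry.kappa_r,
        ratio_kz_kr=geometry.kappa_z / geometry.kappa_r,
    )


@dataclass(frozen=True)
class ComplexModulusCurve:
    """Complex shear modulus G*(omega) on a strictly increasing frequency grid.

    ``gstar`` holds G'(omega) + i G''(omega); ``flags`` (optional) marks
    frequencies whose values are unreliable (outside the data-supported band,
    or trap-dominated), one bool per frequency, True = flagged.
    """

    omega: np.ndarray
    gstar: np.ndarray
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        gstar = np.asarray(self.gstar, dtype=complex)
        if omega.ndim != 1 or omega.size == 0:
            raise ValueError("omega must be a non-empty 1D array")
        if np.any(omega <= 0) or np.any(np.diff(omega) <= 0):
            raise ValueError("omega must be positive and strictly increasing")
        if gstar.shape != omega.shape:
            raise ValueError("gstar must match omega in shape")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "gstar", gstar)
        if self.flags is not None:
            flags = np.asarray(self.flags, dtype=bool)
            if flags.shape != omega.shape:
                raise ValueError("flags must match omega in shape")
            object.__setattr__(self, "flags", flags)

    @property
    def g_prime(self) -> np.ndarray:
        return self.gstar.real

    @property
    def g_double_prime(self) -> np.ndarray:
        return self.gstar.imag


def complex_modulus_jeffreys(fluid: JeffreysFluid,
                             omega: np.ndarray) -> ComplexModulusCurve:
    """Closed-form G*(omega) of the Jeffreys model.

    G'(omega) = G omega^2 tau2^2 / (1 + omega^2 tau2^2)
    G''(omega) = G omega [tau1 + tau2/(1 + omega^2 tau2^2)]

    written here with viscosities only (G tau2 = eta2, G tau1 = eta1) so that
    the Newtonian limit eta2 -> 0 is exact without dividing by G.  Equivalent
    to the complex form i omega eta1 + i omega eta2 / (1 + i omega tau2).
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be strictly positive")
    t2 = fluid.tau2
    denom = 1.0 + (omega * t2) ** 2
    g_p = omega**2 * t2 * fluid.eta2 / denom
    g_pp = omega * (fluid.eta1 + fluid.eta2 / denom)
    return ComplexModulusCurve(omega=omega, gstar=g_p + 1j * g_pp)


def complex_modulus_newtonian(eta0: float, omega: np.ndarray) -> ComplexModulusCurve:
    """Newtonian fluid: G' = 0, G'' = omega * eta0 exactly."""
    _require_positive("eta0", eta0)
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be strictly positive")
    return ComplexModulusCurve(omega=omega, gstar=1j * omega * eta0)


def memory_kernel(fluid: JeffreysFluid, particle: ProbeParticle,
                  t: np.ndarray | float) -> np.ndarray:
    """Exponential friction memory kernel of the Maxwell branch.

    zeta_p(t) = 6*pi*a*(eta2/tau)*exp(-t/tau) for t >= 0.  Its time integral
    is the Maxwell-branch Stokes drag 6*pi*a*eta2.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("memory kernel is defined for t >= 0 only")
    if fluid.is_newtonian:
        return np.zeros_like(t)
    tau = fluid.tau2
    return particle.friction(fluid.eta2) / tau * np.exp(-t / tau)


def memory_kernel_ft(fluid: JeffreysFluid, particle: ProbeParticle,
                     omega: np.ndarray | float) -> np.ndarray:
    """Fourier transform of the memory kernel: 6*pi*a*eta2 / (1 + i*omega*tau)."""
    omega = np.asarray(omega, dtype=float)
    if fluid.is_newtonian:
        return np.zeros(omega.shape, dtype=complex)
    return particle.friction(fluid.eta2) / (1.0 + 1j * omega * fluid.tau2)


@dataclass(frozen=True)
class FeasibilityDiagnostics:
    """Sampling-rate feasibility of a passive tracking measurement.

    tau_D is the time for the bead to diffuse the displacement d; sampling
    faster than 1/tau_D (lags shorter than tau_D, i.e. deborah > 1) makes the
    bead look stationary and biases moduli upwards.  For d^2 = 1e-17 m^2,
    a = 1 um and room temperature, tau_D evaluates to approximately eta/20
    seconds (eta in Pa·s) and the artefact threshold rate is ~20 kHz in water.
    """

    tau_D: float
    deborah: float
    threshold_rate: float
    threshold_lag_rule: float
    tau_tr: float | None = None


def feasibility_diagnostics(eta: float, particle: ProbeParticle, d: float,
                            tau_ob: float,
                            technique_length: float | None = None,
                            ) -> FeasibilityDiagnostics:
    """Diffusion-time diagnostics for a tracking setup.

    Parameters
    ----------
    eta : float
        Fluid viscosity [Pa·s].
    particle : ProbeParticle
        Probe bead (radius, temperature).
    d : float
        Displacement scale to resolve [m] (e.g. the spatial resolution).
    tau_ob : float
        Observation lag between frames [s].
    technique_length : float, optional
        Characteristic technique length L [m]; if given, the threshold lag
        tau_tr = L^2/D above which the probe leaves the measurement volume is
        also reported.
    """
    _require_positive("eta", eta)
    _require_positive("d", d)
    _require_positive("tau_ob", tau_ob)
    zeta = particle.friction(eta)
    tau_D = zeta * d**2 / particle.kBT
    tau_tr = None
    if technique_length is not None:
        _require_positive("technique_length", technique_length)
        D = particle.kBT / zeta
        tau_tr = technique_length**2 / D
    return FeasibilityDiagnostics(
        tau_D=tau_D,
        deborah=tau_D / tau_ob,
        threshold_rate=1.0 / tau_D,
        threshold_lag_rule=eta / 20.0,
        tau_tr=tau_tr,
    )
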