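"""Time-domain statistics to complex modulus: the GSER inversion stack.

Routes implemented (all Kramers–Kronig-free: storage and loss moduli come
from one complex expression, never reconstructed from each other):

* Free probe (azimuthal channel): G*(omega) = d*kBT / (3 pi a * i omega *
  msd_hat(omega)) for a d-dimensional MSD — the generalized Stokes–Einstein
  relation with the inertial term dropped (negligible below MHz for micron
  beads).  Equivalently through the creep compliance J(t) proportional to
  the MSD, with G* = 1/(i omega J_hat).
* Trapped probe (radial/axial channels): G*(omega) = (kappa / 6 pi a) *
  i omega A_hat / (1 - i omega A_hat), where A is the normalised position
  autocorrelation; the normalised MSD Pi = 1 - A gives algebraically
  identical forms.
* The closed-form check for a Jeffreys fluid: the trapped-probe inversion of
  the analytic autocorrelation must return the model's own G*(omega); the
  per-frequency residual of that identity is exposed as a diagnostic.

The Fourier transform of discrete, non-uniformly sampled data is done with
the closed-form unilateral transform of the piecewise-linear interpolant,
with explicit linear extrapolations below the first sample and beyond the
last one.  It is exact for data that are truly piecewise linear, which pins
the Newtonian self-consistency of the whole stack to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize as _opt

from .rheology_models import (
    ComplexModulusCurve,
    JeffreysFluid,
    ProbeParticle,
    complex_modulus_jeffreys,
)

__all__ = [
    "DiscreteFTSpec",
    "FTResult",
    "supported_band",
    "default_omega_grid",
    "estimate_terminal_gradient",
    "estimate_initial_gradient",
    "ft_piecewise_linear",
    "compliance_from_msd",
    "gser_free",
    "gser_trapped",
    "trapped_modulus_forms",
    "analytic_trapped_npaf",
    "analytic_trapped_npaf_transform",
    "jeffreys_gser_identity",
    "fit_jeffreys_modulus",
]


@dataclass(frozen=True)
class DiscreteFTSpec:
    """How to transform a finite data set: target grid and tail assumptions.

    ``value_at_zero`` and ``initial_gradient`` define the linear extension
    below the first sample (``initial_gradient=None``: straight line from
    (0, value_at_zero) to the first sample); ``terminal_gradient`` the linear
    tail beyond the last one (``None``: estimated by least squares on the
    last decade of samples).
    """

    omega: np.ndarray
    value_at_zero: float = 0.0
    initial_gradient: float | None = None
    terminal_gradient: float | None = None

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        if omega.ndim != 1 or omega.size == 0 or np.any(omega <= 0):
            raise ValueError("omega must be a 1D array of positive frequencies")
        object.__setattr__(self, "omega", omega)


@dataclass(frozen=True)
class FTResult:
    """Transform values with a per-frequency reliability mask (True = in band)."""

    omega: np.ndarray
    values: np.ndarray
    reliable: np.ndarray


def supported_band(t: np.ndarray) -> tuple[float, float]:
    """Frequency band supported by a sample-time grid: [2 pi/span, pi/min step]."""
    t = np.asarray(t, dtype=float)
    pos = t[t > 0]
    if pos.size < 2:
        raise ValueError("need at least two positive sample times")
    dt_min = np.diff(np.sort(np.unique(t))).min()
    return 2.0 * math.pi / pos.max(), math.pi / dt_min


def default_omega_grid(t: np.ndarray, points_per_decade: int = 10) -> np.ndarray:
    """Log-spaced frequency grid over the data-supported band."""
    lo, hi = supported_band(t)
    n = max(2, int(np.ceil(points_per_decade * np.log10(hi / lo))))
    return np.geomspace(lo, hi, n)


def estimate_terminal_gradient(t: np.ndarray, y: np.ndarray,
                               decades: float = 1.0) -> float:
    """Least-squares slope of the last ``decades`` decade(s) of samples."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = t >= t.max() / 10.0**decades
    if mask.sum() < 2:
        mask = np.zeros_like(t, dtype=bool)
        mask[-2:] = True
    return float(np.polyfit(t[mask], y[mask], 1)[0])


def estimate_initial_gradient(t: np.ndarray, y: np.ndarray,
                              n_points: int = 4) -> float:
    """Least-squares slope of the first ``n_points`` samples."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = min(n_points, t.size)
    if n < 2:
        raise ValueError("need at least two samples")
    return float(np.polyfit(t[:n], y[:n], 1)[0])


def ft_piecewise_linear(t: np.ndarray, y: np.ndarray,
                        spec: DiscreteFTSpec) -> FTResult:
    """Unilateral Fourier transform of the piecewise-linear interpolant.

    For g(t) piecewise linear with node values g_k at times t_k, initial
    value g(0), possible jumps D_j at times t_j, and terminal slope gdot_inf,

        i w ghat(w) = g(0) + sum_j D_j e^{-i w t_j}
                      + (1/(i w)) [ sum_segments c_s (e^{-i w a_s} - e^{-i w b_s})
                                    + gdot_inf e^{-i w t_N} ]

    (integration by parts twice; the divergent tail is regularised in the
    usual distributional sense).  Exact for truly piecewise-linear data.
    Frequencies outside the data-supported band are computed but flagged
    unreliable, never silently dropped.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or t.size < 2:
        raise ValueError("t and y must be matching 1D arrays with >= 2 samples")
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing with t[0] >= 0")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")

    omega = spec.omega
    term = (estimate_terminal_gradient(t, y)
            if spec.terminal_gradient is None else spec.terminal_gradient)

    # Segment list (start, end, slope) covering [0, t_N], plus any jump where
    # the sub-t0 linear extension does not land on the first sample.
    jumps_t: list[float] = []
    jumps_d: list[float] = []
    data_slopes = np.diff(y) / np.diff(t)
    if t[0] == 0.0:
        g0 = y[0]
        a_s, b_s, slopes = t[:-1], t[1:], data_slopes
    else:
        g0 = spec.value_at_zero
        if spec.initial_gradient is None:
            first_slope = (y[0] - g0) / t[0]
        else:
            first_slope = spec.initial_gradient
            extended = g0 + first_slope * t[0]
            if extended != y[0]:
                jumps_t.append(t[0])
                jumps_d.append(y[0] - extended)
        a_s = np.concatenate([[0.0], t[:-1]])
        b_s = t
        slopes = np.concatenate([[first_slope], data_slopes])

    iw = 1j * omega[:, None]
    seg = np.sum(slopes[None, :] * (np.exp(-iw * a_s[None, :])
                                    - np.exp(-iw * b_s[None, :])), axis=1)
    tail = term * np.exp(-1j * omega * t[-1])
    iw_ghat = g0 + (seg + tail) / (1j * omega)
    for tj, dj in zip(jumps_t, jumps_d):
        iw_ghat = iw_ghat + dj * np.exp(-1j * omega * tj)
    ghat = iw_ghat / (1j * omega)

    lo, hi = supported_band(t)
    reliable = (omega >= lo) & (omega <= hi)
    return FTResult(omega=omega, values=ghat, reliable=reliable)


def compliance_from_msd(msd_values: np.ndarray, particle: ProbeParticle,
                        dim: int = 1) -> np.ndarray:
    """Creep compliance from a probe MSD: J(t) = (3/d) * pi * a * MSD_d(t) / kBT.

    ``dim`` is the dimensionality of the MSD (1 for a single component such
    as the azimuthal arc length, 3 for the full-vector MSD, for which the
    prefactor reduces to pi*a/kBT).  J(0) = 0 for any viscoelastic fluid, as
    MSD(0) = 0 guarantees.
    """
    if dim not in (1, 2, 3):
        raise ValueError("dim must be 1, 2 or 3")
    msd_values = np.asarray(msd_values, dtype=float)
    if np.any(msd_values < 0):
        raise ValueError("MSD values must be non-negative")
    return (3.0 / dim) * math.pi * particle.radius_a * msd_values / particle.kBT


def _resolve_scales(particle: ProbeParticle | None, kBT: float | None,
                    radius: float | None) -> tuple[float, float]:
    if particle is not None:
        return particle.kBT, particle.radius_a
    if kBT is None or radius is None:
        raise ValueError("provide either particle or both kBT and radius")
    return float(kBT), float(radius)


def gser_free(t: np.ndarray, msd_values: np.ndarray,
              omega: np.ndarray | None = None, *,
              particle: ProbeParticle | None = None,
              kBT: float | None = None, radius: float | None = None,
              dim: int = 1,
              terminal_gradient: float | None = None) -> ComplexModulusCurve:
    """Complex modulus from the MSD of a force-free (azimuthal) component.

    G*(omega) = d * kBT / (3 pi a * i omega * msd_hat(omega)) for a
    d-dimensional MSD; the transform uses value 0 at t = 0 and a terminal
    gradient fitted to the last decade of lags (override with
    ``terminal_gradient``).  Frequencies outside the data-supported band are
    flagged in the returned curve.
    """
    kbt, a = _resolve_scales(particle, kBT, radius)
    t = np.asarray(t, dtype=float)
    msd_values = np.asarray(msd_values, dtype=float)
    if omega is None:
        omega = default_omega_grid(t)
    spec = DiscreteFTSpec(omega=omega, value_at_zero=0.0,
                          terminal_gradient=terminal_gradient)
    ft = ft_piecewise_linear(t, msd_values, spec)
    gstar = dim * kbt / (3.0 * math.pi * a * 1j * ft.omega * ft.values)
    return ComplexModulusCurve(omega=ft.omega, gstar=gstar,
                               flags=~ft.reliable)


def trapped_modulus_forms(A_hat: np.ndarray, omega: np.ndarray,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three algebraically equivalent trapped-probe expressions.

    Given the transform A_hat of the normalised position autocorrelation and
    Pi_hat = (1 - i omega A_hat)/(i omega) (transform of Pi = 1 - A), returns

        f1 = 1/(i omega Pi_hat) - 1
        f2 = i omega A_hat / (1 - i omega A_hat)
        f3 = A_hat / Pi_hat

    each equal to G*(omega) * 6 pi a / kappa.
    """
    iwA = 1j * omega * np.asarray(A_hat, dtype=complex)
    pi_hat = (1.0 - iwA) / (1j * omega)
    f1 = 1.0 / (1j * omega * pi_hat) - 1.0
    f2 = iwA / (1.0 - iwA)
    f3 = np.asarray(A_hat, dtype=complex) / pi_hat
    return f1, f2, f3


def gser_trapped(t: np.ndarray, corr_values: np.ndarray, kappa: float,
                 omega: np.ndarray | None = None, *,
                 particle: ProbeParticle | None = None,
                 radius: float | None = None,
                 input_kind: str = "npaf",
                 trap_dominated_threshold: float = 0.05,
                 terminal_gradient: float | None = 0.0) -> ComplexModulusCurve:
    """Complex modulus from a trapped component's A(tau) or Pi(tau).

    G*(omega) = (kappa / 6 pi a) * i omega A_hat / (1 - i omega A_hat).
    ``input_kind`` is "npaf" (A, value 1 at tau=0) or "nmsd" (Pi, value 0 at
    tau=0; converted through the identity i omega Pi_hat = 1 - i omega A_hat).
    Frequencies where |G*| 6 pi a / kappa falls below
    ``trap_dominated_threshold`` are flagged: there the trap compliance
    overshadows the fluid and the recovered modulus is untrustworthy, as are
    frequencies outside the data-supported band.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if particle is not None:
        a = particle.radius_a
    elif radius is not None:
        a = float(radius)
    else:
        raise ValueError("provide particle or radius")
    t = np.asarray(t, dtype=float)
    corr_values = np.asarray(corr_values, dtype=float)
    if omega is None:
        omega = default_omega_grid(t)
    if input_kind == "npaf":
        spec = DiscreteFTSpec(omega=omega, value_at_zero=1.0,
                              terminal_gradient=terminal_gradient)
        ft = ft_piecewise_linear(t, corr_values, spec)
        iwA = 1j * ft.omega * ft.values
    elif input_kind == "nmsd":
        spec = DiscreteFTSpec(omega=omega, value_at_zero=0.0,
                              terminal_gradient=terminal_gradient)
        ft = ft_piecewise_linear(t, corr_values, spec)
        iwA = 1.0 - 1j * ft.omega * ft.values
    else:
        raise ValueError("input_kind must be 'npaf' or 'nmsd'")
    denom = 1.0 - iwA
    floor = np.finfo(float).eps * 100
    degenerate = np.abs(denom) < floor
    denom = np.where(degenerate, floor, denom)
    reduced = iwA / denom
    gstar = kappa / (6.0 * math.pi * a) * reduced
    flags = (~ft.reliable) | degenerate \
        | (np.abs(reduced) < trap_dominated_threshold)
    return ComplexModulusCurve(omega=ft.omega, gstar=gstar, flags=flags)


def _trapped_embedding_modes(fluid: JeffreysFluid, particle: ProbeParticle,
                             kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """Decay rates and weights of A(tau) for a 1D trapped bead in a Jeffreys fluid.

    From the two-variable Markovian embedding (bead position x, auxiliary Q):
    the stationary autocorrelation of a linear OU system is
    C(tau) = exp(-M tau) Sigma with Sigma = diag(kBT/kappa, kBT/kappa_star),
    so A(tau) = sum_i c_i exp(-lambda_i tau) from the eigen-decomposition of
    the drift matrix M.  Rates may form a complex-conjugate pair; A(tau) is
    real either way.
    """
    if fluid.is_newtonian:
        zeta0 = particle.friction(fluid.eta1)
        return (np.array([kappa / zeta0], dtype=complex),
                np.array([1.0], dtype=complex))
    zeta0 = particle.friction(fluid.eta1)
    kstar = 6.0 * math.pi * particle.radius_a * fluid.G
    tau = fluid.tau2
    M = np.array([
        [kappa / zeta0, kstar / zeta0],
        [kappa / zeta0, (kstar + zeta0 / tau) / zeta0],
    ])
    Sigma = np.diag([particle.kBT / kappa, particle.kBT / kstar])
    lam, V = np.linalg.eig(M.astype(complex))
    Vinv = np.linalg.inv(V)
    right = Vinv @ Sigma[:, 0]
    weights = V[0, :] * right / Sigma[0, 0]
    return lam, weights


def analytic_trapped_npaf(fluid: JeffreysFluid, particle: ProbeParticle,
                          kappa: float, tau_grid: np.ndarray) -> np.ndarray:
    """Closed-form A(tau) for a 1D harmonically trapped bead in the model fluid."""
    lam, w = _trapped_embedding_modes(fluid, particle, kappa)
    tau_grid = np.asarray(tau_grid, dtype=float)
    vals = np.sum(w[None, :] * np.exp(-lam[None, :] * tau_grid[:, None]), axis=1)
    return vals.real


def analytic_trapped_npaf_transform(fluid: JeffreysFluid,
                                    particle: ProbeParticle, kappa: float,
                                    omega: np.ndarray) -> np.ndarray:
    """Closed-form A_hat(omega): sum_i c_i / (lambda_i + i omega)."""
    lam, w = _trapped_embedding_modes(fluid, particle, kappa)
    omega = np.asarray(omega, dtype=float)
    return np.sum(w[None, :] / (lam[None, :] + 1j * omega[:, None]), axis=1)


def jeffreys_gser_identity(fluid: JeffreysFluid, particle: ProbeParticle,
                           kappa: float, omega: np.ndarray,
                           A_hat: np.ndarray | None = None) -> np.ndarray:
    """Per-frequency relative residual of the trapped-probe identity.

    Left side: the Jeffreys model's own G*(omega) written in viscosities,
    omega^2 tau eta2/(1 + omega^2 tau^2) + i omega [eta1 + eta2/(1 + omega^2
    tau^2)].  Right side: (kappa/6 pi a) i omega A_hat/(1 - i omega A_hat)
    with ``A_hat`` analytic (default) or supplied from data.  For the exact
    transform the residual vanishes; on simulated data it measures the
    end-to-end inversion error.
    """
    omega = np.asarray(omega, dtype=float)
    lhs = complex_modulus_jeffreys(fluid, omega).gstar
    if A_hat is None:
        A_hat = analytic_trapped_npaf_transform(fluid, particle, kappa, omega)
    iwA = 1j * omega * A_hat
    rhs = kappa / (6.0 * math.pi * particle.radius_a) * iwA / (1.0 - iwA)
    return np.abs(lhs - rhs) / np.abs(lhs)


def fit_jeffreys_modulus(curve: ComplexModulusCurve, eta1: float,
                         use_flags: bool = True) -> tuple[float, float]:
    """Recover (G, tau) of a Jeffreys fluid from a measured modulus curve.

    The solvent viscosity eta1 is assumed known (it is in any designed
    experiment).  Fits log G and log tau by least squares on the relative
    errors of both moduli, using only unflagged frequencies when available.
    """
    omega = curve.omega
    gp = curve.g_prime
    gpp = curve.g_double_prime
    if use_flags and curve.flags is not None:
        keep = ~curve.flags
        if keep.sum() >= 4:
            omega, gp, gpp = omega[keep], gp[keep], gpp[keep]
    if omega.size < 4:
        raise ValueError("not enough usable frequencies for a Jeffreys fit")
    gstar = gp + 1j * gpp
    scale = np.abs(gstar)

    def resid(p):
        G = np.exp(p[0])
        tau = np.exp(p[1])
        den = 1.0 + (omega * tau) ** 2
        m = (G * (omega * tau) ** 2 / den
             + 1j * omega * (eta1 + G * tau / den))
        r = (m - gstar) / scale  # relative to |G*|: robust to noisy signs
        return np.concatenate([r.real, r.imag])

    good = gp > 0
    if good.sum() < 2:
        raise ValueError("storage modulus is nowhere positive: no elastic "
                         "signal to fit")
    G0 = float(np.median(gp[good][-max(3, good.sum() // 4):]))
    excess = gpp - omega * eta1
    if np.any(excess > 0):
        tau0 = 1.0 / omega[int(np.argmax(excess))]
    else:
        tau0 = 1.0 / np.sqrt(omega.min() * omega.max())
    sol = _opt.least_squares(resid, x0=[np.log(G0), np.log(tau0)])
    return float(np.exp(sol.x[0])), float(np.exp(sol.x[1]))
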