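"""Brownian dynamics of an overdamped bead in a toroidal optical trap.

Everything here integrates the dimensionless equations of motion, with
lengths in units of sqrt(kBT/kappa_r) and time in units of zeta0/kappa_r
(the inverse radial corner frequency in the pure solvent).  Two integrators
are provided:

* :func:`simulate_newtonian` — the bead in a Newtonian solvent, three coupled
  overdamped Langevin equations with the ring-trap force.
* :func:`simulate_jeffreys` — the bead in a single-mode Jeffreys fluid.  The
  exponential memory kernel of the Maxwell branch is removed by a Markovian
  embedding: one auxiliary length-valued variable Q per axis turns the
  non-Markovian dynamics into six coupled memoryless SDEs.  The Maxwell
  branch couples the bead and Q through a shared Wiener increment dW1, on top
  of the independent solvent increment dW0; the three noise amplitudes
  sqrt(2/(De+1)), sqrt(2De/(De+1)) and sqrt(2(De+1)/De) reproduce
  equipartition (var zhat = kappa_r/kappa_z, var Qhat = kappa_r/kappa_star)
  exactly, which the test suite uses to lock the transcription.

Both use Euler–Maruyama: the noise is additive, the dynamics overdamped, and
weak first order is sufficient for the ensemble statistics extracted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .rheology_models import TrapGeometry

__all__ = [
    "SimulationConfig",
    "TrajectoryEnsemble",
    "trap_force",
    "initial_state",
    "simulate_newtonian",
    "simulate_jeffreys",
]

#: Bead closer than this (dimensionless) to the z-axis aborts the run: the
#: ring force direction is undefined there and, for any sane geometry
#: (R_hat >= 10), reaching it signals a mis-configured run, not physics.
Z_AXIS_GUARD = 1e-12


@dataclass(frozen=True)
class SimulationConfig:
    """Run-control block for the stochastic integrators.

    ``n_steps`` counts post-burn-in integration steps; the burn-in span
    ``burn_in_hat`` (dimensionless time, ``None`` = integrator default) is
    simulated and discarded before recording starts.  Every ``save_stride``-th
    post-burn-in state is recorded, always including the initial one.
    """

    dt_hat: float
    n_steps: int
    n_particles: int
    seed: int
    burn_in_hat: float | None = 0.0
    save_stride: int = 1

    def __post_init__(self) -> None:
        if self.dt_hat <= 0:
            raise ValueError("dt_hat must be positive")
        if self.n_steps < 1 or self.n_particles < 1:
            raise ValueError("n_steps and n_particles must be >= 1")
        if self.burn_in_hat is not None and self.burn_in_hat < 0:
            raise ValueError("burn_in_hat must be >= 0")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_steps // self.save_stride + 1


@dataclass
class TrajectoryEnsemble:
    """Recorded ensemble: uniform time grid plus per-particle 3D positions.

    ``positions`` has shape (n_particles, n_samples, 3) in the order
    (x, y, z).  ``aux_Q`` (same shape) carries the Maxwell-branch auxiliary
    variables and is present exactly when the run was viscoelastic (De > 0).
    ``params`` is the full provenance block (geometry, fluid groups, config,
    units tag) from which the run can be reproduced.
    """

    times: np.ndarray
    positions: np.ndarray
    aux_Q: np.ndarray | None = None
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1D")
        dt = np.diff(self.times)
        if self.times.size > 1 and (np.any(dt <= 0) or not np.allclose(
                dt, dt[0], rtol=1e-9, atol=0.0)):
            raise ValueError("times must be strictly increasing and uniform")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3 \
                or self.positions.shape[1] != self.times.size:
            raise ValueError(
                "positions must have shape (n_particles, n_samples, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        if self.aux_Q is not None:
            self.aux_Q = np.asarray(self.aux_Q, dtype=float)
            if self.aux_Q.shape != self.positions.shape:
                raise ValueError("aux_Q must match positions in shape")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def dt_sample(self) -> float:
        return float(self.times[1] - self.times[0])


def trap_force(position: np.ndarray, geometry: TrapGeometry) -> np.ndarray:
    """Restoring force of the toroidal trap at a point (SI or any consistent units).

    F = -kappa_r (1 - R/rho) (x, y, 0) - kappa_z z (0, 0, 1), rho = sqrt(x^2+y^2):
    the negative gradient of U = kappa_r/2 (rho - R)^2 + kappa_z/2 z^2.  The
    azimuthal component is identically zero.  Accepts a single 3-vector or an
    (..., 3) array.
    """
    p = np.asarray(position, dtype=float)
    if p.shape[-1] != 3:
        raise ValueError("position must have 3 components on the last axis")
    rho = np.hypot(p[..., 0], p[..., 1])
    if np.any(rho <= 0):
        raise ValueError("force undefined on the z-axis (x = y = 0)")
    factor = -geometry.kappa_r * (1.0 - geometry.major_R / rho)
    out = np.empty_like(p)
    out[..., 0] = factor * p[..., 0]
    out[..., 1] = factor * p[..., 1]
    out[..., 2] = -geometry.kappa_z * p[..., 2]
    return out


def _ring_drift_xy(x: np.ndarray, y: np.ndarray, R_hat: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless ring-trap drift on (x, y): -(1 - R_hat/rho) * (x, y)."""
    rho = np.hypot(x, y)
    if np.any(rho < Z_AXIS_GUARD):
        raise RuntimeError(
            "particle reached the z-axis: ring force undefined; "
            "check R_hat and dt_hat (this should never happen for R_hat >= 10)")
    f = -(1.0 - R_hat / rho)
    return f * x, f * y


def initial_state(R_hat: float, kz_over_kr: float, n_particles: int,
                  rng: np.random.Generator, with_Q: bool = False,
                  ) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw initial bead states on the ring with thermal transverse spread.

    Azimuth uniform on the generator circle; radial offset N(0, 1) and axial
    offset N(0, kappa_r/kappa_z) (the stationary variances).  The auxiliary
    variables start at Q = 0, the zero-force fixed point of the Maxwell
    branch; burn-in completes equilibration.
    """
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_particles)
    r = R_hat + rng.standard_normal(n_particles)
    z = np.sqrt(1.0 / kz_over_kr) * rng.standard_normal(n_particles)
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    Q = np.zeros_like(pos) if with_Q else None
    return pos, Q


def _check_ring_geometry(R_hat: float, kz_over_kr: float) -> None:
    if kz_over_kr <= 0:
        raise ValueError("kz_over_kr must be positive")
    if R_hat <= 3.0:
        raise ValueError(
            f"R_hat must exceed 3 (torus wide relative to thermal width), got {R_hat}")


def _record_grid(config: SimulationConfig) -> tuple[np.ndarray, int]:
    n_rec = config.n_samples
    times = np.arange(n_rec) * (config.save_stride * config.dt_hat)
    return times, n_rec


def simulate_newtonian(R_hat: float, kz_over_kr: float,
                       config: SimulationConfig) -> TrajectoryEnsemble:
    """Euler–Maruyama integration of the bead in a Newtonian solvent.

    Dimensionless equations (unit radial stiffness, unit friction, kBT = 1):

        dx = -(1 - R_hat/rho) x dt + sqrt(2) dWx
        dy = -(1 - R_hat/rho) y dt + sqrt(2) dWy
        dz = -(kz/kr) z dt + sqrt(2) dWz

    The burn-in span (default 10 dimensionless time units) is simulated and
    discarded.  Identical config + seed gives a bit-identical ensemble.
    """
    _check_ring_geometry(R_hat, kz_over_kr)
    dt_max = 0.05 * min(1.0, 1.0 / kz_over_kr)
    if config.dt_hat > dt_max:
        raise ValueError(
            f"dt_hat={config.dt_hat} exceeds stability guard {dt_max:.4g} "
            "(0.05 x fastest relaxation time)")
    burn_in = 10.0 if config.burn_in_hat is None else config.burn_in_hat
    n_burn = int(round(burn_in / config.dt_hat))

    rng = np.random.default_rng(config.seed)
    pos, _ = initial_state(R_hat, kz_over_kr, config.n_particles, rng)
    x, y, z = pos[:, 0].copy(), pos[:, 1].copy(), pos[:, 2].copy()

    dt = config.dt_hat
    amp = np.sqrt(2.0 * dt)
    times, n_rec = _record_grid(config)
    out = np.empty((config.n_particles, n_rec, 3))

    def step() -> None:
        nonlocal x, y, z
        fx, fy = _ring_drift_xy(x, y, R_hat)
        noise = rng.standard_normal((3, config.n_particles))
        x = x + fx * dt + amp * noise[0]
        y = y + fy * dt + amp * noise[1]
        z = z - kz_over_kr * z * dt + amp * noise[2]

    for _ in range(n_burn):
        step()
    out[:, 0, 0], out[:, 0, 1], out[:, 0, 2] = x, y, z
    rec = 1
    for i in range(1, config.n_steps + 1):
        step()
        if i % config.save_stride == 0:
            out[:, rec, 0], out[:, rec, 1], out[:, rec, 2] = x, y, z
            rec += 1
    out = out[:, :rec]
    times = times[:rec]

    params = {
        "model": "newtonian",
        "R_hat": R_hat,
        "kz_over_kr": kz_over_kr,
        "config": {
            "dt_hat": config.dt_hat, "n_steps": config.n_steps,
            "n_particles": config.n_particles, "seed": config.seed,
            "burn_in_hat": burn_in, "save_stride": config.save_stride,
        },
        "units": "dimensionless",
    }
    return TrajectoryEnsemble(times=times, positions=out, params=params)


def default_burn_in_jeffreys(De: float, kstar_over_kr: float) -> float:
    """Default equilibration span: ten relaxation times of the slowest mode.

    The fluid mode relaxes on tau_hat = De * kappa_r / kappa_star (the fluid
    relaxation time in corner-frequency units); the trap modes on <= 1.
    """
    return max(10.0, 10.0 * De / kstar_over_kr)


def simulate_jeffreys(R_hat: float, kz_over_kr: float, kstar_over_kr: float,
                      De: float, config: SimulationConfig) -> TrajectoryEnsemble:
    """Euler–Maruyama integration of the bead in a Jeffreys fluid (Markovian embedding).

    The six dimensionless SDEs integrated, with rho = sqrt(x^2 + y^2),
    alpha = kappa_star/kappa_r and the ring drift g(x) = -(1 - R_hat/rho) x:

        dx  = [g(x) - alpha Qx] dt + sqrt(2/(De+1)) dWx0 + sqrt(2De/(De+1)) dWx1
        dz  = [-(kz/kr) z - alpha Qz] dt + (same two noises)
        dQx = [g(x) - alpha (De+1)/De Qx] dt + sqrt(2(De+1)/De) dWx1

    (y like x, Qy/Qz like Qx with their axis drifts).  dW1 is SHARED between
    each position equation and its paired Q equation — the correlation is part
    of the embedding, not an implementation detail.  De = 0 is rejected: use
    :func:`simulate_newtonian` (the Q-noise diverges as De -> 0).
    """
    _check_ring_geometry(R_hat, kz_over_kr)
    if De <= 0:
        raise ValueError("De must be > 0; route De = 0 to simulate_newtonian")
    if kstar_over_kr <= 0:
        raise ValueError("kstar_over_kr must be positive")
    alpha = kstar_over_kr
    beta = (De + 1.0) / De
    dt_max = 0.05 * min(1.0, 1.0 / (beta * alpha), 1.0 / kz_over_kr)
    if config.dt_hat > dt_max:
        raise ValueError(
            f"dt_hat={config.dt_hat} exceeds stability guard {dt_max:.4g} "
            "(0.05 x fastest relaxation time incl. the Q mode)")
    burn_in = (default_burn_in_jeffreys(De, alpha)
               if config.burn_in_hat is None else config.burn_in_hat)
    n_burn = int(round(burn_in / config.dt_hat))

    rng = np.random.default_rng(config.seed)
    pos, Q = initial_state(R_hat, kz_over_kr, config.n_particles, rng,
                           with_Q=True)
    x, y, z = pos[:, 0].copy(), pos[:, 1].copy(), pos[:, 2].copy()
    qx, qy, qz = Q[:, 0].copy(), Q[:, 1].copy(), Q[:, 2].copy()

    dt = config.dt_hat
    a0 = np.sqrt(2.0 / (De + 1.0) * dt)          # solvent noise on positions
    a1 = np.sqrt(2.0 * De / (De + 1.0) * dt)     # shared noise on positions
    aQ = np.sqrt(2.0 * (De + 1.0) / De * dt)     # shared noise on Q
    times, n_rec = _record_grid(config)
    out = np.empty((config.n_particles, n_rec, 3))
    outQ = np.empty_like(out)

    def step() -> None:
        nonlocal x, y, z, qx, qy, qz
        gx, gy = _ring_drift_xy(x, y, R_hat)
        gz = -kz_over_kr * z
        w0 = rng.standard_normal((3, config.n_particles))
        w1 = rng.standard_normal((3, config.n_particles))
        x_n = x + (gx - alpha * qx) * dt + a0 * w0[0] + a1 * w1[0]
        y_n = y + (gy - alpha * qy) * dt + a0 * w0[1] + a1 * w1[1]
        z_n = z + (gz - alpha * qz) * dt + a0 * w0[2] + a1 * w1[2]
        qx = qx + (gx - alpha * beta * qx) * dt + aQ * w1[0]
        qy = qy + (gy - alpha * beta * qy) * dt + aQ * w1[1]
        qz = qz + (gz - alpha * beta * qz) * dt + aQ * w1[2]
        x, y, z = x_n, y_n, z_n

    for _ in range(n_burn):
        step()
    out[:, 0, 0], out[:, 0, 1], out[:, 0, 2] = x, y, z
    outQ[:, 0, 0], outQ[:, 0, 1], outQ[:, 0, 2] = qx, qy, qz
    rec = 1
    for i in range(1, config.n_steps + 1):
        step()
        if i % config.save_stride == 0:
            out[:, rec, 0], out[:, rec, 1], out[:, rec, 2] = x, y, z
            outQ[:, rec, 0], outQ[:, rec, 1], outQ[:, rec, 2] = qx, qy, qz
            rec += 1
    out = out[:, :rec]
    outQ = outQ[:, :rec]
    times = times[:rec]

    params = {
        "model": "jeffreys",
        "R_hat": R_hat,
        "kz_over_kr": kz_over_kr,
        "kstar_over_kr": kstar_over_kr,
        "De": De,
        "config": {
            "dt_hat": config.dt_hat, "n_steps": config.n_steps,
            "n_particles": config.n_particles, "seed": config.seed,
            "burn_in_hat": burn_in, "save_stride": config.save_stride,
        },
        "units": "dimensionless",
    }
    return TrajectoryEnsemble(times=times, positions=out, aux_Q=outQ,
                              params=params)
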