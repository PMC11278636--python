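"""Torus-adapted trajectory statistics: MSD, NPAF, NMSD and anisotropy.

The natural coordinates of a halo-trapped bead are the radial distance r,
the axial position z and the azimuthal arc length s = R_hat * theta
(theta unwrapped).  Radial and axial motion are confined and stationary;
azimuthal motion is free diffusion.  Correlation estimators average over all
time origins and all particles.

Conventions that matter:

* The azimuthal MSD uses the arc length at the FIXED trap radius R_hat, not
  the instantaneous bead radius, which makes it independent of torus size and
  directly comparable to 1D free diffusion.
* The radial autocorrelation is computed on (r - R_hat) WITHOUT removing the
  empirical mean: on a narrow torus the stationary mean radius exceeds R_hat
  (more volume outside the ring than inside), and precisely that offset is
  the long-time plateau of A_r the anisotropy analysis measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .halo_simulator import TrajectoryEnsemble

__all__ = [
    "CylindricalComponents",
    "CorrelationSet",
    "cylindrical_decompose",
    "make_lag_grid",
    "msd",
    "npaf",
    "nmsd",
    "correlate_ensemble",
    "master_curve_axial",
    "MasterCurves",
    "radial_anisotropy",
    "RadialAnisotropy",
    "radial_skewness",
    "annulus_area_ratio",
]


@dataclass
class CylindricalComponents:
    """Per-particle cylindrical series of shape (n_particles, n_samples).

    ``s`` is the azimuthal arc length R_hat * unwrapped theta; ``theta_raw``
    the wrapped angle in (-pi, pi].  ``radial_fluctuation`` is r - R_hat.
    """

    r: np.ndarray
    z: np.ndarray
    s: np.ndarray
    theta_raw: np.ndarray
    R_hat: float
    times: np.ndarray

    @property
    def radial_fluctuation(self) -> np.ndarray:
        return self.r - self.R_hat


def cylindrical_decompose(traj: TrajectoryEnsemble,
                          R_hat: float | None = None,
                          arc_at_instantaneous_radius: bool = False,
                          ) -> CylindricalComponents:
    """Decompose an ensemble into (r, z, s, theta) components.

    theta is unwrapped cumulatively per particle; sampling must be fine
    enough that no per-step angular change reaches pi, otherwise the
    unwrapping is unreliable and an error is raised.  Set
    ``arc_at_instantaneous_radius`` to integrate r(t)*dtheta instead of the
    fixed-radius convention R_hat*theta (exposed for comparison only).
    """
    if R_hat is None:
        R_hat = traj.params.get("R_hat")
        if R_hat is None:
            raise ValueError("R_hat not given and absent from traj.params")
    x = traj.positions[:, :, 0]
    y = traj.positions[:, :, 1]
    z = traj.positions[:, :, 2]
    r = np.hypot(x, y)
    if np.any(r <= 0):
        raise ValueError("sample on the z-axis: decomposition undefined")
    theta = np.arctan2(y, x)
    dtheta = np.diff(theta, axis=1)
    # steps beyond pi alias back into (-pi, pi] and are undetectable in
    # principle; steps approaching pi are the observable symptom of a
    # sampling rate too coarse for reliable unwrapping
    wrapped = (dtheta + np.pi) % (2.0 * np.pi) - np.pi
    if np.any(np.abs(wrapped) >= 0.9 * np.pi):
        raise ValueError(
            "angular steps approach pi between consecutive samples: "
            "unwrapping unreliable, reduce save_stride or dt")
    theta_unwrapped = np.unwrap(theta, axis=1)
    if arc_at_instantaneous_radius:
        mid_r = 0.5 * (r[:, 1:] + r[:, :-1])
        s = np.concatenate(
            [np.zeros((r.shape[0], 1)),
             np.cumsum(mid_r * np.diff(theta_unwrapped, axis=1), axis=1)],
            axis=1)
    else:
        s = R_hat * theta_unwrapped
    return CylindricalComponents(r=r, z=z, s=s, theta_raw=theta,
                                 R_hat=float(R_hat), times=traj.times)


def make_lag_grid(n_samples: int, max_lag: int | None = None,
                  dense_until: int = 16, growth: float = 1.25) -> np.ndarray:
    """Pseudo-logarithmic integer lag grid (multi-tau style), starting at 0.

    Every lag up to ``dense_until``, then multiplicative growth by ``growth``
    per point, capped at ``max_lag`` (default n_samples - 1).
    """
    if max_lag is None:
        max_lag = n_samples - 1
    max_lag = min(max_lag, n_samples - 1)
    lags = list(range(0, min(dense_until, max_lag) + 1))
    k = float(lags[-1])
    while lags[-1] < max_lag:
        k *= growth
        nxt = min(int(np.ceil(k)), max_lag)
        if nxt > lags[-1]:
            lags.append(nxt)
    return np.asarray(lags, dtype=int)


def _as_2d(series: np.ndarray) -> np.ndarray:
    a = np.asarray(series, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2:
        raise ValueError("series must be 1D or (n_particles, n_samples)")
    return a


def msd(series: np.ndarray, lags: np.ndarray,
        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-and-ensemble averaged mean squared displacement.

    Returns ``(values, stderr, n_pairs)`` over the integer lag grid.  All
    valid ordered pairs of each particle's series enter the time average;
    the standard error is estimated from the particle-to-particle scatter of
    the per-particle time averages (particles are independent).
    """
    a = _as_2d(series)
    n_part, n_samp = a.shape
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 0) or np.any(lags >= n_samp):
        raise ValueError("lags must lie in [0, n_samples - 1]")
    values = np.empty(lags.size)
    stderr = np.empty(lags.size)
    n_pairs = np.empty(lags.size, dtype=int)
    for i, k in enumerate(lags):
        if k == 0:
            values[i] = 0.0
            stderr[i] = 0.0
            n_pairs[i] = n_part * n_samp
            continue
        # adjacent origins are strongly correlated at long lags: subsample
        # them (multi-tau style) — negligible statistical cost, big speedup;
        # short series use every origin so small fixtures are exactly the
        # all-pairs estimator
        step = 1 if n_samp <= 256 else max(1, k // 8)
        d = a[:, k::step] - a[:, :-k:step]
        per_particle = np.mean(d * d, axis=1)
        values[i] = per_particle.mean()
        stderr[i] = (per_particle.std(ddof=1) / np.sqrt(n_part)
                     if n_part > 1 else np.nan)
        n_pairs[i] = d.size
    return values, stderr, n_pairs


def _normalised_corr(series: np.ndarray, lags: np.ndarray, kind: str,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = _as_2d(series)
    n_part, n_samp = a.shape
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 0) or np.any(lags >= n_samp):
        raise ValueError("lags must lie in [0, n_samples - 1]")
    norm = np.mean(a * a)
    if norm == 0:
        raise ValueError("zero-variance series: normalised correlation undefined")
    values = np.empty(lags.size)
    stderr = np.empty(lags.size)
    n_pairs = np.empty(lags.size, dtype=int)
    for i, k in enumerate(lags):
        if kind == "nmsd":
            # Pi = <dx^2>/(2<x^2>), estimated from displacements so that the
            # stationarity identity Pi = 1 - A is a genuine check, not an
            # algebraic tautology.
            if k == 0:
                values[i], stderr[i] = 0.0, 0.0
                n_pairs[i] = n_part * n_samp
                continue
            step = 1 if n_samp <= 256 else max(1, k // 8)
            prod = (a[:, k::step] - a[:, :-k:step]) ** 2 / 2.0
        elif k == 0:
            prod = a * a
        else:
            step = 1 if n_samp <= 256 else max(1, k // 8)
            prod = a[:, k::step] * a[:, :-k:step]
        per_particle = np.mean(prod, axis=1)
        values[i] = per_particle.mean() / norm
        stderr[i] = (per_particle.std(ddof=1) / np.sqrt(n_part) / norm
                     if n_part > 1 else np.nan)
        n_pairs[i] = prod.size
    return values, stderr, n_pairs


def npaf(series: np.ndarray, lags: np.ndarray):
    """Normalised position autocorrelation A(tau) = <x(t) x(t+tau)> / <x^2>.

    No mean removal: pass mean-free coordinates (z) or deliberately offset
    ones (r - R_hat, whose nonzero mean IS the signal of interest).
    """
    return _normalised_corr(series, lags, "npaf")


def nmsd(series: np.ndarray, lags: np.ndarray):
    """Normalised MSD Pi(tau) = <dx^2(tau)> / (2 <x^2>) = 1 - A(tau)."""
    return _normalised_corr(series, lags, "nmsd")


@dataclass
class CorrelationSet:
    """Lag grid plus per-component correlation estimates for one ensemble.

    ``lags`` are lag times (sample spacing times the integer grid).  The
    ``stderr`` mapping carries one standard-error array per estimate, keyed
    like the fields; ``meta`` records estimator provenance.
    """

    lags: np.ndarray
    msd_r: np.ndarray
    msd_z: np.ndarray
    msd_theta: np.ndarray
    npaf_r: np.ndarray
    npaf_z: np.ndarray
    nmsd_r: np.ndarray
    nmsd_z: np.ndarray
    n_pairs: np.ndarray
    stderr: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    COMPONENTS = ("msd_r", "msd_z", "msd_theta",
                  "npaf_r", "npaf_z", "nmsd_r", "nmsd_z")


def correlate_ensemble(traj: TrajectoryEnsemble,
                       R_hat: float | None = None,
                       lag_grid: np.ndarray | None = None,
                       max_lag: int | None = None) -> CorrelationSet:
    """Full correlation analysis of an ensemble: MSDs, NPAFs and NMSDs.

    Radial statistics are computed on (r - R_hat) without mean removal, axial
    on z, azimuthal MSD on the fixed-radius arc length.
    """
    comp = cylindrical_decompose(traj, R_hat=R_hat)
    n_samp = comp.r.shape[1]
    if lag_grid is None:
        lag_grid = make_lag_grid(n_samp, max_lag=max_lag)
    dr = comp.radial_fluctuation
    msd_r, se_mr, npairs = msd(dr, lag_grid)
    msd_z, se_mz, _ = msd(comp.z, lag_grid)
    msd_t, se_mt, _ = msd(comp.s, lag_grid)
    npaf_r, se_ar, _ = npaf(dr, lag_grid)
    npaf_z, se_az, _ = npaf(comp.z, lag_grid)
    nmsd_r, se_pr, _ = nmsd(dr, lag_grid)
    nmsd_z, se_pz, _ = nmsd(comp.z, lag_grid)
    dt = comp.times[1] - comp.times[0] if comp.times.size > 1 else 1.0
    # ergodic long-time limit of A_r: <x>^2/<x^2> on the radial offset,
    # estimated from per-particle means (far better conditioned than the
    # autocorrelation tail when the plateau is small)
    m_p = dr.mean(axis=1)
    msq = float(np.mean(dr * dr))
    m = float(m_p.mean())
    se_m = (float(m_p.std(ddof=1) / np.sqrt(m_p.size))
            if m_p.size > 1 else np.nan)
    offset_plateau = m * m / msq
    offset_plateau_se = 2.0 * abs(m) * se_m / msq
    return CorrelationSet(
        lags=lag_grid * dt,
        msd_r=msd_r, msd_z=msd_z, msd_theta=msd_t,
        npaf_r=npaf_r, npaf_z=npaf_z, nmsd_r=nmsd_r, nmsd_z=nmsd_z,
        n_pairs=npairs,
        stderr={"msd_r": se_mr, "msd_z": se_mz, "msd_theta": se_mt,
                "npaf_r": se_ar, "npaf_z": se_az,
                "nmsd_r": se_pr, "nmsd_z": se_pz},
        meta={"R_hat": comp.R_hat, "n_particles": comp.r.shape[0],
              "n_samples": n_samp, "source": dict(traj.params),
              "radial_offset_plateau": offset_plateau,
              "radial_offset_plateau_se": offset_plateau_se},
    )


@dataclass
class MasterCurves:
    """Axial master curves: MSD_z and A_z against the rescaled lag (kz/kr) * t."""

    u: list[np.ndarray]
    msd_scaled: list[np.ndarray]
    npaf: list[np.ndarray]
    kz_over_kr: list[float]
    collapse_msd: float
    collapse_npaf: float


def _collapse_metric(us: Sequence[np.ndarray], ys: Sequence[np.ndarray],
                     trunc_frac: float = 0.25) -> float:
    """Max inter-curve spread on the overlapping rescaled-lag range.

    Each curve is first truncated to lags within ``trunc_frac`` of its span
    (estimates near the full span are origin-starved and dominated by
    noise), then interpolated onto a common grid; the spread is measured
    relative to the master curve's overall scale, so that the decayed tail
    of an autocorrelation — where the pointwise mean sits in the noise
    floor — cannot blow the metric up.
    """
    us2, ys2 = [], []
    for u, y in zip(us, ys):
        keep = u <= trunc_frac * u.max()
        if keep.sum() < 4:
            keep = np.ones_like(u, dtype=bool)
        us2.append(u[keep])
        ys2.append(y[keep])
    lo = max(u[u > 0].min() for u in us2)
    hi = min(u.max() for u in us2)
    if hi <= lo:
        raise ValueError("rescaled lag ranges do not overlap")
    grid = np.geomspace(lo, hi, 64)
    # linear interpolation in u itself: exact where the curves are locally
    # linear (small u), and the curves are flat where spacing is coarse
    interped = np.array([np.interp(grid, u, y) for u, y in zip(us2, ys2)])
    mean = interped.mean(axis=0)
    scale = np.max(np.abs(mean))
    spread = (interped.max(axis=0) - interped.min(axis=0)) / scale
    return float(spread.max())


def master_curve_axial(corrsets: Sequence[CorrelationSet],
                       kz_over_kr_values: Sequence[float],
                       trunc_frac: float = 0.25) -> MasterCurves:
    """Rescale axial correlations onto their stiffness-free master curves.

    MSD_z is divided by the axial trap variance kappa_r/kappa_z (so the
    plateau is 2) and both it and A_z are plotted against (kz/kr) * lag; for
    an overdamped bead in a Newtonian fluid all stiffness ratios collapse
    onto 2(1 - exp(-u)) and exp(-u).
    """
    if len(corrsets) != len(kz_over_kr_values) or len(corrsets) < 1:
        raise ValueError("need one kz/kr value per correlation set")
    us, msds, npafs = [], [], []
    for cs, ratio in zip(corrsets, kz_over_kr_values):
        us.append(cs.lags * ratio)
        msds.append(cs.msd_z * ratio)   # variance is kr/kz in natural units
        npafs.append(cs.npaf_z)
    if len(corrsets) == 1:
        c_msd = c_npaf = 0.0
    else:
        c_msd = _collapse_metric(us, msds, trunc_frac)
        c_npaf = _collapse_metric(us, npafs, trunc_frac)
    return MasterCurves(u=us, msd_scaled=msds, npaf=npafs,
                        kz_over_kr=list(kz_over_kr_values),
                        collapse_msd=c_msd, collapse_npaf=c_npaf)


@dataclass
class RadialAnisotropy:
    """Long-time radial autocorrelation plateaus across torus sizes."""

    R_hat: np.ndarray
    plateau: np.ndarray
    plateau_se: np.ndarray
    exponent: float
    exponent_stderr: float


def radial_anisotropy(corrsets: Sequence[CorrelationSet],
                      R_hat_values: Sequence[float],
                      window_fraction: float = 0.1,
                      trend_tolerance: float = 0.5,
                      estimator: str = "tail_mean") -> RadialAnisotropy:
    """Estimate A_r(inf) per torus size and its power-law exponent in R_hat.

    On a narrow torus the bead spends more time outside the ring than inside,
    so <r> > R_hat and A_r does not decay to zero; the plateau scales like
    R_hat^-2.

    Two estimators of the plateau:

    * ``"tail_mean"`` — the mean of A_r over the terminal lag window (the
      last decade of available lags, lags >= ``window_fraction`` times the
      longest one).  If A_r still trends across that window by more than
      ``trend_tolerance`` times its own plateau value (and the trend is
      resolved against noise), the estimate is refused.
    * ``"mean_offset"`` — the ergodic limit <x>^2/<x^2> of the radial offset
      x = r - R_hat, from per-particle time averages.  Identical in
      expectation for a stationary ergodic signal but with far smaller
      variance, which matters when the plateau (~R^-2) sits below the
      tail noise of desk-scale ensembles; the tail mean is cross-checked
      for consistency.
    """
    if len(corrsets) < 3:
        raise ValueError("need >= 3 torus sizes for a power-law fit")
    if estimator not in ("tail_mean", "mean_offset"):
        raise ValueError("estimator must be 'tail_mean' or 'mean_offset'")
    plateaus, ses = [], []
    for cs in corrsets:
        lags = cs.lags
        mask = lags >= window_fraction * lags.max()
        if mask.sum() < 3:
            mask = np.zeros_like(lags, dtype=bool)
            mask[-3:] = True
        vals = cs.npaf_r[mask]
        errs = cs.stderr["npaf_r"][mask]
        tail_mean = float(vals.mean())
        noise = float(np.mean(errs))
        if estimator == "tail_mean":
            # trend check: straight-line fit across the window
            t = lags[mask]
            slope = np.polyfit(t, vals, 1)[0]
            drift = abs(slope) * (t.max() - t.min())
            if drift > trend_tolerance * abs(tail_mean) and drift > 3.0 * noise:
                raise ValueError(
                    "radial autocorrelation has not plateaued in the "
                    "terminal window; extend the run before estimating "
                    "A_r(inf)")
            plateaus.append(tail_mean)
            ses.append(noise / np.sqrt(mask.sum()))
        else:
            plateau = cs.meta.get("radial_offset_plateau")
            if plateau is None:
                raise ValueError("mean_offset estimator needs the offset "
                                 "plateau in CorrelationSet.meta")
            if abs(tail_mean - plateau) > 4.0 * max(noise, 1e-12):
                raise ValueError(
                    "autocorrelation tail is inconsistent with the ergodic "
                    "mean-offset plateau; the run may not be stationary")
            plateaus.append(float(plateau))
            ses.append(float(cs.meta.get("radial_offset_plateau_se", np.nan)))
    plateaus = np.asarray(plateaus)
    ses = np.asarray(ses)
    if np.any(plateaus <= 0):
        raise ValueError(
            "a plateau estimate is not resolved above noise (<= 0): "
            "increase the ensemble size or run length")
    R = np.asarray(R_hat_values, dtype=float)
    res = _sps.linregress(np.log(R), np.log(plateaus))
    return RadialAnisotropy(R_hat=R, plateau=plateaus, plateau_se=ses,
                            exponent=float(res.slope),
                            exponent_stderr=float(res.stderr))


def radial_skewness(comp: CylindricalComponents) -> float:
    """Sample skewness of the radial position distribution (pooled over the ensemble)."""
    return float(_sps.skew(comp.r.ravel()))


def annulus_area_ratio(R: float, b: float) -> float:
    """Inner/outer annulus area ratio of the torus cross-section in the z = 0 plane.

    Ai = pi (R^2 - (R-b)^2), Ao = pi ((R+b)^2 - R^2); the ratio (2R-b)/(2R+b)
    runs from 1/3 at R = b to 1 as R -> inf and quantifies the outward bias
    of the radial equilibrium distribution.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    if R < b:
        raise ValueError("R < b: torus is self-intersecting")
    return (2.0 * R - b) / (2.0 * R + b)
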