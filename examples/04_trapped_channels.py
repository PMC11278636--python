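"""What the confined channels can — and cannot — see.

For a soft, slow fluid (kappa* << kappa_r, De = 10) the trap compliance
overshadows the fluid at low frequency in the radial and axial channels:
naively inverting their MSDs through the free-probe relation plateaus at
kappa/(6 pi a) instead of the fluid's modulus.  The trapped-probe inversion
(from the normalised position autocorrelation) removes the trap and returns
the fluid, but only above the corner frequency.
"""

import numpy as np

import halorheo as h
from halorheo.experiments_io import (
    jeffreys_run_config,
    trapped_channel_plateaus,
    canonical_scenario,
)
from halorheo.gser_inversion import analytic_trapped_npaf_transform

De, ratio = 10.0, 0.25
cfg = jeffreys_run_config(De, ratio, 1.0 / 3.0, n_particles=300, seed=11)
traj = h.simulate_jeffreys(150.0, 1.0 / 3.0, ratio, De, cfg)

out = trapped_channel_plateaus(traj, De, ratio)
print("apparent low-frequency storage plateaus (free-probe inversion of the")
print("confined channels) versus the trap stiffness over 6 pi a:")
print(f"  radial: {out['gprime_plateau_r']:.4g} Pa  "
      f"vs kr/(6 pi a) = {out['kappa_over_6pia_r']:.4g} Pa")
print(f"  axial : {out['gprime_plateau_z']:.4g} Pa  "
      f"vs kz/(6 pi a) = {out['kappa_over_6pia_z']:.4g} Pa")
# the confined channels measure the trap, not the fluid, at long times —
# the reason the free azimuthal channel is the broadband route.

# the trapped-probe identity: inverting the analytic autocorrelation of a
# trapped bead returns the fluid's own modulus exactly
fluid, particle, geometry = canonical_scenario(De, ratio, 1.0 / 3.0)
omega = np.geomspace(1.0, 1e4, 7)
resid = h.jeffreys_gser_identity(fluid, particle, geometry.kappa_r, omega)
print(f"\ntrapped-probe identity residual on the analytic autocorrelation: "
      f"max {resid.max():.2e}")
A_hat = analytic_trapped_npaf_transform(fluid, particle, geometry.kappa_r,
                                        omega)
print(f"|A_hat| at {omega[0]:.3g} and {omega[-1]:.3g} rad/s: "
      f"{abs(A_hat[0]):.3g}, {abs(A_hat[-1]):.3g} s")
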