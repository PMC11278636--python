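"""Natural units, dimensionless groups and sampling feasibility.

Builds the canonical scenario — a 1 um bead in water held by a ring trap of
radial stiffness 1 uN/m — and prints the natural length/time units, the
reduced geometry, the Deborah numbers of an actin-solution-like Jeffreys
fluid, and the acquisition-rate ceiling for artefact-free tracking.
"""

import numpy as np

import halorheo as h

fluid = h.JeffreysFluid.from_relaxation_time(eta1=1e-3, G=1e-3, tau=1000.0)
particle = h.ProbeParticle(radius_a=1e-6, temperature_T=298.0)
geometry = h.TrapGeometry(major_R=1e-5, kappa_r=1e-6, kappa_z=1e-6 / 3)

us = h.unit_system(geometry.kappa_r, fluid, particle)
print(f"length unit sqrt(kBT/kr) = {us.length_unit:.3e} m")
print(f"time unit  zeta0/kr      = {us.time_unit:.3e} s")
print(f"reduced bead radius a^   = {float(us.length_to_hat(particle.radius_a)):.1f}")
print(f"reduced ring radius R^   = {float(us.length_to_hat(geometry.major_R)):.1f}")

groups = h.dimensionless_groups(fluid, particle, geometry)
print(f"\nMaxwell stiffness kappa* = {groups.kappa_star:.3e} N/m")
print(f"kappa*/kappa_r           = {groups.ratio_kstar_kr:.3e}")
print(f"Deborah number De        = {groups.De:.0f}")
# De >> 1 with kappa* << kappa_r: the regime where only the free azimuthal
# channel of a ring trap can reach the fluid's terminal (low-frequency) response.

diag = h.feasibility_diagnostics(eta=1e-3, particle=particle,
                                 d=np.sqrt(1e-17), tau_ob=1e-3,
                                 technique_length=0.5e-3)
print(f"\ndiffusion time over the spatial resolution: {diag.tau_D:.3e} s")
print(f"artefact-free acquisition ceiling: {diag.threshold_rate / 1e3:.1f} kHz")
print(f"residence time in a 0.5 mm focal depth: {diag.tau_tr:.0f} s")
# sampling faster than ~20 kHz in water makes the bead look stationary and
# biases apparent moduli upward; the residence time caps conventional
# passive tracking at ~minutes, which the ring trap removes.
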