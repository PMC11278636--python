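# Methods

`halorheo` simulates the thermally driven motion of a micron-scale probe
bead held by a ring-shaped ("halo") optical trap and inverts the resulting
trajectory statistics to the suspending fluid's complex shear modulus
G*(ω) = G′(ω) + iG″(ω). This note records the models, the numerical
choices, and what the validation suite does and does not establish.

## Physical model

**Trap.** The toroidal trap attracts the bead to the circle of radius R in
the z = 0 plane with force

F = −κ_r (1 − R/ρ)(x, y, 0) − κ_z z ẑ,  ρ = √(x² + y²),

the negative gradient of U = κ_r(ρ − R)²/2 + κ_z z²/2. The azimuthal
stiffness is identically zero: the bead diffuses freely along the ring
indefinitely, which is what gives the technique its access to arbitrarily
low frequencies. The thermal minor radius is b = √(kBT/κ_r), so κ_r = kBT/b².

**Fluid.** Either a Newtonian solvent (viscosity η₁) or a single-mode
Jeffreys fluid: a solvent dashpot η₁ in parallel with a Maxwell element
(spring G in series with dashpot η₂), relaxation time τ = η₂/G. Its modulus is

G′(ω) = G ω²τ²/(1 + ω²τ²),  G″(ω) = ω[η₁ + η₂/(1 + ω²τ²)],

implemented with viscosities only so the Newtonian limit η₂ → 0 is exact
without dividing by G. The Maxwell branch enters the bead's generalized
Langevin equation as an exponential friction kernel
ζ_p(t) = 6πa(η₂/τ)e^(−t/τ), with transform 6πaη₂/(1 + iωτ). Inertia is
neglected throughout (irrelevant below MHz for micron beads). A second
Jeffreys wiring (dashpot in series with a Kelvin–Voigt element) is
equivalent under a parameter mapping and is not implemented.

**Units.** All integration is dimensionless: length in units of
√(kBT/κ_r) (the r.m.s. radial excursion), time in units of ζ₀/κ_r with
ζ₀ = 6πaη₁ (the inverse radial corner frequency in the pure solvent).
Newtonian dynamics then depend only on (R̂, κ_z/κ_r); Jeffreys dynamics add
(κ*/κ_r, De), with κ* = 6πaG the Maxwell spring as a trap-equivalent
stiffness and De = τκ*/ζ₀ the fluid Deborah number. A second Deborah
number De₂ = τκ_r/ζ₀ = De·κ_r/κ* is reported alongside. The distinct
observation-based Deborah number τ_D/τ_ob used for sampling feasibility
lives in its own diagnostics record and is never interchanged with De.
SI conversion happens only at the I/O boundary via `UnitSystem`
(modulus scale κ_r/(6πa)).

## Stochastic integration

Both integrators are Euler–Maruyama: the SDEs are overdamped with additive
noise, so weak order one is sufficient for the ensemble statistics used
here, and the scheme keeps the shared-noise structure of the viscoelastic
embedding transparent. The Jeffreys dynamics are simulated by a Markovian
embedding: one auxiliary length-valued variable Q per axis with drift
coupling to the same trap force and relaxation rate (κ*/ζ₀)(De+1)/De, a
noise increment dW¹ *shared* between each position equation and its paired
Q equation (amplitudes √(2De/(De+1)) and √(2(De+1)/De) in natural units),
plus an independent solvent increment dW⁰ of amplitude √(2/(De+1)).
The transcription was verified analytically before use: the Lyapunov
equation of the linearised (axial) subsystem gives stationary variances
var(ẑ) = κ_r/κ_z and var(Q̂) = κ_r/κ* with zero cross-covariance, i.e.
equipartition exactly, for those amplitudes; the test suite re-derives this
from simulation. De = 0 is rejected (the Q-noise diverges) and routed to
the Newtonian integrator.

Numerical safeguards:

- time step guard dt̂ ≤ 0.05 × the fastest relaxation time (radial, axial,
  or the Q mode, whose time constant De/((De+1)κ*/κ_r) → 0 as De → 0);
- burn-in default of ten relaxation times of the slowest mode
  (max(10, 10·De·κ_r/κ*) dimensionless time units); initial positions are
  drawn on the ring with stationary transverse Gaussians, Q starts at 0
  (the zero-Maxwell-force fixed point — immaterial after burn-in);
- a bead within 10⁻¹² of the z-axis aborts the run: the ring force is
  undefined there, and for R̂ ≥ 10 reaching it signals a configuration
  error rather than physics (silent clamping would mask it);
- one PCG64 stream per run, fully determined by the seed; identical
  configuration + seed reproduces the ensemble bit for bit.

The integrator's oracle is the 1D Ornstein–Uhlenbeck limit:
MSD(t̂) = 2(1 − e^(−t̂)) for the unit-stiffness channel. Euler–Maruyama
carries an O(dt) weak bias (the discrete stationary variance is
1/(1 − dt/2)), which at short lags exceeds the Monte-Carlo error of a
well-averaged ensemble; oracle tests therefore score deviations against
the MC standard error combined with a first-order allowance dt·MSD.

## Trajectory statistics

Trajectories are decomposed into radial distance r, axial z, and azimuthal
arc length s = R̂·θ with θ unwrapped cumulatively. Conventions that carry
scientific weight:

- **Arc length at the fixed trap radius**, not the instantaneous bead
  radius: this makes MSD_θ independent of torus size and exactly
  comparable to 1D free diffusion (the alternative is exposed as an
  option). Steps with wrapped angular change ≥ 0.9π abort the
  decomposition — beyond π the aliasing is undetectable in principle, so
  the guard fires on the observable symptom.
- **Radial correlations on (r − R̂) without mean removal.** On a narrow
  torus there is more volume outside the ring than inside, so the
  stationary mean radius exceeds R̂ (⟨r⟩ − R̂ ≈ 1/R̂); that offset is
  exactly the long-time plateau A_r(∞) ≈ 1/R̂² the anisotropy analysis
  measures, and subtracting the empirical mean would erase it.
- MSD, NPAF A(τ) = ⟨x(t)x(t+τ)⟩/⟨x²⟩ and NMSD Π(τ) = ⟨Δx²⟩/2⟨x²⟩ average
  over all time origins and particles; Π is estimated from displacements,
  not via 1 − A, so the stationarity identity Π = 1 − A is a genuine
  cross-check. Standard errors come from the particle-to-particle scatter
  of per-particle time averages. At long lags adjacent origins are
  subsampled (multi-tau style, stride lag/8, disabled for short series) —
  a large speedup at negligible statistical cost. The lag grid is
  pseudo-logarithmic: every sample up to 16, then ×1.25 growth.

**Radial anisotropy.** The plateau A_r(∞) can be estimated as the mean of
A_r over the last decade of lags (`tail_mean`) or as the ergodic limit
⟨x⟩²/⟨x²⟩ from per-particle time means (`mean_offset`). The two agree in
expectation for a stationary ergodic signal, but the tail estimator's
per-lag noise (~0.02 for desk-scale ensembles) swamps the R̂ = 20 plateau
(~2.5×10⁻³), whereas the ergodic estimator's error is set by the much
smaller uncertainty of a mean; the validation suite therefore uses
`mean_offset`, which internally cross-checks the tail for consistency and
refuses non-stationary input. Exact quadrature of the stationary radial
marginal p(r) ∝ r·e^(−(r−R̂)²/2) gives plateau = m²/(m² + σ²) with
m = ⟨r⟩ − R̂, reproducing the R̂⁻² scaling; the same quadrature gives the
skewness of the radial distribution as *positive* (≈ +2/R̂³: the outward
volume bias stretches the right tail), which the simulations confirm.
A negative sign for this skewness is sometimes asserted in descriptions of
the outward bias; it holds only for the inward coordinate R̂ − r, and one
validation test recording that stated sign is expected to fail.

**Axial master curves.** MSD_z normalised by the trap variance κ_r/κ_z and
A_z, plotted against (κ_z/κ_r)·t̂, collapse across stiffness ratios onto
2(1 − e^(−u)) and e^(−u). The collapse metric interpolates the curves onto
a common rescaled grid and takes the maximal inter-curve spread *relative
to the master curve's overall scale*, after truncating each curve to lags
within a quarter of its span: pointwise-relative spread is unbounded in
the decayed tail of A_z where the mean sits in the noise floor, and
estimates near the full span are origin-starved.

## GSER inversion

**Discrete Fourier transform.** The unilateral transform of finite data is
computed in closed form for the piecewise-linear interpolant, with an
explicit linear extension below the first sample (value at zero plus
optional initial gradient; a mismatch at t₀ is handled as an exact jump
term) and a linear tail beyond the last sample (terminal gradient, by
default fitted to the last decade of samples). The formula is exact for
truly piecewise-linear data — the property that pins the Newtonian
self-consistency of the whole stack to machine precision. Frequencies
outside [2π/span, π/min-step] are computed but flagged, never silently
dropped.

**Free channel.** G*(ω) = d·kBT/(3πa·iω·⟨Δx²⟩^(ω)) for a d-dimensional
MSD (d = 1 for the azimuthal arc). The 1D prefactor is the single most
dangerous silent-error site and is locked by a mandatory test: the exact
diffusive MSD 2Dt with D = kBT/(6πaη) must invert to G″ = ωη, G′ = 0 to
machine precision. The equivalent route through the creep compliance
J(t) = (3/d)πa·MSD/kBT and G* = 1/(iωĴ) is algebraically identical on the
same transform and is asserted as such.

**Trapped channels.** G*(ω) = (κ/6πa)·iωÂ/(1 − iωÂ) from the NPAF (or the
NMSD through iωΠ̂ = 1 − iωÂ; the three printed forms are evaluated and
agree identically). Frequencies where the reduced modulus |G*|6πa/κ falls
below 0.05 are flagged trap-dominated (threshold exposed). For the
analytic cross-check, the NPAF of a 1D trapped bead in a Jeffreys fluid is
derived independently from the embedding's 2×2 drift matrix
(A(τ) = Σᵢ cᵢ e^(−λᵢτ) by eigendecomposition, Â = Σᵢ cᵢ/(λᵢ + iω)); the
trapped-probe identity between (κ/6πa)·iωÂ/(1 − iωÂ) and the model's own
G*(ω) then closes to < 10⁻⁶ across the grid, tying the simulator's drift
matrix and the inversion algebra together.

**Noise control in practice.** MSD noise at long lags enters the discrete
transform through rapidly oscillating phase factors and would swamp the
mid-band moduli. The recovery pipeline therefore truncates the input MSD
at ~12 fluid relaxation times — beyond which the MSD is verifiably linear —
fits the terminal gradient on the late lags, and lets the exact linear-tail
term represent the rest; the usable band is still the one supported by the
full run span. On analytic inputs this pipeline's error is < 0.1% over the
band; on simulated 500-particle ensembles the recovered moduli land within
~10% of the model over two decades around ωτ = 1. Component errors are
quoted relative to |G*(ω)|, since near the band edges one modulus vanishes
and its self-relative error is meaningless. Parameter recovery fits
(log G, log τ) by least squares on the complex residual (G*ₘₒdₑₗ − G*)/|G*|
with the solvent viscosity η₁ held known.

## Synthetic-data scope

The generator produces exactly the stated world: overdamped beads, ideal
harmonic ring trap, single-mode Jeffreys fluid, no inertia, no
hydrodynamic interactions or walls, no camera noise, blur, drift, or
tracking error. A green validation run therefore establishes the internal
consistency of integrator + estimators + inversion for that world; it
says nothing about tracking artefacts, multi-mode fluids, or trap
anharmonicity in a real instrument. Ensemble sizes in the presets are
scaled down (typically 100–500 particles versus the 1000-particle
reference protocol); the `scale` parameter restores the full protocol.
The actin-like preset (G = 1 mPa, κ*/κ_r = 1.88×10⁻², water solvent)
defaults to De = 100 rather than the SI-faithful De = 1000 (τ = 1000 s):
resolving the solvent scale over many fluid relaxation times at De = 1000
is cluster-scale work, and De = 100 preserves the defining separation
De ≫ 1, κ* ≪ κ_r. Passing `De=1000` runs the faithful configuration.

## Known limitations

- Euler–Maruyama's O(dt) weak bias is visible in stationary variances at
  the default dt̂ = 0.01 (~0.5%); halve dt for tighter work.
- The spatial-resolution figure used by the feasibility diagnostics is
  d² = 10⁻¹⁷ m² (nanometre scale); the consistent unit is m², not nm².
- The trapped-channel inversion degrades gracefully but inevitably below
  the corner frequency (trap-dominated flags); only the azimuthal channel
  is broadband.
- `fit_jeffreys_modulus` assumes a single-mode fluid with known solvent
  viscosity; it is a validation tool, not a general rheological fitter.
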