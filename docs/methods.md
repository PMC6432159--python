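# Methods

## Model

The system is a coarse-grained polyelectrolyte in an implicit solvent:
N beads of mass m and charge −e joined by harmonic bonds
U_bond = (k/2)(ℓ − ℓ₀)² with k = 600 kBT/σ², ℓ₀ = 1 σ. All bead pairs
(bonded ones included, as usual for this bead-spring class) repel through
the WCA potential, σ_bb = 1 σ, ε_bb = 1.2 kBT between mobile beads and
σ_bw = 1.5 σ, ε_bw = 2.5 kBT against wall beads. Reduced units (σ, m, kBT,
e) are used throughout; time is τᵤ = σ√(m/kBT).

The membrane wall is hollow: two square lattices of immobile beads (default
spacing 1.5 σ) inset from the nominal wall faces by one σ_bw so that the WCA
contact surface felt by a mobile bead coincides with the faces at
z = ±w/2, w = 4.5 σ. Beads within the pore radius (2.25 σ) of the z axis
are removed to open the channel; with σ_bw = 1.5 σ the lattice has no gaps a
mobile bead can slip through. The box is periodic in x and y; z is closed by
soft harmonic caps (a mode flag restores full 3D periodicity). The default
box is the full-scale study geometry 48.0 × 49.36 × 200.0 σ;
`SystemConfig.desk()` is the reduced 20 × 20 × 80 σ geometry used for fast
ensembles.

Electrostatics has three modes. `direct`: truncated-and-shifted Coulomb,
U = λ_B q_i q_j (1/r − 1/r_c) with λ_B = 3 σ, minimum image, default cutoff
10 σ. `screened`: Debye–Hückel, U ∝ e^{−r/ℓ_D}/r, likewise shifted; the
default screening length is κ⁻¹ = (8π λ_B I)^{−1/2} ≈ 4.9 σ at the study's
salt concentration. `none` for neutral reference runs. Forces are the exact
negative gradients of the implemented energies (verified by finite
differences in the tests); mesh-Ewald electrostatics is deliberately out of
scope — the pair forms keep the model exactly self-consistent at desk scale.

**Implicit ions and the Manning correction.** The full-scale system carries
explicit counterions and 256 salt molecules. The desk-scale configuration
replaces them with the screened pair interaction. Because the chain sits
above the Manning threshold (λ_B/ℓ_c = 3 > 1), the explicit-ion system
condenses counterions onto the backbone, reducing the effective line charge
to ≈ ℓ_c/λ_B of bare. A bare-charge Debye–Hückel chain would therefore be
far stiffer than the system it stands in for (OSF ℓ_p ≈ 19 σ, i.e. rod-like
at N = 32, where the real chain starts as a coil with η ≈ 6–8). In implicit
mode the screened pair coupling is accordingly rescaled by the condensation
fraction squared (`ForceField.charge_scale`, default ℓ₀/λ_B = 1/3 when ions
are implicit, 1 otherwise). The driving field still acts on the bare monomer
charge; the drag of condensed ions inside the pore is a feature of explicit
ions that implicit mode does not carry.

## Initialization, equilibration, release

The chain starts threaded: ⌈w/ℓ₀⌉ + 1 head beads lie along the pore axis
with the head at z = w/2 + 0.35 σ (the zero-force point of the exit gate),
and the rest grows as a cis-side self-avoiding walk (unbiased directions,
backtracking on dead ends). Counterions and salt are inserted uniformly at
random in the fluid with overlap rejection; explicit-ion builds are exactly
charge neutral. Builds are bit-reproducible per seed.

Equilibration holds the head fixed with the field off (default 5×10⁴ steps
at dt = 0.005 τᵤ, several Rouse times of the desk-scale cis chain). During
this phase a soft half-space spring (k = 600, plane z = w/2 − 0.3 σ) keeps
non-head monomers on the cis side of the exit face. Physically the head
already plugs the single-file channel; the plane makes the start state
airtight against rare thermal squeezes, so every run is released from
exactly s = 1 and the ensemble variance of s is identically zero at t = 0.

Release switches the field on inside the pore slab (|z| ≤ w/2, closed
interval, force −qE ẑ on every charged bead there) and activates the exit
gate: a WCA-form half-space repulsion on the head monomer with zero force at
z = w/2 + 0.35 σ. Penetrating back to the exit plane itself would cost
~85 kBT, so in practice the head never re-enters the channel; because the
gate is force-continuous the invariant is asserted as z_head ≥ w/2 − 0.25 σ
rather than as a hard wall.

## Integrator

BAOAB splitting of Langevin dynamics with friction ζ = 1 m/τᵤ: velocity
half-kick, half-drift, exact Ornstein–Uhlenbeck velocity refresh
(v ← c₁v + c₂√(kBT/m) ξ, c₁ = e^{−ζdt/m}), half-drift, half-kick. At ζ = 0
the scheme reduces exactly to velocity Verlet; the tests verify energy
conservation there (secular drift measured on block means — the shadow
Hamiltonian oscillates with the stiff bonds at amplitude ≈ 10⁻³ kBT/bead at
dt = 0.005, which is not drift), momentum conservation, equipartition and
the Boltzmann statistics of the bond lengths against a 1D quadrature oracle
(Jacobian r², harmonic + WCA bonded potential). The same seed reproduces a
trajectory bit for bit. Overlap clamps (r² floored at (0.4 σ)²) keep forces
finite if a pathological input is supplied; properly built systems never
reach them.

The translocation coordinate is sampled every integrator step, so waiting
times are exact at dt resolution and Σ_s w_k(s) = τ_k holds to float
round-off; s(t) is stored at a 10-step stride and frames, when requested, at
a configurable stride.

## Analysis conventions

**Normalized waiting times.** Each state s occupies a width-1/N bin in s̃,
so w̃(s̃) is a step function and its exact integral is Σw/⟨τ⟩ = 1;
`EnsembleRecord.w_tilde_curve()` exposes the step polyline on which the
trapezoid rule reproduces that integral to round-off.

**Scaled time.** Conformation and tension time series are binned on
t̃ = t/τ_k per run, so every run spans [0, 1]; a global-⟨τ⟩ mode is
available (`time_mode="ensemble"`). Ensemble η is ⟨R_e²⟩/⟨R_g²⟩ (means
first, ratio second); A, P, θ, φ are averaged per frame. Sub-chain
membership is by monomer z; region II (closed interval |z| ≤ w/2) belongs to
neither sub-chain. Bins whose sub-chain has fewer than two beads are
flagged, not averaged.

**Pore distances.** D_n is the Euclidean distance to the pore-axis point on
the wall face of the monomer's own side. Λ_n is the backbone contour length,
walked toward the pore, up to the point where the backbone crosses that wall
face. Referencing both to the entrance makes D = Λ exact for a straight
chain on the axis and keeps Λ = bond count for any unit-bond path ending at
the face. Both vanish for in-pore monomers. Note that ensemble profiles
⟨D_n⟩/⟨Λ_n⟩ can slightly exceed 1 within roughly a pore radius of the mouth:
D is referenced to the axis point while the backbone may cross the face
off-axis. The straightened-section rule (ratio of means ≥ 0.9, scanned from
the pore outward) is insensitive to this.

**Tension front.** The front is the deepest cis bond whose mean tension
exceeds the trans-side plateau by 3 ensemble standard errors, scanning from
the free end toward the pore. The plateau is estimated from the bonds
already pulled through the pore, so the rule needs a few translocated bonds
to be meaningful — front detection is reported but not interpreted before
s̃ ≈ 0.15. A uniform profile returns an absent-front flag (the weak-field
case).

**Drift–diffusion.** v(s) = 1/w(s). The entropic model implements the
general two-exponent free energy and its equal-exponent closed form
(γ′ = 0.69), the pore driving force eE(N_m,II − N_c,II), and the Rouse
friction ζ(N_m,II + N_c,II); a (+1) ion counts as condensed in the pore when
it is in region II within λ_B of a monomer. Variance curves are population
variances across runs on a real-time or scaled-time grid (step
interpolation; finished runs contribute s = N). Diffusion exponents are
least-squares slopes of log⟨Δs²⟩ vs log t on a caller-chosen window; the
reduced-scale tests use the first half-decade of resolvable growth.

**Log-normal machinery.** p(s,t) fits hold A_s fixed at w(s)/⟨τ⟩ and
optimize (σ_s, μ_s) by Levenberg–Marquardt; non-convergence is flagged, not
raised. Derived quantities: W_s = 2 sinh(√(2 ln 2) σ_s) e^{−σ_s²} μ_s and
⟨t_s⟩ = μ_s e^{σ_s²/2}. Two estimands must not be mixed: the occupancy
density p(s,t) (fraction of runs at s at time t, normalized by ⟨τ⟩, on
log-spaced bins) has mean time ≥ the mean first-arrival time, and at desk
scale under weak driving the two differ strongly because states are
revisited diffusively. The consistency check "fit mean vs direct mean" is
therefore run on matching estimands: the synthetic log-normal fixture, and
first-passage-time histograms from real runs. At full scale the distinction
nearly vanishes, which is why published consistency plots can overlay the
two.

**Hump and scaling.** s̃* is the argmax of w̃ inside s̃ ∈ [0.05, 0.95]
(excluding the switch-on response peak and the end overshoot), optionally
after a short moving average (the desk-scale tests use 3 states). The
(N − s*) ∼ N^β fit is a log-log regression over ≥ 3 chain lengths.

## Synthetic fixtures

The fixture generators produce data with closed-form ground truth computed
independently of the analysis code: a rigid rod translocating at constant
speed (exact s(t), w(s) = ℓ₀/v, discrete-rod η = 12(n−1)/(n+1), D ≡ Λ),
freely jointed coils (η = 6N/(N+1)), uniform-ball globules with random ends
(η → 2), i.i.d. log-normal passage times, and chains with prescribed bond
lengths (affine tension map). They emulate the geometry and statistics of
the observables, not the dynamics: passing fixture tests validates the
analysis chain, while the engine physics is validated separately
(gradient/conservation/equipartition checks and reduced-scale ensembles).

## Reduced-scale study conditions and known limitations

The qualitative ensembles use N = 32 chains, M = 32 runs per field, screened
implicit-ion electrostatics, fields E = 0.2 and 32 kBT/(eσ), in the desk
box. At this scale the package reproduces: τ decreasing steeply with E
(≈ 280 τᵤ at E = 0.2 vs ≈ 4 τᵤ at E = 32); a weak-field waiting-time hump
near the midpoint and a strong-field hump that moves later and grows a
switch-on spike; cis-chain elongation with t̃ at strong field (η_I, A_I, P_I
all rise toward rod values before the final depletion drop); variance of s
vanishing at both ends with weak-field exponent ξ ≈ 1 and a strong-field
exponent well above it; and the straightened-section boundary never passing
the tension front.

Two full-scale features shrink below their thresholds at N = 32 and are
knowingly not reached (their tests assert the full-scale statement and are
expected to fail at desk scale): the strong-field hump position s̃* > 0.5
(the published scaling N − s* ≈ 2 N^0.58 itself predicts s̃* ≈ 0.52 at
N = 32; measured ≈ 0.46–0.47) and a ballistic early variance exponent
ξ > 1.5 (measured 1.2–1.4 across seeds: the window between variance
resolvability, quantized at 1/M, and the momentum relaxation time m/ζ = 1 τᵤ
is under a decade at τ ≈ 4 τᵤ). The (N − s*) ∼ N^0.58 scaling fit is
validated on constructed power-law families; full-scale ensembles (N up to
384, M = 500) are supported by the same code path but are multi-hour runs.

Other limitations: no hydrodynamic interactions (Langevin friction is
local), no bending stiffness (flexible backbone only — double-stranded DNA
would need an angular potential), no pore surface charge, and mesh-Ewald
electrostatics is an extension point rather than a mode.
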