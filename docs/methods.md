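# Methods

`macroioncg` simulates soluble, hydrophilic macroions — nanometre-scale ions
such as Keplerate metal-oxide clusters, dendrimers or small charged
biomacromolecules — at coarse-grained resolution, to study how mobile
counterions mediate an effective attraction between like-charged solutes and
how that attraction depends on surface charge density.

## Model

**Macroion.** A rigid hollow sphere: `n_beads` CG beads (default 68) whose
centers sit exactly on a shell of diameter 25 Å (the size of a typical
2.5 nm cluster). Beads are placed on a Fibonacci (golden-spiral) lattice,
re-centered so the shell's center of mass coincides with its geometric
center to machine precision; for 68 beads the minimal bead spacing is
4.68 Å, close to the ideal uniform value. `n_charged` of the beads (chosen
uniformly at random from a recorded seed, or by a greedy max-spread rule)
carry −1 e each. All beads of one macroion move as a single rigid body —
the shell has no internal degrees of freedom.

**Counterions and solvent.** Every charged surface bead is matched by
exactly one +1 e counterion, so every system is electrically neutral by
construction. The solvent is a neutral CG bead fluid in the 4-waters-per-bead
convention (72 g/mol per bead, as for all species).

**Interactions.** All species pairs interact through one LJ 12-6 potential
(ε = 4.5 kJ/mol, σ = 5 Å, r_c = 15 Å, plain truncation; an energy-shifted
variant is available for strict-NVE work). Charges interact through the bare
Coulomb potential U = k_q q_α q_β / r with k_q e² = 1389.35 kJ·Å/mol — the
CG solvent is non-polar and provides no dielectric screening, so a
counterion in contact with a charged bead is bound by ≈ 278 kJ/mol
(≈ 110 k_BT at 300 K): counterion condensation is strong and deliberate.
Periodic electrostatics use classical Ewald summation (tinfoil boundaries)
with a single accuracy knob δ: α = s/r_c and k_max = 2αs with
s = √(−ln δ). Intra-body charge pairs are excluded consistently in the
real- and reciprocal-space parts. The Ewald path is validated against an
isolated-pair closed form, the NaCl Madelung constant (Evjen sum, 1.74757
recovered to 4 digits), α-independence on a random plasma, and central
finite differences of the energy.

**Internal units.** Å, ps, g/mol, e; the derived energy unit is
(g/mol)(Å/ps)² = 0.01 kJ/mol, so Newton's equations carry no conversion
factors. k_B = 0.83145, k_q e² = 138 935 in internal units; pressure
converts at 166.054 bar per internal unit and mass density at 1.66054
(g/mol/Å³ → g/cm³).

## Dynamics

Point particles use velocity Verlet; rigid bodies use COM translation plus
quaternion rotation with the Dullweber–Leimkuhler–McLachlan (DLM) splitting
— a sequence of exact axis-wise free rotations, so rigidity is exact by
construction and a torque-free shell conserves its space-frame angular
momentum to rounding (measured: 6 × 10⁻¹³ relative over 10⁴ steps).
Degenerate bodies (single beads, linear pairs) simply skip zero-inertia
axes. The timestep is 10 fs everywhere.

Ensembles:

- **NVE** — drift < 10⁻⁴ relative over 10⁵ steps for LJ systems (measured
  3 × 10⁻⁷ for a bound pair, 4 × 10⁻⁵ for colliding shells).
- **NVT** — deterministic Berendsen velocity rescale (default coupling
  1 ps); conserves the builder's zero total momentum to < 10⁻⁸.
- **NPT** — NVT plus an isotropic Berendsen barostat (coupling 5 ps,
  water-like compressibility) acting on the molecular-virial pressure
  P = (2K_trans + Σ F·r − Σ_bodies F_bead·arm)/3V. Supported for LJ and
  DSF electrostatics; NPT with full Ewald raises `NotImplementedError`
  (the reciprocal-space virial is not implemented; no workflow here
  needs it).
- **Langevin** — BAOAB splitting with the exact Ornstein–Uhlenbeck update
  applied to free velocities, body COM velocities and body-frame angular
  momenta. A free particle recovers D = k_BT/(mγ) within the statistical
  error of the test (≈ 2%).

Forces come from a cell-grid Verlet neighbor list (2 Å skin,
displacement-triggered rebuild) whose output is bit-identical to an
all-pairs reference on every tested system. A capped steepest-descent
minimizer removes builder overlaps before dynamics; a per-step displacement
above σ/2 aborts the run with a diagnostic rather than producing garbage.

## Implicit-solvent surrogate mode

The charge-density sweep runs macroions + counterions only, under Langevin
dynamics, with two deliberate substitutions:

- **WCA repulsion** (LJ truncated and shifted at 2^{1/6}σ) replaces full LJ
  between all species. The explicit CG solvent is a *good* solvent — solvent
  and solute beads share identical ε and σ — so the solvent-mediated
  potential of mean force between solutes carries no net vdW adhesion.
  Removing the solvent while keeping full LJ would introduce a spurious
  vacuum adhesion that aggregates even uncharged shells; WCA is the
  consistent good-solvent limit, and it reproduces the explicit-solvent
  control behavior (uncharged shells do not assemble).
- **Damped-shifted-force (DSF) electrostatics** (Fennell–Gezelter form)
  replace Ewald, with a deliberately gentle damping α = 0.1 Å⁻¹ and
  r_c = 20 Å. The damping parameter is a physical smoothing choice, not an
  accuracy knob: at the α ≈ 0.25 that an Ewald-style accuracy heuristic
  would suggest, the erfc screening cuts the contact counterion–bead force
  to ~35% of bare Coulomb and destroys the bridging physics. At α = 0.1 a
  contact pair keeps ≥ 90% of the bare force. Against Ewald on a thermally
  perturbed rock-salt box the relative RMS force error is of order 20% —
  an honest statement of what truncating bare Coulomb at half a small box
  costs; the sweep's conclusions rest on contact-scale bridging, which DSF
  preserves, not on far-field force fidelity.

Langevin friction for the sweep is γ = 0.1 ps⁻¹ — strong enough to
thermostat, weak enough that macroions diffuse (D = k_BT/Mγ ≈ 0.5 Å²/ps)
and encounter one another within the run length.

## Measurements

- **g(r)** — standard ideal-gas-normalized pair correlation, minimum-image,
  frame-averaged; macroion positions are rigid-body COMs. Normalisation is
  conventional (ρ = N/V), so ρ∫4πr²g dr over the full range equals N−1.
- **Coordination number** — n = ρ∫₀^R 4πr² g(r) dr by trapezoid with an
  interpolated endpoint. The auto shell limit is the first local minimum of
  the 5-point-smoothed g(r) searched in 25–50 Å (past the two close-range
  peaks: direct contact, and contact bridged by one interstitial bead);
  ties break to smaller r, and a windowed search with no minimum is an
  error, never a guess.
- **MSD / diffusion** — time-origin-averaged MSD (FFT algorithm, verified
  against the O(T²) sum) on unwrapped coordinates; D = slope/6 fitted over
  10–50% of the maximum lag (excludes ballistic onset and noisy tail), then
  divided by the standard CG rescaling factor 4 for all species (CG
  dynamics are ~4× too fast because the landscape is smoothed).
- **Force decomposition** — the engine carries separate vdW and
  electrostatic per-particle force channels; the net force on a macroion is
  the sum over its beads. Projection convention: force on macroion A dotted
  with the unit vector from the pair midpoint to A's center — negative
  means attraction toward the partner.
- **Clustering** — single-linkage under a COM contact cutoff of 32 Å
  (direct-contact peak plus one bead diameter of margin), via union of the
  contact graph; labels are deterministic (lowest member index) and the
  result equals a brute-force label-spreading oracle on every tested frame.
- **Assembly indicator** — mean first-neighbor count (neighbors within the
  contact cutoff, averaged over macroions and over the final 20% of
  frames); sustained values above 2 mean aggregates beyond dimers/trimers.

## Study presets and problem sizes

The package encodes its study designs as presets, all reproducible
bit-for-bit from (name, seed, scale):

| preset | composition | protocol |
| --- | --- | --- |
| `solvent_diffusion` | 1000 solvent beads at 0.97 g/cm³ (box 49.8 Å) | NVT 300 K; 50 ps equil (τ = 0.5 ps) + 2 ns production (τ = 10 ps) |
| `npt_density` | 512 solvent beads, started at 0.90 g/cm³ | NPT 300 K / 1 bar; 0.3 ns equil + 0.5 ns production |
| `two_macroion_forces` | 2 × 20-charge macroions pinned in contact (30 Å), 40 counterions, ~1580 solvent, box 60 Å | Ewald (accuracy 3e-4); Langevin γ = 1; 30 ps equil + 0.6 ns with stored force channels |
| `charge_sweep` | 8 macroions with q ∈ {0,2,4,5,6,8,16,20}, 8q counterions, box 100 Å | implicit mode; γ = 1 equil 30 ps, γ = 0.1 production 1.2 ns |
| `uncharged_control` | 8 uncharged shells, box 100 Å (sweep dilution) | implicit mode; 30 ps + 500 ps |
| `charge_switch_off` | 4 × 16-charge shells preformed as a contact tetrahedron + 64 counterions | implicit mode; 20 ps charged, then all charges zeroed, 200 ps |

These sizes are the package's deliberate desk scale: hundreds to ~2000
particles and 1–2 ns, versus the hundreds of thousands of particles and
hundreds of nanoseconds a cluster-scale study would use. Consequences to
keep in mind: aggregation statistics at 8 macroions are noisier than at
27–50; the sweep box (100 Å) is ~7× more concentrated than a dilute
experimental solution so that encounters happen within the run; and the
uncharged control runs in the implicit good-solvent mode at the sweep's
dilution, because an explicit-solvent control small enough for the desk is
too crowded for "no aggregation" to be a measurable statement (the
random-contact baseline alone exceeds trimers). What a
passing sweep shows is the *existence and location* of the
assembly transition in charge count, not converged aggregate-size
distributions.

## What the synthetic conditions do not capture

The generator builds random dispersions (or pinned geometries) of identical
macroions in a structureless LJ solvent. It does not emulate solvent
polarity or dielectric screening (charges interact at vacuum strength),
hydrogen bonding, size or charge polydispersity, pH/ionic-strength effects,
or hydrodynamic interactions (Langevin friction is local). Passing tests
therefore demonstrate the counterion-mediated mechanism in a minimal model,
not quantitative transferability to any specific chemistry.

## Known limitations

- The solvent state point quoted for this bead model (0.97 g/cm³ *and*
  fast self-diffusion at ambient conditions) is not reachable with a
  plainly truncated 12-6 fluid at ε/k_BT ≈ 1.8: at 0.97 g/cm³ and 300 K
  the reduced state (ρ* = 1.01, T* = 0.55) lies below the LJ triple point,
  so the solvent is glassy (measured rescaled D ~ 10⁻⁸ cm²/s there) and
  the measured NPT density at 300 K / 1 bar is ≈ 0.84 g/cm³. This frozen
  solvent also leaves the explicit-solvent contact dimer bound by direct
  LJ adhesion/depletion rather than counterion bridging, so its
  instantaneous-projection force ratio sits near 1.
- Four reference-value tests in `tests/test_acceptance.py` (solvent
  diffusion, NPT density, dimer force ratio, and the exact transition
  charge — the last shifted by the 7× concentration of the scaled sweep
  box) encode the quoted values at the quoted conditions and fail,
  documenting these model- and scale-level gaps rather than hiding them;
  all engine-level validations (closed forms, Madelung, conservation laws,
  fluctuation–dissipation, clustering and MSD oracles) and the qualitative
  controls (charge-switch-off disassembly, no-aggregation-when-uncharged,
  assembly above a small charge threshold, loosening at high charge) pass.
- NPT is unavailable with full Ewald (no reciprocal-space virial).
- DSF electrostatics carry tens-of-percent far-field force error on small
  boxes (contact forces ≥ 90% faithful); use Ewald wherever it is
  affordable.
- Single macroion species per system; cubic boxes only; no bonded terms.
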