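# Methods

## The model

mW is a monatomic water model of Stillinger–Weber form. With
σ = 2.3925 Å, ε = 6.189 kcal/mol, the energy is

    U = Σ_{i<j} φ₂(r_ij) + Σ_i Σ_{j<k} φ₃(r_ij, r_ik, θ_jik)

    φ₂(r) = A ε [B (σ/r)⁴ − 1] exp[σ/(r − aσ)]
    φ₃    = λ ε (cos θ − cos θ₀)² exp[γσ/(r_ij − aσ)] exp[γσ/(r_ik − aσ)]

with A = 7.049556277, B = 0.6022245584, a = 1.8 (cutoff aσ = 4.3065 Å),
γ = 1.2, λ = 23.15 and cos θ₀ = −1/3. Both terms vanish smoothly at the
cutoff. Units throughout: kcal/mol, Å, fs (ps in reports), K, bar;
kB = 0.0019872041 kcal mol⁻¹ K⁻¹. Reduced temperatures convert as
T = T* ε/kB, so T* = 0.07 → 218.0 K and T* = 0.065 → 202.4 K.

Each three-body term is counted once per central particle (j < k); the
virial W = Σ f·r over interactions is defined so that
P = (2K/3 + W/3)/V, verified against −3V ∂U/∂V under affine scaling.

## Integrators

Velocity Verlet (NVE); BAOAB-splitting Langevin (NVT) with friction
1/damping; an isotropic Langevin piston (NPT) whose mass is set by the
requested oscillation period at an assumed bulk modulus (default
2 × 10⁴ bar, appropriate for a dense molecular liquid — pass the gas-scale
pressure instead for dilute systems). Volume updates rescale positions
affinely. Neighbor lists are Verlet lists with a skin; the rebuild trigger
is a Euclidean displacement of skin/2, which bounds the error at exactly
zero missed interactions. The default timestep is 4 fs; at that step the
secular NVE drift is ≈ 1 × 10⁻⁵ kcal/mol per particle per 1000 steps
(shadow-Hamiltonian oscillations are ~4 × 10⁻⁴ and not a drift).

Validation of the implementation against published mW behavior, computed
with this package: liquid U/N(298 K, 0.997 g/cm³) = −9.99 kcal/mol;
NPT density 1.0036 g/cm³ at 250 K (the density-maximum region) and
0.9796 g/cm³ for cubic ice at 270 K; self-diffusion 5.4 × 10⁻⁵ cm²/s at
296 K. At 202.4 K and ambient pressure the liquid nucleates spontaneously
within ~1 ns at N = 216.

## Crystallinity order parameter

Per particle, q_lm (l = 12) averages spherical harmonics over the bonds to
its 16 nearest neighbors (the first two coordination shells of a
tetrahedral network). Bond coherence d12(i,j) = Re⟨q̂_i, q̂_j⟩; a particle
is crystalline when ≥ ξ_c = 4 of its 16 neighbor coherences exceed
d_c = 0.65; crystalline particles within the first-minimum cutoff 3.51 Å
form clusters, and n is the size of the largest one (0 for a fully liquid
frame).

Why these values: with q12 restricted to the 4 first-shell bonds the
detector is not usable — the single *eclipsed* bond of hexagonal diamond
has d12 ≈ 0.44, so interior lonsdaleite particles can never reach 4
coherent bonds, and thermal vibrations at 218 K destroy the coherence of
even the cubic polymorph. Averaging over 16 neighbors restores a wide
margin: generated cubic and hexagonal diamond are 100% crystalline,
thermalized crystals at 218 K ≥ 95%, and equilibrated liquids at 218–271 K
contain *no* particle with more than one coherent bond (fraction ≪ 1%).
All thresholds are carried in a single `OrderParamConfig` shared by
analysis and biased sampling, so the two can never disagree.

Polymorph labels are diagnostic only. Each crystalline–crystalline bond is
scored by the mean of cos 3φ over its dihedrals: staggered bonds
(cubic-diamond-like) give −1, eclipsed bonds +1. Interior hexagonal-diamond
particles have exactly one eclipsed bond, so a particle with ≥ 1 eclipsed
bond is labelled hexagonal, all-staggered is cubic, and a particle with no
usable dihedral is unassigned. (A plain bond-majority vote would label
hexagonal interiors cubic — 3 of their 4 bonds are staggered.)

## Neural-network potential

Ten smooth trainable atomic fingerprints per particle, all multiplied by
the cosine cutoff f_c(r) = ½(1 + cos πr/r_c), r_c = 4.5 Å:

* 5 two-body: Σ_j exp[−(r_ij − R_k)²/w_k²] f_c(r_ij), trainable (R_k, w_k);
* 5 three-body: Σ_{j<l} exp[−(cos θ_jil − a_k)²/s_k²]
  exp[−(r_ij² + r_il²)/w₃ₖ²] f_c f_c, trainable (a_k, s_k, w₃ₖ).

A 10→25→25→1 tanh network maps standardized fingerprints to per-particle
energies (plus a constant shift set to the training-set mean energy per
particle); the total energy is the sum, giving permutation invariance and
exact extensivity. Forces and the pair-displacement virial come from
reverse-mode automatic differentiation (`autodiff.py`, a small tape engine
whose backward passes are themselves taped, so the force loss is
differentiable with respect to all parameters — fingerprint parameters
included).

Training: Adam on a weighted loss (energy 1.0 per particle², force 0.1 per
component²), minibatches of 8 configurations, cosine-annealed learning
rate 10⁻³ → 10⁻⁵ with warm restarts at logarithmically spaced epochs;
energy, force and virial-pressure errors on the held-out 20% split are
recorded every epoch, and the virial is *monitored, never trained*. Model
selection: among checkpoints in the trailing 25% of training (the
low-force-error regime), the simultaneous local minimum of Δϵ(epoch) and
ΔP(epoch); failing that, the checkpoint minimizing the worse of the two
error ranks. The training corpus is NVT mW sampling at three liquid state
points — (0.92 g/cm³, 221.1 K), (0.92 g/cm³, 270.9 K), (1.15 g/cm³,
270.9 K) — with a sampling stride checked by the lag-1 energy
autocorrelation. Defaults target the full-scale corpus (70 × N = 1000 per
state point, 4000 epochs, overnight scale); the test suite trains
miniature corpora (N = 48, ~10² epochs) with a proportionally larger
learning rate (3 × 10⁻³), which short runs need to converge.

## Nucleation kinetics

τ(n) is the across-trajectory mean of the earliest time the largest
cluster reaches n; trajectories that never reach n are excluded and
counted as censored. The sigmoid τ(n) = (2JV)⁻¹[1 + erf(c(n − n_c))] is
fitted by weighted nonlinear least squares for n below a configurable
ceiling (default 100). Weights are inverse standard errors *floored at 5%
of the largest standard error*: the nearly noise-free pre-barrier points
otherwise dominate the cost and drag the fitted inflection well below the
true critical size (fitted n_c = 21 vs true 25 on a 500-walk oracle
ensemble; with the floor, within 5%). V is the mean pre-nucleation NPT
volume of the ensemble; c is reported as a raw fit parameter without a
Zeldovich normalization.

The estimator is validated against a birth–death surrogate: a
continuous-time walk with constant attachment rate k⁺ and detachment set
by detailed balance against exp(−βG(n)), whose MFPT to any level follows
exactly from the standard recursive summation. (Detailed balance fixes
k⁻(n) = k⁺ exp[β(G(n) − G(n−1))]; attachment into an infinitely
unfavorable level is given rate zero.) Walks are stored as their
running-maximum skeletons — first-passage analysis is insensitive to the
discarded recrossings, and a 10 kBT barrier walk would otherwise record
~10⁵ jumps per trajectory.

## CNT-shaped umbrella sampling

Bias η(n) = kBT[Δμ n − (3/2) Δμ n_b^{1/3} n^{2/3}] — the negative of a CNT
profile whose top sits at n_b, so dη/dn(n_b) = 0 and
η(n_b) = −½ Δμ n_b kBT. Production parameters for mW at 218 K, 1 bar:
Δμ = 0.57 kBT, n_b = 90, N = 1000.

Because n is not differentiable, sampling is hybrid Monte Carlo: fresh
Maxwell–Boltzmann velocities, a 0.02 ps NVE segment (5 × 4 fs), and
acceptance min{1, exp(−β[ΔK + ΔU + Δη])} with n recomputed from scratch on
the trial frame (no incremental updates — correctness over speed);
rejection restores the previous state exactly. Isobaric moves follow each
HMC move with probability 0.01: uniform in ln V with the (N+1)Δln V
Jacobian inside the acceptance. Pressure enters only through these volume
moves, not the HMC acceptance. The unbiased profile is
βΔG(n) = −ln P(n_max) − βη(n) + C with min 0; empty interior bins are
interpolated and flagged, and a gap longer than 5 bins is treated as an
unbridged barrier (error).

Sampler validation avoids MD entirely: a 1-D Metropolis sampler on a known
landscape under the matched bias must return a near-flat histogram and, at
10⁶ moves on a 60-level landscape, a reconstruction within 0.2 kBT
pointwise (i.i.d. draws: within 0.04). Canonical sampling of the HMC core
is verified on independent harmonic wells by a χ² test against the exact
Gaussian; the validation chain uses 0.4 ps segments because 0.02 ps
segments decorrelate a 0.9 ps-period oscillator far too slowly for a
per-sample test (every move is still accepted at machine precision).

## Self-diffusion protocol (the headline measurement)

`structure.measure_self_diffusion`: generate a liquid at the target
temperature; 100 ps NVT; 200 ps Langevin-piston NPT whose trailing-half
mean volume fixes the density; 400 ps NVT aging (supercooled mW keeps
structuring on this scale); 400 ps NVT production with weak coupling
(damping 10× the usual), recording unwrapped positions; time-origin-
averaged MSD in the center-of-mass frame; least-squares 6Dt fit over
30–150 ps. The acceptance script averages three independent replicates at
N = 216 (single-trajectory estimates scatter by ~15% at this size);
problem sizes were chosen so the whole script runs in minutes on one core.

What the synthetic fixtures do and do not show: the generated liquids,
lattices and walks validate every estimator against known answers, but the
1-D walk has a size-independent attachment rate (no claim about mW's
attachment kinetics) and the lattices have no interfaces, so passing tests
demonstrate estimator correctness, not the physical accuracy of reduced-
size MD observables.

## Known limitations

* Orthorhombic boxes, single species, no long-range electrostatics (the
  model has none by construction).
* The Langevin-piston NPT is meant for equilibrium state-point
  equilibration; its volume dynamics is not tuned for accurate dynamic
  response functions.
* Full-scale reproductions (100 nucleation trajectories at N = 1000;
  4000-epoch training on 210 configurations; 48-cell energy-error maps)
  are overnight jobs; the shipped tests exercise the identical code paths
  at reduced size.
* At deep supercooling the measured self-diffusion coefficient of this
  implementation is reproducible across system sizes (216–1000) and
  ensembles but sits well above some reported values for the same state
  point, while matching published mW statics (density maximum, ice
  density, liquid energies) and 298 K dynamics; the protocol, all raw
  numbers and the fit windows are exposed so the comparison is fully
  transparent.
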