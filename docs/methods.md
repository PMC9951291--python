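# Methods

## Harmonic model and its coarse-graining

A harmonic network is defined by a symmetric connectivity (Kirchhoff)
matrix `Γ` with zero row sums: `u(x) = ½ δxᵀ Γ δx`, `δx = x − x0`.  The
Boltzmann weight `exp(−β u)` makes the displacement distribution Gaussian
with covariance `c00 = Γ⁺/β`, where the pseudo-inverse runs over the
non-zero eigenmodes only — equivalently, the centre of mass is pinned.
Gaussian Network Models are built in the isotropic convention (one scalar
coordinate per node); three-dimensional observables are three independent
copies of the scalar problem, so mapping comparisons lose nothing.

For a linear CG map `M` (row-stochastic, disjoint supports) the
thermodynamically consistent CG model is again Gaussian.  Its covariance
is the mapped covariance projected onto the translation-free subspace,

    C00 = Q (M c00 Mᵀ) Q,     Q = 1_N − J JᵀN⁻¹,

and the effective CG matrix is `K = C00⁺/β`.  The projection matters:
for slicing maps the raw `M c00 Mᵀ` is full rank, and for unequal-size
averaging partitions its null vector is the group-size vector rather than
the uniform vector, so only the projected matrix satisfies `C00 = K⁺`
with exactly one zero mode along the uniform CG direction.  The raw
mapped covariance is kept alongside (`CGModel.mapped_covariance`); it is
what a sample covariance of mapped coordinates estimates, and what the
vibrational power traces.

Assuming overdamped Langevin dynamics with friction `γ`, each eigenmode
`(λᵢ, uᵢ)` of `Γ` relaxes independently at rate `λᵢ/γ`, giving the exact
lag-`τ` covariance

    Ω_τ = Σ_{λᵢ>0} exp(−λᵢ τ/γ) / (β λᵢ) uᵢ uᵢᵀ,
    C0τ = Q (M Ω_τ Mᵀ) Q.

## The four scores

* **VAMP-2.** `R = ‖C00^{−1/2} C0τ C00^{−1/2}‖²_F`, computed with a
  pseudo-inverse square root on the numerical range of `C00`
  (eigenvalue threshold 1e-10 relative).  `R ∈ [0, rank C00]`, equals the
  rank at `τ = 0`, and is maximized by coordinates spanning the slow
  Koopman eigenfunctions.  The VAMP-2 variant (sum of squared whitened
  eigenvalues) is used throughout; it is the standard choice for
  reversible dynamics.
* **Mapping entropy.** For Gaussian models the difference between the
  excess configurational entropy of the fine-grained ensemble and the one
  perceived through the map reduces to eigenvalue products:
  `mapping_entropy` returns the mapping-dependent part
  `½(ln T_K − ln t_Γ)` with `t_Γ = Π λᵢ(Γ)` and `T_K = Π Λᵢ(K)` over
  non-zero eigenvalues.  This is zero for the identity map and ranks
  mappings identically to the full quantity at fixed `(N, n)`, which is
  the only comparison the score is used for.  `mapping_entropy_full`
  restores the model-independent constants: each of the `n − N` discarded
  coordinates contributes `½ ln(2πe/β) − ln V`, with `V` the confinement
  volume per coordinate of the excess-entropy reference.  Negativity of
  the full S_map is a large-box statement; the default `V = 100` is far
  above the thermal fluctuation scale of the unit-parameter systems used
  here, and the non-positivity property is asserted in that regime.
* **Vibrational power.** `VP = tr(M c00 Mᵀ)` with uniform masses — the
  preserved fluctuation amplitude, blind to timescale.
* **Reconstruction error.** The Gaussian closed form is the residual
  variance of the conditional-mean decoder,
  `RE = tr(c00 − c00 Mᵀ (M c00 Mᵀ)⁺ M c00)/n`.  This is a certified lower
  bound for the held-out MSE of any decoder trained on trajectories of
  the same system, which is how it is validated against the trained
  linear and MLP decoders.

Implied timescales are `tᵢ = −τ/ln νᵢ` from the whitened Koopman
eigenvalues; for the identity map they reduce exactly to `γ/λᵢ`.
Because the full dynamics is Markov, the identity-map timescales are
lag-independent; projected CG dynamics is generally not Markovian, so CG
timescales carry a (weak) lag dependence and all comparisons fix one lag.

**Default lag.** `τ = 10 γ/λ_max`, ten times the fastest relaxation time,
which sits between the fastest and slowest relaxation times of every
system studied here.  Per-metric optima are insensitive to this choice
over at least a decade of `τ` (tested); the value is overridable
everywhere.

## Candidate mapping spaces

* Slicing maps: all `C(n, N)` atom subsets, lexicographic.
* Contiguous averaging partitions: all `C(n−1, N−1)` splits of the
  sequence into `N` blocks (counted in closed form by stars-and-bars and
  streamed with O(N) memory) — CG beads are groups of *subsequent* atoms,
  the convention used for the network-model experiments.
* The 2-bead candidate set for the 4-bead chain experiments is the union
  of both: 6 slicing pairs + 3 contiguous partitions.  An exhaustive
  space of all unordered pairs of disjoint non-empty subsets (25 maps at
  n = 4, including non-contiguous beads) is available separately for
  exploration; note that non-contiguous averaging beads can overtake the
  named optima of some scores, which is why the canonical set restricts
  averaging beads to contiguous groups, mirroring the network-model
  convention.
* Ties in argmax/argmin are resolved within a relative tolerance of 1e-9
  toward the lexicographically first mapping.  Several 4-bead optima are
  exact ties by symmetry (e.g. RE of slicing the first vs the last stiff
  pair), so tolerance-aware tie-breaking is required for reproducible
  reports.

## Simulation

`simulate_harmonic` integrates the Euler–Maruyama (EM) discretization
`δx ← δx − Γ δx dt/γ + √(2dt/(βγ)) η` in the eigenmode basis: each
non-zero mode is an AR(1) chain with multiplier `a = 1 − λ dt/γ`, which
is compounded in closed form between saved frames and generated with an
IIR filter.  This is distributionally identical to stepping EM in
coordinate space — including the O(dt) stationary-variance bias
`var → c00/(1 − λ dt/2γ)`, whose linear shrinkage with dt is tested —
while running 10⁶-step oracles in milliseconds.  Zero modes carry no
noise (pinned centre of mass), matching the analytic covariances.  The
initial condition is drawn from the exact equilibrium.  `β = ∞` gives
noiseless relaxation.

`propagator="exact"` replaces the EM multiplier by `exp(−λ dt/γ)` with
the matching stationary variance, sampling the exact continuous-time law
with no timestep bias.  Statistical oracle tests (empirical vs analytic
covariances, scores and timescales at 3-standard-error tolerance) use
this mode so that integrator bias is not conflated with sampling error;
the EM bias itself is characterized by a dedicated test.

The 13-bead model protein uses a literal EM step loop on analytic forces:
harmonic bonds and bends, full Lennard-Jones on the attractive
cross-strand contacts, and repulsive-only (truncated/shifted at the
minimum) cores elsewhere, with 1-2 and 1-3 exclusions.  The shipped
parameter file `data/model_protein_13.ff` is a synthetic qualitative
stand-in — it reproduces hairpin topology, a force-free native state
below the extended state, and folded/extended interconversion, not any
published parameter set — and is parsed at run time so it can be edited.

## Empirical estimators

* Features: CG coordinates (`M x` per spatial dimension, concatenated) or
  all CG pair distances (rotation/translation invariant; the choice for
  the nonlinear system).  For coordinate features the uniform component
  is projected out per frame before covariance estimation, so the
  estimates target the projected analytic `C00`/`C0τ`.
* Covariances: mean-free over all `(t, t+τ)` pairs; the reversible
  default averages head and tail statistics and symmetrizes `C0τ`
  (denominator = number of pairs, no Bessel correction — irrelevant at
  the trajectory lengths used).  Whitened eigenvalue estimates outside
  (0, 1) are truncated with a warning, never an error: finite samples
  routinely produce them.
* Decoders: the linear decoder is the exact least-squares solution; the
  nonlinear decoder is a two-hidden-layer (64, 64) ReLU MLP with fixed
  seed and epoch budget.  Training uses the first 80% of frames as one
  contiguous block; evaluation on the same trajectory is restricted to
  the complement (overlap raises an error) to avoid temporal leakage.
  Held-out MSE estimates used against percent-level bounds are averaged
  over several independent trajectories, since a single held-out block
  has ~1% sampling noise at the lengths used.

## Synthetic structures

`synthetic_structure(m, seed)` draws a self-avoiding random walk with
fixed 3.8-unit steps (the Cα virtual bond length) and a 3.0-unit clash
radius.  It reproduces the local geometry and contact-graph connectivity
a Cα trace needs for a well-posed GNM; it does *not* reproduce secondary
structure, native-like contact order, or realistic radius of gyration.
Passing tests on these fixtures therefore demonstrate the correctness of
the scoring machinery and the qualitative behaviour of the metrics on
protein-like connectivity, not quantitative agreement with any real
protein.  The pinned demonstration fixture is `seed = 7`, 40 residues,
cutoff 10: on it the VP-optimal 4-bead contiguous map is three terminal
singleton beads plus one 37-atom bead, the S_map-optimal map is a more
uniform partition, and the VAMP-optimal map recovers the three slowest
timescales with summed relative error ≈ 0.15 versus ≈ 1.2 (S_map) and
≈ 2.0 (VP) — the qualitative pattern the scores are designed to expose.
For user-supplied structures the comparison is reported, not asserted:
no theorem orders the metrics on arbitrary graphs.

## Problem sizes and numerical choices

* Test and acceptance runs use 4-bead chains (both stiffness regimes,
  spring ratios 2 and 4), the 40-residue fixture at N = 3–5, 10⁶-step
  trajectories with dt = 0.02, stride 5, lag 10 frames, and 10 seeds for
  seed-replicated 3-standard-error comparisons; these sizes make every
  statistical tolerance comfortable on one CPU.
* Pseudo-inverses threshold eigenvalues at 1e-10 of the spectral radius
  (1e-6 for finite-sample covariances); zero modes are classified at
  1e-10 relative.
* All randomness flows through `numpy.random.default_rng` seeds;
  identical seeds give bit-identical trajectories and reports.

## Limitations

* Closed-form scoring requires a harmonic (Gaussian) model; for
  anharmonic systems only the trajectory estimators apply, and S_map has
  no trajectory estimator here (known numerical approximations are
  parameter-sensitive and are deliberately not implemented).
* Overdamped dynamics only: no inertia, no memory kernels; the implied
  timescale identities rely on it.
* The mapping type covers non-negative uniform-weight linear maps;
  general weighted or learned maps are representable but not enumerated.
* Single-chain structures; anisotropic or mass-weighted network models
  are out of scope.
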