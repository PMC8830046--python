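# Methods

`pathcommit` implements the analysis arc used to resolve rare-event
binding kinetics — transition path sampling (TPS), committor analysis, a
likelihood-trained neural committor model with automated architecture
search, permutation feature relevance, and umbrella-sampling/WHAM free
energies with a transition-state-theory (TST) rate bound — on stochastic
toy systems designed to emulate the solute–solvent coupling of divalent
ion binding (e.g. Mg²⁺ exchanging a hydration water for an RNA phosphate
oxygen).

## The toy system

The model dynamics is underdamped Langevin motion on

    V(x, z) = h ((x/a)² − 1)² + Σⱼ (κⱼ/2)(zⱼ − x)²

* `x` — the "distance-like" reactive coordinate; two wells at x = ±a
  (a = 1 by default) separated by a barrier of height `h` (k_BT units).
* `zⱼ` — bath ("solvent") coordinates harmonically slaved to x with
  stiffness κⱼ. Slow bath modes lag the reactive motion, reproducing the
  essential feature of hydration-shell coupling: the committor at fixed x
  depends on the solvent state. Defaults: 8 bath coordinates, κⱼ
  log-spaced over [0.1, 5].
* noise coordinates — feel no force and diffuse freely; the *feature
  columns* labelled noise in shooting datasets are injected i.i.d.
  standard normal, giving ground-truth-irrelevant inputs for the
  relevance analysis.
* defaults: h = 8 k_BT (direct transitions rare, TPS productive at desk
  scale), friction γ = 1, k_BT = 1, m = 1, timestep 0.01.

Integration uses the BAOAB splitting, which samples the canonical
configurational density with small timestep bias; the stability bound is
dt < 2/ω_max (`PotentialSpec.stability_limit`, ≈ 0.25 for the default
system). Metastable states are threshold rules: A at x > 0.8, B at
x < −0.8. Additional potential kinds: a single harmonic well (closed-form
reference for equipartition, umbrella windows and WHAM) and an arbitrary
2D spline-interpolated grid potential.

## Transition path sampling

Two-way shooting with fixed path length: a slice is drawn uniformly from
the interior frames of the current reactive path, all velocities are
redrawn from the Maxwell–Boltzmann distribution, and the dynamics is run
forward (and backward from the negated velocities, then time-reversed) so
the segments concatenate to the original length. Trials are accepted iff
their endpoints lie in different states; rejected moves repeat the
previous path. Full velocity redraw keeps the acceptance rule exact for
fixed-length sampling at the cost of a lower acceptance rate on stiff
systems (a few percent on the default 8-k_BT, 8-bath system). Initial
reactive paths are harvested from boosted-temperature dynamics and
re-checked against the production state definitions.

## Committor analysis

The committor p_A of a configuration is estimated by launching `n_trials`
(default 100) trajectories with fresh Maxwell–Boltzmann velocities and
counting first entries into A and B within a time horizon; unresolved
trials are excluded from p_A = n_A/(n_A + n_B) and reported separately
(a point with no resolved trial is flagged, never silently zero).
Transition states are configurations with 0.45 < p_A < 0.55 (exclusive).

Reaction-coordinate quality is diagnosed by the distribution p(p_A) on a
level set of the candidate coordinate, compared with the binomial
reference — the distribution of k/n with k ~ Binomial(n, ½) that an
ideal coordinate produces on its 0.5 iso-surface. Histograms use bin
width 0.05 (20 bins), which resolves the reference at n = 100 without
empty-bin noise; the divergence statistic is the total-variation distance
between normalized histograms (a concrete scalar standing in for the
visual comparison practitioners usually make). Level-set half-widths
default to 0.05 for λ-like coordinates and 0.02 nm for distances.

## Molecular feature battery

For coordination-shell geometries (an ion plus ligands with roles), the
default schema has exactly 83 columns: 20 ion–water distances, 20
coordination angles about the ion with the phosphate oxygen O1P as apex,
6 ion–site distances (r_I, r_O2P, r_P, r_N7, r_O6, r_Cl), r_ex,
the derived difference r_I − r_ex, the effective hydration distance

    s6 = Σ(five closest ion–water-oxygen distances) + r_ex,

Steinhardt order parameters q₃/q₄/q₆ for the first (≤ 0.3 nm) and second
(0.3–0.5 nm) hydration shells, two tetrahedral order parameters, and 26
geometric hydrogen-bond counts (O–O < 0.35 nm and H-donor-acceptor angle
< 30°, the community-standard criterion). When a reference atom is absent
the non-strict mode pads with documented fill values (1.0 nm distances,
zero angles/counts); strict mode raises, naming the feature.

The knowledge-based reaction coordinate is

    λ = atan2(s6 − s6⁰, r_I − r_I⁰),  s6⁰ = 1.18 nm, r_I⁰ = 0.18 nm,

so λ = π/2 is the inner-sphere and λ = 0 the outer-sphere coordination;
values are kept on the principal branch (−π, π], which contains every
anchor of interest (inner π/2, outer 0, transition window 0.6–1.0,
saddle ≈ 0.8).

Numerical notes: Steinhardt q_l uses the rotationally invariant
spherical-harmonic average and is validated against the Legendre
addition-theorem identity q_l² = N⁻² Σᵢⱼ P_l(ûᵢ·ûⱼ); for the ideal
octahedron q₄ = √(7/12) ≈ 0.764 and q₆ = 1/(2√2) ≈ 0.354. Features
involving arccos are exactly isometry-invariant only away from 0°/180°,
where the inverse cosine amplifies rounding; the invariance tests use
generic (tie-free) configurations for that reason.

## Committor regression

The committor model is a multilayer perceptron mapping standardized
features to a scalar reaction coordinate q̃, linked to a probability by
p = 1/(1 + e^(−q̃)) ≡ (1 + tanh(q̃/2))/2, trained by minimizing the
binomial negative log likelihood

    l = − Σᵢ [ n_Aⁱ ln pᵢ + n_Bⁱ ln(1 − pᵢ) ],

with probabilities clipped at ε = 10⁻⁷. The training recipe: features
standardized on the training rows only; 72/8/20 train/validation/test
split; Adam with batch size 128; 50 epochs with early stopping on the
validation loss (patience 10, best weights restored); refinement for up
to 200 further epochs with plateau-triggered learning-rate reduction
(factor 5, floor 10⁻⁵, plateau patience 7). Layers use ReLU with
Glorot-uniform initialization and standard dropout, or SELU with
LeCun-normal initialization and alpha dropout; a single dropout layer may
sit after the input, mid-stack, or before the output. The network,
backpropagation and Adam are implemented directly in NumPy; gradients are
verified against central finite differences in the test suite, and every
stochastic stage is seeded, so runs are bit-reproducible.

Architecture search is uniform random sampling of (hidden layers 1–6,
width 32–256, ReLU/SELU, dropout position/rate 0–40%, learning rate
log-uniform 10⁻⁴–10⁻²), ranking by validation loss, refining a best
subset (default 5), and selecting the final model by the sharpest peak of
the true-committor histogram over its predicted transition states — ties
break toward the lower validation loss. The desk-scale default budget is
30 trials (exposed in config); when no candidate predicts any transition
state at all, `tune` falls back to the validation-loss ranking with a
warning.

## Feature relevance

Single relevance: each feature column in turn is replaced by a random
permutation of itself (exactly preserving the marginal), the loss is
re-evaluated, and r_sⁱ = (lᵢ − l_opt)/(l_max − l_opt), so the most
informative feature scores exactly 1. Combined relevance is greedy: at
each step the remaining feature whose permutation (with all previous
permutations maintained) raises the loss least is permuted next — rank 1
is the least important — for N(N+1)/2 permuted-dataset evaluations in
total (3486 at N = 83). The cumulative relevance r_c(n) = (l(n) −
l_opt)/(l_rand − l_opt) is 1 at n = N by construction. One fixed
permutation per feature is drawn from the run seed and reused across
steps, which makes the sequence deterministic; losses are evaluated on
the full labelled dataset unless restricted.

## Free energy and rates

Umbrella windows apply a harmonic bias (k/2)(ξ − c)² along x (or an
(x, y) pair on grid potentials); adjacent-window histogram overlap below
1% warns and zero overlap raises. WHAM iterates the standard
self-consistency equations to a 10⁻⁷ tolerance on the window offsets
(cap 10⁵ iterations), in 1D or 2D. Convergence is diagnosed by block
analysis (default 8 contiguous blocks); because a free-energy profile is
defined only up to a constant, the per-block profiles are gauged on the
commonly occupied bins before the spread is computed — min-shifting each
block independently would convert one noisy tail bin into a spurious
uniform offset.

The TST rate is the flux-over-population upper bound

    k_TST = √(k_BT / 2π m_eff) · e^(−F(x*)) / ∫_reactant e^(−F) dx,

with the thermal flux prefactor ⟨v θ(v)⟩. Recrossings of the dividing
surface only reduce the true rate, so k_TST ≥ k_direct is promoted to a
test: the bound is checked against rates counted in long unbiased runs of
the same double well. The effective mass defaults to the particle mass
for the coordinate x; for general collective coordinates it should be
supplied (or derived from the equilibrium variance of the coordinate
velocity).

## Synthetic data: what it does and does not emulate

`fixture_shooting_data` skips the dynamics entirely: features come from a
Gaussian mixture, labels from n_A ~ Binomial(n_trials, p_true(X)) with a
known committor law, and p_true is stored. This isolates the learning
stack — a network that fails here is wrong, independent of sampling
noise. `generate_shooting_dataset` produces dynamics-consistent labels
via the brute-force committor over window-restricted equilibrium draws
(the bath conditional given x is exactly Gaussian, so the draw is exact).
What passing these tests shows: the estimator, loss, training loop,
search, relevance bookkeeping and WHAM machinery are correct, and the
method behaves as theory predicts on systems whose ground truth is
computable (a phase-space backward-Kolmogorov solve serves as the
committor oracle in the tests). What it does not show: anything about
force fields, real hydration-shell energetics, feature completeness on
atomistic data, or MD-scale sampling adequacy — those require molecular
simulation outside this package's scope.

## Problem sizes

Defaults in the test-suite and demo configurations are chosen for a
single CPU: shooting datasets of 300–2000 points with 50–100 trials per
point, tuner budgets of ~6 architectures, TPS runs of a few hundred
moves on paths of 301–801 frames, umbrella protocols of 11–21 windows at
10⁴–10⁵ steps each. All sizes are parameters; scaling them up changes
cost, not code paths.

## Known limitations

* Fixed-length TPS with full velocity redraw only; no aimless shooting,
  flexible lengths, or path reweighting.
* The committor model gives no reactive-flux/transmission-coefficient
  correction; k_TST remains an upper bound.
* The 83-feature schema pads or errors when reference atoms are missing;
  it does not read MD trajectory formats.
* Histogram-based diagnostics (p(p_A), WHAM) inherit binning choices;
  defaults are documented above and configurable.
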