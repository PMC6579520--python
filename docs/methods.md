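# Methods

This note records the models, estimators, numerical choices and known
limitations behind `confland`, in the order data flows through the pipeline.

## Synthetic generator

The trajectory generator (`synthgen`) is a discrete-time hidden Markov
model: a hidden macrostate chain with a reversible, row-stochastic
transition matrix; categorical microstate emissions per macrostate; and
isotropic Gaussian feature noise around fixed microstate centers.

**Prescribed timescales.** `make_generator` symmetrizes a random count-like
matrix with a diagonal tuned near the target spectrum, row-normalizes it
(fixing a stationary distribution and an eigenvector basis) and rescales the
non-unit eigenvalues to `exp(-step_time / t_k)` for the requested timescales
`t_k`. Rescaling can push entries slightly negative; alternating projections
between "exact spectrum" and "nonnegative reversible" run until both hold,
and a candidate is accepted only if the realized timescales are within 0.5%
of the request (in practice they match to ~0.1% or better). Timescales
shorter than the step are rejected as unrealizable.

**Identifiable emissions.** Emission rows have *disjoint* microstate
support (a contiguous block per macrostate, Dirichlet(5) weights inside).
Two consequences are used throughout the tests: macrostates are exactly
identifiable from microstates, and the observed microstate chain is itself
Markov with `T_micro[m, m'] = macro_T[b(m), b(m')] · emission[b(m'), m']`,
so microstate-level ground truth (stationary distribution, timescales) is
available in closed form.

**Linear observability.** Feature centers default to `n_features = n_micro`
generic positions (uniform in a hypercube, minimum separation six noise
standard deviations). With at least as many generic dimensions as
microstates, every state function — in particular the slow eigenfunctions —
is expressible as a linear function of the features. This is what makes
tICA-based recovery well-posed; with fewer dimensions the slow eigenfunction
is generally *not* linearly observable and tICA can only return its best
linear approximation. The default emission noise is `emission_sd = 0.05`
(feature units); because the center box scales with the noise, the
signal-to-noise ratio of the features is scale-invariant.

**What the generator does not emulate.** Real MD features are
high-dimensional, continuous, non-Gaussian within states, and weakly
non-Markovian at short lags; trajectory lengths vary; and states are not
cleanly separable. Passing the recovery experiments therefore demonstrates
the correctness of the estimators under their own assumptions, not the
quality of any particular protein model.

**Bead chains.** Contact-map and RMSD machinery is exercised on bead-chain
ensembles built by penalized optimization: virtual bonds at 0.38 nm,
specified contacts pulled to 0.32 nm, all other eligible pairs kept beyond
0.55 nm, then per-frame Gaussian jitter of 0.005 nm — margins chosen so the
0.4 nm contact truth table holds exactly in every frame. Geometrically
unsatisfiable specifications are detected and reported.

**Two-timescale linear-Gaussian process.** For slow-direction recovery a
separate construction is provided: two independent stationary AR(1)
processes (timescales 100 and 10 steps) observed through an invertible
linear mixture. This is the setting in which tICA provably recovers the
slow direction; the jump-process generator carries irreducible eigenvector
sampling error (~2–10% in cosine at 10⁵ frames) that reflects the data, not
the estimator.

## Featurization

Distances are *minimum heavy-atom* residue–residue distances, in nm, for
pairs separated in sequence by at least two intervening residues
(`|i − j| ≥ 3`), matching the convention of the contact thresholds: pairs
closer than 0.4 nm count as contacts, both for dynamic-pair selection
(pairs must cross 0.4 nm at least once to be kept) and for mean contact
maps. The logistic transform `1/(1 + exp(steepness·(d − center)))` uses
steepness 5 nm⁻¹ and center 0.5 nm, mapping the center to exactly 0.5.
Dihedral features are (sin, cos) of every *defined* φ, ψ, χ₁; undefined
angles (χ₁ of Gly/Ala, chain termini) are omitted rather than zero-filled,
which would inject constant fake columns into tICA. Column order is the
deterministic lexicographic pair/angle enumeration recorded in
`column_labels`.

## tICA

Covariances are symmetrized estimates over in-trajectory lagged pairs
(lagged pairs never span trajectory boundaries): C(0) averages both time
windows and C(τ) is symmetrized, enforcing a real spectrum on finite data.
Whitening discards covariance eigenpairs below 1e-10 of the largest —
a deterministic, scale-aware rank control — and eigenvalues are clipped to
(−1, 1].

*Kinetic content* of component i is defined as tᵢ/2 — the commute-map
variance — normalized over components with positive timescale; the
truncation rule keeps the smallest leading set whose cumulative content
reaches the requested fraction (0.95 by convention). Components with
nonpositive eigenvalue have undefined timescales, carry no resolvable
kinetics, and are dropped under the commute map. The commute scaling
constant √(tᵢ/2) is isolated in one function so an alternative convention
can be substituted.

## Markov state models

k-means (k-means++ init, tolerance 1e-6, ≤500 Lloyd iterations; via
scikit-learn) discretizes projected data; held-out trajectories are
assigned to the *training* centers. Counts are sliding-window, never
crossing trajectory boundaries; the escape-probability analysis corrects
the resulting overcounting explicitly through N_eff = N/τ. Estimation
restricts to the largest strongly connected component of the count graph
(ties broken toward more counts) and runs the standard self-consistent
reversible maximum-likelihood iteration on symmetric weights
`x_ij ← (c_ij + c_ji)/(c_i/x_i + c_j/x_j)` to a max-change tolerance of
1e-12 (≤10⁶ sweeps). The unit test cross-checks the fixed point against a
direct likelihood maximization over the same parameterization.

**VAMP-2 scoring.** In-sample, the rank-10 VAMP-2 score is
`1 + Σ_{i=2..10} λᵢ²`. Out-of-sample, the test correlation operator is
expressed in the train model's top-rank π-orthonormal eigenfunction basis
Ψ: a reversible MSM (T_test, π_test) is re-estimated from the test counts
restricted to states shared with the train active set (frames in unseen
states are dropped, with a logged fraction, and trajectories are split at
the gaps so no artificial transitions arise), and the score is
`‖C00^{-1/2} C0t Ctt^{-1/2}‖_F²` with `C00 = Ψᵀ diag(π_test) Ψ`,
`C0t = Ψᵀ diag(π_test) T_test Ψ`, `Ctt = C00`, capped at the rank. Basing
the test operator on the re-estimated model (rather than raw empirical
covariances) makes train = test reduce *exactly* to the in-sample formula,
which the suite asserts to 1e-8; the construction is isolated in one
function for substitution.

**Validation.** Implied timescales report NaN, never a negative time, for
nonpositive eigenvalues. The Chapman–Kolmogorov test aggregates over
metastable sets (argmax memberships from the coarse-graining), comparing
set persistence under T(τ)ᵏ against re-estimation at lag kτ with
count-based standard errors `√(p(1−p)/(N/kτ))`. Escape probabilities use
the Beta(N_eff·f, N_eff·(1−f)) central 95% interval; the trajectory
bootstrap (40 replicates by convention) averages the estimates and takes
the 2.5th/97.5th percentiles of the per-replicate CI bounds. Degenerate
endpoints (f = 0 or 1) collapse the corresponding bound to the estimate.
The frequentist coverage experiment uses the plain per-replicate Beta
interval: percentiles-of-bootstrap-bounds deliberately widen the interval
and are not the object whose coverage is near 95%.

## HMM coarse-graining

Baum–Welch with discrete emissions runs on lag-strided frames (multiples of
the Markovian lag), so the hidden chain is modeled at the lag rather than
at sub-lag resolution. Initialization is a PCCA⁺-style fuzzy partition:
simplex vertices by successive farthest-point search in the space of the
top right eigenvectors, memberships by the linear transform onto those
vertices with negatives clipped and rows renormalized; the initial
macrostate matrix is the membership-projected MSM, softened toward uniform
(9:1) to keep EM off the boundary. Observation probabilities are floored at
1e-12 before renormalization so held-out microstates cannot zero out a
likelihood. EM stops at an absolute log-likelihood change below `tol`
(default 1e-6) or `max_iter` (default 500); on the reference million-frame
dataset the parameters are converged to ~1e-4 max-norm within ten
iterations, and the validation experiments run with `tol = 1e-3`,
`max_iter = 50` on that basis. Microstate memberships are the emission
posteriors `P(macro | micro) ∝ obs[a, m]·π_a`. Hard assignment is
argmax-membership with ties broken toward the lower macrostate index and
logged. The macrostate count is a user decision informed by
`macrostate_sweep` (log-likelihood and timescales per candidate count);
automatic selection of "structural separation" is out of scope.

## Landscape

Fluxes use the third power of the macrostate transition matrix to eliminate
sparsity: `F_ij = π_i (T³)_ij / (3·lag_time)`, symmetric under detailed
balance. The per-unit-time normalization (dividing by power × lag) is the
package's convention and is isolated in `flux_matrix`. Dissimilarities for
the 2-D embedding are `log(1/F_ij)`, shifted only as needed to be
nonnegative (an unconditional shift-to-zero would collapse equal-flux
geometries); metric MDS runs SMACOF stress majorization (scikit-learn) from
≥50 random starts and returns the minimum-stress embedding together with
every restart's stress, so a user can re-select a projection by any other
criterion (the minimum-stress rule replaces manual aesthetic selection
because it is deterministic and testable). Free energies are
`−kT ln(π_i/π_max)`, exactly zero at the most populated state and invariant
to rescaling π. Structural annotation superposes frames by the Kabsch
algorithm on a conformationally homogeneous core (default: the SET-motif
residue ranges 257–290 and 327–376) and evaluates Cα RMSD over the full
selection; macrostate RMSDs are observation-probability-weighted means of
microstate RMSDs, and structural diversity is the minimum over reference
frames of the mean RMSD to the other sampled frames, with frames sampled
proportionally to `obs[macro, micro]/n_frames(micro)`.

## Coverage and mutant analysis

Coverage expressions are evaluated over per-label visited-state sets with
union/intersection/difference and full Venn-region enumeration. The
coverage grid draws trajectories without replacement, truncates to a
maximum length, counts distinct states, and averages five draws (grid steps
of 50 trajectories and 50 time units by convention); for a fixed draw the
grid is exactly monotone along both axes. Minimal time to a coverage target
is the minimum of trajectories × length over qualifying grid points.

Differential contact maps subtract the wild-type mean contact fraction from
the mutant's; relative change is |absolute|/WT, forced to zero where the WT
fraction is zero (a never-formed contact has no meaningful enrichment);
selection requires absolute change > 0.2 *and* relative change > 3, both
strict. Residue deletions zero every change touching the position.
Candidate frames are extracted after a burn-in (default 750 ns worth of
frames — the convention adopted for mutant trajectories, configurable) when
all top-5 positive contacts are formed or none of the top-5 negative
contacts is formed, strided by 10 (20 when a trajectory has more than 7,500
qualifying frames); clusters are expanded by including every 10th frame
within 0.3 nm minimum RMSD of any cluster member. Discovery curves count
first visits by a query cohort to states never visited by the reference
cohort, against aggregate query frames. Manual structure-inspection steps
of the original protocol are out of scope; the chain ends at frame sets for
human review.

## Binding kinetics

The induced-fit scheme E + S ⇌ ES ⇌ E′S is integrated under
pseudo-first-order conditions ([S] ≥ 10× enzyme, as in the stopped-flow
design of 1 µM enzyme vs 16–2000 µM ligand) by exact eigendecomposition of
the 3×3 rate matrix; off-regime, the full bimolecular system with ligand
depletion is integrated with BDF at absolute tolerance 1e-12. Global
fitting optimizes the four rate constants in log space with the
fluorescence coefficients (a, b, c, bkg) profiled out by linear least
squares at every step — reducing an 8-parameter problem to 4 nonlinear
ones — from 20 log-uniform multi-starts plus one data-driven start derived
from conventional double-exponential fits (slope/intercept of
k_obs^fast = k₁[S] + k₋₁ + k₂ + k₋₂ and the slow-phase plateau k₂ + k₋₂).
Standard errors come from the Jacobian at the optimum, mapped to the linear
scale by the delta method.

**Conformational selection.** The alternative scheme E ⇌ E′, E′ + S ⇌ E′S
starts from the pre-mixing E/E′ equilibrium. Its observable constrains the
two apo conformers to one shared fluorescence coefficient: the signal
change is ligand-mediated, and — a fact worth recording — *without* this
constraint a three-species conformational-selection model with four free
coefficients can reproduce induced-fit data exactly (both mechanisms give
observed-rate sums and products linear in [S], and free amplitudes absorb
the eigenvector differences), making the model comparison vacuous. With
the constraint, fitting conformational selection to induced-fit data
leaves a large residual, reproducing the expected rejection of the
alternative.

**Slow-phase expression.** The printed slow-phase relation
`k_obs^slow ≈ k₁[S] + (k₋₂ + k₂) + k₋₁k₋₂/(k₁[S] + k₋₁ + k₂ + k₋₂)` keeps
its additive k₁[S] term while the plateau constant is quoted as k₋₂ + k₂;
`kobs_predictions` exposes both the full expression and the plateau rather
than resolving the tension between them.

Equilibrium constants are K_d1 = k₋₁/k₁ (µM), K_eq = k₋₂/k₂,
K_d = K_d1·K_eq/(1 + K_eq); first-order error propagation is cross-checked
against Monte-Carlo propagation in the tests (agreement within 2%).
Binding free energy is reported in kT units as ln(K_d in molar). The
reference rate constants used across examples and validation
(k₁ = 0.3 µM⁻¹s⁻¹, k₋₁ = 92.7 s⁻¹, k₂ = 0.2 s⁻¹, k₋₂ = 6.0 s⁻¹) realize
K_d1 = 309 µM and K_eq = 30, hence K_d = 309·30/31 ≈ 299 µM, with a
fluorescence model (a = 1.0, b = 0.45, c = 0.25, bkg = 0.1) in which >80%
of the signal change occurs in the fast phase. An optional dead-time
truncation (default 5 ms) can be applied to traces before fitting.

## Validation experiments and problem sizes

`confland.validation` fixes the reference study conditions: a 3-macrostate
/ 12-microstate generator with timescales 80 and 15 steps, sampled as 200
trajectories × 5,000 steps in 10 seed groups (10⁶ frames; 10 sampling seeds
for the MSM experiment); 5× 50:50 group shuffle-splits for VAMP-2
discrimination against a deliberate 2-state lumping; 10⁵ frames for tICA
slow-direction recovery; 500 replicates of 25 × 200-step trajectories for
escape-interval coverage; and the 8-concentration stopped-flow design with
1% dynamic-range noise over 20 seeds for kinetics recovery. These sizes
make every experiment a genuine statistical test while completing in a few
minutes on one CPU; `scripts/acceptance.py` reruns all of them from a
single seed.

## Known limitations

- No Bayesian MSM uncertainty, transition-path theory beyond pairwise
  fluxes, or continuous-emission HMMs.
- No periodic-image correction beyond what the trajectory reader provides;
  synthetic fixtures are non-periodic.
- The out-of-sample VAMP-2 estimator and the commute-scaling constant are
  conventions (each isolated in one function); other choices exist in the
  literature.
- The reversible MLE convergence tolerance (1e-12) and k-means tolerance
  (1e-6) are this package's choices; results are insensitive to them at the
  tested sizes.
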