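# Methods

## Model and procedure

The package implements a semi-supervised clustering procedure for data
`X ∈ R^{m×n}` whose `n` columns (genes or samples) are assumed to lie near
a union of `c` low-dimensional linear subspaces, with a small labeled
subset whose classes are trusted.  Four components interact:

1. a **low-rank self-representation** `X ≈ XZ + E` whose coefficient
   matrix `Z` yields the affinity graph;
2. **harmonic-function label propagation** on that graph, generalized with
   per-item label confidences;
3. a **density-peak pointer tree** that schedules the order in which
   unlabeled items are pseudo-labeled; and
4. a **gravitational-search optimizer** that assigns each batch of new
   pseudo-labels a confidence vector by minimizing the propagation
   objective.

The loop: solve the representation once, propagate, pseudo-label the next
wave with the current predictions, optimize that wave's confidences, fold
the wave into the labeled set, re-propagate, repeat until no unlabeled
items remain (or, in evaluation settings, until accuracy stops improving,
in which case leftover items take labels from the final prediction
matrix).  Confidences are never revisited after their wave: initially
labeled items keep confidence 1 forever, and each wave's optimized vector
is frozen.

### Representation subproblem

The augmented-Lagrangian sweep alternates:

* `Z`: one linearized proximal step
  `Z ← svt(Z − ∇q(Z)/(βη), 1/(βη))` with majorization constant
  `η = ‖X‖₂² + 1`, where `q` is the quadratic part of the Lagrangian and
  `svt` the exact nuclear-norm proximal map.  One step per sweep (standard
  linearized-ADMM practice) suffices because the multipliers change every
  sweep anyway; the subproblem objective provably never increases.
* `E`: elementwise soft threshold at `1/β` of the residual
  `X − XZ + Λ₁/β`.  The noise term enters the objective with unit weight;
  the `λ₁` balance parameter is carried in the configuration for
  completeness but does not appear in the update equations.
* `H`: elementwise soft threshold at `λ₂·d_ij/β` — the proximal map of the
  distance-weighted sparsity `λ₂ Σ d_ij |H_ij|`.  Near pairs are barely
  shrunk, far pairs strongly, which is what makes the affinity local.  A
  raw linear-term reading of the penalty (no absolute value) is available
  via `h_penalty="linear"`.
* multipliers `Λ₁, Λ₂` by exact gradient ascent; `β ← min(β_max, ρβ)`.

**Self-representation is excluded** (`zero_diagonal=True`, enforced through
the separable `H` step so `diag(Z) → 0`).  This is a deliberate design
choice, not cosmetic: with dense additive noise the unconstrained problem
is minimized by the trivial `Z ≈ I` — each noisy column is the only exact
representation of itself, and the nuclear-norm cost `n` of the identity
undercuts the ℓ1 cost of routing the noise through `E` — which carries no
cluster information at all (measured off-block affinity mass 0.54 and
end-to-end accuracy ≈ 0.40 on the default noisy fixture, versus 0.06 and
≈ 0.98 with the diagonal excluded).  Excluding the diagonal is the same
remedy sparse-subspace clustering uses for the same degeneracy.  The
unconstrained form remains available via `zero_diagonal=False`.

The stop test is relative Frobenius change of `Z` below `ξ = 10⁻⁵`, read as
the *continue-while-above* condition, with a 500-sweep guard that returns
the current iterate with a warning.  On the default problem sizes the
affinity's block structure is in place well before the guard; full
`ξ`-convergence takes ≈ 800 sweeps and changes the affinity negligibly.

The affinity is `W = (|Z| + |Z|ᵀ)/2`.  Taking absolute values first keeps
Laplacian weights non-negative, which the propagation objective needs to be
a valid smoothness penalty (the signed average is available via
`literal_eq2` for inspection, not for propagation).  The diagonal of `W`
is ignored when building `L = D − W`.

### Propagation

`F = (L + U)⁻¹ U (μ∘Y)` is computed by Cholesky factorization of the
positive-definite `L + U`, never an explicit inverse.  `λ_∞ = 10⁵` is kept
finite and the system solved as written; the conditioning (≈ λ_∞ / typical
degree) is well within double precision.  Isolated unlabeled items — rows
that do not enter the objective — get zero prediction rows; a connected
component of two or more items containing no labeled item makes the system
singular and raises an error naming the members.  Predictions are the
per-row argmax, ties to the lowest class index; labels of labeled items are
never re-assigned from `F`.

### Selection schedule

`d_c` is the value at the ascending 2%-position of the `n(n−1)/2` unordered
pair distances.  `ρ_i` counts strict `d_ij < d_c` neighbors, self excluded
(the printed counting rule would otherwise always count the item itself).
Density ties are broken by item index — the lower index counts as denser —
so "nearest strictly denser neighbor" is well defined, the pointer graph is
a tree rooted at the unique tie-broken density maximum, and wave assignment
terminates.  Waves climb the tree from the labeled set along "next"
pointers; when no reachable unlabeled items remain, waves descend along
"previous" pointers from everything selected so far.  A literal transcript
of the published step numbering can skip an order value when a climbing
wave is empty; orders here are consecutive integers, which preserves the
partition property and is what the wave loop iterates over.

### Confidence optimization

Fitness of a candidate confidence vector = the propagation objective with
that vector substituted into the wave's rows of `μ` and `F` re-solved under
it (without re-solving, fitness would not depend on the candidate and the
optimization would be vacuous).  Because `F` is linear in the confidences
once `L + U` is factorized, the fitness is an exact quadratic form in the
`I` wave confidences; the optimizer precomputes `(Q, b, c)` from
`1 + 2I + I(I−1)/2` direct evaluations and evaluates particles in `O(I²)`.
A unit test pins the quadratic route to the direct solve at 1e-8.

The swarm: `N = 50` particles in `(0,1]^I`, velocities start at zero,
`G(t) = G0·e^{−αt/T}` with `G0 = 100`, `α = 20`, `T = 100`.  Masses come
from min-oriented normalization (best = minimum fitness); the all-equal
degenerate case falls back to uniform masses with a warning.  The
zero-mass (worst) particle's acceleration is defined as 0 — it moves by
inertia alone.  Random force weights are drawn per pair and dimension,
velocity inertia weights per particle, all from one seeded stream.
Positions are clamped to `[10⁻⁶, 1]` (confidence 0 is outside the model).
The returned vector is the best position ever visited (elitist recording;
`literal_final_population` restores the final-population minimum).  With
one particle the optimizer degenerates gracefully to its initial position.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `lambda2` | 1 | weight of the distance penalty in the representation |
| `lambda_inf` | 1e5 | label-fit weight on labeled rows (soft clamp) |
| `beta0, beta_max, rho_admm` | 1, 1e4, 1.01 | penalty schedule of the solver |
| `xi` | 1e-5 | relative-change stop tolerance of the solver |
| `dc_fraction` | 0.02 | quantile defining the density cut-off `d_c` |
| `gsa_N, gsa_T` | 50, 100 | swarm size and steps per wave |
| `gsa_G0, gsa_alpha` | 100, 20 | gravitational-constant schedule |
| `epsilon` | 2.2204e-16 | zero-denominator guard in the force law |
| `labeled_fraction` | 0.10 | initially labeled share in experiments |

All values are validated on load; experiments derive every random draw
from one seed per run.

## Synthetic data

`make_subspace_data` draws `c` orthonormal bases (consecutive blocks of a
random orthogonal frame when `orthogonal=True`, guaranteeing the mutual
orthogonality under which low-rank representation provably block-
diagonalizes), standard-normal coefficients, and i.i.d. Gaussian ambient
noise; cluster sizes are balanced.  Defaults (`n=205, m=80, c=4, d=5,
σ=0.05`) match the dimensions of a classic yeast galactose-pathway
compendium so experiments run at a realistic size, with a noise level small
relative to the unit-scale signal (columns have norm ≈ √d).  The generator
makes no attempt to mimic count distributions, heteroscedasticity, dropout
or batch structure of real expression data — passing tests demonstrate
correct mechanics and subspace recovery under the model's own assumptions,
not performance on any real compendium.  `make_nonspherical_2d` supplies
two-moons and chain shapes for density-schedule tests, and
`plant_mislabels` corrupts chosen labels for robustness experiments.

## Numerical choices and degenerate inputs

* `svt` uses full SVD (problem sizes are modest); `τ = 0` is allowed.
* Relative change with a zero previous iterate counts as converged only if
  the step is also zero.
* All-zero pairwise distances give `d_c = 0` with a warning; all-zero
  prediction rows warn and fall to class 1.
* `split_labeled` rounds half away from zero (10% of 205 → 21) and warns
  when a class receives no labeled item.
* "Accuracy no longer increases" stops on ties (`current ≤ previous`),
  needs ground truth (it is an evaluation-mode rule; exhausting the
  unlabeled pool is the default), and is never checked before one wave has
  run.  A `max_waves` guard (default `n`) bounds the loop.
* ACC pads the contingency table to square before the Hungarian
  assignment, so mismatched class alphabets are handled; NMI returns 0
  when both entropies vanish.

## Known limitations

* The representation solver is `O(n²)`–`O(n³)` per sweep in memory and
  time; thousands of items are fine, tens of thousands are not.
* The distance penalty uses raw Euclidean distances; no scaling or feature
  normalization is applied by default, so features on wildly different
  scales should be normalized upstream.
* Wrong labels among the *initially* labeled items are outside the model's
  defenses: their confidence is fixed at 1 by construction, and only
  pseudo-labels created during self-training are down-weighted.
* The plateau stopping rule requires ground truth and is therefore only
  meaningful in benchmark settings.
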