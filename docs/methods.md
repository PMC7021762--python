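# Methods

## Model

`netfrail` treats a connected, undirected, unweighted network as the support
of a continuous-time random walk ("information flow"): `dp/dt + Lp = 0`
with `L = I − Π` and `Π` the column-normalized adjacency matrix
(`π_kj = A_kj / deg(j)`).  The stationary state is the degree law
`(p_s)_k = deg(k) / 2|E|`.  Because the walk is reversible, `L` is
self-adjoint under the scalar product `⟨u, w⟩ = Σ_k u_k w_k / (p_s)_k`; the
implementation verifies this detailed-balance symmetry at construction and
solves the eigenproblem through the symmetrizing similarity
`B = G^{1/2} L G^{-1/2}` (a symmetric matrix handed to a dense symmetric
eigensolver), which guarantees a real ascending spectrum and a basis that is
G-orthonormal even inside degenerate eigenspaces.  The zero mode is stored
as `p_s` itself; conveniently `⟨p_s, p_s⟩_G = Σ p_s = 1`, so it is already
G-normalized.  All results are invariant under rotations of a degenerate
eigenspace (asserted by a test that rotates the flat block of the complete
graph by a random orthogonal matrix).

The metric is the canonical reversible-chain choice `G = diag(1/p_s)`; the
environment slot of the extended metric is fixed to `g₀₀ = 1`.  The
iterative scheme never projects on the environment row, so solver results
are provably independent of `g₀₀` (tested at 0.5/1/2); the frailness norm
is defined at `g₀₀ = 1`.

## Perturbation

A query set `S` (`|S| = Q`) is coupled to one environment node with
symmetric exchange rates and compensating diagonal terms, giving the
manifestly Laplacian rank-`Q` form

```
ΔL = r · Σ_{k∈S} (e₀ − e_k)(e₀ − e_k)ᵀ .
```

Two conventions tie the per-node rate `r` to the intensity `ε`:

* **per_node** (package default): `r = ε`.  The projected perturbation is a
  Gram form that grows monotonically with `S` in the positive-semidefinite
  order.  Three structural claims then hold *exactly*: frailness never
  decreases when a query node is added; no configuration destabilizes the
  walk below the Fiedler number `λ_F`; and the all-node query saturates the
  bound, `μ(V) = λ_F`.
* **shared**: `r = ε/Q`, so that at `ε = 1` the environment column of the
  perturbed transition matrix is stochastic.  Useful for fixed-budget
  comparisons, but the monotonicity and `λ_F`-bound guarantees then hold
  only up to the dilution factor `Q/(Q+1)` and fail on generic fixtures —
  which is why it is not the default.

## Solving the perturbed stationary problem

Three routes, deliberately redundant:

1. **Perturbative scheme.** With the ansatz `p* = p̂ + α p_s + e₀`,
   `p̂ = Σ_{k>1} c_k v_k`, the coefficients iterate
   `λ_k c_{n,k} = −Σ_j c_{n−1,j} ΔL̄_kj − α_{n−1} ΔL̄_k1 − ΔL̄_k0` with
   `p̂₀ = 0, α₀ = 1`.  For the zero-mode update two readings exist; the one
   derived from projecting stationarity on `(0, p_s)` (both terms divided by
   `ΔL̄₁₁`) reproduces the direct kernel solution and is the default
   (`variant="eq5b_consistent"`); the variant that divides the constant term
   by `ΔL̄₀₀` instead is kept behind `variant="eq7b_literal"` and
   demonstrably converges to a non-stationary point on heterogeneous
   networks.  Defaults: `tol = 1e−10` on the step difference, `max_iter =
   10⁴`, divergence bound `1e6`.
2. **Direct kernel oracle.** `L₀ + ΔL_ε` is itself the Laplacian of a
   connected walk for `ε > 0`, so its kernel is one-dimensional and
   positive; `scipy`'s SVD-based null space provides the stationary state
   against which the scheme is validated to `1e−6` (∞-norm) over random
   networks, query sets and intensities.
3. **Bisection.** The critical intensity `μ̂` is located by bisecting the
   scheme's converge/diverge dichotomy on `[λ_F/10, 10λ_F]` (doubling the
   upper end, capped at `2¹⁰ λ_F`, and returning `+∞` when no divergence
   exists — e.g. any single-node query), to interval tolerance
   `1e−6 · λ_F`.

Two numerical subtleties in the dichotomy. The iteration is an affine map
whose matrix is `−Λ⁻¹ΔL′` on the non-zero modes; its fixed point can be
reached in a handful of steps even when unstable, because on symmetric
fixtures (any regular graph) the forcing is exactly orthogonal to the
expanding modes.  `iterate_scheme` therefore (i) injects a one-off
deterministic kick of relative size `1e−8` after the first step — the fixed
point of an affine map is unchanged; only stability is probed — and (ii)
after first reaching `tol` keeps iterating for a probation window (500
steps), declaring convergence only if the step difference does not regrow
a hundredfold from its floor.  Runs that exhaust `max_iter` unresolved are
classified by their last contraction ratio.

## Frailness

The transformed perturbation `ΔL′_kj = ΔL̄_kj − (ΔL̄_k1/ΔL̄₁₁) ΔL̄_1j`
eliminates the zero mode; row and column 1 vanish identically, and for
`Q = 1` the whole matrix vanishes (`ΔL̄` is a rank-one bilinear form), which
the implementation returns as an exact zero.

The frailness is `ρ = ‖ΔL′_ε‖ / λ_F` with, by default, the spectral norm of
the full extended matrix.  The norm choice deserves care, and the package
exposes three variants because they answer different questions:

* `spectral` (default) — the operator norm of the full `ΔL′`, environment
  row/column included.  It is zero iff `Q ≤ 1`, linear in `ε`, monotone
  under query-set growth (exhaustively tested), and dominated by the metric
  weight `1/p_s = 2|E|/deg` of the query nodes — so configurations pairing a
  hub with a *marginal* (degree-1) node score highest.  This is the variant
  whose ranking drives all cohort analyses.
* `operator` — the spectral radius of `Λ⁻¹ΔL′` on the non-zero modes: the
  *exact* stability radius of the scheme.  The scheme converges iff
  `ρ_op < 1`, bisection agrees with `μ_op = ε/ρ_op` to solver precision on
  every fixture, and `λ_F ≤ μ_op` with equality at full coverage.
* `frobenius` — a sensitivity variant.

The two leading variants coincide exactly on flat-spectrum networks
(complete graphs), where the convergence condition in terms of the plain
norm is sharp.  On heterogeneous networks the spectral form upper-bounds
the operator form, so its analytic threshold `ε/ρ` is a conservative
(sufficient-convergence) intensity.  A further structural fact fixes the
"full matrix" choice: restricted to the self-adjoint network block, `ΔL̄`
is `ε ×` an orthogonal projector (the G-weighted query indicators are
orthonormal), so the block's Schur complement has top eigenvalue exactly
`ε` for every `Q ≥ 2` — a norm confined to that block would be constant and
carry no information.  All discrimination between configurations lives in
the environment coupling row/column retained by the default.

## Stationary currents

`J_ik = π*_ik p*_k − π*_ki p*_i` at the perturbed stationary state, with
total intensity `I = Σ_{ik} |J_ik|`.  The *exact* stationary `I(ε)` is
smooth and monotone through `μ` — and identically zero on regular graphs,
where the perturbed operator is symmetric and detailed balance never breaks.
The macroscopic transition at `μ` appears in the state the *scheme* reaches
within a fixed iteration budget (default 1000): below `μ` that state is the
stationary one, above `μ` it is dominated by the growing mode, and `I`
steps up by many orders of magnitude across the threshold.  `intensity_scan`
therefore evaluates the scheme-budget state and flags the first interior
peak of `dI/dε` (ignoring slope wiggles below a tenth of the scan's
steepest slope); the flagged grid point brackets `μ` to within one grid
step.  `stationary_currents` (single `ε`) always uses the exact kernel
state.

## Cohort analysis

Pathway gene sets are induced on the PPI; the largest connected component is
kept when its size is within [10, 500]; name patterns (e.g. disease
pathways) can be excluded.  Per sample, the query set is the intersection of
its mutated genes with the subnetwork; `ρ` is computed for `|S| ≥ 2`, single
hits are recorded as structurally null, empty intersections dropped.  The
pair table averages `ρ` over all samples in which a gene pair is co-mutated
(samples with additional mutations included).  The Gene Frailness Index per
gene: `m*` counts samples where the gene is co-mutated with ≥ 1 other
network gene, `σ = m*/n_samples` with `n_samples` the full cohort size
(configurable to the per-network count), `ρ̃` is the median over the
non-null samples carrying the gene (a flag re-admits null samples), and
`ρ′ = ρ̃ / max ρ̃` normalizes per network so the index is comparable across
networks.

The marginal-mutation enrichment test: population = samples with non-null
frailness on the network (minimum 20, else skipped); success = the query set
contains a gene of degree exactly 1 in the subnetwork (threshold
configurable); draw = the 10 highest-`ρ` samples, ties broken by sample
label for determinism; upper-tail hypergeometric `P(X ≥ x)`.

**Calibration.** An iid mutation cohort is *not* a null for this test: the
frailness measure structurally ranks marginal-mutation carriers high, so the
test rejects often (≈ 0.7 at our fixture scale) — that is the detected
effect, not a false-positive rate.  Calibration is therefore assessed under
a permutation null (frailness shuffled across informative samples), where
the realized rejection rate at nominal 0.05 is ≈ 0.01–0.04: the discrete
hypergeometric's attainable levels near 0.05 are sparse at `N ≈ 50–90`,
`n = 10`, so the exact test is conservative.  The test suite compares the
realized rate against the *exact* expected null rejection rate computed
from each replicate's `(N, K, n)` table, and additionally asserts the rate
never exceeds the nominal level.

## Synthetic data

The generators define the study conditions; they are ordinary, tested code.

* Networks: complete graphs (the 20-node complete network is the standard
  solver fixture); connected Erdős–Rényi draws (retrying with incremented
  seed); preferential-attachment graphs (`m = 1` gives trees rich in
  marginal genes); and a "PPI-like" family — a Barabási–Albert core with a
  controlled minority of degree-1 genes attached to degree-weighted core
  nodes, mimicking interactomes where growth-factor-like leaves hang off
  hubs.
* Mutation cohorts: genes-by-samples Bernoulli draws with a long-tailed
  frequency law — two driver-like genes at 35% and 25% (the frequencies of
  the two dominant breast-cancer drivers) and a `rank^−1.5` tail rescaled to
  a 2% mean (a typical per-gene background rate; trend fixtures use 6% so
  that the co-mutation bins `m* = 1..5` are all populated at 400 samples).
  The planted effect adds, in 20% of samples, the top driver plus one random
  marginal gene — the co-occurrence pattern the enrichment analysis is
  designed to flag, and a known positive control.

What the generator does *not* emulate: mutational signatures, copy-number
events, gene-length effects, inter-gene mutation correlations beyond the
planted pattern, and identifier-harmonization noise.  Passing tests
demonstrate the internal consistency and calibration of the machinery on
data with the right marginal statistics, not biological validity on real
cohorts.

## Problem sizes and defaults

Dense linear algebra throughout (networks here are ≤ a few hundred nodes;
the eigendecomposition is computed once per network and reused across
samples).  Defaults: `ε = 1` for comparable scores across query sets;
kernel/zero-eigenvalue tolerance `1e−10`; detailed-balance symmetry
tolerance `1e−8`; scheme tolerance `1e−10` with `10⁴` iterations; bisection
tolerance `1e−6 λ_F`; pathway size bounds 10–500; enrichment `top_n = 10`,
`min_patients = 20`, marginal degree 1.  Test-suite and acceptance-script
simulations use networks of 8–32 nodes and cohorts of 150–400 samples with
300–500 calibration replicates — sizes at which every stochastic check is
stable across seeds.

## Known limitations

* Directed or weighted networks are rejected; the detailed-balance structure
  the whole spectral machinery rests on is specific to reversible walks.
* The analytic threshold from the default (spectral) frailness is
  conservative off the flat-spectrum regime; use `norm="operator"` when the
  exact stability boundary is needed.
* Gene-identifier harmonization is exact string matching; no ID-mapping
  service is bundled.
* Raw enrichment p-values are reported per network; no multiple-testing
  correction across networks is applied.
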