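# Methods

## Model and assumptions

The Golgi is an array of `NC` well-mixed cisternae. Glycoprotein carriers are
injected into cisterna 1 at rate `q` (fixed to 1; it is a pure scale since
every displayed distribution is normalized by `q`) as glycan index `k = 1`,
and glycosylation advances the index along a line graph `k → k+1`,
`k = 1..Ns−1`. The model is mean-field: no finite-copy-number noise, no
competition effects beyond Michaelis–Menten saturation, and no tree- or
DAG-structured reaction networks. Index `Ns` is absorbing within a cisterna
(no reaction out of the last species), and material leaves cisterna `j` for
`j+1` (or, from `j = NC`, for the plasma membrane) at rate `μ⁽ʲ⁾`.

Enzyme–substrate binding follows a shape-mismatch model: substrate `k` has
shape `ℓ_k = k` exactly, enzymes have continuous shapes `ℓ_α⁽ʲ⁾ ∈ [1, Ns]`,
and the binding probability is `exp(−σ|k − ℓ_α⁽ʲ⁾|)` with a single scalar
specificity `σ ≥ 0` shared by all enzymes (the absolute-value mismatch
metric). An optional per-enzyme, per-cisterna 0/1 activity mask restricts
enzymes to subsets of cisternae, breaking the approximate NE–NC symmetry of
the unrestricted model.

Two kinetic closures:

* **Linear effective rates.** Reaction flux `φ(j,k) = R_eff(j,k)·c_k⁽ʲ⁾` with
  `R_eff(j,k) = Σ_α activity·R_α⁽ʲ⁾·P⁽ʲ⁾(k,α)`. The per-cisterna balance
  equations form a lower-bidiagonal linear system solved exactly by forward
  substitution (`scipy.linalg.solve_banded`), cisterna by cisterna. This
  parametrization is the contract used by the optimizer: the flux is first
  order in the substrate concentration with a k-independent capacity
  `R_α⁽ʲ⁾` per enzyme.
* **Michaelis–Menten.** Flux `k → k+1` in cisterna `j` is
  `Σ_α V(j,α)P(k,α)c_k / [M(j,α)(1 + Σ_k' P(k',α)c_{k'}/M(j,α))]` — the
  saturation factor couples all substrates competing for one enzyme. Because
  the flux is linear in `c` once the per-enzyme saturation factors are
  frozen, the solver iterates: freeze saturations, solve the bidiagonal
  system, damp (factor 0.5), repeat until the balance residual falls below
  10⁻¹⁰·q (at most 10⁵ sweeps), falling back to stiff ODE integration
  (LSODA) on failure. In the dilute limit (`M → ∞`, `V/M → R`) this reduces
  to the linear closure; the equivalence of optimizing either
  parametrization is verified numerically on a small instance rather than
  algebraically.

Binding probabilities are computed as `exp` of a log clipped at −690 so they
never underflow to exact zero. Flux conservation
`Σ_k μ⁽ᴺᶜ⁾c_k⁽ᴺᶜ⁾ = q` holds to ~10⁻¹⁶ for the linear solver (it is exact
algebra) and to the residual tolerance for the MM solver.

## Objectives

Fidelity is `F = D(c*‖c̄)/H(c*)` in nats; the entropy normalization makes
targets of different complexity comparable. Displayed probabilities are
floored at 10⁻¹² and renormalized before the KL — with finite σ every
species has positive probability in exact arithmetic, so the floor only
guards underflow; it also means a target peak placed where the machinery
puts (numerically) no mass costs a large but finite ~`p·ln(p/10⁻¹²)`.
Delta (zero-entropy) targets are refused by `fidelity` with instructions to
use the raw KL. Diversity is `Σ_i (1+exp(−Ns(c_i−c_th)))⁻¹` with sharpness
`1/τ = Ns` and default threshold `c_th = 1/Ns`; it is a differentiable
species-above-threshold count, bounded by `Ns`, and a uniform profile sits
exactly at `Ns/2`.

## Optimization

Each fit is a seeded multi-start of SLSQP on box-normalized coordinates in
`[0,1]`: `μ` and `R` are log-interpolated between their bounds (the boxes
span 2–3 decades), `L` linearly between 1 and `Ns`. Defaults: 32 starts
drawn uniformly in the normalized box (log-uniform in physical rates),
`maxiter` 200, `ftol` 10⁻⁹, forward-difference step 10⁻⁶. σ is scanned on a
grid rather than optimized jointly, with argmin ties broken toward the
smallest σ; the landscape analysis re-includes σ as a coordinate. A start
counts as "near best" when its final value is within
`max(0.01, 5%·best)` of the best start — the reported
`fraction_near_best` is a cheap degeneracy indicator. Failed steady-state
evaluations inside a line search return a large finite penalty (10⁶) so the
optimizer backs off instead of crashing.

The fidelity landscape has genuinely flat plateaus: when transit depth
(`~Σ_j R_eff/μ⁽ʲ⁾`) is far too small to reach the target's support, every
target index sits at the KL floor and the gradient vanishes. Multi-start
sampling in the log-box handles this at desk scale; scans that compare
configurations therefore use the same number of starts per grid point.

For the MM-side optimization (`check_ab_equivalence`) the coordinates are
`(μ, M, V, L)` with `M ∈ [1, 10⁶]` and `V ∈ [10⁻², 2×10⁷]` log-scaled, wide
enough that the dilute limit embeds the whole linear feasible box.

## Complexity

A profile's complexity is called from the curve `m ↦ D(p‖GMM_m)`: Gaussian
mixtures on the index grid fitted by weighted EM directly on the support
points (weights = abundances), which is deterministic given a seed and
minimizes the divergence actually plotted (up to discretization of the
mixture onto the grid). Initialization is quantile-spaced means with
per-restart jitter, equal weights, `sd = range/(2m)`, 10 restarts by
default; component sds are floored at 0.5 index units to prevent collapse
onto single grid points (a delta profile therefore retains a constant
discretization residue of ≈0.24 nats — the curve is flat from `m = 1`, which
is what the saturation call keys on). The curve is made nonincreasing by
construction: each `m` considers fresh fits, a split of the previous
solution's heaviest component, a narrow component inserted at the largest
pointwise KL excess (the signature of a missed peak), and an un-refined
padded copy of the previous solution.

The mixture optionally (and by default) includes one uniform background
component whose weight is fitted by the same EM. Raw spectra carry a
uniform chemical-noise floor that no finite Gaussian mixture can absorb;
without the background term the KL floor charges that baseline as one extra
spurious broad component and shifts every call upward. On noise-free
profiles the background weight collapses toward zero. `background=False`
recovers the pure mixture, for which the single-component fit equals the
weighted moment estimator exactly.

Saturation rule: `m*` is the smallest `m` with
`curve[m] − curve[m+w] < tol·curve[1]` for all `w = 1..window`
(`tol = 0.01`, `window = 2`). The rule is this package's operational
definition — saturation is otherwise only a qualitative notion — and
`m_max` is returned with a flag when no saturation occurs.

## Landscape geometry

The Hessian of `F` at an optimum is computed by central finite differences
(step 10⁻³) on the full box-normalized coordinate vector
`(μ, R, L, σ)` of dimension `NC + 2·NE·NC + 1`, with the stencil center
shifted inward where the optimum touches the box (one-sided differencing at
boundaries), then symmetrized and eigen-decomposed. Box normalization makes
curvatures comparable across blocks whose physical units span different
decades; σ is normalized over `[0, 10]` by default. Each eigenvector is
labelled by the block of its largest-magnitude component (ties broken in
the order μ, R, L, σ); per-block stiffness is `ln(mean λ)` over the block's
eigenvalues with negatives clipped at zero and a floor of 10⁻¹²
(numerical noise at a genuine minimum). At desk scale ((3,3), Ns = 100) σ
is reliably the single stiffest direction and the R block the sloppiest on
average, though individual R directions scatter across the spectrum rather
than all collecting in the sloppiest third.

Degeneracy probing clusters the near-best multi-start endpoints by
single-linkage at radius 0.05 in normalized coordinates (discrete
degeneracies, e.g. enzyme-relabeling permutations) and counts Hessian
eigenvalues below 10⁻⁶ of the largest as continuous flat directions.

## Synthetic data

The generators define the study conditions; all are pure functions of
(spec, seed).

* `random_mixture_spec(m, Ns=200)` emulates coarse-grained MSMS targets:
  quantile-spaced means with 15% jitter, Dirichlet(1) weights, and sds drawn
  from [2, 6] index units *at the 20-component spacing* (10 indices at
  Ns = 200) and scaled proportionally with the actual spacing — so
  few-component stand-ins have wide peaks and many-component stand-ins
  narrow ones, the two benchmark regimes. The wide/narrow distinction is
  what the σ_min-ordering results rest on.
* `separated_mixture_spec` is the round-trip variant: narrow sds (1.5–2.5)
  independent of m, means kept clear of the grid boundary (a wide component
  near the boundary is truncated by discretization and is then no longer an
  exact mixture), and Dirichlet(5) weights so every component carries
  visible mass — a component of weight ≲0.002 is statistically invisible in
  the KL curve and unrecoverable in principle.
* `make_msms_like` models counting statistics:
  `counts ~ Poisson(N·[(1−b)·target + b/Ns])` with total intensity `N` and
  chemical-noise baseline fraction `b` (defaults in tests: `N = 10⁵`,
  `b = 0.02`). It does not model isotope envelopes, adducts, or m/z
  calibration; passing round trips show robustness to counting noise and a
  uniform baseline, not to structured spectral artifacts.
* `make_recovery_fixture` draws in-bounds parameters (log-uniform rates) and
  returns them with their own displayed distribution, so the optimizer's
  target is attainable with `F = 0` by construction.

## Problem sizes and numerical choices

Analyses default to desk scale — `Ns = 200` for 20-peak targets, `Ns ≤ 100`
elsewhere, 4–32 starts — chosen so the full pipeline runs on one CPU in
minutes; the realistic `Ns = 2×10⁴` is supported but not default. Parameter
boxes default to `μ ∈ [0.01, 1]/min` and `R ∈ [0.018, 20]/min`. With ~10⁶
total ion counts a normalized noisy spectrum is within total variation 0.01
of its generating distribution, which sets the scale for what "recovering"
a target means under realistic counting noise.

## Known limitations

* Optimization is local multi-start; no global guarantees. Comparisons
  between configurations carry multi-start noise, handled with explicit
  tolerances (5–10%) in tests.
* The A/B (linear vs MM) equivalence is demonstrated numerically on small
  instances, not proved symbolically here.
* The complexity call depends on the (tol, window) saturation rule; very
  unequal component weights or overlapping peaks lower the recoverable m.
* Hessian group labels use the dominant-component rule; strongly mixed
  eigenvectors (e.g. R–μ mixing along continuous degeneracies) are assigned
  to a single block.
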