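# Methods

## Model

A scalar response is a sum of Hilbert-space inner products of functional
predictors with unknown coefficient functions, Y = Σ_{j∈J} ⟨Xʲ, βʲ⟩ + ε,
where only an unknown subset J of the p predictors is active.  Estimation
and selection happen jointly through a groupwise penalty in which each
predictor's entire coefficient function is one group:

F(β) = ½ E_n (Y − ⟨X, β⟩)² + λ(1−α) Σ‖βʲ‖ + αλ Σ‖βʲ‖² + (λ_der/2) Σ‖(βʲ)″‖².

The first penalty term uses the (non-squared) L² norm of each block, which
produces exact zeros; the squared term (α > 0) adds strong convexity, hence
uniqueness and a more stable path; the curvature term penalizes
∫ (βʲ)″(t)² dt and controls the roughness of the fitted coefficient
functions.

All computation is in basis coordinates.  Each H_j is spanned by m_j basis
functions with Gram matrix G_j (entries ∫ b_i b_k) and second-derivative
Gram matrix B_j″ (entries ∫ b_i″ b_k″), both computed by fixed-order
Gauss–Legendre quadrature: 10 nodes per inter-knot interval for B-splines
(exact for the polynomial integrands) and 10 nodes per 1/(4m) subinterval
for Fourier systems.  Observed curves are converted to coordinates by
unpenalized per-curve least squares on each curve's own time grid, so
unbalanced designs are supported and roughness is controlled only in the
regression objective, not at projection time.  Centering subtracts the
per-coordinate and response means and stores them for prediction.

## Solvers

**ADMM.**  Per predictor, the empirical covariance is eigendecomposed via
the symmetric matrix n⁻¹ G_j^{1/2} X̃_j X̃_jᵀ G_j^{1/2}; its eigenvectors
define an orthonormal (Karhunen–Loève) basis in which ⟨f, g⟩ is the plain
dot product.  In those coordinates the ADMM splitting alternates a linear
solve (the system matrix Z Zᵀ + nρ I + λ_der G″ is Cholesky-factorized once
per (ρ, λ_der) and reused across iterations and the whole λ grid), a
closed-form group soft-threshold with Elastic-Net shrinkage
ρ/(ρ+2αλ) · S_{λ(1−α)/ρ}, and a scaled-dual update.  ρ = 1 is fixed; the
stopping rule is the standard combined absolute/relative primal–dual
residual criterion (tol_abs = 1e-6, tol_rel = 1e-4, max 10000 iterations;
non-convergence is flagged, not raised).  The reported coefficient is the
duplicate variable γ, which is exactly sparse.  Matrix square roots use a
symmetric eigendecomposition with an eigenvalue floor of 1e-12 times the
largest eigenvalue, and eigenvector signs follow a first-nonzero-positive
convention so results are platform-reproducible.  All m components are
retained: selection happens in the regression, not by truncating the
eigenbasis.

**GMD.**  The groupwise-majorization-descent solver works in the original
basis and minimizes the same objective without the 1/n factor on the loss.
The closed-form block update
βʲ ← (2αλ + γ_j)⁻¹ S_{λ(1−α)}(Uʲ + γ_j βʲ), with U = −∇L and γ_j slightly
above the largest eigenvalue of the j-th diagonal block of
H = Z Zᵀ + λ_der P, is exact when the group penalty is the Euclidean norm of
the block coordinates.  Because ‖βʲ‖_{H_j} = (bᵀ G_j b)^{1/2}, the solver
performs a per-block change of variables b̃ = G_j^{1/2} b once, after which
the penalty is exactly Euclidean, with transformed design Z = G^{1/2} X̃ and
curvature matrix P = G^{-1/2} B″ G^{-1/2}.  This makes the two solvers
minimize the same functional objective, which the tests exploit by requiring
objective agreement to 1e-4 against each other and against independent
convex-programming solutions.

The λ path starts at the KKT-derived λ_max = max_j ‖Uʲ(0)‖/(1−α) (top of a
100-point log-spaced grid down to a configurable fraction, default 1e-3) and
proceeds with warm starts.  At each step the sequential strong rule
‖Uʲ‖ > (2λ_{k+1} − λ_k)(1−α) selects candidate blocks; after convergence on
the candidates, a KKT sweep over the excluded blocks re-includes any
violator and the solve repeats until no violations remain, so the screened
path equals the unscreened path exactly.  Cyclic block order with
active-set sweeps (iterate over the currently nonzero blocks, then one full
sweep) gives determinism; convergence is declared when the maximum relative
block change drops below 1e-6 (at most 5000 sweeps).  Pure ridge (α = 1) is
a direct linear solve, not a GMD loop.

**Scale conventions.**  The model API takes λ and λ_der per sample (the E_n
scale) for both solvers and multiplies by the training size internally where
a solver's raw updates expect unnormalized weights.  Cross-validation folds
apply the same per-sample penalty regardless of fold size for the same
reason.  Certification: at every converged fit, active blocks satisfy
stationarity and inactive blocks satisfy ‖Uʲ‖ ≤ λ(1−α); a block exactly on
that boundary is optimal at zero, so the public `kkt_check` flags only
excesses beyond tolerance while the internal backstop re-includes boundary
blocks conservatively.

## Tuning

k-fold cross-validation (default k = 5, subject-level folds, deterministic
under a seed) searches a net over α and λ_der and, for each net point, a
data-driven λ grid built once from the full training data: for GMD from
λ_max downward; for ADMM log-spaced between 0.9 times the smallest and 1.1
times the largest block norm of the ridge estimate (raised, when necessary,
to 1.01 times the exact KKT threshold so the largest λ provably yields the
empty model).  The winning triple minimizes the mean validation MSE (no
one-standard-error rule), and the final model is refit on all data at that
triple.  In near-noiseless regimes the validation curve can decrease
monotonically down to the grid floor, in which case the floor acts as the
effective selector of model size; this is a known property of minimum-MSE
tuning for selection problems, and the default floor of 1e-3·λ_max is part
of the method's stated conditions rather than a quantity adapted per
dataset.  An optional outer loop over the number of basis functions is
available but off by default.

## Synthetic-data generator

The generator implements the benchmark design the package is validated against:
p = 19 predictor curves per subject, each a running cumulative sum of
i.i.d. N(0,1) increments over a 500-point grid on [0,1] (a discretized
Brownian motion whose variance grows linearly along the grid), and

Y = ⟨X¹, β¹⟩ + ⟨X², β²⟩ + ⟨X³, β³⟩ + σ ε,  ε ~ N(0,1),

with β¹(t) = sin(3πt/2), β²(t) = sin(5πt/2), β³(t) = t², inner products
computed by a 500-point Riemann sum before 400 grid points are dropped so
that the 100 retained observation times are equally spaced.  (The sine
arguments admit an alternative t² reading; `beta_arg="squared"` switches to
it, and the selection behavior is insensitive to the choice.)  Scenarios
vary n ∈ {100, 200, 500} and σ ∈ {0.01, 0.1, 1}; each replicate projects the
observed curves onto m = 21 cubic B-splines, splits subjects 80/20, tunes by
5-fold CV and scores the test RMSE plus per-predictor selection indicators
(3 active, 16 inactive), aggregated to percentages over replicates.  All
randomness derives from one scenario seed through named substreams (curves,
noise, split, folds), making reruns bit-identical.

What the generator does not emulate: measurement noise on the curves
themselves, between-predictor correlation, non-Gaussian increments, and any
smoothing at the curve-representation stage.  Because the curves are
projected by plain least squares, very little of the generated signal is
lost, and absolute prediction errors here are substantially smaller than
pipelines that smooth the predictors before regression; selection
percentages and the ordering of methods are the transferable quantities,
not absolute RMSE levels.  Passing the simulation tests therefore shows
correct selection behavior under this generative process, not performance
on any particular real dataset.

## Default study-scale choices

The scenario runner defaults are sized for a single CPU: 20 replicates per
scenario, a 40-point λ grid, λ_der net {0, 10⁻²}·s with
s = tr(Z Zᵀ)/(n·tr(P)) (a per-sample, data-driven scale matching the loss
Hessian to the curvature penalty), Elastic-Net α net {0.25, 0.75}, and
fold fits at tolerance 3e-5 capped at 300 sweeps (final refits use the
tighter defaults).  The full 100-replicate, nine-scenario table runs through
the same interface by raising `reps` and the nets.

## Numerical choices and degenerate inputs

Gram matrices are symmetrized and floored as described; a Gram matrix that
is not positive definite raises an error naming the predictor.  Projection
of a curve with fewer observation points than basis functions raises a
rank-deficiency error naming the curve.  λ grids are rejected as degenerate
when the response is orthogonal to all predictors.  Eigenvalue ties in the
KL step are broken by the stable eigensolver order with the sign convention
above.  The unpenalized ("OLS") baseline uses minimum-norm least squares
when the coordinate dimension exceeds the sample size, which is the p ≈ n
regime of the n = 100 scenarios; the oracle baseline is the same solve
restricted to the three truly active predictors.

## Known limitations

No inference (standard errors or p-values) on the coefficient functions is
provided.  Orthogonalization is strictly per predictor — cross-predictor
covariance is not diagonalized, and no multivariate functional PCA is
attempted.  Basis families are limited to B-splines, Fourier systems and
user-supplied callables; there is no data-driven basis.  The strong rule is
used only with the GMD solver; ADMM tunes each penalty configuration
independently instead.
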