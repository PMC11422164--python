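# Methods

## Model

For a phenotype vector `y` over N samples (cells, repeated measures) with a
continuous state `x_i ∈ R^Q` per sample (time, pseudotime, cell state) and a
biallelic genotype `g ∈ {0,1,2}^N`, the mapping model is

    y = α + β ⊙ g + γ + ε,
    α ~ N(0, K),   β ~ N(0, δ_g K),   γ ~ N(0, δ_d K ⊙ R),   ε ~ N(0, σ² I),

with `K = k(X, X)` a kernel matrix over the states, `R` the kinship between
samples and `⊙` the elementwise product. `α` is the shared baseline
trajectory, `β` the *dynamic* genetic effect (an effect size that is itself a
function of `x`), and `γ` the donor-specific trajectory deviation that
absorbs trans-genetic and repeated-measure confounding; omitting `γ` inflates
the test statistics (the calibration study reproduces this contrast). For
repeated samples from unrelated donors `R = Z Zᵀ` with `Z` the one-hot donor
indicator; a general kinship matrix is accommodated by a truncated
eigendecomposition `R ≈ Z Zᵀ` keeping ≥ 99.9% of eigenvalue mass.

The working kernel is the ARD squared exponential
`k(x_j, x_k) = σ_k² exp[−Σ_q (x_jq − x_kq)²/(2 ρ_q)]` with `ρ_q` acting as a
squared lengthscale (relevance 1/ρ_q per dimension). Designated periodic
dimensions (cell-cycle phase) use `exp[−sin²(Δ/2)/ρ]`, period 2π. The
static+dynamic composite `K* = σ_k² e^{−ρ₀} 1 1ᵀ + K` adds a
state-independent covariance share governed by `ρ₀`.

## Sparse bounds and low-rank algebra

All likelihoods go through the variational (Titsias) bound with M inducing
points `T`: with `Φ = K_NM L⁻ᵀ` (`L = chol(K_MM)`), the model covariances are

    V   = σ² I + Φ Φᵀ
    V_d = V + δ_d (Φ Φᵀ) ⊙ Z Zᵀ
    V_g = V_d + δ_g (GΦ)(GΦ)ᵀ,   G = diag(g)

and the bounds subtract trace penalties `tr(K̃)/2σ²`, `(1+δ_d)tr(K̃)/2σ²`,
`[(1+δ_d)tr(K̃)+δ_g tr(GK̃G)]/2σ²` respectively, where
`K̃ = K_NN − K_NM K_MM⁻¹ K_MN` (only its diagonal is ever formed). No N×N
matrix is materialized: the Hadamard donor term is the sum of disjoint
row-masked blocks `(D_dΦ)(D_dΦ)ᵀ`, so `V_d = D + U Uᵀ` with an *arrowhead*
inner Woodbury matrix — N_d + 1 blocks of size M with dense coupling only to
the first block — eliminated donor-by-donor in O(N_d M³ + N M²). The noise
`D` may be heteroscedastic (used by the Poisson path). The H2 covariance is
one more rank-M Woodbury layer on top of the V_d handle. A general (related
donor) `Z` falls back to a dense inner factorization.

Kernel matrices that are Cholesky-factorized receive relative diagonal
jitter on an escalation ladder 1e-8 → 1e-6 → 1e-4 (first rung that
factorizes); the small first rung keeps the T = X tightness of the bound at
~1e-8 relative.

## Three-step null estimation

Per phenotype (never per variant):

1. **H0** `y = α + ε`: maximize the bound jointly over {log σ_k², log ρ,
   log σ², T} by L-BFGS with analytic gradients (the kernel-variance
   gradient uses the fact that every kernel block scales linearly with it).
   Initialization: T by k-means on X, ρ_q at the per-dimension median
   squared pairwise distance; 3 restarts with jittered ρ by default, best
   bound kept.
2. **H1** `y = α + γ + ε`: with ρ̂, T̂ frozen, maximize over {log δ_d,
   log σ²} (numerically differentiated L-BFGS — two parameters).
3. **H2** is never refit: variants are tested against the H1 fit.

Phenotypes are rank inverse-normal transformed by default (Blom constant
0.375); a flag disables this.

## Score test and its null distribution

Per variant, `S = yᵀ V̂_d⁻¹ G Φ Φᵀ G V̂_d⁻¹ y = ‖Φᵀ(g ⊙ V̂_d⁻¹y)‖²`, with
`V̂_d⁻¹y` cached, costing O(NM + N_d M²) per variant. Its null law is the
generalized chi-squared `Σ_m λ_m χ²_{1,m}` with weights the nonnegative
eigenvalues of the M×M matrix `Φᵀ G V̂_d⁻¹ G Φ`; eigenvalues below
1e-10·λ_max are discarded as numerical zeros. The score statistic is the
covariance-derivative form exactly; no trace-derivative centering is added
(the weighted-χ² null absorbs the distribution), and the dense oracle in the
tests checks the covariance-derivative part.

Tail probabilities use a three-stage cascade, each stage validated against
closed forms and Monte Carlo:

- **Ruben series** (weight spread < 1e3): the tail as a mixture of central
  χ² tails with scale β = λ_min; coefficients are nonnegative and sum to 1,
  so the truncation error is bounded by the unassigned mixture mass
  (stopped at 1e-10, ≤ 4000 terms). Exact to ~1e-11 and exact in one term
  for equal weights.
- **Imhof inversion** (large spread): the oscillatory inversion integral by
  24-point Gauss–Legendre panels spanning one asymptotic period each, with
  Euler-type acceleration of the alternating panel series; absolute
  accuracy ~1e-9 at ~1–10 ms.
- **Kuonen saddlepoint** for p below 1e-9 (Lugannani–Rice form), where
  absolute-accuracy inversion is uninformative; results are flagged
  `saddlepoint`.

Benjamini–Hochberg FDR is reported per phenotype alongside raw p-values;
`qq_data` emits expected-vs-observed −log₁₀ p pairs for calibration plots.

## Bayes factors

`log BF = L2^{H2} − L2^{H1}` evaluated on the grid δ_g ∈ {0.01, 0.1, 0.5}
with all other parameters frozen; the reported value is the log of the
arithmetic mean of the grid BFs (log-sum-exp). A zero genotype gives
log BF = 0 identically.

## Static/dynamic decomposition

With the K* kernel, ρ₀ for the baseline is estimated in H0 and an
independent ρ₀ for the donor term in H1 (the γ trace penalty uses the γ
kernel's own K̃). Two testing modes:

- `fixed_static`: intercept and static effect β₀ are profiled out by
  generalized least squares under V̂_d (the GLS profiling construction is
  this package's); the score test then runs on the GLS residual with the
  dynamic (non-constant) kernel part in the β prior.
- `random_static`: β carries the full K* prior with the γ component's ρ₀
  (shared static-to-dynamic ratio); evidence is reported as a Bayes factor.

## GPLVM

For an expression matrix Y (N×J) the baseline model per gene, with covariate
random effects `W b_j`, `b_j ~ N(0, σ_j² Δ)`, integrates to the matrix-normal
bound

    log p(Y|X) ≥ log MN(Y | 0, Σ, I + Φ Φᵀ + W Δ Wᵀ) − (J/2) tr(K̃),

kernel variance pinned at 1, `Σ = diag(σ_j²)`, Δ one scalar per covariate
block (donor, batch). Latent coordinates carry iid standard-normal priors
(none on a periodic phase dimension). Gradients are analytic throughout
(including through the covariate term), with cost O(N(M+P)² + NJ(M+P)) per
evaluation and no N×N matrices.

The bound is multimodal in X; plain joint optimization collapses the
lengthscale before the latent ordering resolves ("clumping" onto inducing
points). The fitter therefore runs a lengthscale continuation — ρ frozen at
4.0 then 1.0 for 150 L-BFGS iterations each while {X, T, Σ, Δ} organize,
then everything released — from several initial configurations (PCA scores;
Isomap embeddings at neighborhood sizes 10 and 25, which resolve global
orderings that linear projections fold over; the periodic phase from the
angle of the first two PCs), keeping the solution with the best final
bound. Reported latent dimensions are standardized to zero mean and unit
variance (phase dimensions reduced modulo 2π); signs/rotations are not
identified, so downstream comparisons should use absolute or circular
correlations.

## Poisson counts

For counts, the Jensen bound
`L1 = Σ_i [−log y_i! + y_i f̄_i − exp(f̄_i + k̃_ii/2)]` yields GLM-style
weights `w_i = exp(f̄_i + k̃_ii/2)` and working responses
`ν_i = f̄_i + (y_i − w_i)/w_i`. The stationary inducing values solve
`(K_MM⁻¹ + CᵀWC) u = CᵀW(ν − offset)` — both sides depend on the iterate, so
the system is solved as a damped fixed point (step halved on objective
decrease, stopped when the stationarity gradient falls below 1e-9). The
iteration runs in whitened coordinates `u = L a` so the inner system is
`I + ΦᵀWΦ` and stays well conditioned even when `K_MM` is nearly singular. The linearization point includes the
donor random effect: `Ã = (C, D_1 C, …, D_{N_d} C)` with per-donor inducing
values `u_d ~ N(0, δ_d K_MM)`, i.e. a penalized quasi-likelihood expansion
around the full conditional mode. This matters: without the donor blocks
the working response carries an O(γ²) linearization error that does not
shrink with count depth, and — because the working model's noise is pinned
at W⁻¹ with no free residual variance — donor variance would otherwise
masquerade as a spurious tiny-lengthscale kernel fit. For the same reason
{σ_k², ρ, δ_d} are estimated jointly (numerically differentiated L-BFGS
with step 1e-4, since the inner solve makes tighter finite differences
noisy) on the working Gaussian bound `log N(ν − offset | 0, W⁻¹ + ΦΦᵀ +
δ_d(ΦΦᵀ)⊙ZZᵀ)`, with the fixed point re-solved (warm-started) at every
outer evaluation. Hyperparameters and T initialize from a Gaussian H0 fit
to centered log1p counts (the large-count limit). A constant offset (log
exposure) defaults to log ȳ; the working response is mean-centered for
testing, the same convention as the Gaussian phenotype. The score test then
substitutes y → ν and V̂_d → W⁻¹ + A B⁻¹ Aᵀ and proceeds unchanged. Binary
outcomes are out of scope.

## Synthetic data

The generator draws exactly from the model: dense-kernel draws for α, β and
per-donor γ (no inducing points), Binomial(2, maf) donor genotypes expanded
to cells, Gaussian or Poisson observation. Because the generator is dense
and exact, approximation error of the sparse inference path shows up as
estimation error in tests rather than being shared between generator and
fitter. It does not emulate LD between variants, ascertainment, library-size
variation or scRNA-seq dropout; passing tests therefore demonstrate
correctness of the inference machinery under the model, not robustness to
real-data artifacts.

Reference study conditions (fixed once): states `x ~ N(0,1)` per dimension,
ARD-SE kernel variance 1.0 with ρ = 0.3 for association studies, residual
σ² = 0.5, donor ratio δ_d = 0.3, 30 donors × 10 cells, maf ~ U(0.1, 0.5).
The latent-recovery study uses ρ = 1.0 — a smooth trajectory, which is the
regime where one-dimensional pseudotime is identifiable; at ρ = 0.3 (≈5
lengthscales of wiggle across the state range) orderings are fundamentally
multimodal and no optimizer can be expected to recover them reliably.

## Validation studies and problem sizes

`dyngp.validate` (used by the acceptance script and tests) runs: dense-oracle
equivalence on 20 random instances (N ≤ 20, M ≤ 5, N_d ≤ 4, rtol 1e-8);
bound dominance/tightness on 10 instances; χ² tail checks against closed
forms and a 10⁷-draw Monte Carlo; null calibration with 2000 tests at
N = 300, N_d = 30 spread over 40 phenotypes × 50 variants (λ_GC estimates
the procedure's calibration rather than one phenotype's realized dispersion)
with M = 20 so the Nyström remainder is negligible, plus the same tests with
the donor term removed; power over δ_g ∈ {0, 0.1, 0.5} with 200 replicates
each at N = 150; δ_d recovery over 50 replicates at N = 200; GPLVM recovery
over 20 replicates at N = 150, J = 30; the Poisson M = N reduction and the
large-count agreement between the Poisson and Gaussian-on-log-counts tests;
and Bayes-factor sign checks over 100 replicates at N = 300, M = 16 (like
the calibration study, enough inducing points that Nyström truncation does
not erode the evidence for wiggly realized effects).

The large-count agreement study runs where the equivalence actually holds:
mean count 10³, smooth latent log-rate with variance 0.02, no donor
deviations, both pipelines estimating their own nuisances. At larger latent
variance or with donor terms the two tests genuinely differ — the Poisson
noise W⁻¹ is heteroscedastic and pinned while the Gaussian σ̂² is pooled
and absorbs misfit — by amounts that scale with the latent variance, not
the count depth, so such conditions would measure a model difference rather
than the large-count reduction.

## Known limitations

- Inducing-point count M is user-chosen; no data-driven selection.
  Calibration degrades mildly (λ_GC ≈ 1.03 at the reference conditions) when
  M is too small for the fitted smoothness.
- The H0/H1 objectives are non-convex; restarts mitigate but do not
  eliminate local optima. GPLVM recovery depends on initialization quality
  in the low-information regime (short trajectories, few genes).
- The score test relies on the plug-in V̂_d; with very few donors the
  variance-component estimates are noisy and sizes drift.
- Mini-batch (stochastic variational) training, random Fourier features,
  negative-binomial and binary likelihoods, colocalisation and hierarchical
  downstream models are out of scope.
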