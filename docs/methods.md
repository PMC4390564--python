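# Methods

## Model

`epimixed` fits Gaussian linear mixed models on pedigreed populations in
which each individual carries, besides the usual additive genetic effect
`u_i`, a transgenerational epigenetic effect `w_i` defined by the
autorecursion

    w_i = λ (w_sire(i) + w_dam(i)) + ε_i,        λ = (1 − v)/2,

where `v ∈ [0, 1]` is the reset coefficient: the expected proportion of
parental epigenetic marks erased at meiosis. The residual epigenetic
effect `ε_i` is independent of the parental effects with variance `σw²`
(founder), `(1 − λ²) σw²` (one known parent), or `(1 − 2λ²) σw²` (both
known), chosen so that `V(w_i) = σw²` is constant across generations.
Stacking the recursion, `w = P w + ε` with `P` holding λ at the parental
columns of each row, gives

    V(w) = T σw² = (I − P)⁻¹ V(ε) (I − P′)⁻¹.

Two limits anchor the interpretation: `λ = 0` (total reset) gives `T = I`
— epigenetic variance indistinguishable in structure from an
individual-level environmental effect — and `λ = 0.5` (no reset) gives
`T = A` on non-inbred pedigrees, indistinguishable from additive genetics.
Identification of (σw², λ) therefore rests entirely on contrasts between
relative classes (parent–offspring λσw² vs full-sib 2λ²σw²; half-sib λ²σw²
vs uncle–nephew 2λ³σw²), and weakens at both ends of the λ range.

The generalized model adds a maternal genetic effect `m` correlated with
`u` through a 2×2 covariance `G` (both structured by `A`), plus any number
of identity-structured random terms (permanent environment,
herd-year-season). Fixed factors are treatment-coded with an intercept.

### Assumptions

- Epigenetic and additive effects are uncorrelated; both are Gaussian
  (a large number of marks with small effects).
- λ is the same for sires and dams, and constant over environments and
  ages. Sex-specific or hierarchical transmission is out of scope.
- `A⁻¹` uses Henderson's rules **without** inbreeding accounting, matching
  the model's assumption of unit diagonals. This is exact when breeding
  individuals are non-inbred — true for discrete-generation designs where
  only non-inbred individuals reproduce — and an approximation otherwise.
- `diag(T) = 1` holds exactly only when mates are epigenetically
  unrelated. `build_T` implements the recursion definition above, so
  `build_T_inverse` (one-pass rank-one rules, pattern fixed by the
  pedigree, values a 7-entry table lookup in λ) is its exact inverse on
  *every* pedigree, including ones with related matings.

## Gibbs sampler

One cycle updates, in fixed ascending-equation order:

1. **Locations** `b, u, w, (m, p, h)` by single-site draws
   `s_i ~ N((r_i − Σ_{j≠i} c_ij s_j)/c_ii, σe²/c_ii)` over the mixed model
   equations `C s = r`, where `C = W′W + Σ` adds `A⁻¹ σe²/σu²`,
   `T⁻¹ σe²/σw²`, `σe²/σx² I` per identity term, and `σe² G⁻¹ ⊗ A⁻¹` for a
   correlated pair. The sweep kernel is numba-compiled over the CSR
   arrays; standard normals are pre-drawn from the single seeded
   generator, so results are bit-reproducible and numba-independent.
2. **λ** from its full conditional given `w`. The reference scheme
   (`paper_tn`, default) is a truncated normal on (0, 0.5) whose mean and
   precision are assembled from parental sums with the `(1 − kλ²)` factors
   frozen at the current λ; this is not an exact Gibbs step because those
   factors depend on λ. The `metropolis_exact` mode uses that truncated
   normal as a proposal and accepts/rejects against the exact conditional
   (which keeps the `−½ Σ log d_i(λ)` terms); it is the mode used by the
   joint-calibration test. Truncated-normal draws use inverse-CDF with a
   far-tail fallback; when the parental effects carry no information
   (zero precision) λ is drawn from its uniform prior.
3. **T⁻¹ refresh** — only the value vector, on the fixed pattern.
4. **Variances**: `σx² ~ (q_x + s_x²)/χ²(count_x + n_x)` with quadratic
   forms `u′A⁻¹u`, `w′T⁻¹w`, `p′p`, `e′e`; `G` from the inverse-Wishart
   conditional with scale `[u m]′A⁻¹[u m] + G₀` and df `n + n_G`. The
   default priors are the flat improper choices `(s² = 0, n = −2)` and
   `(n_G = −3, G₀ = 0)`; the sampler refuses nonpositive posterior
   degrees of freedom, and any non-finite draw aborts with a state dump.

The coefficient matrix is never re-allocated: its union sparsity pattern
(data cross-products plus all prior-precision components) is computed
once, and each cycle refreshes only the numeric data vector.

### Chain protocol

Defaults are `n_iter = 120,000`, `burn_in = 20,000`, `thin = 5` — a
desk-scale stand-in for the reference protocol of 1.25M cycles with 250k
burn-in (reachable via `--paper-scale` in the CLI). Single-site Gibbs
mixes slowly here: with one record per individual the split of phenotypic
variance among `u`, `w`, `e` is identified only through pedigree
contrasts, and the variance components random-walk along near-flat
ridges. Measured on 3,000-individual populations, 20,000-cycle chains
give effective sample sizes around 5 for the variances; 60,000+ cycles
give ESS ≈ 15–50. Posterior widths from short chains are conservative
(too wide) in the well-identified regime and can be too narrow in the
confounded regime (a chain stuck on part of a ridge); convergence should
always be checked with the Geweke/ESS report.

## Simulator

`simulate_population` emulates discrete-generation populations: an even
base generation (half sires, half dams) with `u ~ N(0, σu²)`,
`w ~ N(0, σw²)`; each later generation consists of full-sib families
whose sire and dam are drawn at random from the previous generation
(polygamy allowed, sexes alternate within families so both sexes exist);
descendants draw `u_j ~ N(½u_f + ½u_m, ½σu²)` and
`w_j ~ N(λw_f + λw_m, (1 − 2λ²)σw²)`; one record
`y = μ + u + w + N(0, σe²)` per individual, μ = 100. The
`paper_as_written` variant replaces the offspring epigenetic variance
with `(1 − λ)²σw²`, which breaks stationarity of `V(w)` across
generations; the default is the model-consistent choice, since
parameter-recovery experiments require the generating and fitting models
to coincide. Presets `dataset1` (σu²=210, σw²=120, σe²=270, λ=0.30) and
`dataset2` (σu²=90, σw²=60, σe²=450, λ=0.10, i.e. v=0.80) carry the benchmark
scenarios with a 3,000-individual base and two generations of 3,000
families of 10.

What the simulator does **not** emulate: selection, assortative mating,
overlapping generations, missing phenotypes, systematic environmental
structure correlated with family, or genotype data. Passing recovery
tests on simulated data therefore shows the estimator is calibrated
under its own assumptions, not that those assumptions hold in real
populations.

### Scaled study sizes

Test and example runs scale the design down, keeping the family size of
10 (which carries the full-sib information) and shrinking counts:
recovery replicates use 600 founders + 2 × 120 families (3,000
individuals) with 20,000-cycle chains; the confounding contrast uses
1,600 founders + 2 × 400 families (9,600 individuals) with 80,000-cycle
chains, because at 3,000 individuals the γ² posterior under `dataset1`
ratios is itself support-wide (scaling the full-size posterior standard
deviation by √21 predicts an HPD95 width ≈ 0.43, which we observe) and
the width contrast against `dataset2` only emerges once the
well-identified scenario tightens; the LogCPO comparison uses
~840-individual populations over 10 replicates.

## Diagnostics and model comparison

- **Summaries**: posterior mean, posterior SD, and HPD95 as the shortest
  interval containing 95% of sorted draws (never wider than the
  equal-tail interval). Derived quantities (h², γ², m², v, 1 − v) are
  computed per draw and then summarized.
- **Convergence**: Geweke z (first 10% vs last 50%, variances adjusted by
  per-segment effective sample size) and ESS by Geyer's initial monotone
  positive sequence estimator. These are transparent in-house substitutes
  for the unspecified test used in the reference analysis; they are
  advisory, not gating.
- **LogCPO**: `Σ_i ln[ Ns / Σ_j 1/p(y_i | θ_j) ]` with
  `p(y_i | θ_j) = N(y_i; fitted_i(θ_j), σe²(θ_j))`, computed with
  log-sum-exp stabilization over all stored draws. Densities condition on
  the drawn location effects; effect-marginalized CPO is out of scope.
  Fitting with `store_fitted=True` retains the per-draw location
  predictions that the computation needs.

## Numerical choices

- λ domain closed at 0.5 (`1 − 2λ² = 0.5 > 0` there); the truncated
  normal treats it as an open upper bound.
- Internal ids are 1..n in topological order (parents first); external
  labels are preserved bidirectionally.
- Dense `A`/`T` construction refuses n > 2000 by default — only the
  sparse inverses are needed at scale.
- Sampler initialization: each variance starts at an equal share of half
  the phenotypic variance; λ starts at 0.25; effects at zero.
- Single chain per fit; one `numpy.random.Generator` seeded from
  `random_state` drives every draw.

## Known limitations

- No inbreeding adjustment in `A⁻¹` (see above); pedigrees in which
  inbred individuals reproduce get an approximate additive prior.
- The default λ update is the reference scheme, which is approximate;
  for strict correctness at small n use `metropolis_exact` (acceptance
  rates are near 1 in practice, so the cost is negligible).
- Variance-component mixing is slow (see chain protocol); desk-scale
  chains quantify uncertainty honestly only through their HPDs, and
  model comparison should use long chains.
- LogCPO is a pseudo-marginal criterion; it is not a Bayes factor and
  its harmonic-mean form can be unstable when the posterior places mass
  on very small residual variances.
- Because the CPO densities condition on the drawn effects, the
  comparison rewards in-sample fit: when the λ → 0 ridge is active (the
  iid-structured epigenetic term trades likelihood-neutrally against
  the residual, so flat priors leave substantial posterior mass at
  large σw² even when the data carry no epigenetic signal), the model
  with the epigenetic term attains the higher LogCPO on data simulated
  without epigenetic variance. Selecting against a spurious epigenetic
  term via LogCPO therefore requires either data that concentrate the
  σw² posterior near zero or an effect-marginalized predictive density,
  which this package does not implement.
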