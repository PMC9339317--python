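# Methods

This note documents the generative models, estimator conventions, numerical
choices, and known limitations of `heritsim`. Problem sizes quoted here are
the package's desk-scale defaults; everything scales up by raising replicate
counts and grid sizes.

## Trait model and estimands

Genotypes are biallelic counts G_ij ∈ {0,1,2} at M markers for n
individuals, standardized per column as Γ_ij = (G_ij − 2p_j)/√(2p_j(1−p_j)).
The phenotype follows the polygenic model

    y_i = Σ_{j∈C} Γ_ij β_j + ε_i,   β_j ~ N(0, h²/m),  ε_i ~ N(0, 1−h²),

over the m causal markers C, so σ²g = h², σ²e = 1 − h², and E var(y) = 1.
All studies use h² = 0.8. Estimators target σ²g; the h² estimate divides by
the empirical phenotype variance (denominator n−1 throughout). Note that a
single β draw moves the realized sample variance of y by sd ≈ h²√(2/m)
(±0.11 at m = 100), so any check of the variance normalization must average
over trait draws; the package does so wherever that quantity is reported.

Standardization defaults to empirical frequencies p̂_j = (2n)⁻¹Σ_i G_ij;
true frequencies can be supplied for theory checks. Monomorphic columns are
dropped with a warning. A frequency-rescaling exponent α is supported via
the multiplier [2p(1−p)]^(α/2), chosen so that α = −1 reproduces the
standard unit-variance scaling; the alternative convention that applies α
directly as the exponent is available behind `literal_exponent=True`, since
both appear in the literature.

## Genotype simulators

Five population LD structures are built as explicit correlation matrices
Σ*: independent (identity), first-order autocorrelation (ρ^|j−ℓ|), block
(constant ρ inside equally sized blocks, default size 10), exchangeable
(constant ρ everywhere), and exact repeat (d = round(g·m) of the m causal
markers copied r extra times; copies are byte-identical, hence unit
correlation with their source and siblings). For the four correlation-based
kinds M = 2m with causal markers alternating (odd positions); for repeat
the first m markers are causal and the copies are appended. ρ ranges over
{0, 0.2, 0.4, 0.6, 0.8} and r over {0, 2, 4, 6, 8} with g = 0.1 in the
study grids.

Two backends generate genotypes:

* `gaussian` — rows i.i.d. N(0, Σ*), i.e. already-standardized continuous
  genotypes with the target correlation holding exactly. The bias algebra
  below is exact on this scale, so it is the backend for theory checks.
  Sampling uses closed-form factorizations (AR(1) recursion, shared block /
  common factors), never a dense Cholesky.
* `binomial_threshold` — each individual is the sum of two independent
  latent-Gaussian-threshold haplotypes: allele present when the latent
  variable falls below Φ⁻¹(p_j), so E(G_ij) = 2p_j and columns carry the
  latent correlation attenuated by the double thresholding. ρ is defined on
  the latent scale; realized genotype correlation is somewhat smaller. This
  asymmetry cancels in the alternating-causal designs (R_FF = R_CC holds on
  the genotype scale by symmetry) and is irrelevant for repeats (copies are
  exact), so the bias predictions remain applicable.

Allele frequencies are drawn once per experiment uniformly on (0.05, 0.95) —
a common-variant filter — and held fixed across replicate data sets.

## Pedigrees and gene drop

A k-ship of j-th cousins descends from one ancestral couple: k full-sib
branches, each extended through unrelated founder mates for j generations,
one sampled individual per branch. Expected relatedness between sampled
cousins is φ = 2·(1/4)^(j+1): 0.125, 0.03125, 0.0078125 for first, second,
third cousins (third cousins fall below the conventional 0.025 relatedness
pruning threshold). Groups are mutually unrelated; founders are outbred
(F ≡ 0). The relatedness study samples 400 individuals as 10 40-ships with
M ∈ {400, …, 4000} markers, all causal.

Gene drop places markers equally spaced on a single 3,000 cM chromosome.
Founder haplotypes are independent Bernoulli(p_j) draws; each meiosis
recombines under the Haldane model (crossovers from a Poisson process at
1 per 100 cM, no interference; expected 30 crossovers per meiosis). Realized
IBD then induces genotype correlation with expectation φ, verified directly:
with true-frequency standardization the empirical kinship over first-cousin
pairs averages 0.12517 ± 0.0003 at M = 2000. Empirical-frequency
standardization instead shrinks empirical kinship in related samples (the
sample mean absorbs shared ancestry; ~0.11 for this design), which is the
realistic analysis condition and does not bias the HE ratio.

## Estimators

All moments estimators report raw values — negative or above-one estimates
are never truncated (a clip-to-[0,1] helper exists for plotting only).

* **Haseman–Elston**: σ̂²g = Σ_{i<k} y_i y_k Ψ_ik / Σ_{i<k} Ψ²_ik, computed
  from the exact off-diagonal sums. A diagonal GRM raises a
  non-identifiability error.
* **HE matrix form**: (y′Ψy − n)/(tr(Ψ′Ψ) − n), valid for
  variance-standardized y and near-unit GRM diagonal; both preconditions
  are checked (tolerance 0.2) rather than silently assumed.
* **Dicker-1**: (‖Γ′y‖² − M y′y)/(n(n+1)), the fixed-effect moment
  estimator for independent markers. Under LD it inflates monotonically in
  (R_CC + R_CF)/m.
* **Dicker-1-Σ**: whitens by an LD matrix before the quadratic form.
  `inverse` mode requires M < n and a well-conditioned Σ; `pseudoinverse`
  handles rank-deficient Σ but refuses rank(Σ) = n, where the estimator is
  undefined (singular values below max(n,M)·eps·σ_max are treated as zero).
  Whitening by the empirical Σ of the same data collapses ΓΣ⁻¹Γ′ to n times
  the projection onto the column space of Γ and shrinks the estimate by
  ≈ (n−M)/(n+1); the population Σ* should be passed for the unbiased
  whitened estimator. Both behaviours are tested.
* **Dicker-2**: [μ₁‖Γ′y‖² − Mμ₁²y′y]/(n(n+1)μ₂) with μ₁ = tr(Σ)/M,
  μ₂ = tr(Σ²)/M − tr(Σ)²/(Mn); trace moments are computed through the
  smaller Gram matrix (tr Σ² = ‖ΓΓ′‖²_F/n²), so the M×M matrix is never
  formed when M > n. μ₂ ≤ 0 (e.g. Σ = I with M = n) raises.
* **ML / REML**: the Gaussian likelihood y ~ N(0, σ²gΨ + σ²eI) is evaluated
  through a one-time eigendecomposition of Ψ (O(n) per likelihood point
  after O(n³) setup). The total variance is profiled analytically and the
  ratio h = σ²g/(σ²g+σ²e) is optimized on [0,1] by a 0.001-step grid plus
  bounded refinement to 1e-8 — deliberately avoiding multi-dimensional
  optimizer fragility. REML projects out a grand-mean intercept via Helmert
  contrasts before fitting. Boundary estimates are flagged, and a GRM with
  degenerate eigenvalue spread (identity-like) raises: σ²g is only
  identifiable when Ψ ≠ I.
* **Gold standard**: the realized genetic variance share
  ‖Γ_Cβ − mean‖²/‖y − mean‖² using the true simulated β; exactly 1 when
  ε ≡ 0 and exactly 0 when β ≡ 0.

HE and Dicker-2 are approximately equal — the equivalence is O(1/n) in
absolute terms. At the n = 1000 study cells their per-replicate relative
difference stays below 1%; at n = 200, or whenever the estimate itself is
near zero (as happens under relatedness, where the estimator's spread is
large), the relative difference is unbounded even though the absolute
difference is tiny, so equivalence checks in that regime are made on the
σ²g scale. The exact trace identity n²tr(Σ²) = M²tr(Ψ²) holds to 1e-10.

## Bias theory

With unrelated individuals, E(HE) is approximated by the ratio of
expectations (M/m)·σ²g·(R_CC+R_CF)/(R_CC+2R_CF+R_FF), where R_CC, R_CF,
R_FF sum squared correlations of the population LD matrix over
causal–causal, causal–noncausal, and noncausal–noncausal pairs. The R sums
are computed from Σ* (not the empirical Σ), since the prediction is an
expectation over genotypes; an empirical variant exists for diagnostics.
No LD gives (m, 0, M−m) and no bias; M = 2m with R_FF = R_CC (alternating
causal under autocorrelation or blocks) cancels exactly; exchangeable
correlation cancels exactly; causal markers in locally high LD inflate, and
the repeat structure deflates to σ²g(m+rd)²/(m(m+rd(2+r))) — equal to σ²g
iff d = 0 or d = m, and 0.288 at the study corner (m=200, g=0.1, r=8,
σ²g=0.8), which Monte-Carlo HE means reproduce within 3 standard errors.
Predictions are exposed on both the σ²g and h² scales (identical here since
σ²g + σ²e = 1).

For Dicker-1 only the monotone inflation diagnostic (R_CC+R_CF)/m ≥ 1 is
certified (its full expectation involves an additional unidentified
constant); simulated Dicker-1 means order exactly as the diagnostic across
ρ ∈ {0, 0.4, 0.8}.

Under relatedness without LD, E(S_ΨΨ) → Σ_{i<k}φ²_ik and
E(S_YΨ) → σ²g Σ_{i<k}φ²_ik as M → ∞, so the HE ratio still targets σ²g and
its spread no longer grows with M. Convergence is O(n²/M) from the
unrelated-pair noise floor (≈ n²/2M added to S_ΨΨ), so at n = 400, M = 4000
the expected gap to the limit is still ≈ 15–20%; the package verifies the
monotone approach over M ∈ {400, 2000, 4000} rather than asserting closeness
at any fixed M.

One relatedness result deserves emphasis because it runs against a common
intuition: at this design's scale the cousin sample does *not* have lower
MSE than the unrelated sample. The cousin HE numerator contains
Σ_groups φ·[(Σ_i y_i)² − Σ_i y²_i]/2, and the squared group sums carry a
χ²₁-type fluctuation from each group's shared polygenic value. With 10
groups this puts an M-independent floor of sd ≈ 0.35 on the estimator
(measured 0.28 at M = 1000, 0.34 at M = 4000, matching the prediction),
whereas the unrelated HE sd grows like √(2M)/n and reaches only ≈ 0.22 at
M = 4000. Relatedness stabilizes HE against growing M (flat MSE vs growing
MSE — both reproduced), but with this few independent families it does not
win outright; that would require more groups or larger M.

## Likelihood surfaces

Surfaces evaluate the log-likelihood on a (σ²g, σ²e) grid with spacing 0.05
over [0.05, 1.5]² (bounds chosen to contain the truth (0.8, 0.2) and the
ridge), subtract each replicate's own maximum, and average — so every
stored cell is ≤ 0; the 60%-quantile truncation is applied only when
rendering. The ridge orientation is diagnostic of the n/M regime, and the
direction follows directly from the spectrum of Ψ: for n > M the GRM has
n − M zero eigenvalues whose directions estimate σ²e directly, pinning the
conditional maxima σ²e*(σ²g) to a horizontal line (measured slope −0.07 at
n=1000, m=200); for M ≫ n the GRM is near-identity, only the total variance
is well constrained, and the ridge follows the anti-diagonal
σ²g + σ²e = const (measured slope −0.64 at n=200, m=3000, tending to −1 as
M/n grows). At Ψ = I exactly the likelihood depends on the parameters only
through their sum and the fit raises a non-identifiability error.

## Randomness and reproducibility

Every generator accepts a seed or Generator; studies spawn independent
per-replicate `SeedSequence` streams from one master seed, with the
allele-frequency draw on its own stream so frequencies stay fixed across
replicates. Reruns with the same master seed are byte-identical (CSV-level
tests enforce this). Estimator failures inside replicate loops are recorded
per replicate with their reason, never dropped.

## Desk-scale defaults

Study-1 cells default to 200 replicates, Study-2 surfaces and Study-3 cells
to 100 (the full 500 sits behind `full=True`); `scale_factor` rescales
counts further. The acceptance script uses 200 replicates for HE/Dicker-1
targets and 100 for ML and cousinship targets. Monte-Carlo standard errors
accompany every summary so that scaled-down runs compare means within
3 standard errors rather than asserting point equality.

## What the simulations do and do not show

The generators emulate the study conditions — uniform common-variant
frequencies, stylized one-parameter LD structures, exact marker copies,
outbred pedigrees on a single chromosome — not real genomes: no frequency
spectrum realism, no mixed LD blocks, no crossover interference, no
multi-chromosome maps, no inbreeding, no population structure, and
phenotypes are fully additive with Gaussian effects. Conclusions about the
*relative* behaviour of estimators under controlled misspecification
transfer; absolute error magnitudes on real data do not. Known limitations:
Dicker-1-Σ is undefined for M ≥ n (inverse) or rank(Σ) = n (pseudoinverse);
the HE matrix form assumes standardized phenotypes; REML here handles an
intercept only (no covariates); and the likelihood fit is a 1-D profile,
which is exact for this two-component model but does not generalize to
multiple variance components.
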