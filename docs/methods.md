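# Methods

## The estimand

For ordinal variables X ∈ {1..I}, Y ∈ {1..J} with joint cell probabilities
h_ij, marginal mass functions p_i = Σ_j h_ij, q_j = Σ_i h_ij and marginal
CDFs F_i = Σ_{k≤i} p_k, G_j = Σ_{k≤j} q_k (with F_0 = G_0 = 0), the
population Spearman rank correlation is

    ρ_s = 3 (A − 1) / B,
    A   = Σ_i Σ_j h_ij (F_i + F_{i−1}) (G_j + G_{j−1}),
    B   = sqrt[(1 − Σ_i p_i³)(1 − Σ_j q_j³)].

ρ_s is defined whenever both margins have some variation (Σp³ < 1 and
Σq³ < 1); a flat margin raises `DegenerateMarginError` rather than
returning NaN.  The square root in B is essential: with it, plugging the
observed cell proportions ĥ into the formula reproduces *exactly* the
classical sample Spearman correlation computed from midranks (ties get the
mean of the rank positions they occupy).  That identity is enforced by a
property test against both a direct midrank computation and
`scipy.stats.spearmanr` on 200 random tables at 1e−12, and it pins down
independence ⇒ ρ_s = 0 (A ≡ 1) and comonotone equal-margin tables ⇒ ρ_s = 1.

## Asymptotic variance

The vector of observed cell proportions is a scaled multinomial; dropping
the last cell (h_IJ = 1 − rest) gives a nonsingular covariance
Σ = diag(h) − hhᵀ.  Because ρ_s is smooth in h, the delta method yields

    √n (ρ̂_s − ρ_s) → N(0, ρ̇_sᵀ Σ ρ̇_s),

with no independence or continuity assumption.  The gradient is

    ρ̇_s = (3 Ȧ − ρ_s Ḃ) / B,

where Ȧ and Ḃ are obtained by the chain rule through the marginal CDFs.
We evaluate the unconstrained partials over all I·J cells and subtract the
partial with respect to the eliminated cell; this is algebraically
identical to the reduced-coordinate derivative and has the advantage of
vectorizing cleanly over stacks of tables (`ordspear._batch`).  The
quadratic form is computed equivalently as
Σ_k D_k² h_k − (Σ_k D_k h_k)², which is invariant to the constant shift.
Analytic gradients are checked against central finite differences
(step 1e−6, perturbations kept inside the simplex by using test tables
bounded away from the boundary) on 100 random tables at 1e−6; observed
agreement is ~1e−9.

Inference is plug-in: gradient and Σ are both evaluated at ĥ.
Null-restricted variance estimation is out of scope.  Tests are two-sided
z-tests; confidence intervals are symmetric normal intervals.  No Fisher-z
transformation is applied.

## Variance comparators

* **Bootstrap** — pairs resampled with replacement, implemented as a
  multinomial redraw of cell counts at the observed proportions.  The two
  schemes induce the same resampling distribution (the estimator depends on
  the data only through the table), and the multinomial route is cheaper
  and exactly invariant to the order of the input pairs.  The bootstrap
  test uses the z-statistic with bootstrap SE, so all three methods are
  variance estimators for the identical point estimate; the percentile
  interval is reported alongside.  Default B = 1000 resamples.  Resamples
  with a flat margin are dropped and counted.
* **Naive independence approximation** — var = 1/(n−1), the classical
  large-sample null variance of Spearman's rho for continuous data under
  independence (the formula behind common software z-tests).  It ignores
  ties and dependence; it is included purely as the baseline whose failure
  under dependence the simulations display, and its method tag says so.

## Synthetic data generator

`gaussian_copula_table` discretizes a standard bivariate normal with latent
correlation ρ_latent at cutpoints Φ⁻¹(F_i), Φ⁻¹(G_j); cell probabilities
are CDF rectangle differences (`scipy.stats.multivariate_normal`, absolute
accuracy ~1e−8; requested margins are reproduced to 1e−8).  Category i is
taken as latent value in (c_{i−1}, c_i]; the boundaries carry zero
probability, so the convention only fixes determinism.  The reference
design used throughout the tests is ρ_latent = 0.5 with margins
p = (0.2, 0.2, 0.2, 0.2, 0.2) and q = (0.5, 0.25, 0.125, 0.0625, 0.0625),
giving ρ_s = 0.4249; latent 0.55 and 0.65 give 0.4695 and 0.5608.

Replicate sampling draws cell indices directly from the implied multinomial
(one stream, platform-portable seeds); a latent-normal path
(`sample_pairs_latent`) exists for didactic parity and is distributionally
identical.  What the generator does *not* emulate: real ordinal data with
misclassification, clustering/dependence across observations, or margins
estimated from data — passing tests show correctness of the method under
i.i.d. multinomial sampling, not robustness to those features.

## Monte Carlo experiments

`run_size_experiment` tests H₀: ρ = ρ_s(truth) and reports bias, MSE and
rejection rate per (n, method); `run_power_experiment` fixes the null while
the generating scenario differs.  Defaults follow the reference study:
20000 replicates, sample sizes (25, 50, 100, 200, 400, 800), α = 0.05.
The bootstrap arm defaults to 2000 replicates × B = 400 resamples — a
desk-scale design whose own binomial MC standard error (~0.005 at a 5%
rate) is attached to every cell, as it is for all cells.  Each
(scenario, n, method) cell derives its own `SeedSequence` child from the
master seed, so any cell reproduces bit-identically in isolation.
Replicates with a flat observed margin (vanishingly rare under the
reference design) are dropped and counted.  A latent-correlation 0.95
robustness variant can be run via the config interface; it has no
reference numbers attached.

## Numerical choices

* Probability tables must sum to 1 within 1e−9 on input and are then
  renormalized; cells below −1e−12 are rejected by name.
* Degeneracy threshold: Σp³ or Σq³ within 1e−12 of 1.
* ρ values are clipped to [−1, 1] to absorb last-ulp overshoot at the
  boundary; the delta variance is floored at 0.
* Bootstrap variance uses ddof = 1; cells with fewer than two surviving
  resamples are treated as degenerate.
* Ties in midranks use `scipy.stats.rankdata(method="average")`.

## Known limitations

* Inference is asymptotic; at n ≲ 50 the z-test over-rejects (the size
  study shows ~0.09 at n = 25), and the bootstrap is preferable there.
* Variance is estimated at ĥ, not under the null; size can differ slightly
  from nominal when the null is far from the estimate.
* Continuous (tie-free) Spearman, Kendall's τ and polychoric correlation
  are non-goals.
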