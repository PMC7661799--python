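# Methods

## Model and pipeline

The analysis treats a battery of p psychometric measures as nodes of a
Gaussian graphical model.  For each group separately:

1. **Pairwise associations.**  Declared-continuous pairs use Pearson
   correlation (p-value from the t transform with n−2 df).  Pairs involving
   ordinal measures use latent-Gaussian estimators under the standard
   threshold model: polychoric (ordinal/ordinal) and polyserial
   (continuous/ordinal), both by two-step maximum likelihood — thresholds
   fixed at standard-normal quantiles of the marginal cumulative
   proportions, then a one-dimensional likelihood maximization over the
   latent correlation ρ (golden-section on [−0.999, 0.999], absolute
   tolerance 1e-4, endpoint values checked so perfect-association tables
   return the clip boundary).  Bivariate-normal cell probabilities are
   computed by 32-point Gauss–Legendre quadrature of the conditional-normal
   representation per threshold strip (tails truncated at ±6 sd, where the
   neglected mass is ~1e-9); the integrand is smooth, so quadrature error is
   far below sampling error at any realistic n.  Ordinal scales with more
   than 10 declared levels (e.g. 0–14 sum scores) are treated as continuous:
   their contingency tables are too sparse for stable polychoric estimation
   and their scores are effectively sums of many items.  The declared level
   count (not the observed one) drives the rule so that bootstrap resamples
   of the same column are always typed identically.
2. **Significance screening** ("only significant correlations are
   maintained").  Polychoric/polyserial p-values come from a Wald test with
   the observed information obtained by central-difference second
   derivatives at ρ̂ (step 1e-3), falling back to a likelihood-ratio test
   against ρ=0 when the numerical information is not positive; boundary
   estimates are treated as p=0.  By default the screen is applied **after**
   regularization, at edge level: estimated edges whose underlying pairwise
   correlation has p > α (default 0.05, unadjusted) are removed.  The
   alternative order — zeroing non-significant correlations before the
   graphical lasso — is implemented (`filter_stage="pre"`) but not the
   default: zeroing entries of a polychoric matrix at n≈80 typically leaves
   it strongly indefinite (minimum eigenvalue ≈ −0.13 under the built-in
   study design), and after any positive-semidefinite repair the surviving
   near-null eigen-directions let dense precision matrices reach essentially
   unbounded likelihood, so penalty selection degenerates toward the densest
   model.  Measured on the built-in two-group design, the post-filter order
   recovers the planted structure in a clear majority of seeds; the
   pre-filter order essentially never does.
3. **PSD repair.**  The (possibly filtered) correlation matrix is made
   positive semidefinite by eigenvalue clipping at 1e-8, reconstruction and
   rescaling of the diagonal to 1; PSD inputs pass through untouched.
4. **Graphical lasso.**  Authored blockwise coordinate-descent solver
   (numba-compiled) maximizing log det K − tr(SK) − λΣ_{i≠j}|K_ij|; the
   penalty is off-diagonal only, so the working covariance keeps the input
   diagonal.  Convergence: maximum absolute change of the working
   covariance below 1e-5 (configurable), cap 1000 sweeps; inner lasso
   tolerance is a tenth of that.  The solver matches the independent
   reference implementation in scikit-learn to ~1e-4 on random problems and
   satisfies the KKT conditions to ~1e-10 at tight tolerance.
5. **Penalty selection.**  λ is chosen by BIC = −2ℓ + E·ln n over a
   descending log-spaced grid of 100 values from λ_max (the largest
   absolute off-diagonal of S, above which the model is empty) to
   0.01·λ_max, warm-starting each fit from the previous one.  ℓ is
   evaluated at the *unpenalized maximum likelihood refit constrained to
   the selected support* (computed by the same blockwise algorithm with
   pinned zeros).  Scoring the shrunken lasso estimate instead makes BIC
   monotone decreasing in density — the L1 penalty degrades the likelihood
   of the retained strong edges more than dropping weak ones saves — and on
   the study-sized problems it always selects the densest grid point.  BIC
   ties resolve to the larger λ (sparser model).  BIC rather than EBIC with
   γ>0 is the default; γ is not exposed because the refit-BIC already
   selects consistently in the regimes tested.
6. **Network.**  Edge weights are partial correlations
   w_ij = −K_ij/√(K_ii·K_jj); entries below 1e-8 count as structural zeros.

## Centrality

Distances are d_ij = 1/|w_ij| (absent edges: ∞): the standard transform for
association networks, making stronger edges shorter.  Strength sums
absolute incident weights (a signed variant exists behind a flag, for
researchers who want cancellation between positive and negative edges).
Betweenness and closeness are computed from an authored all-pairs Dijkstra
with geodesic counting; equal-length geodesics are all counted, with ties
detected at relative tolerance 1e-9 (exact floating-point tie sums compare
equal; the tolerance guards against last-ulp differences in summation
order).  Betweenness is the unnormalized Σ_{j<k} p_jk(i)/p_jk with endpoints
excluded; pairs with no connecting path contribute nothing.  Closeness is
r_i/Σd (r_i = reachable others) restricted to the node's component, 0 for
isolated nodes; the unscaled 1/Σd variant is available because the two
conventions differ exactly by the factor r_i and published tables are often
ambiguous about which was used.

## Community detection

Modularity uses the weighted Newman–Girvan form on absolute edge weights
(partial-correlation networks carry negative edges; signed-modularity
variants are deliberately out of scope, so a strong negative edge counts as
a strong connection for community purposes — a documented approximation).
The optimizer is the greedy local-move/aggregation algorithm
(networkx's Louvain implementation) wrapped in 20 seeded restarts with the
best-Q partition kept and community labels made contiguous in node order,
because single runs are sweep-order dependent.  Isolated nodes form
singleton communities.  Q < 0.3 is read as no community structure,
0.3–0.7 as genuine community structure, > 0.7 as exceptionally strong.

## Two-group comparison

Each group's pipeline is bootstrapped end to end: B subject resamples with
replacement (default 1000; the shipped experiments use 200), full
re-estimation and centrality computation per resample.  Resamples with a
constant column or a failed estimation are redrawn (cap: 10·B draws) and
counted.  For every node × metric cell, z = (mean_A − mean_B)/√(SD_A² +
SD_B²) from the bootstrap moments, two-sided normal p, Bonferroni at
α = 0.05 over all m = p × 3 defined cells; cells with both SDs zero are
excluded from m and flagged undefined.  Bootstrap SDs (not SEs of the mean)
enter the z: the bootstrap SD estimates the sampling SD of the estimator,
so the quadrature sum estimates the SD of the mean difference.  Raw scores
are compared with pooled-variance t tests (Welch behind a flag) for
effectively-continuous measures and two-sided Mann–Whitney U for ordinal
ones, Bonferroni-corrected across measures.

## Synthetic data

The generator draws latent vectors from N(0, Σ) with Σ the
correlation-rescaled inverse of a specified precision matrix (unit latent
variances make thresholds standard-normal quantiles, matching the
polychoric model and removing scale redundancy).  Ordinal columns arise by
counting thresholds below the latent score; continuous columns are an
affine map onto the instrument range (center at mid-scale, SD = range/6,
rounded to 0.01).  Default thresholds reproduce skewed instrument marginals
(most children near the scale top for the theory-of-mind subscales,
binomial-shaped eye-gaze sum scores).

The built-in two-group design has 11 measures (three 0–5 ordinal comic-strip
subscales, four 0–14 eye-gaze composites, 0–4 encoding and interpretation,
0–8 response construction, 0–36 near-continuous response evaluation).  The
TD-like precision is exchangeable with all partial correlations +0.09 — the
largest uniform value that keeps an 11-variable precision positive definite
is 1/(p−1) = 0.1, which is why a "dense and strong" group is impossible
under partial-correlation weights.  The ASD-like precision has a 6-node
block (ring at 0.3 with second-neighbour chords at 0.15 — a complete
6-block at 0.3 would be indefinite), a complete 4-node block at 0.3, two
bridge edges at 0.1 between the blocks, and one fully disconnected node.
The bridge/within ratio was chosen so the planted partition's modularity
falls in the conventional 0.3–0.7 community band.

What the generator does *not* emulate: item-level response processes,
missing data, floor/ceiling artifacts beyond what thresholds induce,
group differences in marginal score levels (both groups share thresholds,
so passing tests say nothing about mean-score contrasts), or non-Gaussian
latent dependence.  Passing end-to-end tests therefore demonstrates that
the machinery recovers latent-Gaussian block structure at realistic sample
sizes — not that any real population has such structure.

## Experiment sizes and numerical choices

The shipped test experiments scale the computations to keep full runs
practical on a single CPU: bootstrap experiments use B = 200 replicates
(the pipeline default remains 1000), a six-measure mixed battery for the
null-calibration study (50 replicate experiments) and the hub-difference
power study (20 experiments), both at the study's n = 81/76.  The power
design plants a hub node with three partial-correlation-0.45 edges in one
group and none in the other: a global strength difference whose
most-affected node is the hub.  Under partial-correlation weights the
per-node strength of a positive-definite model is tightly bounded, so
modest uniform differences (e.g. 0.15 vs 0.05 exchangeable) are genuinely
undetectable at these sample sizes — the bootstrap SD of strength (~0.3)
caps |z| near 2.5, below the Bonferroni threshold of ~3.2.

Known numerical caveats: graphical-lasso edge sets are monotone along a
descending penalty path only up to genuine zero-crossings of individual
precision entries (verified against scikit-learn); the tests treat a lost
edge as legitimate only when its coefficient was shrinking through zero.
Polychoric estimation requires at least two observed categories per
variable; bootstrap resamples violating this are redrawn and counted
rather than silently dropped, which would bias B.
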