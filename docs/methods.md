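# Methods

## Model

Promoter-level log2 expression in each dataset is modeled as

    E[p,s] = c_s + c_p + Σ_m N[m,p] · A[m,s] + ε[p,s],   ε ~ N(0, σ²)

with sample offsets `c_s`, promoter baselines `c_p`, known motif-by-promoter
site counts `N` and latent motif activities `A`. The decomposition is
gauge-degenerate (constants can move between `c_s`, `c_p` and `A`), so the
fit pins it down by convention: expression is centered over promoters and
samples, the design columns (site counts per motif) are mean-centered over
promoters, and each motif's activities sum to zero over the samples of a
dataset. Activities are the MAP estimate under an isotropic Gaussian prior
(ridge penalty λ, default 1.0, overridable and selectable by promoter-wise
5-fold cross-validation via `choose_lambda_cv`):

    A = (Xcᵀ Xc + λI)⁻¹ Xcᵀ Ecc        (per sample column)

Error bars are the square roots of the diagonal of the ridge posterior
covariance `σ̂² (XcᵀXc + λI)⁻¹`, one value per motif shared across the
dataset's samples. `σ̂²` is the residual sum of squares divided by the total
number of observations (promoters × samples); with thousands of promoters a
degrees-of-freedom correction would change it by well under a percent, and
the simple estimator keeps the brute-force test oracle exact. Because the
doubly-centered expression has zero row sums, the zero-sum gauge holds by
construction; it is re-enforced numerically after the solve. Motifs whose
site-count row is entirely zero are reported with `A = 0`, flagged
`inestimable` in the fit metadata, and drop out of downstream ranking
naturally (their scaling factor is zero, see below).

## Cross-dataset standardization and z-scores

Per dataset and condition (`a` epithelial-like, `b` mesenchymal-like),
activities are averaged over replicates with the error of the mean under
independence, `σ̄ = √(Σσ²)/n`; inverse-variance weighting is available
behind a flag but is not the default, the plain arithmetic mean being the
simplest defensible reading. The two condition means are re-centered around
their midpoint (the formula's quantities are condition-level, so the
midpoint — not the all-sample mean — is the natural center), then both
activities and errors are divided by

    S = √((Ā*_a² + Ā*_b²)/2)

so each retained (motif, dataset) pair has unit RMS. `S = 0` means the motif
carries no signal in that dataset (exactly antisymmetric condition means
only occur when both are zero after re-centering); division by zero has no
meaningful value, so such motifs are excluded from that dataset's
contribution and logged. Rescaled activities are grouped by condition across
datasets and averaged exactly as replicates were, giving per motif

    z = (Ā*_b − Ā*_a) / √(σ̄*_b² + σ̄*_a²).

Group averaging divides the combined error by the number of contributing
datasets (the same rule as replicate averaging); this is one of two
defensible readings and is applied uniformly. Note that after rescaling the
condition means of *every* motif are ±1, so the z ranking is driven by the
propagated errors and by sign consistency across datasets, not by effect
magnitude — this is the intended behavior of the standardization.

## Target scores and posteriors

The target score of promoter `p` for motif `m` compares two Gaussian
profile likelihoods of the promoter's expression across samples: the full
fitted model versus the model with motif `m`'s contribution removed
(`N[m,p] := 0`). In both models the promoter baseline `c_p` is profiled out
(re-estimated by the per-promoter sample mean); activities and `c_s` stay
fixed at their global fit values. With the fit's residual variance σ²,

    R = (SSR_reduced − SSR_full) / (2σ²).

Profiling `c_p` in both models (not only the reduced one) is deliberate: it
makes the two models coincide exactly when `N[m,p] = 0`, so such pairs score
R = 0 and posterior 0.5 — the uninformative value. Because activities are
zero-sum over samples, removing a motif's contribution does not shift the
profiled baseline, which yields the closed form used by the vectorized
scorer (`SSR_red − SSR_full = 2N·(A rᵀ) + N²·ΣA²`) — verified against the
explicit per-pair computation in the tests. The posterior under a uniform
0.5 prior is the logistic transform `p = 1/(1+e^(−R))`, and evidence
combines across datasets as the probability product `p_comb = Π p_i`,
computed per dataset and multiplied; promoters absent from a dataset simply
contribute no factor, and the factor count is reported alongside `p_comb`.
No numerical agreement with any public web server's internals is claimed:
the likelihoods here are the package's own closed-form choice within the
stated target-vs-not-target semantics.

## Network construction

Candidate nodes are motifs with `|z|` above the node threshold (default
2.0). For every regulator gene known to bind a candidate motif B, an edge
A → B is added when the gene's best-promoter `p_comb` under motif A exceeds
the edge threshold (defaults 0.35 for human, 0.15 for mouse); "consistently
predicted across datasets" is operationalized as this combined product
exceeding the threshold, since that is the quantity the thresholds attach
to, rather than per-dataset unanimity. Edges are keyed by the regulator
gene, so a gene bound by several motifs produces one annotated edge per
(source, target) pair, and self-loops (a motif targeting its own regulator)
are retained. Nodes without any retained interaction are removed to a
fixpoint; a self-loop counts as an interaction (the alternative reading —
requiring an interaction with *another* motif — would differ only for
self-loop-only nodes). Raising either threshold can only remove structure.
DOT export colors nodes by the sign of z (positive red; negative color
configurable, green by default, blue also in circulation for the same
meaning).

## Gene-level summaries

Gene expression is the sum of the gene's promoter expression on the linear
scale (log2 input is de-logged first). Log2 fold changes compare group
means with a pseudocount (default 1.0 on the linear scale, configurable)
guarding zero denominators; the input-scale flag covers both the normalized
linear and log readings of the upstream quantification.

## Synthetic data: what it emulates and what it does not

The generator emulates a collection of EMT expression studies: by default 3
datasets, 50 motifs, 2000 promoters, 2 replicates per condition, planted
activity effect 1.0 (log2 scale) and Gaussian noise sd 0.2 — an effect/noise
ratio typical of a clear regulatory signal over biological replicates.
Sample offsets are drawn N(0, 0.25) and promoter baselines N(5, 4)
(mean, variance), fixed documented choices on the log2 scale. A fraction
(default 0.2) of motifs is active, with activity ±effect/2 in the two
conditions and a per-motif sign held consistent across datasets; inactive
motifs have activity 0. Site counts are sparse non-negative integers:
a Bernoulli(density) mask with counts 1 + Poisson(1) where it fires, so the
realized nonzero fraction equals the density parameter. Planted network
edges A → B put 3 binding sites of motif A on the promoter(s) of the
regulator gene of motif B; regulator-gene promoters carry *no background
sites*, which makes the planted edge set the unique ground truth — with
background sites there, random (active motif, regulator promoter) pairs
would be genuine targets of the generative model without being planted
edges, and edge-recovery precision would measure generator ambiguity rather
than method error.

Passing recovery tests on these fixtures shows the estimator inverts its
own generative model under realistic noise; it does not show robustness to
what real data add: batch effects, non-Gaussian noise, errors in the
site-count predictions, unmodeled regulators, or condition-dependent
baselines. Read-level simulation is out of scope by design.

## Numerical choices and edge cases

- λ = 0 is allowed only for well-conditioned designs; a singular or
  near-singular system (condition number > 1e12) raises an error advising
  λ > 0.
- Residual variance is floored at 1e-300 so error bars stay positive even
  on noiseless input.
- Ranking ties in top-target lists break by gene ID ascending (and by
  promoter ID among a gene's promoters); z-score tables sort by |z|
  descending with a stable sort.
- All TSV writers use a fixed 10-significant-digit float format and sorted
  ordering, so pipeline reruns with the same seed are byte-identical.
- Seeded generation derives independent deterministic substreams for the
  truth, the site counts and each dataset from the single user seed.

## Problem sizes

The test suite uses a small bundle (2 datasets, 8 motifs, 150 promoters)
for unit-level checks and the default bundle (3 datasets, 50 motifs,
2000 promoters) for recovery checks; the 20-seed recovery test and the full
suite run in well under a minute on one CPU because the per-dataset fit
reduces to a motifs × motifs solve and all target scoring is vectorized.
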