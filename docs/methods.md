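# Methods

This note documents the statistical machinery in `symptomnet`, the
assumptions behind it, the defaults and why they were chosen, and what
the synthetic-cohort experiments do and do not demonstrate.

## The model

The estimand is a Gaussian graphical model over p subscale ratings (plus
an age covariate): a precision matrix Θ whose scaled negative
off-diagonal entries are partial correlations,
ρ_ij = −θ_ij/√(θ_ii·θ_jj). An edge means two subscales remain associated
after conditioning on every other subscale and on age. The model assumes
the observations are i.i.d. draws whose dependence structure is that of
a latent multivariate normal; marginals may be arbitrary continuous
(or, approximately, ordinal) distributions, which is what the
nonparanormal transformation absorbs.

## Preprocessing

Order is fixed and logged on the data object: orientation → univariate
outliers → multivariate outliers → transformation → correlation → PSD
repair.

- **Orientation.** Instruments scored "higher = better" are reflected
  with x → hi − x when the score maximum is known, else negated. Done
  before any statistic is computed so all correlations have a common
  difficulty direction.
- **Univariate outliers** (`z_cut = 3.5`): cells beyond ±3.5 SD of their
  variable's missing-excluded mean are set missing. Means/SDs are
  computed once before any replacement; replacements are simultaneous,
  so the rule does not cascade.
- **Multivariate outliers** (`alpha = 0.001`): rows whose Mahalanobis D²
  (computed on a mean-imputed copy; the imputation is never written
  back) exceeds χ²_{p,0.999} are removed. The α is configurable because
  standard practice varies between 0.001 and 0.0001.
- **Nonparanormal transformation**: per variable with m observed values,
  midranks/m winsorised to [δ_m, 1−δ_m] with
  δ_m = 1/(4·m^{1/4}·√(π·log m)), then the standard-normal quantile
  function. Being rank-based, it is invariant to any strictly monotone
  marginal distortion; ties map to identical values. Output is centred
  and scaled to unit sample SD (divisor m−1). Age is appended as an
  ordinary column *before* the transform, so the covariate is
  gaussianised like any node.
- **Correlations**: Pearson over complete pairs (default) or complete
  rows. `effective_n` — the sample size later used by EBIC and the
  threshold — is the number of analysed rows under pairwise estimation
  (the single-n convention of the common network-estimation workflow);
  a mean-pairwise-n alternative is available via
  `effective_n_mode="mean_pairwise"`.
- **PSD repair**: pairwise matrices need not be positive semidefinite,
  and the graphical lasso requires PSD input. Negative eigenvalues are
  clipped to 1e−8, the matrix rebuilt and its diagonal renormalised,
  iterating to convergence (≤100 rounds). The maximum elementwise change
  is recorded.

## Estimation

The penalty path is 100 log-spaced values on
[0.01·λ_max, λ_max], λ_max = max off-diagonal |correlation| (at which the
glasso solution is exactly diagonal). Each fit is an L1-penalised
maximum-likelihood precision estimate with the diagonal unpenalised,
solved by block coordinate descent (duality-gap tolerance 1e−6, up to
500 outer sweeps; the smallest penalties on the path can stop at the
iteration cap without affecting selection, since EBIC minima sit well
inside the path). Selection minimises
EBIC = −n·[log det Θ̂ − tr(SΘ̂)] + E·log n + 4·E·γ·log p with γ = 0.5;
ties break toward the larger penalty, consistent with the sparsity
assumption. The path is searched from the sparse end so tie-breaking is
ordering-independent.

Thresholding zeroes |w_ij| < τ = √(log(p(p−1)/2)/n). The constant is the
bound popularised for regularised partial-correlation networks; the
literature states "a theoretical bound" in several variants, so τ is
config-overridable (`tau_override`) and the unthresholded adjacency is
always retained alongside, allowing the thresholded/non-thresholded
comparison. p here includes the covariate node, since thresholding
happens before the covariate is dropped.

Age is included in estimation and removed from the reported network by
deleting its row/column from the adjacency (no re-estimation) — every
remaining edge is thereby conditioned on age, but age itself never
enters plots or centrality.

Variant switches (`PipelineConfig`) cover: raw vs transformed scores,
pairwise vs listwise correlations, regularised vs unregularised
(pseudo-inverse partial correlations), thresholded vs not.

## Communities

Walktrap with walk length t = 4 (the algorithm's usual default; the
choice is exposed in config) on absolute edge weights — random walks
need nonnegative weights, and partial-correlation symptom networks are
almost entirely positive, so taking |w| is the standard convention.
Transition probabilities are computed analytically, hence the procedure
is fully deterministic. The merge tree is cut at maximum modularity
Q = (1/2m)·Σ_ij [a_ij − k_i·k_j/(2m)]·δ(c_i, c_j), again on absolute
weights; Q is recomputed by the package's own modularity function rather
than taken from the clustering backend, which doubles as a consistency
check. The backend does not expose dendrogram heights, so the merge
sequence records merge order as the height proxy. Edgeless networks
return singletons with Q = 0 by convention.

## Node inference

- Strength Σ_j |w_ij| uses absolute weights (making strength ≥
  |expected influence| an invariant); expected influence is the signed
  sum; bridge strength sums |w_ij| over nodes in other communities.
- Predictability is OLS of each node on all other non-covariate nodes
  over listwise-complete rows of the transformed data, R² clipped to
  [0, 1]. OLS rather than a penalised nodewise model because n ≫ p in
  the intended regime; a penalised variant would matter only when
  p approaches n. For data generated from a known precision matrix the
  population value is R²_i = 1 − (1/θ_ii)/Σ_ii, which the tests verify
  to within 0.05 at n = 5000.
- The SD-bias diagnostic correlates (Spearman) each centrality index
  with per-variable raw-score SDs; exact permutation p-values for ≤10
  nodes, asymptotic otherwise. A strong association flags centrality as
  an artefact of differential variability.
- During bootstraps, communities for bridge strength are frozen at the
  full-sample partition so replicate vectors are comparable.

## Stability

The edge bootstrap redraws rows with replacement and re-runs the whole
estimation (transform → correlations → path → EBIC → threshold) per
replicate. Reported per edge: bootstrap mean, min/max, 95% quantile
interval overall and conditional on the edge being nonzero, and
%-nonzero. The conditional interval ignores replicates where
regularisation zeroed the edge, and is therefore meaningful only
together with %-nonzero. Note the overall quantile interval need not
bracket the bootstrap *mean* when fewer than 2.5% of replicates produce
extreme weights; the report carries min/max so this can be seen.

The case-dropping bootstrap removes a proportion π of rows without
replacement (grid 0.10–0.75 in steps of 0.05 by default), re-runs the
pipeline, and correlates replicate centrality vectors with the
full-sample ones. CS(cor) is the largest π at which ≥95% of replicates
correlate ≥ cor (default 0.7); indices with CS ≥ 0.5 are conventionally
interpretable. Replicate failures (degenerate resamples) are skipped and
counted, with a 5% ceiling for the edge bootstrap.

All replicate randomness derives from one `SeedSequence` spawned into
per-replicate substreams, so results are independent of scheduling and
exactly reproducible from the seed.

Network comparison is the Pearson correlation of vectorised strict lower
triangles; subgroup analysis estimates one network per group label
(hard minimum 100 rows, warning under 300) and compares each with the
full-sample network.

## Synthetic cohorts

The generator emulates a referred-cohort rating study: n = 714 children,
23 bounded integer subscales in four latent blocks (sizes 5/8/6/4),
within-block edge probability 0.5, between-block 0.03 plus 4 guaranteed
bridge edges, partial correlations 0.10–0.35 in magnitude (10%
negative), an age covariate (uniform 5.2–18.6 years) loading 0.3 on five
subscales, 2% MCAR missingness, 3 injected univariate outliers (6 SD
single cells, the data-entry errors the ±3.5 SD rule exists for) and 6
injected multivariate outliers — rows whose D² is driven to twice the
χ²_{p,0.9999} quantile by breaking the correlation pattern while keeping
each coordinate within ~3.2 marginal SDs, so they evade the univariate
screen exactly as real inconsistent raters do.

Two observation-model choices were made deliberately:

- **Skewing map**: x → (e^{s·x} − 1)/s, strictly monotone with identity
  as s → 0. An odd map such as a plain sinh stretches both tails
  symmetrically and produces zero skewness, so an asymmetric map is
  required to emulate the right-skewed marginals of difficulty ratings.
  The default s = 0.35 yields marginal skewness ≈ 0.4–1.0, matching
  what parent-rating subscales typically show.
- **Discretisation**: the skewed latent is mapped linearly onto the
  score bounds with the (2.5%, 97.5%) sample quantiles as anchors, then
  clipped and rounded half-to-even. Anchoring at the sample extremes
  instead would let single extreme draws define the score range, giving
  no floor/ceiling truncation and dozens of spurious |z| > 3.5 cells per
  cohort; quantile anchoring reproduces the mild floor/ceiling piling
  (~7% of cells) of real bounded scores and leaves essentially all
  3.5-SD exceedances to the injected outliers.

The generator does **not** model item-level responses, MNAR missingness,
rater effects, or longitudinal structure. Consequently, passing tests
demonstrate that the pipeline recovers latent-Gaussian dependence
structure under realistic marginal distortion and contamination — not
that any particular empirical dataset satisfies those assumptions.

`benchmark_true_model()` provides a fixed, deterministic 4-block
structure (chain edges 0.25, closing edges 0.15, bridges 0.12, one
designated 0.30 edge) used by calibration experiments that need an edge
of known exact magnitude.

## Problem sizes in the shipped experiments

Unit and acceptance tests run at the study scale (n ≈ 700, p = 23) for
estimation checks, n = 5000 for consistency checks, and use B = 200
bootstrap replicates and ~30 case-dropping replicates per proportion on
a 7-point grid — desk-scale sizes chosen so the full experiment suite
runs in minutes while keeping binomial noise on the measured rates well
inside the asserted margins. The methodological defaults remain
B = 2000 and the 14-point grid.

## Known limitations

- EBIC uses a single effective n with pairwise-complete correlations;
  under heavy or structured missingness this overstates the information
  available to some pairs.
- The threshold constant is one of several "theoretical bound" variants
  in circulation; results near the boundary should be read with the
  unthresholded network alongside.
- Absolute-weight conventions (strength, walks, modularity) discard sign
  structure; networks with many strong negative edges would need the
  signed variants this package deliberately omits.
- OLS predictability is slightly optimistic in small samples (no
  cross-validation).
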