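# Methods

## Model

A subject is a vector of *n_f* scalar features with no time axis. For every
ordered feature pair (*i*, *j*), *i* ≠ *j*, a reference population defines a
linear constraint x̂_j = α_ij·x_i + β_ij, fitted by ordinary least squares
(minimizing squared vertical residuals) on the population instances. The
package keeps, per direction, the slope, intercept, and the sample standard
deviation σ_ij of the signed training residuals. A subject's deviation in
the (i, j) plane is converted to a dimensionless score
z_ij = |x_j − x̂_j| / σ_ij, and the undirected edge weight W_ij combines the
two directional scores. The resulting per-subject network is symmetric,
non-negative, with zero diagonal.

The linear form is deliberate: expression data are customarily transformed
to behave linearly, and the reference sets in the intended applications are
tiny (5 training instances per fit in the leave-one-out design), so any
higher-order model would overfit. Relationships are treated as
instantaneous: no lagged or longitudinal structure is modeled. The fit
backend is pluggable in principle (the module surface takes any
`ReferenceModelSet`), but only the linear backend is implemented.

### Standardization choices

* **z-score baseline** (`mode="signed"`, default): the signed training
  residuals of an OLS fit have mean exactly 0, so the z-score needs no
  centering term: z = |residual| / sample-std(signed residuals). The
  alternative `mode="absolute"` standardizes the absolute deviation against
  the training distribution of absolute residuals,
  z = | |d| − mean|d| | / std|d|; both are exposed through the same
  interface.
* **ddof = 1** for every sample standard deviation (configurable). With
  5-point training sets the bias of the ML estimator is material; the
  unbiased-variance convention is the defensible default.
* **direction combination** (`combine`, default `mean`): the method fits
  n_f(n_f − 1) directional models but the network is undirected. The mean
  of the two available directional scores is the symmetric choice; `max`
  and `min` are provided. Empirically (noted in the tuning study below)
  `max` separates abnormal from normal densities more sharply, but `mean`
  remains the default as the neutral reading.

### Degenerate planes

A direction is degenerate when the predictor has (numerically) zero
variance or the residual spread is below 10⁻¹² times the data scale
(a perfect fit cannot standardize a deviation). Degenerate directions are
excluded from the combination; if both directions of a pair are degenerate
the edge is absent (weight 0) and a warning is logged. Models always need
≥ 3 training instances (two to fix a line, one residual degree of freedom);
fewer is an error. Missing values are rejected at load time.

## Centrality and topology

α-centrality solves x = αWx + e by a dense linear solve plus one step of
iterative refinement; the fixed-point residual is stored on the result and
stays below 10⁻⁸ in all tested regimes. Defaults: e = 1,
α = 0.9·(1/λ_max(W)) — the admissibility condition is α < 1/λ_max, which
keeps (I − αW)⁻¹ a convergent non-negative Neumann series; for the empty
network W = 0 any α works and x = e. Scores are normalized to max 1.
Centrality is computed on the full weighted matrix; weight thresholds
(1.5, 3.0) are display/summary conventions, applied by `threshold_network`
and `link_density`, not to the centrality solve (a flag allows otherwise).
Ranking ties break lexicographically by feature id, so results are
deterministic. An edge "exists" when its weight is positive; link density
counts existing edges at or above a threshold over all n_f(n_f − 1)/2
pairs; the giant component is the largest connected component over
positive-weight edges (size ties go to the component containing the
lexicographically smallest id).

## Synthetic generator

`generate_synthetic` emulates a time-course expression matrix: feature j at
instance t (t = 1…n, 1-based) is a_j·t + b_j + ζ, with a_j, b_j ~ N(0, 1)
drawn once per feature and ζ ~ N(0, noise_std²) per entry (defaults:
10 instances, 20 features, noise_std = 1). The shared dependence on t makes
all feature pairs strongly correlated, which is what gives the pairwise
reference models their footing; the noise mimics natural expression
variability. Planted anomalies (default: +2 added to features F05 and F10
of instance T10) are applied after the noise draw, and the noise stream is
independent of the perturbation list, so perturbed and unperturbed runs at
the same seed differ exactly at the planted entries. The linear trend is a
replaceable callback.

What the generator does **not** emulate: realistic transcriptomic
covariance structure, heteroscedastic or heavy-tailed noise,
batch/normalization artifacts, or any regulatory network topology. Passing
tests on this generator show the machinery is correct and that planted
pairwise anomalies surface as hubs under the stated noise level — not that
the method's biological findings on real expression data are reproduced.

## Measured behavior of the planted-anomaly experiment

With the defaults above and the leave-one-out pipeline, over 100 fixed
replicate seeds:

* the abnormal instance's link density at threshold 1.5 exceeds the mean
  density of the nine normal instances in **93%** of runs (abnormal mean
  density ≈ 0.34 vs normal ≈ 0.21);
* both planted features rank in the abnormal network's top-3
  α-centralities in **15%** of runs (top-5: ≈ 31%).

The hub-recovery rate is bounded by the conditions, not the estimator: the
subject's own noise ζ_j enters every edge incident to feature j exactly as
a planted shift does, so with ζ ~ N(0, 1) and a +2 shift, even an oracle
that knows the true generating trend and ranks features by |true deviation|
(the likelihood-ratio ordering) places both planted features in the top-3
in only ≈ 39% of runs (Monte-Carlo, 10⁵ draws). Single illustrative runs
can and do show clean recovery (see the README example); across seeds a
noisy unperturbed feature frequently outranks a planted one. Alternative
settings (max/min combination, absolute-z baseline, centrality on
thresholded networks) were surveyed and move the recovery rate by at most a
few points, confirming the ceiling is informational; none of them is
promoted to default on that basis.

## Numerical and design notes

* Pair-model fitting is vectorized over all pairs via the centered
  cross-product matrix; it agrees with the per-pair scalar path and with
  closed-form normal equations to ~10⁻¹⁴ relative. Results are independent
  of pair evaluation order (single fixed reduction order).
* Edge weights are exactly symmetric by construction (Z + Zᵀ before
  division), and invariant to per-feature affine transforms of data and
  subject (the OLS fit and σ absorb them) to ~10⁻⁹ even under extreme
  scalings.
* The 6 × 500 leave-one-out benchmark (≈125k directional models per fold,
  the shape of a scaled-down transcription-factor screen) runs in about a
  second; memory is dominated by the n·f² residual tensor.
* All ids are strings; reports never use positional indices. Synthetic ids
  are 1-based and zero-padded (F05, F10).
* Readers/writers: CSV/TSV matrices (strict numeric parsing, located
  errors), GraphML round-trips weights at full precision, edge lists are
  sorted by (source, target), so all outputs are byte-stable.

## Known limitations

* Only the linear reference backend exists; SVM/ANN-style backends are out
  of scope.
* No classification rule for unlabeled subjects is provided: the package
  returns per-class networks and summary statistics; turning them into a
  classifier is the user's modeling decision.
* End-point instances of a monotone series (first/last time step) are
  extrapolation points for models fitted on the rest, which inflates their
  networks' densities relative to interior instances; this is inherent to
  the leave-one-out design.
* Real microarray preprocessing (normalization, probe filtering) is out of
  scope; input matrices are assumed pre-normalized.
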