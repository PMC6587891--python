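# Methods

## Network construction

A subject is an `n × m` matrix of ROI time series (rows: regions, columns:
time points). Three network kinds are built per subject, independently of
every other subject:

**First-order (Pearson).** `C¹_ij = Cov(x_i,x_j)/√(Var(x_i)Var(x_j))` for
`i ≠ j`; the diagonal is forced to 0 in every network kind so
self-connections never enter features, thresholds or graph metrics. A
constant (zero-variance) region is an error naming the region, not a silent
NaN.

**Second-order (triplet).** Squared Euclidean distances
`D_ij = Σ_t (x_it − x_jt)²` between region time series; each region's k
nearest neighbors, with distance ties broken toward the smaller region index
so results are deterministic; the aggregate relative distance
`dist'(x_i,x_v) = k·D_iv − Σ_{u∈N_i} D_iu` (the sum over the neighbor set of
the antisymmetric relative-distance terms `S^i_uv = D_iv − D_iu`). Entries
are assigned only from a center to its own neighbors: the negated `dist'`
values, min-max rescaled to [0, 1] **globally over all computed entries of
the subject's matrix** — per-row rescaling would destroy cross-row
comparability before symmetrization. Larger relative distance means weaker
connectivity, hence the negation before rescaling. Non-neighbor entries are
0, so after the symmetrization `C² = (C + Cᵀ)/2` a pair connected in only
one direction keeps half its normalized value; this is taken literally from
the construction rather than patched. If every computed value is identical
(e.g., all rows equal) there is no ordinal information; the network is set
to 0 with a warning rather than to a fabricated uniform 0.5.

**Hybrid.** `C = μ·C¹ + (1−μ)·C²` elementwise, `μ ∈ [0,1]`; entries
therefore lie in `[−μ, 1]`. Optional thresholding zeroes entries with
`|C_ij| < t` (absolute value — first-order edges can be negative) and is
applied after fusion.

Scale invariance holds by construction: Pearson is scale-free, and the
global min-max absorbs the distance scale of the triplet network.

## Edge selection and projection

Networks are vectorized to their `n(n−1)/2` upper-triangle weights in fixed
row-major `(i<j)` order.

**Non-negative elastic net.** `β ≥ 0` minimizing
`½‖y − β₀ − Fβ‖² + λ1·Σβ + ½λ2·‖β‖²`, labels coded ±1 (patient = +1),
solved by cyclic coordinate descent with non-negative soft-threshold
updates on a precomputed Gram matrix; converged when the largest
coefficient change in a sweep is below 1e-8, capped at 10⁴ sweeps with a
warning. The unpenalized intercept `β₀` (implemented by centering) is
essential: edge weights are non-negative for the second-order network and
mostly positive for Pearson, so without an intercept a non-negative
combination cannot represent ±1 targets and the selection degenerates.
Edges with `β > 0` are selected; if none survive, the fold falls back to
all edges with a warning. Defaults `λ1 = λ2 = 0.01` keep tens of edges on
the packaged cohorts; `select_penalties` optionally chooses them by inner
stratified 5-fold CV over a log grid `{1e-3 … 1}` (opt-in via
`penalty_cv=True` because it multiplies cost ~50-fold and changes no
qualitative behavior on the synthetic cohorts). Features are not
standardized: edge weights are already bounded by construction.

**Kernel discriminant analysis.** Gaussian kernel
`K(a,b) = exp(−γ‖a−b‖²)`; the two-class kernel Fisher discriminant
maximizes `(αᵀMα)/(αᵀ(N+εI)α)` with `M` the between-class and `N` the
within-class kernel scatter; the leading generalized eigenvector is
`α ∝ (N+εI)⁻¹(m₊ − m₋)`. γ defaults to the median heuristic (reciprocal of
the median pairwise squared distance of training features), ε to
`1e-3·trace(N)/n_train`; both overridable. The sign of α is fixed so
training patients score above training controls. Test subjects get the
label of the nearest training score (ties to the smaller training index).

## Evaluation protocol

Stratified 10-fold cross-validation repeated 20 times (defaults; both
configurable), fully reproducible from one seed via spawned sub-seeds.
Network construction is per subject and may be precomputed; elastic net and
KDA are fit on training folds only — no held-out subject influences any
fitting step. Per repeat, out-of-fold predictions and scores are pooled and
the eight metrics (ACC, SEN, SPE, PPV, NPV, F1, BAC, AUC; patient =
positive class) computed once; the report is mean ± std across repeats.
Undefined ratios (zero denominators) are NaN with a warning, never silently
0. AUC uses the average-rank form, which is exactly the Mann–Whitney
statistic with half credit for ties.

Out-of-fold KDA scores are affinely calibrated per fold — centered on the
midpoint of the training class means and scaled by their gap — before
pooling. The calibration uses training information only and is monotone
within a fold, so per-fold decisions are unchanged; without it, pooled
ranks across folds are meaningless because each fold's discriminant has its
own arbitrary scale.

**DeLong test.** Paired AUC comparison via placement values: the variance
of the AUC difference is assembled from the empirical covariances of the
per-patient and per-control placements, `z = ΔAUC/√var`, two-sided normal
p. Equal AUCs with zero variance give p = 1; unequal AUCs with a zero
variance estimate are an error rather than a fake p.

**Greedy parameter search.** Coordinate-wise over the grids
k ∈ {5,…,45}, μ ∈ {0,0.1,…,1}, t ∈ {0,…,0.4}: k first (at μ = 0.5, t = 0),
then μ, then t; each candidate scored by repeated-CV mean accuracy under
the caller's plan; ties resolve to the smaller value. The function scores
candidates on whatever cohort it is given — to avoid selection bias, give
it training subjects only and evaluate the chosen triple on fresh data.

## Synthetic cohorts

Subjects are drawn from zero-mean multivariate Gaussians (i.i.d. across
time) whose correlation matrix follows a block model (communities with
`within`/`between` correlations); patient-group perturbations add deltas to
chosen entries, repaired to positive definiteness by eigenvalue flooring at
1e-6 and re-normalization to unit diagonal. Optional i.i.d. measurement
noise of scale `noise_sd` dilutes correlations by `1/(1+noise_sd²)`. The
population Pearson matrix equals the target exactly, so empirical networks
converge to known ground truth (checked at max-abs 0.05 for m = 5000).

Packaged study conditions (chosen once; 20 regions and 170 time points, 40
patients + 40 controls — small enough that the full protocol runs in
minutes on one CPU, large enough for stable CV estimates):

- `separable_scenario`: 4 blocks (within 0.6, between 0.1), six
  between-block edges +0.5 in patients, noise 0.2 — strongly separated.
- `ordinal_perturbation_scenario`: 4 blocks (within 0.4, between 0.05), ten
  same-sign within-block perturbations (eight +0.1, two +0.08), noise 0.2.
  Within a block all target correlations are equal, so population nearest
  neighbors are tied; each perturbation deterministically pulls one partner
  ahead, reordering the k-NN sets while changing any single pairwise
  correlation by at most 0.1.

What the generator does *not* emulate: temporal autocorrelation (the
population correlation of i.i.d. draws is already the target, and no
operation under test depends on spectra), hemodynamics, motion or scanner
artifacts, site effects, and non-Gaussian tails. Passing tests therefore
demonstrate correctness of the algorithms and protocol on planted covariance
structure, not clinical performance on real fMRI.

## Graph topology

Connectivity strength is the mean absolute node strength of the weighted
matrix; the thirteen remaining metrics are computed on the binarized graph
(edge iff `|C_ij| ≥ t`): average degree, density, mean local clustering,
characteristic path length, global and local efficiency, closeness
(`(n−1)/Σ distances`, averaged), mean normalized node and edge betweenness,
radiality (mean of `diameter + 1 − mean distance to others`), degree
assortativity (NaN with a warning for regular graphs), structural
consistency, and the discrete-MLE power-law exponent
`α = 1 + N/Σ ln(d_i/(d_min − 0.5))` with `d_min` the smallest positive
degree (accurate once `d_min` is a few steps above 1, as in dense brain
graphs). Disconnected graphs get path-based metrics on the largest
connected component with a warning. Structural consistency removes a
fraction `p_H = 0.1` of edges, reconstructs the adjacency by first-order
eigen-perturbation of the reduced matrix, and scores the fraction of
removed edges among the equally many top-ranked unobserved links, averaged
over 20 seeded repeats. Group comparison uses Welch's two-sample t-test per
metric with pairwise NaN exclusion.

## Biomarkers

SAC (significant alteration of connectivity) per edge is the absolute
difference of group-mean weights, min-max normalized over edges — the top
edge scores exactly 1 whenever any difference exists — sorted descending
with lexicographic tie-breaks. Region weights accumulate the scores of the
top-30 (configurable) SAC edges incident to each region and are min-max
normalized; only regions incident to those edges are listed. SAC is
symmetric in the group labels. Subnetwork extraction restricts group-mean
matrices to a named region set and reports the difference matrix and mean
subnet strengths.

## Numerical choices and limitations

- k-NN and nearest-neighbor ties break toward smaller indices; SAC ties
  lexicographically; grid-search ties toward smaller parameter values — all
  orderings are deterministic.
- Networks serialize with 17 significant digits, so file round-trips are
  exact to 1e-12.
- Two classes only (patient/control); multi-class KDA is out of scope.
- The triplet network is the more noise-sensitive component by design; on
  cohorts whose group difference is purely pairwise, the best hybrid weight
  tends toward μ = 1, and the search is expected to find that.
- Structural consistency uses dense eigendecomposition (O(n³) per repeat):
  fine for brain-scale n ≤ a few hundred, not for large graphs.
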