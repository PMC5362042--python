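# Methods

## The analysis model

`mfcparc` treats a cortical seed region as a set of `Ns` surface vertices
to be partitioned by their whole-brain connectivity profiles. Two
modalities define those profiles over the `Nw` non-seed target vertices:

* **Functional.** For subject *s* with vertex-by-timepoint matrix `X`,
  `C(i,j) = corr(X_i, X_j)` between seed vertex *i* and target vertex
  *j*, Fisher transformed, `z = arctanh(r)`. Per-subject matrices are
  summed to represent the group; row correlations are invariant to that
  sum-vs-mean choice.
* **Structural covariance.** Thickness at a vertex, concatenated across
  subjects, is the random variable; `C(i,j)` is the cross-subject
  correlation between seed vertex *i* and target vertex *j*, Fisher
  transformed. This is a single group-level matrix — there is no
  per-subject version, and the two modalities deliberately keep separate
  aggregation code paths.

Assumptions: vertex signals are approximately jointly Gaussian (so
Pearson correlation is the right dependency measure and `var(z) ≈
1/(n−3)`), subjects are exchangeable and independent, and connectivity
profiles — not signal amplitudes — carry the anatomical information
(every step is invariant to affine rescaling of a single vertex's data).

## Clustering

* **Ward**: agglomerative minimum-variance on the raw `Ns × Nw` Fisher-z
  rows with Euclidean distance, no dimensionality reduction, cut at `k`.
  Deterministic; backed by `scipy.cluster.hierarchy`.
* **Spectral**: Ng–Jordan–Weiss symmetric-normalised variant. Affinity
  `A_ij = (corr(row_i, row_j)+1)/2` (diagonal set to 1 exactly); embed by
  the `k` leading eigenvectors of `D^(−1/2) A D^(−1/2)`; row-normalise;
  k-means with 50 seeded restarts. Eigenvectors are ordered by descending
  eigenvalue and sign-fixed (first nonzero coordinate positive) so runs
  are reproducible bit-for-bit given the seed. The normalised Laplacian
  was chosen over the unnormalised one as the standard-tutorial default.

Affinities are built from the stored z-valued rows rather than
back-transformed r values: row correlation is nearly invariant under the
monotone arctanh map, and the choice is recorded in output metadata.
Cluster ids are relabelled 1..k by first appearance along the seed-vertex
ordering so output files are stable.

## Model selection

* **Split-half VI** (natural logs, so values are in nats and bounded by
  `ln Ns`): subjects are split into two disjoint halves (sizes differing
  by at most one), each half aggregated and parcellated at every `k`,
  and the two partitions compared; 100 random splits by default.
  "Significant VI change" between adjacent `k` is a paired two-sided
  t-test across the split samples at α = 0.05; a repeat set with
  identical differences (e.g. all zeros) counts as no evidence of change.
  The plateau candidate is the smallest `k` whose VI does not differ
  significantly from `k−1`, scanning from the largest `k`; with real
  planted structure VI typically rises significantly everywhere and no
  plateau exists.
* **Silhouette**: each subject's own matrix is parcellated at every `k`
  and scored by the mean silhouette width of its labels under Euclidean
  distance between connectivity rows (the same representation both
  algorithms cluster); singleton clusters score 0 by convention. The
  selected `k` is the silhouette argmax with exact ties going to the
  smallest `k` — the model with the fewest degrees of freedom.

## Agreement and seed-network statistics

Parcellations are compared after Hungarian matching of cluster labels on
the contingency table (maximising total overlap; ties broken towards the
larger summed per-pair dice, a transpose-symmetric criterion). Dice is
reported per matched pair and as the unweighted mean. Atlas overlap is
cluster-relative: the fraction of a cluster's vertices inside the region
mask.

Whole-brain statistics use region-averaged signals. Functional mode:
per-subject seed-to-region Fisher-z values, one-sample **right-tailed**
t-test per region, Benjamini–Hochberg FDR over regions at α = 0.05
(`statsmodels` implementation; a right tail is used because the analysis
asks for positively coupled regions, and negative-mean regions then
correctly receive p > 0.5). Thickness mode: one group z per region,
significant when `z > 0.4`; the accompanying one-sided p comes from the
null `z ~ Normal(0, 1/√(n−3))`. The published description of this
standard error is written as "1/n−3"; the standard Fisher-z standard
error `1/√(n−3)` is used and the reading documented here. Zero-variance
signals are hard errors, not silent `r = 0`, because they indicate broken
inputs.

## Inter-subject stability

5-fold resampling, 30 repeats: folds are rounded-equal with the remainder
in the last fold (248 subjects → 50/50/50/50/48); per fold the held-in
aggregate (sum of per-subject matrices, or sum of per-group thickness
matrices) is correlated per seed vertex, across the `Nw` targets, with
the held-out aggregate, and the map averaged over all fold × repeat
comparisons. Identical subjects give exactly 1; independent noise gives
≈ 0. Thickness folds need at least 4 subjects each, so small cohorts must
reduce the fold count.

## The synthetic cohort generator

Each of `K` seed clusters has a fingerprint row over `M` target modules
(default: cluster *c* loads 1.0 on module *c* and 0.5 on a secondary
module). Per subject, module latent time courses `g_m(t) ~ N(0,1)` drive
target vertices (`x_j = g_m + σ_f ε`) and seed vertices
(`x_i = Σ_m F[c,m] g_m + σ_f ε`). Thickness replaces the latents with
per-subject scalar factors `f_m ~ N(0,1)` scaled to millimetres by the
factor loading, around per-vertex baselines drawn once from
U(1.5, 4.5) mm; the baseline range affects nothing downstream because
correlations are location- and scale-invariant. ROI masks are all-true
except a declared boundary subset (the last 10% of seed indices), each
flipped off independently per subject with probability `roi_flip_prob` —
mimicking rater disagreement at region edges. All draws come from a
single seeded RNG stream in subject order, so cohorts are bit-reproducible.

Default conditions (also the reference conditions of the acceptance
suite): 40 subjects, `Ns = 120`, `Nw = 400`, `T = 200`, `K = 2`, `M = 4`,
functional noise SD 0.5 per unit-variance latent, thickness loading
0.3 mm with 0.15 mm noise (signal-to-noise 2 in both modalities), ROI
flip probability 0.2. Cluster and module memberships are contiguous
near-equal blocks of the vertex index ranges. Replicate-based checks
(silhouette argmax rate, noise-monotonicity of cross-modal dice) use 20
replicate cohorts of 16 subjects, `Ns = 60`, `Nw = 150`, `T = 100` —
small enough to replicate comfortably while keeping the planted structure
well above the noise floor.

What the generator does **not** emulate: temporal autocorrelation and
hemodynamics, head motion and scanner artifacts, spatial smoothness and
surface geometry, and between-subject heterogeneity of fingerprints.
Passing tests therefore demonstrate correctness of the statistical
machinery on data satisfying its assumptions, not robustness to real
acquisition artifacts; on real data the preprocessing that this package
deliberately excludes (filtering, nuisance regression, surface mapping)
must be done upstream.

## Numerical conventions and degenerate inputs

* Correlations are clipped to `|r| ≤ 1 − 1e−7` before `arctanh`, so exact
  duplicates (and noiseless synthetic data) stay finite; `|r| > 1` beyond
  1e−8 is an input error.
* Probabilistic-ROI retention is inclusive (`counts/n ≥ threshold`), so
  9 of 12 subjects passes a 75% cut.
* VI values within 1e−12 of zero are clamped to exactly 0; one-sample
  t-tests on zero-variance samples return the sign-determined limit
  (±∞, p ∈ {0, 1}, or 0.5 at exact zero) instead of NaN.
* Ward ties are measure-zero on continuous data; a cut that cannot
  produce `k` nonempty clusters raises a numerical error rather than
  silently merging.
* Files store floats with 17 significant digits and are parsed with
  round-trip precision, so write→read→write is byte-identical.

## Known limitations

* Spectral clustering recovers disconnected affinity components exactly,
  but on fully degenerate affinities (all entries equal) any partition is
  acceptable; only determinism is guaranteed.
* The thickness modality has no subject-level matrices, so split-half VI
  and silhouette selection operate on functional inputs (or on half-stack
  thickness matrices for VI); a per-subject thickness silhouette is not
  defined.
* Dice-based comparison requires equal `k` on both sides; comparing
  parcellations of different granularity is out of scope.
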