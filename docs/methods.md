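# Methods

## Model and assumptions

`omifuse` assumes that clinically meaningful patient subtypes manifest as
cluster structure in the Euclidean geometry of z-scored omics features, and
that different omics layers carry that structure to different degrees — per
patient, not only per cohort.  The pipeline has four stages:

1. **Preprocessing.** Per layer, patients with more than 20% missing
   entries are dropped, then features with more than 20% missing entries
   over the surviving patients (both thresholds strict: a fraction exactly
   at 0.2 is kept, patients filtered before features).  Residual missing
   values are imputed with the feature mean of the observed entries —
   after centering, mean imputation places them at 0, the least
   informative value — and each retained feature is centered and divided
   by its population standard deviation (ddof = 0).  Dividing by the
   variance instead is available via `sd_convention="variance"` for
   compatibility with mean/variance-style normalization, but z-scores are
   the default because all downstream distances are Euclidean and expect
   unit-SD features.  Zero-variance features are dropped with a warning.
   Cohorts are intersected: only patients present in every layer (and the
   clinical table, if given) are analyzed.  `shift_rescale` (translate to
   non-negative, divide by the maximum) is provided only for parity with
   non-negative factorization preprocessing and is not part of the
   pipeline.

2. **Affinity.** The scaled-exponential kernel
   `a(i,j) = exp(-d(i,j)^2 / (mu * eps(i,j)))` with the locally adaptive
   bandwidth `eps(i,j) = (mean_Ni d + mean_Nj d + d(i,j))/3`, K = 20
   neighbors and mu = 0.5.  The neighborhood `N_i` excludes patient i
   (a distance-0 self-neighbor would deflate the bandwidth), and neighbor
   ties are broken by patient index so runs are deterministic.  On
   duplicate-heavy data `eps` can vanish off-diagonal; it is floored at
   1e-12 with a warning, which sends duplicate pairs to affinity ~1, the
   sensible limit.  Note that this kernel has the squared distance over a
   bandwidth *linear* in distance, so in high dimension the off-diagonal
   affinities concentrate near zero; the consequences for cluster-count
   selection are discussed below.  Only the kernel is implemented — the
   iterative cross-diffusion of full similarity-network fusion is a
   different method and deliberately out of scope.

3. **Explainability weights.** For layer t and patient i, the within-omics
   prediction is the mean profile of i's k = 20 nearest neighbors in layer
   t; the cross-omics prediction uses the neighbor set found in another
   layer u.  Similarity is `theta_{t,u,i} = exp(-||x - xhat||_2 /
   sigma_{t,i})` with `sigma_{t,i}` the mean distance to i's k nearest
   neighbors in layer t, floored at 1e-12.  The exponent uses the
   unsquared L2 norm (a `squared=True` Gaussian variant is available; the
   ratio/softmax construction is well defined either way).  The ratio
   `s_{t,i} = theta_{t,t,i} / (c_{t,i} + epsilon)` with epsilon = 1e-8
   guards division by zero; with more than two layers the cross term
   `c_{t,i}` is the arithmetic mean of `theta_{t,u,i}` over the other
   layers (pooling the other layers' neighbor sets instead would be a
   reasonable alternative; the mean keeps each layer's contribution
   interpretable and reduces to the two-layer formula exactly).  Weights
   are the plain softmax of the ratios, no temperature; s is clipped at 50
   before exponentiation to avoid overflow, which cannot change the argmax
   and matters only when one weight already saturates in float64.  With a
   single layer the weight is trivially 1.

4. **Fusion and clustering.** The fused matrix `a(i,j) = sum_t w_{t,i}
   a_t(i,j)` uses row i's weights and is therefore asymmetric; it is
   symmetrized as (A + A^T)/2, which equals averaging the (i,j)- and
   (j,i)-weighted values, then min-max normalized over off-diagonal
   entries with the diagonal pinned to 1 (including the unit diagonal in
   the range would compress everything else; both choices are exposed as
   options).  Subtypes come from consensus clustering: `reps = 1000`
   iterations (200 in the test profile), each drawing 80% of patients
   without replacement and cutting an average-linkage dendrogram of the
   1 - a distance at k; the consensus matrix is co-clustering counts over
   co-sampling counts, diagonal 1, never-co-sampled pairs 0 with a
   warning.  Final labels cut an average-linkage tree of 1 - consensus.
   One master seed drives all subsampling; per-k child seeds are derived
   with a seed sequence, so reruns are byte-identical.

## Choice of the cluster count

Candidate counts k = 2..10 (clamped to n - 1) are each consensus-clustered
and scored by mean silhouette; the best k wins, with ties within 1e-12
going to the smaller k, and users may fix k outright.

The silhouette substrate matters more than is obvious.  Because the kernel
concentrates fused similarities into a narrow band in high dimension,
silhouettes computed on the fused 1 - a distance are tiny (~0.005 on the
reference simulation) and nearly flat in k, so the argmax is decided by
consensus sampling noise and k is frequently over-estimated even when the
partition itself is essentially correct.  A consensus-matrix substrate was
also evaluated and rejected: degenerate cuts of pure-noise data (one giant
cluster plus stable singletons) are highly reproducible and score ~0.95,
so it cannot distinguish structure from stable artifacts.  The default
substrate is therefore the concatenated standardized feature matrix, which
selects the true k with a clear margin on signal data and stays near zero
on null data; `silhouette_substrate="integrated"` restores the fused-
distance behavior.

## Validity indices and downstream analyses

Davies-Bouldin and Calinski-Harabasz are computed from their definitions
on the concatenated standardized features (coincident centroids raise an
error naming the cluster pair; zero within-cluster scatter yields an
infinite CHI).  Silhouette, and the log-rank test behind the survival
comparison, delegate to scikit-learn and lifelines respectively.
Signature scores are rank-based (mid-rank percentiles, so ties are well
defined and any monotone per-gene transform leaves scores unchanged): per
gene a percentile rank across samples, per sample the mean rank over the
signature's genes, re-expressed as a percentile across samples.  Drug
recommendation considers inhibitor/antagonist mechanisms only and flags a
target gene as upregulated in a subtype when a two-sided Wilcoxon rank-sum
test of subtype vs rest gives p < 0.05 *and* the subtype median exceeds
the rest's median (the test alone is undirected); p-values are used raw by
default, with the alpha exposed.  Subtype-vs-rest is used rather than all
pairwise contrasts, keeping one decision per (subtype, gene).

## Synthetic cohorts

The generator produces what the pipeline assumes and nothing more: per
layer, an n x p Gaussian noise matrix (noise_sd = 1) on which a
signal_fraction (default 20%) of features carry subtype mean shifts of
signal_strength (default 3) noise-SD units; the informative features are
partitioned one block per subtype, each subtype elevating only its own
block, which gives cleanly separable centroids with a between-centroid
distance that scales the same way in every layer.  Missingness is applied
uniformly at random.  Survival times are exponential with per-subtype
hazards (default geometric spacing from 0.02 to 0.1 per unit time over the
subtypes) censored by an independent exponential whose rate is solved by
bisection so the expected cohort censoring fraction hits the target
(default 20%).  The defaults — 120 patients, 3 equal subtypes, two
200-feature layers — are the reference conditions used by the test suite
and the acceptance script; the test profile lowers consensus reps from
1000 to 200, which changes consensus entries by at most a few percent and
none of the reported decisions.

What the generator does *not* emulate: methylation beta-value
distributions, count overdispersion, feature-feature correlation, batch
effects, or informative (outcome-dependent) missingness.  Passing tests
therefore demonstrate that the machinery is correct and well calibrated on
separable Gaussian structure, not that real cohorts of any particular
cancer type will separate.

## Known limitations

* Kernel affinities underflow toward the min-max floor in very high
  dimension; clustering is unaffected (relative order survives) but the
  fused matrix's absolute values should not be interpreted as
  probabilities.
* The per-patient weights compare neighborhood predictive power, not
  biological importance; a layer can be heavily weighted because it is
  smooth, not because it is causal.
* k selection by silhouette inherits silhouette's bias toward convex,
  balanced clusters.
* The log-rank comparison treats subtypes as fixed groups; it does not
  account for the fact that the labels were estimated from (independent)
  molecular data.
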