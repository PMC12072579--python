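# omifuse

Explainable multi-omics integration and disease subtyping from patient
similarity networks.

Molecular subtyping groups patients by shared biology rather than by
histology, and integrating several omics layers (e.g. mRNA expression, DNA
methylation, miRNA) usually separates clinically distinct groups better
than any single layer.  Most integration methods, however, are black boxes:
they return a partition without saying *which* omics layer drove it for
*which* patient.  `omifuse` is aimed at computational biologists who want
both the subtypes and that attribution.

## Method

Given omics layers indexed by *t* over a shared cohort, each layer is
z-scored per feature and turned into a patient affinity matrix with the
scaled-exponential kernel

```
a_t(i,j) = exp( -d(i,j)^2 / (mu * eps(i,j)) ),
eps(i,j) = ( mean_{l in N_i} d(i,l) + mean_{l in N_j} d(j,l) + d(i,j) ) / 3
```

where `d` is the Euclidean distance and `N_i` the K nearest other patients
(K = 20, mu = 0.5 by default).

The explainability weights come from a weighted-nearest-neighbor argument.
For each layer *t* and patient *i*, the profile `x_{t,i}` is predicted as
the mean of its k nearest neighbors, with the neighborhood taken either in
layer *t* itself (within-omics) or in another layer *u* (cross-omics).
Prediction quality is

```
theta_{t,u,i} = exp( -|| x_{t,i} - xhat_{t,u,i} ||_2 / sigma_{t,i} )
```

with `sigma_{t,i}` the mean distance from *i* to its k nearest neighbors in
layer *t*.  The ratio `s_{t,i} = theta_{t,t,i} / (mean_{u != t}
theta_{t,u,i} + epsilon)` measures how much layer *t*'s own neighborhood
structure explains its profiles beyond what the other layers' neighborhoods
do; a softmax over layers gives per-patient weights `w_{t,i}` summing to 1.

The fused similarity `a(i,j) = sum_t w_{t,i} a_t(i,j)` is symmetrized,
min-max normalized, and consensus-clustered (1000 subsampled average-linkage
hierarchical clusterings at an 80% sampling rate).  The cluster count is
scanned over k = 2..10 and chosen by the mean silhouette of each candidate
partition (computed on the concatenated standardized features by default).
Downstream utilities cover log-rank survival comparison across subtypes,
rank-based gene-signature scoring, and inhibitor/antagonist drug
recommendation from target-gene upregulation.

## Worked example

```python
import omifuse as om
from sklearn.metrics import adjusted_rand_score

spec = om.SimulationSpec(seed=1)          # 120 patients, 3 subtypes, 2 layers
bundle, truth, survival = om.simulate_cohort(spec)
out = om.subtype_cohort(bundle, reps=200, seed=1)

print("chosen k:", out.result.k)
print("ARI vs simulated truth:",
      round(adjusted_rand_score(truth, out.result.labels), 3))
print(out.result.silhouette_by_k.head(4).to_string(index=False))
print(out.result.per_subtype_weight_medians.round(3))

surv = survival.copy()
surv["subtype"] = out.result.labels
chi2, df, p = om.logrank_test(surv)
print(f"log-rank: chi2={chi2:.1f}, df={df}, p={p:.2e}")
```

prints

```
chosen k: 3
ARI vs simulated truth: 1.0
 k  silhouette
 2    0.067710
 3    0.095007
 4    0.071670
 5    0.066046
          mRNA  methylation
subtype
1        0.501        0.499
2        0.501        0.499
3        0.500        0.500
log-rank: chi2=39.6, df=2, p=2.52e-09
```

The silhouette scan peaks at k = 3 and the recovered partition matches the
simulated subtypes exactly (adjusted Rand index 1.0).  Both simulated
layers carry the same signal strength here, so the median omics weights sit
at 0.5 — with an uninformative layer in the mix they shift toward the
informative one.  The three recovered subtypes differ sharply in overall
survival because the simulation ties the event hazard to the subtype.

The same pipeline runs from the shell:

```
omifuse simulate --n-patients 120 --outdir cohort/
omifuse run --layer mRNA=cohort/omics1.tsv --layer methylation=cohort/omics2.tsv \
            --outdir results/
omifuse downstream --labels results/labels.tsv --clinical cohort/clinical.tsv
```

`omifuse run` writes `labels.tsv`, `weights.tsv` (the per-patient
explainability matrix), `integrated_affinity.tsv`, `silhouette_by_k.tsv`,
`metrics.tsv` and a `manifest.json` recording the configuration, seed and
package versions.

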