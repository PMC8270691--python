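# Methods

This note documents the statistical model behind `lupus-ssc`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish about real data.

## Data model and assumptions

The pipeline expects a genes × samples log2 expression matrix and a
per-visit clinical table (patient, time, SLEDAI, disease state,
demographics, drug-exposure flags). Samples are repeated measures:
several visits per patient, visit counts varying across patients.
Healthy controls contribute one sample each and anchor both the
differential screen and the activity reference. Cohort preprocessing
assumes the usual microarray conditions for quantile normalization —
most genes unchanged across samples — and removes patients that cannot
inform a longitudinal analysis: missing records, drug changes during
follow-up, or a SLEDAI that never moves (variance exactly 0 over ≥ 2
visits; single-visit patients are retained since no variance is defined
for them). The discovery/test split is at the patient level, stratified
by cohort, so repeated measures never leak across the split.

## Signature screen

Two filters define the disease-activity signature:

1. *Differential filter.* Per-gene one-way ANOVA between SLE and
   healthy samples, treating samples as independent (a deliberate
   simplification; the longitudinal structure enters through the second
   filter instead). Benjamini–Hochberg FDR, default q < 0.05.
2. *Longitudinal filter.* For each patient with ≥ `min_visits` (default
   3) visits and nonzero SLEDAI variance, the within-patient
   correlation `r_p(g)` between the gene and SLEDAI; by default
   Spearman with average-rank ties, because SLEDAI is an ordinal score
   (Pearson is available by configuration). The score is the weighted
   mean of |r_p| with weights proportional to visit count. Because
   weights sum to one, the score lies in [0, 1], which makes the fixed
   cutoff (score > 0.6, strict) meaningful regardless of cohort size.
   Alternative weightings (uniform, √n) are exposed but
   visit-proportional is the default: a patient observed longer simply
   carries more information about activity coupling.

The permutation null shuffles both gene (row) and sample (column)
labels of the expression matrix each iteration and recomputes all
scores; the add-one estimator `perm_p = (1 + #{null ≥ obs})/(B + 1)`
keeps p-values in (0, 1]. A second calibration draws random
non-differential gene sets of the same size as the differential set and
compares mean scores. Permutation p-values from one matrix share the
same permutations and are therefore weakly dependent across genes; the
uniformity check in the validation suite pools genes across independent
cohort replicates for this reason.

## Subtype discovery and the single-sample classifier

All clustering happens in the standardized signature space: per-gene
z-scores with means and SDs taken from the training samples once (they
are part of the persisted model; the iterative correction does not
re-standardize).

*Number of subtypes.* Three criteria vote: average silhouette width on
PAM partitions, the Calinski–Harabasz index on k-means partitions, and
the gap statistic with a PCA-aligned uniform reference box and the
one-standard-error rule. Two robustness choices matter and were made
after measuring their failure modes: the CH criterion is computed on a
*different* partition family (k-means) than the silhouette (PAM), so
their sampling noise does not move together — otherwise a structureless
data set can win a 2-of-3 majority at spurious k; and silhouette/CH
votes use a parsimony rule (smallest k within 5 % of the best value)
because on null data the criterion profile is flat and a raw argmax is
arbitrary. The gap statistic's reference must respect feature
correlation (PCA-aligned box); the axis-aligned box systematically
overestimates k on module-structured expression data. Majority vote
decides; ties break toward fewer clusters.

*Consensus.* k-medoids (PAM-style Voronoi iteration, k-medoids++
seeding, best of 5 restarts) under Euclidean and correlation (1 − r)
distances plus Ward agglomerative clustering give three base
partitions. Their co-association matrix (fraction of partitions
co-clustering each pair; entries in {0, ⅓, ⅔, 1}) is clustered with
average linkage on 1 − co-association and cut at k.

*Iterative correction.* Alternating nearest-centroid assignment and
centroid recomputation is exactly a k-means refinement of the consensus
labels, so the within-cluster sum of squares is non-increasing — the
package asserts this invariant on every run. Convergence is declared
when < 1 % of labels change (cap 50 iterations). Ties go to the lowest
cluster index; a cluster that empties keeps its previous centroid and
logs a warning.

*Classification.* A new sample is standardized with the training
parameters and assigned to the nearest centroid. The reported
likelihood is softmax(−distance) at unit temperature — a monotone,
normalized surrogate chosen for determinism and simplicity; it is not a
calibrated posterior probability and is documented as such.

*Naming.* Clusters are named from their module activities: "high" in a
module means the cluster's mean activity exceeds the healthy mean plus
two healthy SDs. High in both IFN and NE (bacterial + fungal) modules →
mixed; one only → IFN-high / NE-high; neither, or two clusters mapping
to one name, is an error rather than a silent guess.

*Severity.* SLEDAI is compared across subtypes with Kruskal–Wallis and
BH-adjusted pairwise Wilcoxon rank-sum tests, after optional Tukey
trimming (values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] over all SLE
samples). The Tukey fences stand in for an unspecified density-based
outlier rule; they are conventional, deterministic and scale-free.

## Term activity (GED), profiles, network

Term activity is the mean absolute z-score of the term's genes against
the healthy reference (a signed-mean variant is available). Genes with
zero healthy variance are dropped from all terms; terms with fewer than
3 mapped genes are dropped. When healthy samples themselves are scored,
the reference is leave-one-out and the denominator uses the prediction
SD (σ·√(1 + 1/(n−1))), so a healthy sample's expected activity is E|Z| =
√(2/π) ≈ 0.798 up to the small-sample bias of the estimated SD (≈ +2 %
at n = 40). Patient samples use the plug-in reference.

Module dysregulation Δ is the difference in mean module activity
between a subtype's samples and healthy samples, with a rank-sum test
per (subtype, module) and BH adjustment across the profile. The term
network uses Spearman correlation of term-activity vectors across the
mixed-subtype samples; an edge requires both |r| ≥ 0.6 and BH-adjusted
q < 0.05 from the t-approximation to the rank-correlation test — the
magnitude threshold alone would keep noise edges at small sample
counts, significance alone would keep weak edges at large ones.
Communities come from greedy modularity maximization (deterministic);
bridge terms are ranked by betweenness restricted to shortest paths
(edge length 1/weight) whose endpoints lie in different communities.

## Treatment statistics

Rates are SLEDAI change per month of 30.44 days. Drug benefit is the
difference in mean rates between exposed and unexposed patients within
a subtype (exposure = flag true at every retained visit; preprocessing
removed drug-changers), with rank-sum tests BH-adjusted across the
table. Repositioning attributes each inter-visit interval's rate to the
subtype of the interval's *first* sample, because samples — not
patients — carry subtype labels and a patient may drift between
subtypes under treatment; with equal visit spacing the per-patient mean
interval rate telescopes to (last − first)/total time. Patient-level
analyses (benefit, demographics) use the majority subtype over the
patient's samples, ties resolved by the earliest sample. Fisher's exact
test is exact for 2×2 (hypergeometric tail); r×c tables are enumerated
exactly over all tables with the observed margins when N ≤ 200 (summing
probabilities ≤ that of the observed table), else estimated by seeded
Monte-Carlo over margin-preserving random tables; the method used is
always reported.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
with planted ground truth for recovery testing. Default conditions
(one number each, with rationale):

| parameter | default | meaning |
|---|---|---|
| `n_patients` / `visits_min..max` | 60 / 4–8 | mid-sized longitudinal cohort |
| `n_healthy` | 30 | healthy reference pool |
| `n_genes` | 2 000 | filtered transcriptome scale |
| `effect_size` | 1.5 | log2 module elevation in active subtypes |
| `mixed_boost` | 1.3 | mixed subtype is the most dysregulated in every module |
| `module_factor_rel_sd` | 0.2 | per-sample module activation variability |
| `n_activity_genes` / `activity_cor` | 50 / 0.8 | activity genes and their within-patient \|r\| target |
| `activity_ifn_overlap` / `activity_ne_overlap` | 0.3 / 0.2 | activity genes inside the IFN / NE modules |
| `noise_sd` | 0.5 | per-gene residual SD (log2) |
| `subtype_sledai_mean` | 12 / 9 / 6 | severity ordering mixed > IFN-high > NE-high |
| `sledai_within_sd` / `sledai_between_sd` | 3.0 / 1.5 | visit-to-visit swing / patient baseline spread |
| `visit_interval_days` | 45 ± 5 | observational follow-up cadence |

SLEDAI trajectories are rounded, clipped Gaussians around
subtype-specific means plus drug-specific slopes (score/month) for
exposed patients. Activity genes carry a fixed SLE-vs-healthy offset
(1.0 log2) plus a SLEDAI-tracking term centered at the patient's own
trajectory mean, with the slope calibrated per patient and per gene
group (including module-factor variance) so the realized within-patient
correlation hits `activity_cor` in expectation. Genes inside a planted
module always track positively — module activation and disease
activity pull the same way. Subtype counts use largest-remainder
allocation, so planted proportions are exact.

The trial generator (`generate_trial`, used for repositioning) differs
deliberately: exact monthly visits, all patients treated, and a damped
within-patient SLEDAI swing (SD 0.5) reflecting a controlled trial;
with equal spacing the pooled interval-rate estimator is then precise
enough to resolve per-subtype slopes of order 0.04–0.33 score/month at
6 patients × 6 visits pooled over replicates.

The two-factor term design (`generate_module_factor_design`) emulates
the mixed-subtype population for the network analysis: two per-sample
activation factors (IFN, NE), exactly sample-orthogonal because they
are planted as independent, each shifting its terms' genes, plus one
bridge term carrying genes of both programs. A bridge correlated with
two orthogonal factors is bounded by r ≤ 1/√2 against either side, so
the design uses enough genes per term (24), samples (400) and factor
variance to place the realized bridge correlations (~0.66) safely above
the 0.6 edge threshold.

**What the generator does not emulate:** probe-level structure, batch
effects, the 24 SLEDAI components, dose–response, informative dropout,
or correlated gene–gene noise beyond the module factors. Passing the
recovery suite therefore shows the *algorithms* recover planted
structure under the stated conditions — not that real cohorts satisfy
those conditions.

## Validation problem sizes

The test and acceptance runs use: signature recovery at 5 000 genes ×
60 patients (10 replicates); permutation calibration at 300 genes × 40
patients with 200 permutations (5 replicates, p-values pooled across
replicates for the uniformity test — within one replicate they share
permutations); null FDR at 400 genes (20 replicates); subtype recovery
at ~200 training samples (10 replicates); repositioning at 6 patients ×
6 visits (50 replicates pooled); drug-benefit sign recovery at ~32
patients per exposure cell. These sizes were chosen as the smallest
designs at which the planted effects are statistically resolvable with
comfortable margins.

## Known limitations

* **A purely activity-correlated signature clusters by state, not
  trait.** All signature genes correlate with the same within-patient
  SLEDAI realization, so their leading variance axis is the shared
  disease-activity state (cross-gene within-patient correlation ≈ ρ²).
  On synthetic cohorts, where that axis is independent of the subtype
  programs, k-selection on the *screened* signature returns 2 (activity
  high vs low) and subtype recovery degrades. The classifier is
  therefore trained on the module panel (planted module genes excluding
  activity trackers; `simulate.module_panel`, or `train-ssc --genes`),
  and the screen is validated by its own recovery criteria. In real
  cohorts the two axes are partially aligned — module activation *is*
  how disease activity manifests in IFN/NE-driven patients — which the
  generator's independence assumption does not capture.
* The assignment "likelihood" is an uncalibrated softmax surrogate.
* The exposed/unexposed benefit contrast inherits all confounding of
  combination therapy; no adjustment is attempted beyond subtype
  stratification.
* Exact Fisher enumeration grows quickly with table totals; beyond
  N = 200 the seeded Monte-Carlo answer carries ~1/√B error.
* Quantile normalization assumes mostly-invariant distributions; on
  cohorts where a large fraction of genes is perturbed (as in
  deliberately small simulations) it attenuates longitudinal
  correlations of strongly shifted genes.
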