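# Methods

## Scope and model of the data

`airmic` analyses a two-group (smoker vs nonsmoker) survey of
upper-airway bacterial communities: a samples × taxa integer count
table from 16S rRNA OTU profiling, a rooted phylogeny with branch
lengths over those taxa, and per-sample metadata (subject, site ∈
{nasopharynx, oropharynx}, side ∈ {left, right}, group, time index).
The pipeline begins at the count table and tree; sequence-level
processing (denoising, OTU picking, taxonomy assignment, tree
inference) is upstream and out of scope.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning; every stage logs and records its
seed, and a rerun with the same config is byte-identical.

## Synthetic studies

Because analyses of this kind are usually validated on data with known
truth, the package ships a first-class generator
(`airmic.simulate`) that emulates the target study design:

* **Design defaults** — 33 + 29 subjects; 4 samples per subject
  (2 sites × 2 sides) at time 0; 1 nonsmoker and 5 smokers re-sampled
  at a second timepoint; sequencing depth drawn as
  `round(max(100, Normal(1335, 603)))`; 200 taxa in 40 genera.
* **Phylogeny** — a pure-birth (Yule) topology with i.i.d. exponential
  branch lengths (mean 0.1, arbitrary units). Taxonomy is
  tree-consistent: phyla, families and genera are monophyletic clades
  obtained by repeatedly splitting the largest frontier clade; ~5% of
  taxa have their genus blanked to exercise the unclassified-pooling
  path.
* **Hierarchical Dirichlet-multinomial counts** — per site a baseline
  simplex from normalised log-normal weights (sigma 2.0 nasopharynx,
  1.2 oropharynx, making the oropharynx the more even, higher-Shannon
  site); smoker means are the baseline with planted genus effects
  multiplied by `2^log2FC` and renormalised; subject compositions
  ~ Dirichlet(θ_group · mean) with θ = 60 (nonsmoker) and 20 (smoker)
  so the smoker group is more dispersed; side/time replicates
  ~ Dirichlet(θ_rep · subject) with θ_rep = 400 giving left/right
  correlation near 1; counts are multinomial at the drawn depth.
* **Planted effects** — by default 5 genera per site with |log2 FC| in
  [0.5, 1.5] and alternating signs, chosen among genera with ≥1%
  baseline abundance (configurable `min_effect_abundance`). Effects
  are applied to the group mean before subject sampling so
  fold-difference recovery is well defined against the recorded
  ground truth. Rationale for the abundance floor: with
  between-subject Dirichlet noise at θ≈50 the sampling CV of a genus
  with mean abundance m is ≈ `sqrt((1−m)/(m(θ+1)))`, so a 2-fold
  change in a 0.1% genus is ~2 CVs of noise *per subject* and
  undetectable at n≈30/group; smoking-associated families reported in
  airway surveys are abundant lineages. The recovery calibration
  plants its effects on ≥3% genera for the same reason.
* **Optional contaminants** — three designated taxa can be mixed into
  every sample at a fixed fraction, emulating the sterile-swab
  background lineages seen in such surveys, so tests can confirm the
  group comparisons are robust to shared background.

What the generator does *not* emulate: PCR/primer bias, chimeras,
read-level error, gender imbalance between groups, and taxon-taxon
correlations beyond the compositional constraint. Passing tests
therefore demonstrate correctness and calibration of the *statistics*
under a standard microbiome noise model, not performance on any real
data set.

## Beta diversity

Unweighted UniFrac is `Σ l_b [branch b observed in exactly one
community] / Σ l_b [branch observed in either]`. Weighted UniFrac is
`W = Σ_b l_b |A_b/A_T − B_b/B_T|`, with the normalised variant
dividing by `D = Σ_tips d_j (A_j/A_T + B_j/B_T)`.

Root handling: branches at or above the lowest common ancestor of the
pair's observed tips are excluded (numerator and denominator), so
disjoint clades score exactly 1 under the unweighted metric; the
normalised-weighted tip depths `d_j` are measured from that same LCA.
Identical communities score exactly 0 under both metrics, and both are
invariant to child order; the unweighted metric ignores count
magnitudes and the weighted metric is invariant to rescaling one
sample's counts. Taxa present in the table but absent from the tree
are a hard error rather than a silent drop.

A note on a subtle conservation property: collapsing a cherry whose
two tips have identical per-sample profiles conserves the unweighted
metric only if the merged branch carries the *sum* of the parallel tip
lengths (stem + l_A + l_B), but conserves the weighted metric with the
abundance-weighted *mean* (stem + (l_A + l_B)/2) — no single merged
length preserves both. The test suite checks each metric against its
conserving merge.

The all-pairs matrix is computed by propagating counts up a flat edge
table (edge × taxon incidence matrix), turning the pairwise sums into
matrix products; results match the per-pair functions and an
independent brute-force branch-classification oracle to 1e-12.

PCoA applies Gower double-centering to −½d², takes the symmetric
eigendecomposition, and scales eigenvectors by √eigenvalue. Negative
eigenvalues (non-Euclidean input) are reported but excluded from
coordinates and from the proportion-explained denominator. Axis order
is by decreasing eigenvalue with stable tie-breaks and the sign of
each axis fixed by making its largest-magnitude loading positive, so
ordinations reproduce across runs.

## Distance-based permutation tests

All three tests share one engine: the observed statistic, `n_perm`
label permutations recomputed vectorially, and the add-one p-value
`p = (1 + #{T* at least as extreme}) / (1 + n_perm)`, which respects
the floor `1/(n_perm+1)` and never reports 0. Extremeness uses a
relative 1e-12 tolerance so exact ties (e.g. all-equal distances)
count as extreme. When any subject contributes more than one sample to
a matrix, permutation exchanges subjects, not samples, preserving
within-subject dependence.

* *Within-group* (dispersion): `T = mean d(i,j) within G1 − within
  G2`; two-sided by default with the direction (which group is more
  dispersed) always reported.
* *Within-vs-between* (membership): `T = mean between − mean within
  (pooled)`; one-sided (greater), since separation implies positive T.
* *PERMANOVA*: `SS_total = (1/n)Σ_{i<j} d²`, `SS_within = Σ_g (1/n_g)
  Σ_{i<j∈g} d²`, `pseudo-F = (SS_between/(k−1))/(SS_within/(n−k))`.
  On Euclidean distances of 1-D data this equals the classical one-way
  ANOVA F to 1e-10 (tested), and the pseudo-F matches
  scikit-bio's PERMANOVA as an independent cross-check.
* *Temporal stability*: `T = mean between-subject − mean
  within-subject (across time)` with subject assignment permuted;
  requires ≥2 subjects with ≥2 timepoints.

Calibration: on 1,000 exchangeable null data sets (20 samples/group,
1,000 permutations) each test's empirical type-I error lies in
[0.03, 0.07] at α = 0.05 (acceptance suite). Power: with a 4-fold θ
ratio at 30 subjects/group and depth 1,000, the within-group test
detects the dispersion difference in ≥80% of simulations, always with
the correct direction.

## Alpha diversity

Samples are rarefied to a common depth (default 800 reads) by uniform
subsampling without replacement (`multivariate_hypergeometric`);
samples below the depth are flagged and excluded from comparisons,
with counts logged. Estimates are means over 10 independent rarefaction
draws — the analysis is equally available single-draw, and the choice
is recorded per run; averaging only reduces subsampling variance.
Chao1 uses the classic `S_obs + F1²/(2F2)` with the bias-corrected
`S_obs + F1(F1−1)/(2(F2+1))` when F2 = 0 (the classic form is undefined
there) and returns `S_obs` when F1 = 0. Shannon uses the natural log
by default with an exact base conversion option. Site comparisons
pair the two sites within subject (signed-rank); group comparisons are
unpaired two-sided rank-sum per (site, side) stratum; comparisons use
time 0 only, avoiding pseudo-replication from repeat sampling.

## Taxa association

Counts are aggregated to genus or family by summing identical lineage
prefixes; taxa unassigned at the target rank pool into one
`unclassified-<parent>` bin per parent, conserving per-sample totals
exactly. "Detected" means count ≥ 1 after aggregation, before any
rarefaction (the rule concerns detectability, which subsampling would
distort).

The test for each taxon is chosen by detection prevalence: abundance
tests (two-sided rank-sum, or signed-rank for the paired site
contrast) require detection in *more than half* the samples of every
level — exactly half falls to the presence/absence branch (Fisher's
exact, or exact McNemar as a binomial test on discordant pairs).
Abundance tests run on per-sample relative abundances; exact variants
are used for the 2×2 tests throughout, and scipy's rank tests apply
normal approximation with tie correction at the usual sample-size
thresholds.

Fold differences are ratios of pooled (group-summed, normalised)
abundances; with both groups non-zero the ratio is exact and exactly
reciprocal under label swap, and a zero pooled abundance is
regularised with ε = half the smallest non-zero pooled relative
abundance in the stratum, keeping ratios finite. Bonferroni multiplies
by the number of taxa tested in the stratum, capped at 1. The paired
site contrast averages each subject's left/right relative abundances
per site before pairing and reports nasopharynx/oropharynx fold
ratios.

## Classification harness

Features are per-sample genus relative abundances, filtered at the
configured stratum abundance threshold (0.2% by default; switchable
off). Each of the (default 500, reduced-profile 100) iterations draws
a training set of the original size with replacement, validates on the
never-drawn samples (~36.8% on average), and records the forest's and
the majority-class baseline's misclassification fractions; degenerate
draws (empty validation or single-class training) are redrawn and
logged. The forest uses the standard library implementation: default
500 trees, 20 candidate features per split (capped at the feature
count), trees grown to purity. Median accuracy over iterations is the
headline number; a whole-data forest's out-of-bag score is reported
alongside, with the bootstrap-validation estimate primary. Mean Gini
(mean decrease in impurity) importances are averaged over iterations
to rank genera.

The model-vs-guess comparison is a Friedman rank-sum test with blocks
= iterations and two treatments, using midranks and the standard tie
correction; all-tied input is defined as statistic 0, p = 1. For two
untied treatments the statistic reduces to `(n − 2w)²/n` (w = blocks
where the model wins), which the tests verify. A percentile bootstrap
95% CI of the mean paired error difference is reported.

## Cluster support

Leaves are (site, side, group) stratum-mean genus profiles (8 in the
full design). Genera pass the filter when their stratum-mean relative
abundance exceeds the threshold in ≥1 stratum. Profiles use relative
abundances by default — raw library-size differences would otherwise
dominate the Euclidean distances — with a counts mode available.
Complete-linkage clustering of Euclidean distances; support for each
internal node is the percentage of bootstrap replicates (subjects
resampled with replacement within each stratum, profiles rebuilt,
tree rebuilt) whose clustering contains the same leaf bipartition
(cluster or complement). The dendrogram exports as Newick with support
values on internal nodes.

## Numerical and degenerate-input policy

Zero-total samples are dropped with a warning at load. Both-empty
sample pairs are an error in distance computation; identical samples
give exactly 0. Dirichlet draws use gamma variates, so taxa with zero
concentration stay exactly absent and underflow falls back to the
normalised mean. Permutation p-values use a relative 1e-12 tie
tolerance. PCoA's positive-eigenvalue cutoff is 1e-10 relative to the
spectral magnitude. The signed-rank test on all-zero differences and
McNemar with no discordant pairs return p = 1 by definition.

## Reduced profiles and problem sizes

The paper-faithful profile (10,000 permutations, 1,000 cluster
bootstraps, 500 × 500-tree forest iterations) is the default config.
Routine runs and the acceptance script use a reduced profile — 1,000–
2,000 permutations, 200–500 bootstraps, 100 iterations of 100 trees —
and the test suite uses smaller synthetic designs (7–30 subjects per
group, 50–100 taxa); these sizes are the package's own choice of
desk-scale problem sizes and are recorded in each run's config
snapshot. Monte-Carlo calibration suites state their sizes in the test
docstrings (e.g. 1,000 null data sets for type-I error, 200 for
dispersion power, 50 for fold-change recovery).

## Known limitations

* The generator's dispersion knob is a single Dirichlet concentration
  per group; real smoker heterogeneity may be structured (subgroups),
  which a scalar θ cannot express.
* Fold-difference recovery is defined against group *mean*
  compositions; per-subject effect heterogeneity is not modelled.
* The univariate tests do not adjust for covariates (e.g. gender
  imbalance between groups) and use Bonferroni only; no FDR option.
* PERMDISP-style distance-to-centroid dispersion testing is not
  implemented — the within-group mean-distance statistic is the
  dispersion test here.
* BIOM support is limited to plain TSV/JSON-style tables; HDF5 BIOM
  dialects are out of scope.
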