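# Methods

## The abundance model

A sample's read-mapping table splits into unique counts U (gene → reads
mapping only there) and multi-read groups (gene set S of size ≥ 2 → reads
whose candidate set is exactly S).  The redistribution engine assigns each
multi-read group's mass to its candidates in proportion to their unique
abundance Ab(U) = U/L and divides by gene length, then normalizes the sample
to a relative-abundance vector Ab(G).  Two numerical choices matter:

- **Degenerate groups.**  When every candidate of a group has Ab(U) = 0 there
  is no proportionality signal; the reads are split equally among candidates
  rather than dropped, so per-sample mass is conserved.  These events are
  logged at debug level.
- **Scale invariance.**  Ab(G) depends only on count ratios; multiplying all
  counts by a constant leaves the profile unchanged (property-tested).

The engine is verified to 1e-12 against an independent oracle that splits
every multi-mapped read one at a time.

Aggregated (taxon/KO) profiles sum member-gene abundances and are **not**
renormalized: the unannotated remainder is real mass, and row sums ≤ 1 keep
aggregation monotone.  The prevalence filter keeps features detected
(Ab(G) > 0) in at least ⌈fraction × n⌉ samples, default 10%, without
renormalizing.

Taxonomy from homology hit tables: hits below 70% coverage or 65% identity
are discarded; a hit votes at a rank only if its identity exceeds the rank
threshold (>65% phylum, >85% genus, >95% species); a rank is assigned to the
taxon with ≥ 50% of the votes and an exact top tie yields no assignment (a
tie is not a consensus); child ranks are blanked when the parent is
unassigned so emitted lineages are always consistent.

## Diversity, PERMANOVA and enterotypes

- **Chao2** uses the bias-corrected incidence form
  S_obs + q1(q1−1)/(2(q2+1)) by default (defined at q2 = 0); the classic
  q1²/(2q2) form is available by flag.  Rarefaction draws k samples with
  replacement, 100 times per k; Chao2 needs ≥ 2 incidence rows, so the k = 1
  point reports mean observed richness.  The mean curve is *not* monotone at
  small k: with q2 ≈ 0 the correction term overshoots and decays, which is a
  property of the estimator, not noise (tests assert monotonicity past this
  transient only).
- **Shannon** uses the natural log (the base only rescales, and all group
  comparisons are rank-based).
- **PERMANOVA** follows the Gower-centered inner-product formulation
  G = −½ J D² J with a hat-matrix pseudo-F, which handles categorical
  covariates (where it reduces to the classic among/within partition and
  matches scikit-bio's statistic exactly — used as a cross-check in tests)
  and continuous covariates with the same code path.  P-values use the
  (1 + exceedances)/(1 + n_perm) convention, so P ≥ 1/(n_perm+1) and the
  test is exact-level; type-I error is calibrated to 0.05 by simulation.
  The headline setting is 9999 permutations; simulations in the test suite
  use 999 to keep calibration runs at 200 datasets tractable.
- **Enterotyping** runs PAM (greedy BUILD + full SWAP passes on the
  precomputed distance matrix) for k = 2..6 on the root Jensen–Shannon
  distance of genus profiles (Bray–Curtis by flag) and picks k by the
  Calinski–Harabasz index.  CH is computed on the PCoA embedding of the same
  distance matrix: distance-only CH variants differ across the literature,
  and the embedding version is the common enterotyping practice.  Group
  balance across enterotypes is tested by Fisher's exact test (collapsing to
  largest-vs-rest above 2 clusters).

## Differential testing

Per-feature two-sided Wilcoxon rank-sum (scipy's exact method for small
tie-free groups, tie-corrected normal approximation otherwise; verified
against full label enumeration at n ≤ 8 per group).  BH adjustment is applied
across all features of one annotation level — genes, species and KOs each
form their own FDR family.  Direction is the group with the higher mean rank;
constant features are recorded with P = 1 and no direction, not dropped.
Zero-inflated features are tested as-is (rank tests tolerate zeros; no
pseudocount).  Replication between cohorts requires significance with the
same direction in both; the validation arm can be held to a raw-P criterion
(smaller validation cohorts rarely clear a per-level FDR bar, so the driver
uses q < 0.05 in discovery and P < 0.05 in validation).

## Reporter scores

KO-level two-sided P-values become signed Z-scores, Z = Φ⁻¹(1 − p/2) with the
sign of the enrichment direction, so a single score carries direction and the
significance rule |score| > 1.65 reads as one-sided 95% per tail.  P = 1 maps
to Z = 0; zero P-values are clipped to the float minimum with a warning
(Φ⁻¹ is evaluated via the survival function, so clipped values stay finite).
A pathway's raw statistic is ΣZ/√k over its k scored members; the reported
score standardizes this against the mean and SD of 1000 random size-k subsets
of the scored-KO universe (all KOs with a computed P in the dataset).  Under
a global null the corrected scores are ≈ N(0,1) and the fraction of pathways
exceeding +1.65 calibrates to ~5% (verified over 50 simulated datasets).

## Tripartite associations

For a species (or clinical index) against a pathway: Spearman ρ against every
KO, then median(in-pathway ρ) − median(out-of-pathway ρ), with a two-sided
Wilcoxon P between the two ρ sets.  The background subtraction removes global
shifts of the ρ distribution (e.g. compositional coupling), which is tested
as an invariance property.  BH families follow the association families:
all species × pathway cells together, species × clinical per index, and all
pathway × clinical cells.  Pathways with fewer than 2 scored KOs are reported
unscored.  Partial Spearman is Pearson correlation of rank vectors
residualized on the covariate's ranks (with intercept), P by t with n − 3 df;
it matches pingouin's implementation to 1e-10 (cross-checked in tests) and
falls back to plain Spearman with a warning when the covariate is constant.

## Classifier

Candidates are the top differentially abundant genes (default 100), ordered
by q, then P, then the larger mean-rank gap.  The error curve uses stratified
10-fold CV with five independent trials; within each training fold genes are
ranked by random-forest mean-decrease-in-impurity importance and forests are
refit on the top-m genes for every m (ranking once per trial on all data is
available by flag, at the cost of selection leakage).  The selection cutoff
is min(mean curve) + between-trial SD at that minimum; the smallest m whose
mean error lies below the cutoff wins, with a 1e-9 tolerance so an error
exactly at the cutoff (to machine precision) counts as below — without it the
rule's answer would depend on float rounding of the cutoff sum.  The final
forest (500 trees by default) trains on the full discovery cohort over the
selected genes; AUC uses the rank (Mann–Whitney) formulation, exact against
brute-force pair counting including tie credit.

## The synthetic cohort generator

The generator emulates what the analysis needs from real data, with known
ground truth:

- **Species abundances** are log-normal per sample (per-species location
  drawn N(0, 1.5), within-species spread σ = 1) renormalized to the simplex.
  Case samples shift planted species by a signed log2 effect before
  renormalization.
- **Reads** are multinomial over genes with weight species abundance × gene
  length.  A configurable fraction of reads on paralog-family genes (families
  span ≥ 2 species by construction) is emitted as multi-read groups over the
  family, so N in the redistribution engine is the family size.  Per-sample
  unique + multi reads always sum to the designed depth.
- **Clinical indices** are intercept + Σ coef × log10(abundance + 1e−6) +
  Gaussian noise (the pseudocount avoids −∞ for absent species; Gaussian
  noise is adequate because downstream analysis uses ranks only).  The stock
  design wires SUA negatively to two control-enriched species and CRP
  positively to two case-enriched ones, with intercepts and spreads on the
  scale of routine serum chemistry.
- **Longitudinal follow-up** moves case compositions linearly toward the
  control centroid by a nondecreasing fraction per timepoint, then
  regenerates reads.
- **Community types** (for enterotype tests) raise one driver genus per type
  by a fixed log separation.

**Power under the default law.**  With σ = 1, a log2 effect of 1 is a 0.69σ
location shift; at n = 40/40 the rank-sum statistic sits near z ≈ 3 while a
BH-adjusted threshold demands z ≈ 2.5–3.2, so detection probability is only
~0.5–0.7 (less after compositional renormalization).  Planted effects of
log2 ≥ 1.5 are detected essentially always; recovery claims in the tests are
therefore stated for effects ≥ 1.5, and the differential-stage sensitivity
benchmark uses an independent feature-level simulation (log-normal features,
σ = 0.7, 50 true effects drawn U[1,2] log2 units among 1000 features) whose
a-priori power exceeds 0.9 at the weakest planted effect.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: no sequence-level error or alignment ambiguity beyond
the paralog-family construction; mapping rate is 100% of emitted reads;
species co-occurrence structure is independent log-normal rather than
ecological networks; clinical indices depend on the microbiome only through
the explicit linear model; library-size variation is a single fixed depth.

## Problem sizes

The analysis drivers run a discovery cohort of 40 + 40 samples (validation
15 + 15) over a 2000-gene, 50-species, 200-KO catalog at 20k reads per
sample, downsampled to a common 15k matched reads — a deliberate desk-scale
study that keeps every stage's statistical behavior visible while running in
minutes.  The test-suite and verification-script simulations state their
sizes inline (200 null datasets at 999 permutations for PERMANOVA
calibration, 20-seed planted-truth runs for the differential and tripartite
stages, 50-seed reporter calibration, 10-seed enterotype recovery); CV
forests in tests use 15–200 trees, with 500 the library default for final
models.

## Known limitations

- The exact semantics of a tied taxonomic consensus is a convention
  (unassigned here); pipelines that break ties lexicographically will assign
  more genes at species rank.
- PERMANOVA covariates are single-factor; no sequential (type-I SS)
  multi-factor partitioning.
- PAM is exact but O(n²k) per SWAP pass; enterotyping beyond a few thousand
  samples would need a faster k-medoids.
- The reporter background resamples KO sets ignoring inter-KO correlation;
  strongly co-abundant pathways inherit slightly anti-conservative scores,
  which the permutation-free 1.65 cutoff does not correct.
- Replication and candidate-gene ordering assume the two cohorts share the
  feature namespace (same catalog), as in a fixed-reference pipeline.
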