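# goutmeta

Case-control analysis of gut metagenomes, built around the question of how a
disease like gout reshapes the gut microbiome: which taxa shift, which gene
functions follow, how both couple to clinical chemistry (serum uric acid,
C-reactive protein, creatinine), and whether a handful of microbial genes can
classify patients.  The package implements the full analysis chain on
gene-catalog read counts and ships a synthetic cohort generator with planted
ground truth, so every stage is testable without sequencing data.

## What it computes

**Gene abundance with multi-mapped read redistribution.**  For each sample,
reads mapping uniquely to gene *i* give Ab(U)ᵢ = Uᵢ/Lᵢ (Lᵢ the gene length in
bp).  A read whose candidate set is the gene set *S* is split across *S* in
proportion to the members' unique abundance, Coᵢ = Ab(U)ᵢ / Σ_{j∈S} Ab(U)ⱼ,
contributing Coᵢ/Lᵢ to gene *i*; the relative abundance is

    Ab(G)ᵢ = (Ab(U)ᵢ + Ab(M)ᵢ) / Σⱼ (Ab(U)ⱼ + Ab(M)ⱼ).

Gene profiles aggregate to phylum/genus/species/KO level via the catalog's
lineage and KO maps (taxonomy from homology hits with rank-specific identity
thresholds and a ≥50% consensus rule).

**Diversity and community structure.**  Chao2 incidence richness with
bootstrap rarefaction, Shannon index, Bray–Curtis distances, PCA/PCoA,
a permutation PERMANOVA (categorical or continuous covariates), and
enterotyping by PAM clustering of genus profiles with the Calinski–Harabasz
index choosing k.

**Differential abundance.**  Two-sided Wilcoxon rank-sum per feature with
Benjamini–Hochberg control per annotation level; enrichment direction by the
higher mean rank; paired signed-rank tests for longitudinal contrasts;
discovery/validation replication calls.

**Reporter-score pathway enrichment.**  Each KO's P becomes a signed
Z = Φ⁻¹(1 − p/2); a pathway with k scored KOs gets Z_pw = ΣZ/√k, standardized
against random same-size KO sets; |score| > 1.65 (the one-sided 95% normal
quantile) flags enrichment.

**Tripartite associations.**  Species × pathway strength is the median
Spearman ρ between the species and in-pathway KOs minus the median ρ against
all out-of-pathway KOs (the background), tested by Wilcoxon between the two ρ
sets; species × clinical links use plain Spearman and a BMI-adjusted partial
Spearman; pathway × clinical uses the same background-corrected machinery.

**Gene classifier.**  Top differentially abundant genes feed a random forest;
five trials of 10-fold cross-validation trace error vs number of
top-importance genes; the smallest gene set whose mean error falls below
min(curve) + SD-at-the-minimum is selected, and performance is reported as
ROC/AUC on training and held-out cohorts.

## Worked example

The numbered drivers under `analysis/` run a complete synthetic study
(discovery cohort 40 cases / 40 controls, validation 15/15, 2000-gene
catalog, 50 species, 200 KOs, 20k reads per sample with 10% multi-mapped):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_build_profiles.py
python analysis/03_diversity_enterotypes.py
...
python analysis/08_longitudinal_recovery.py
```

Representative output (driver 03, 04, 07 and 08):

```
B/F ratio: case median 1.094 vs control 0.445 (P=0.00157)
Bray-Curtis: between-group mean 0.5121 vs within 0.4775 (P=4.74e-13)
PERMANOVA disease: R2=0.0792 P=0.0003
discovery species: 6 of 49 features at q<0.05
replication: 3 of 6 discovery species validated in the validation cohort (raw P<0.05, same direction)
feature selection: m=12 gene(s): ['gene_000941', ...]
AUC: discovery (training) 1.000; validation (held out) 0.776
24W: mean paired Bray-Curtis from own baseline 0.3073 (recovery fraction 0.8)
```

Reading this: cases and controls differ at the community level (PERMANOVA on
disease status is the strongest factor tested), the planted species shifts
are recovered and partially replicate in the smaller validation arm, a
12-gene forest generalizes to held-out samples, and the longitudinal
generator's staged recovery shows up as growing within-person Bray–Curtis
displacement from baseline.

The same stages are scriptable on your own tables via the CLI
(`goutmeta synth|profile|diversity|differential|reporter|tripartite|classify|run`);
inputs are plain TSV/GMT files.

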