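"""Synthetic gene catalogs, case-control cohorts and clinical tables.

Every downstream stage is exercised on data from this module, with planted,
known ground truth: species relative abundances are compositional log-normal,
case samples carry log2-fold shifts on a chosen set of species, reads are
assigned multinomially to genes (weighted by species abundance x gene length)
with a configurable fraction emitted as multi-mapped groups over paralog
families, and clinical indices are noisy linear functions of log species
abundance.  All generation is driven by ``numpy.random.default_rng`` seeds and
is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import GeneCatalog, empty_catalog
from .profiling import ReadMapSample

__all__ = [
    "PlantedEffect",
    "ClinicalIndexModel",
    "CohortDesign",
    "Cohort",
    "generate_catalog",
    "generate_cohort",
    "generate_clinical",
    "generate_longitudinal",
    "generate_community_types",
    "default_design",
]

PSEUDOCOUNT = 1e-6  # floor for log10 species abundance in the clinical model

# phylum name pool; the first entries use real phylum names so that e.g. the
# Bacteroidetes/Firmicutes ratio is computable on synthetic output
PHYLUM_NAMES = ["Bacteroidetes", "Firmicutes", "Proteobacteria", "Actinobacteria", "Fusobacteria"]


@dataclass(frozen=True)
class PlantedEffect:
    """A species-level case/control shift: |log2_effect| in log2 units,
    direction 'case' (enriched in cases) or 'control'."""

    species: str
    log2_effect: float
    direction: str = "case"

    @property
    def signed_log2(self) -> float:
        if self.direction not in ("case", "control"):
            raise ValueError(f"direction must be 'case' or 'control': {self.direction!r}")
        return self.log2_effect if self.direction == "case" else -self.log2_effect


@dataclass(frozen=True)
class ClinicalIndexModel:
    """index = intercept + sum coef * log10(abundance + 1e-6) + N(0, sd)."""

    intercept: float
    coefficients: dict[str, float]
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be > 0")


@dataclass
class CohortDesign:
    n_case: int
    n_control: int
    planted: list[PlantedEffect] = field(default_factory=list)
    depth: int = 50_000
    multiread_rate: float = 0.10
    clinical_model: dict[str, ClinicalIndexModel] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.multiread_rate < 1):
            raise ValueError("multiread_rate must be in [0, 1)")


@dataclass
class Cohort:
    """A generated cohort: read-map samples, labels, and ground truth."""

    samples: list[ReadMapSample]
    labels: pd.Series  # sample_id -> 'case' | 'control'
    ground_truth: pd.DataFrame  # samples x species relative abundance
    species_mu: pd.Series  # per-species log-normal location used


def generate_catalog(
    n_genes: int,
    n_species: int,
    n_kos: int,
    paralog_family_size: dict | None = None,
    seed: int = 0,
    ko_fraction: float = 0.7,
    pathway_size_range: tuple[int, int] = (5, 15),
) -> tuple[GeneCatalog, dict[str, list[str]]]:
    """Random gene catalog plus a GMT-style pathway -> KO-list map.

    Every species owns at least one gene; a ``paralog_family_size['fraction']``
    share of genes is grouped into families of 2..``max_size`` genes spanning
    at least two species (these attract the multi-mapped reads); a
    ``ko_fraction`` share of genes carries a KO id; KOs are grouped into
    pathways of 5-15 members.
    """
    if n_genes < 0 or n_species < 0 or n_kos < 0:
        raise ValueError("counts must be nonnegative")
    if n_genes == 0:
        return empty_catalog(), {}
    if n_genes < n_species:
        raise ValueError("need n_genes >= n_species")
    if n_species < 1:
        raise ValueError("need at least one species for a nonempty catalog")
    rng = np.random.default_rng(seed)

    # lineage scaffolding: species nested in genera nested in phyla
    n_genera = max(1, n_species // 3)
    n_phyla = min(max(2, n_species // 10), len(PHYLUM_NAMES)) if n_species > 1 else 1
    phyla = PHYLUM_NAMES[:n_phyla]
    genus_names = [f"Genus_{i + 1:03d}" for i in range(n_genera)]
    genus_phylum = {g: phyla[i % n_phyla] for i, g in enumerate(genus_names)}
    species_names = [f"Species_{i + 1:04d}" for i in range(n_species)]
    species_genus = {s: genus_names[i % n_genera] for i, s in enumerate(species_names)}

    # gene -> species: one guaranteed gene per species, remainder by weighted draw
    richness = rng.lognormal(0.0, 1.0, size=n_species)
    owner = list(range(n_species)) + list(
        rng.choice(n_species, size=n_genes - n_species, p=richness / richness.sum())
    )
    owner = np.asarray(owner)

    gene_ids = [f"gene_{i + 1:06d}" for i in range(n_genes)]
    lengths = np.clip(rng.lognormal(np.log(750.0), 0.5, size=n_genes), 100, 5000).astype(int)

    species_col = [species_names[o] for o in owner]
    genus_col = [species_genus[s] for s in species_col]
    phylum_col = [genus_phylum[g] for g in genus_col]

    ko_col = np.array([""] * n_genes, dtype=object)
    if n_kos > 0 and ko_fraction > 0:
        ko_names = [f"K{i + 1:05d}" for i in range(n_kos)]
        n_with_ko = int(round(ko_fraction * n_genes))
        chosen = rng.choice(n_genes, size=n_with_ko, replace=False)
        ko_col[chosen] = rng.choice(ko_names, size=n_with_ko)
    else:
        ko_names = []

    # paralog families: sample member genes from distinct species
    spec = {"fraction": 0.10, "min_size": 2, "max_size": 4}
    if paralog_family_size:
        spec.update(paralog_family_size)
    family_col = np.array([""] * n_genes, dtype=object)
    families: list[tuple[str, ...]] = []
    if spec["fraction"] > 0 and n_species >= 2:
        target = int(spec["fraction"] * n_genes)
        free = list(rng.permutation(n_genes))
        placed = 0
        fam_i = 0
        while placed < target and len(free) >= 2:
            size = int(rng.integers(spec["min_size"], spec["max_size"] + 1))
            size = min(size, len(free))
            # greedily pick genes from distinct species
            members, seen_species = [], set()
            rest = []
            for g in free:
                if len(members) == size:
                    rest.append(g)
                elif species_col[g] not in seen_species:
                    members.append(g)
                    seen_species.add(species_col[g])
                else:
                    rest.append(g)
            if len(members) < 2:
                break
            fam_i += 1
            fid = f"fam_{fam_i:05d}"
            for g in members:
                family_col[g] = fid
            families.append(tuple(gene_ids[g] for g in sorted(members)))
            placed += len(members)
            free = rest

    table = pd.DataFrame(
        {
            "length": lengths,
            "phylum": phylum_col,
            "genus": genus_col,
            "species": species_col,
            "ko": ko_col,
            "family_id": family_col,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    catalog = GeneCatalog(table=table, paralog_families=families)

    pathways: dict[str, list[str]] = {}
    if ko_names:
        lo, hi = pathway_size_range
        n_pathways = max(1, n_kos // 10)
        for p in range(n_pathways):
            size = int(rng.integers(lo, min(hi, len(ko_names)) + 1))
            members = rng.choice(len(ko_names), size=size, replace=False)
            pathways[f"path_{p + 1:04d}"] = sorted(ko_names[m] for m in members)
    return catalog, pathways


def _species_abundances(
    catalog: GeneCatalog,
    design: CohortDesign,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Draw per-sample species relative abundances with planted case shifts."""
    species = sorted(catalog.table["species"].unique())
    missing = [p.species for p in design.planted if p.species not in species]
    if missing:
        raise KeyError(f"planted species absent from catalog: {missing}")
    mu = pd.Series(rng.normal(0.0, 1.5, size=len(species)), index=species)
    n = design.n_case + design.n_control
    sample_ids = [f"case_{i + 1:03d}" for i in range(design.n_case)] + [
        f"ctrl_{i + 1:03d}" for i in range(design.n_control)
    ]
    labels = pd.Series(
        ["case"] * design.n_case + ["control"] * design.n_control,
        index=pd.Index(sample_ids, name="sample_id"),
        name="group",
    )
    log_ab = mu.to_numpy()[None, :] + rng.normal(0.0, 1.0, size=(n, len(species)))
    shift = np.zeros(len(species))
    for eff in design.planted:
        shift[species.index(eff.species)] += eff.signed_log2 * np.log(2)
    log_ab[: design.n_case, :] += shift[None, :]
    ab = np.exp(log_ab)
    ab /= ab.sum(axis=1, keepdims=True)
    gt = pd.DataFrame(ab, index=labels.index, columns=species)
    return gt, labels, mu


def _reads_from_truth(
    catalog: GeneCatalog,
    ground_truth: pd.DataFrame,
    design: CohortDesign,
    rng: np.random.Generator,
) -> list[ReadMapSample]:
    """Multinomial read assignment to genes, with multi-mapped emission."""
    gene_ids = list(catalog.gene_ids)
    lengths = catalog.lengths.to_numpy(dtype=float)
    species_col = catalog.table["species"].to_numpy()
    species_index = {s: i for i, s in enumerate(ground_truth.columns)}
    sp_idx = np.array([species_index[s] for s in species_col])
    family_of = catalog.table["family_id"].to_numpy()
    fam_members: dict[str, tuple[str, ...]] = {}
    for fid in pd.unique(family_of[family_of != ""]):
        fam_members[fid] = tuple(g for g, f in zip(gene_ids, family_of) if f == fid)

    samples = []
    for sid, row in ground_truth.iterrows():
        w = row.to_numpy()[sp_idx] * lengths
        p = w / w.sum()
        counts = rng.multinomial(design.depth, p)
        unique: dict[str, int] = {}
        multi: dict[tuple[str, ...], int] = {}
        if design.multiread_rate > 0:
            in_family = family_of != ""
            moved = np.zeros_like(counts)
            moved[in_family] = rng.binomial(counts[in_family], design.multiread_rate)
            for i in np.nonzero(moved)[0]:
                genes = fam_members[family_of[i]]
                multi[genes] = multi.get(genes, 0) + int(moved[i])
            counts = counts - moved
        for i in np.nonzero(counts)[0]:
            unique[gene_ids[i]] = int(counts[i])
        samples.append(
            ReadMapSample(
                sample_id=str(sid),
                unique_counts=unique,
                multi_groups=sorted(multi.items()),
            )
        )
    return samples


def generate_cohort(catalog: GeneCatalog, design: CohortDesign) -> Cohort:
    """Generate read-map samples for a case-control cohort.

    Species abundances are log-normal on the simplex with the designed log2
    shifts applied to cases; reads are multinomial over genes with weight
    species abundance x gene length; a ``multiread_rate`` fraction of the reads
    on paralog-family genes is emitted as multi-read groups over the family.
    """
    rng = np.random.default_rng(design.seed)
    gt, labels, mu = _species_abundances(catalog, design, rng)
    samples = _reads_from_truth(catalog, gt, design, rng)
    return Cohort(samples=samples, labels=labels, ground_truth=gt, species_mu=mu)


def generate_clinical(
    ground_truth: pd.DataFrame,
    design: CohortDesign,
    labels: pd.Series | None = None,
    timepoint: str = "0W",
    seed: int | None = None,
) -> pd.DataFrame:
    """Clinical table with indices that are noisy linear functions of log10
    species abundance; Age and BMI are drawn independently of the microbiome
    unless the design models them explicitly."""
    for name, model in design.clinical_model.items():
        missing = [s for s in model.coefficients if s not in ground_truth.columns]
        if missing:
            raise KeyError(f"clinical model for {name} references unknown species: {missing}")
    rng = np.random.default_rng(design.seed + 10_000 if seed is None else seed)
    out = pd.DataFrame(index=ground_truth.index)
    if labels is not None:
        out["group"] = labels
    out["timepoint"] = timepoint
    out["Age"] = np.clip(rng.normal(40.0, 12.9, size=len(out)), 18, 70).round(1)
    out["BMI"] = np.clip(rng.normal(24.3, 2.9, size=len(out)), 15, 40).round(1)
    log_ab = np.log10(ground_truth + PSEUDOCOUNT)
    for name, model in design.clinical_model.items():
        value = np.full(len(out), model.intercept, dtype=float)
        for sp, coef in model.coefficients.items():
            value += coef * log_ab[sp].to_numpy()
        value += rng.normal(0.0, model.noise_sd, size=len(out))
        out[name] = np.maximum(value, 1e-3)
    return out


def generate_longitudinal(
    catalog: GeneCatalog,
    design: CohortDesign,
    baseline: Cohort,
    recovery_fraction: dict[str, float],
    seed: int = 0,
) -> dict[str, Cohort]:
    """Follow-up cohorts in which case samples move toward the control centroid.

    At each timepoint the case samples' ground-truth species abundances are
    linearly interpolated a fraction ``f`` toward the mean control composition
    (then renormalized) before reads are regenerated.  Fractions must lie in
    [0, 1] and be nondecreasing over the given timepoint order.
    """
    fracs = list(recovery_fraction.values())
    if any(not (0 <= f <= 1) for f in fracs):
        raise ValueError("recovery fractions must be in [0, 1]")
    if any(b < a for a, b in zip(fracs, fracs[1:])):
        raise ValueError("recovery fractions must be nondecreasing over time")
    is_case = (baseline.labels == "case").to_numpy()
    centroid = baseline.ground_truth.loc[~is_case].mean(axis=0)
    out: dict[str, Cohort] = {}
    for t_i, (tp, f) in enumerate(recovery_fraction.items()):
        gt = baseline.ground_truth.copy()
        moved = (1 - f) * gt.loc[is_case] + f * centroid
        gt.loc[is_case] = moved.div(moved.sum(axis=1), axis=0)
        rng = np.random.default_rng(seed + 1000 * (t_i + 1))
        samples = _reads_from_truth(catalog, gt, design, rng)
        for s in samples:
            s.sample_id = f"{s.sample_id}_{tp}"
        gt_t = gt.copy()
        gt_t.index = [f"{i}_{tp}" for i in gt.index]
        labels_t = baseline.labels.copy()
        labels_t.index = gt_t.index
        out[tp] = Cohort(
            samples=samples, labels=labels_t, ground_truth=gt_t, species_mu=baseline.species_mu
        )
    return out


def generate_community_types(
    n_samples: int,
    n_genera: int = 20,
    n_types: int = 2,
    separation: float = 4.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genus-level profiles with planted discrete community types.

    Each type is dominated by a different driver genus (its log-abundance
    raised by ``separation``); used to exercise enterotyping.  Returns the
    samples x genera relative-abundance table and the true type labels.
    """
    if n_types < 2 or n_genera < n_types:
        raise ValueError("need n_genera >= n_types >= 2")
    rng = np.random.default_rng(seed)
    genera = [f"Genus_{i + 1:03d}" for i in range(n_genera)]
    mu = rng.normal(0.0, 1.0, size=n_genera)
    types = rng.integers(0, n_types, size=n_samples)
    log_ab = mu[None, :] + rng.normal(0.0, 0.5, size=(n_samples, n_genera))
    for t in range(n_types):
        log_ab[types == t, t] += separation
    ab = np.exp(log_ab)
    ab /= ab.sum(axis=1, keepdims=True)
    profile = pd.DataFrame(
        ab, index=pd.Index([f"s{i + 1:03d}" for i in range(n_samples)], name="sample_id"),
        columns=genera,
    )
    return profile, pd.Series(types, index=profile.index, name="community_type")


def default_design(seed: int = 0, n_case: int = 40, n_control: int = 40) -> CohortDesign:
    """The stock desk-scale study design used by the analysis drivers.

    Ten planted species (half case-enriched, half control-enriched,
    |log2 effect| 1-2) and two clinical indices wired to planted species the
    way serum urate and C-reactive protein track the case-depleted/enriched
    flora: SUA falls with the control-enriched species (urate-degrading-like),
    CRP rises with the case-enriched species (pro-inflammatory-like).
    Intercepts and noise match the case-control pooled means/spreads of the
    cohort table the clinical model emulates.
    """
    planted = [
        PlantedEffect("Species_0001", 1.5, "case"),
        PlantedEffect("Species_0002", 2.0, "case"),
        PlantedEffect("Species_0003", 1.0, "case"),
        PlantedEffect("Species_0004", 1.5, "case"),
        PlantedEffect("Species_0005", 1.0, "case"),
        PlantedEffect("Species_0006", 1.5, "control"),
        PlantedEffect("Species_0007", 2.0, "control"),
        PlantedEffect("Species_0008", 1.0, "control"),
        PlantedEffect("Species_0009", 1.5, "control"),
        PlantedEffect("Species_0010", 1.0, "control"),
    ]
    clinical = {
        "SUA": ClinicalIndexModel(
            intercept=300.0,
            coefficients={"Species_0006": -40.0, "Species_0007": -30.0},
            noise_sd=50.0,
        ),
        "CRP": ClinicalIndexModel(
            intercept=40.0,
            coefficients={"Species_0001": 8.0, "Species_0002": 6.0},
            noise_sd=8.0,
        ),
        "SCr": ClinicalIndexModel(
            intercept=70.0,
            coefficients={"Species_0006": -8.0},
            noise_sd=15.0,
        ),
    }
    return CohortDesign(
        n_case=n_case,
        n_control=n_control,
        planted=planted,
        depth=50_000,
        multiread_rate=0.10,
        clinical_model=clinical,
        seed=seed,
    )
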