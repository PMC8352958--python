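"""Configuration-driven end-to-end orchestration.

``run_pipeline`` executes synthetic -> profiling -> diversity -> differential
-> reporter -> tripartite -> classifier in dependency order, writing every
stage's tables under one output directory with a provenance header and a
manifest recording the seed, configuration hash and stage list.  The whole
bundle is deterministic under a fixed config + seed; ``bundle_hash`` digests
the output files so two runs can be compared byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import differential as diff
from . import diversity as dv
from . import io as gio
from . import reporter as rep
from . import synthetic as syn
from . import tripartite as tri
from .profiling import build_gene_profile, downsample, prevalence_filter, aggregate

ALL_STAGES = (
    "synthetic",
    "profiling",
    "diversity",
    "differential",
    "reporter",
    "tripartite",
    "classifier",
)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults mirror the analysis conventions
    (FDR 0.05, reporter cutoff 1.65, 10% prevalence, 9999 permutations)."""

    seed: int = 0
    n_case: int = 40
    n_control: int = 40
    n_genes: int = 2000
    n_species: int = 50
    n_kos: int = 200
    depth: int = 20000
    multiread_rate: float = 0.10
    downsample_to: int | None = None  # equal-depth resampling target
    fdr_cutoff: float = 0.05
    reporter_cutoff: float = 1.65
    prevalence_min_fraction: float = 0.10
    n_perm: int = 999
    n_background: int = 1000
    top_n_genes: int = 50
    cv_trials: int = 5
    cv_folds: int = 10
    cv_trees: int = 100
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        if not (0 < self.fdr_cutoff < 1 and 0 < self.prevalence_min_fraction <= 1):
            raise ValueError("threshold out of range")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def bundle_hash(out_dir) -> str:
    """SHA-256 over the sorted relative paths and contents of the bundle."""
    out_dir = Path(out_dir)
    h = hashlib.sha256()
    for f in sorted(p for p in out_dir.rglob("*") if p.is_file()):
        h.update(str(f.relative_to(out_dir)).encode())
        h.update(f.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the configured stages, write the report bundle, return the results.

    A stage failure raises with the stage name prefixed; later stages are not
    run.  Toggled-off stages leave no files in the bundle.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = {"seed": config.seed, "config": config.config_hash()}
    results: dict = {}
    stage = "synthetic"
    try:
        catalog, pathways = syn.generate_catalog(
            config.n_genes, config.n_species, config.n_kos, seed=config.seed
        )
        design = syn.default_design(
            seed=config.seed, n_case=config.n_case, n_control=config.n_control
        )
        design.depth = config.depth
        design.multiread_rate = config.multiread_rate
        cohort = syn.generate_cohort(catalog, design)
        clinical = syn.generate_clinical(cohort.ground_truth, design, labels=cohort.labels)
        results.update(catalog=catalog, pathways=pathways, cohort=cohort, clinical=clinical)
        if "synthetic" in config.stages:
            gio.write_catalog(catalog, out_dir / "catalog.tsv", provenance=prov)
            gio.write_gmt(pathways, out_dir / "pathways.gmt")
            gio.write_readmaps(cohort.samples, out_dir / "readmaps.tsv", provenance=prov)
            gio.write_clinical(clinical, out_dir / "clinical.tsv", provenance=prov)
            gio.write_matrix(cohort.ground_truth, out_dir / "ground_truth_species.tsv", prov)

        stage = "profiling"
        samples = cohort.samples
        if config.downsample_to:
            samples = [
                downsample(s, config.downsample_to, seed=config.seed + i)
                for i, s in enumerate(samples)
            ]
        gene_profile = build_gene_profile(samples, catalog)
        gene_profile = prevalence_filter(gene_profile, config.prevalence_min_fraction)
        profiles = {"gene": gene_profile}
        for level in ("phylum", "genus", "species", "ko"):
            profiles[level] = aggregate(gene_profile, catalog.rank_map(level), level)
        results["profiles"] = profiles
        if "profiling" in config.stages:
            for level, pr in profiles.items():
                gio.write_profile(pr, out_dir / f"profile_{level}.tsv", provenance=prov)

        stage = "diversity"
        if "diversity" in config.stages:
            gp = profiles["gene"].data
            alpha = pd.DataFrame(
                {
                    "gene_count": dv.gene_counts(gp),
                    "shannon": gp.apply(dv.shannon, axis=1),
                }
            )
            dm = dv.bray_curtis(gp)
            perma = dv.permanova(
                dm, cohort.labels.loc[gp.index].to_numpy(), n_perm=config.n_perm,
                seed=config.seed,
            )
            ent = dv.enterotype(profiles["genus"].data, seed=config.seed)
            gdc = dv.group_distance_comparison(dm, cohort.labels.loc[gp.index])
            results["diversity"] = {
                "alpha": alpha,
                "permanova": perma,
                "enterotype": ent,
                "group_distance": gdc,
            }
            gio.write_matrix(alpha, out_dir / "alpha_diversity.tsv", prov)
            gio.write_matrix(
                pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids),
                out_dir / "bray_curtis.tsv",
                prov,
            )
            gio.write_manifest(
                {
                    "permanova": dataclasses.asdict(perma),
                    "enterotype_k": ent.k,
                    "enterotype_ch": ent.ch_scores,
                    "within_mean": gdc.mean_within,
                    "between_mean": gdc.mean_between,
                    "within_between_p": gdc.p_value,
                },
                out_dir / "diversity_summary.json",
            )

        stage = "differential"
        diff_results = {}
        for level in ("gene", "species", "ko"):
            diff_results[level] = diff.differential_abundance(
                profiles[level].data, cohort.labels, fdr_cutoff=config.fdr_cutoff
            )
        results["differential"] = diff_results
        if "differential" in config.stages:
            for level, tab in diff_results.items():
                gio.write_matrix(tab, out_dir / f"differential_{level}.tsv", prov)

        stage = "reporter"
        ko_diff = diff_results["ko"]
        z = rep.ko_zscore(ko_diff["p"], ko_diff["direction"])
        usable = {
            pw: m for pw, m in pathways.items() if any(k in z.index for k in m)
        }
        rep_results = rep.reporter_score(
            z, usable, n_background=config.n_background, seed=config.seed,
            cutoff=config.reporter_cutoff,
        )
        results["reporter"] = rep_results
        if "reporter" in config.stages:
            gio.write_matrix(rep_results, out_dir / "reporter_scores.tsv", prov)

        stage = "tripartite"
        if "tripartite" in config.stages:
            sig_species = diff_results["species"].index[diff_results["species"]["significant"]]
            sp_cols = list(sig_species[:10]) or list(profiles["species"].data.columns[:5])
            sp_pw = tri.species_pathway_matrix(
                profiles["species"].data.loc[:, sp_cols], profiles["ko"].data, usable
            )
            numeric = [c for c in clinical.columns if clinical[c].dtype.kind in "fi"]
            sp_cl = []
            for idx_name in numeric:
                tab = tri.feature_clinical_spearman(
                    profiles["species"].data, clinical[idx_name]
                )
                tab["index"] = idx_name
                sp_cl.append(tab.reset_index(names="species"))
            results["tripartite"] = {"species_pathway": sp_pw, "species_clinical": pd.concat(sp_cl)}
            gio.write_matrix(sp_pw.set_index("species"), out_dir / "tripartite_species_pathway.tsv", prov)
            gio.write_matrix(
                results["tripartite"]["species_clinical"].set_index("species"),
                out_dir / "tripartite_species_clinical.tsv",
                prov,
            )

        stage = "classifier"
        if "classifier" in config.stages:
            cands = clf.candidate_genes(diff_results["gene"], top_n=config.top_n_genes)
            sub = profiles["gene"].data.loc[:, cands]
            curve = clf.cv_error_curve(
                sub,
                cohort.labels,
                n_trials=config.cv_trials,
                n_folds=config.cv_folds,
                seed=config.seed,
                n_estimators=config.cv_trees,
                max_genes=min(20, len(cands)),
            )
            m, genes = clf.select_features(curve)
            model, scores = clf.train_and_score(
                sub, cohort.labels, genes, seed=config.seed, n_estimators=config.cv_trees
            )
            fpr, tpr, auc = clf.roc_auc(scores, cohort.labels.loc[scores.index])
            results["classifier"] = {
                "curve": curve, "m": m, "genes": genes, "auc_train": auc, "scores": scores,
            }
            gio.write_matrix(
                pd.DataFrame(
                    {"m": curve.ms, "mean_error": curve.mean_error, "sd": curve.sd_error}
                ).set_index("m"),
                out_dir / "cv_error_curve.tsv",
                prov,
            )
            gio.write_manifest(
                {"selected_m": m, "selected_genes": genes, "train_auc": auc,
                 "seed": config.seed, "trees": config.cv_trees},
                out_dir / "classifier_model.json",
            )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "stages_run": [s for s in ALL_STAGES if s in config.stages],
    }
    gio.write_manifest(manifest, out_dir / "manifest.json")
    results["bundle_hash"] = bundle_hash(out_dir)
    return results
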