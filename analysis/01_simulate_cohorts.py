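"""Generate the synthetic study: catalog, discovery + validation cohorts,
clinical tables, and longitudinal follow-up of the cases.

Writes the raw study bundle under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import study_config as cfg

from goutmeta import io as gio
from goutmeta.synthetic import default_design, generate_catalog, generate_clinical, \
    generate_cohort, generate_longitudinal


def main() -> None:
    cfg.DATA.mkdir(parents=True, exist_ok=True)
    catalog, pathways = generate_catalog(
        cfg.N_GENES, cfg.N_SPECIES, cfg.N_KOS, seed=cfg.SEED
    )
    gio.write_catalog(catalog, cfg.DATA / "catalog.tsv", {"seed": cfg.SEED})
    gio.write_gmt(pathways, cfg.DATA / "pathways.gmt")

    for name, sizes, seed_off in (("discovery", cfg.DISCOVERY, 0),
                                  ("validation", cfg.VALIDATION, 1)):
        design = default_design(seed=cfg.SEED + seed_off, **sizes)
        design.depth = cfg.DEPTH
        cohort = generate_cohort(catalog, design)
        clinical = generate_clinical(cohort.ground_truth, design, labels=cohort.labels)
        gio.write_readmaps(cohort.samples, cfg.DATA / f"readmaps_{name}.tsv",
                           {"seed": design.seed})
        gio.write_clinical(clinical, cfg.DATA / f"clinical_{name}.tsv")
        gio.write_matrix(cohort.ground_truth, cfg.DATA / f"ground_truth_{name}.tsv")
        print(f"{name}: {len(cohort.samples)} samples at depth {design.depth}")
        if name == "discovery":
            follow = generate_longitudinal(catalog, design, cohort, cfg.RECOVERY,
                                           seed=cfg.SEED + 2)
            for tp, co in follow.items():
                case_only = [s for s in co.samples
                             if co.labels[s.sample_id] == "case"]
                gio.write_readmaps(case_only, cfg.DATA / f"readmaps_{tp}.tsv")
                print(f"  follow-up {tp}: {len(case_only)} case samples "
                      f"(recovery fraction {cfg.RECOVERY[tp]})")

    gio.write_manifest(
        {"seed": cfg.SEED, "n_genes": cfg.N_GENES, "n_species": cfg.N_SPECIES,
         "n_kos": cfg.N_KOS, "depth": cfg.DEPTH, "recovery": cfg.RECOVERY},
        cfg.DATA / "manifest.json",
    )
    print(f"study bundle written to {cfg.DATA}")


if __name__ == "__main__":
    main()
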