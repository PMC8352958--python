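"""Richness, diversity, ordination, community tests and enterotypes.

Asks whether the planted case-control difference shows up at the community
level: Chao2 rarefaction and gene counts per group, Shannon index,
Bray-Curtis within/between-group dissimilarity, the Bacteroidetes/Firmicutes
ratio, PCA, PERMANOVA on disease status and on the clinical indices, and PAM
enterotyping of the genus profile.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

sys.path.insert(0, str(Path(__file__).parent))
import study_config as cfg

from goutmeta import diversity as dv
from goutmeta import io as gio
from goutmeta.profiling import bf_ratio


def main() -> None:
    out = cfg.RESULTS / "diversity"
    out.mkdir(parents=True, exist_ok=True)
    gene = gio.read_profile(cfg.RESULTS / "profiles" / "discovery_gene.tsv").data
    genus = gio.read_profile(cfg.RESULTS / "profiles" / "discovery_genus.tsv").data
    phylum = gio.read_profile(cfg.RESULTS / "profiles" / "discovery_phylum.tsv")
    clinical = gio.read_clinical(cfg.DATA / "clinical_discovery.tsv")
    labels = clinical["group"]

    # rarefaction by group
    rows = []
    for grp in ("case", "control"):
        inc = (gene.loc[labels == grp] > 0).to_numpy()
        curve = dv.rarefaction_curve(inc, n_resamples=100, seed=cfg.SEED)
        curve["group"] = grp
        rows.append(curve)
    rarefaction = pd.concat(rows)
    gio.write_matrix(rarefaction.set_index("k"), out / "rarefaction.tsv")

    alpha = pd.DataFrame({
        "gene_count": dv.gene_counts(gene),
        "shannon": gene.apply(dv.shannon, axis=1),
        "group": labels,
    })
    gio.write_matrix(alpha, out / "alpha.tsv")
    for metric in ("gene_count", "shannon"):
        p = mannwhitneyu(alpha.loc[labels == "case", metric],
                         alpha.loc[labels == "control", metric]).pvalue
        print(f"{metric}: case median {alpha.loc[labels == 'case', metric].median():.3f} "
              f"vs control {alpha.loc[labels == 'control', metric].median():.3f} "
              f"(Wilcoxon P={p:.3g})")

    ratio = bf_ratio(phylum)
    finite = np.isfinite(ratio)
    p_bf = mannwhitneyu(ratio[finite & (labels == "case")],
                        ratio[finite & (labels == "control")]).pvalue
    print(f"B/F ratio: case median {ratio[labels == 'case'].median():.3f} vs "
          f"control {ratio[labels == 'control'].median():.3f} (P={p_bf:.3g})")

    dm = dv.bray_curtis(gene)
    gdc = dv.group_distance_comparison(dm, labels)
    print(f"Bray-Curtis: between-group mean {gdc.mean_between:.4f} vs within "
          f"{gdc.mean_within:.4f} (P={gdc.p_value:.3g})")

    coords, ev = dv.ordinate(profile=gene, method="PCA")
    gio.write_matrix(coords.iloc[:, :5], out / "pca.tsv",
                     {"explained": ",".join(f"{v:.4f}" for v in ev[:5])})

    perm_rows = []
    res = dv.permanova(dm, labels.loc[gene.index].to_numpy(), n_perm=9999, seed=cfg.SEED)
    perm_rows.append(("disease", res.r2, res.p_value))
    print(f"PERMANOVA disease: R2={res.r2:.4f} P={res.p_value:.4g}")
    for idx in ("SUA", "CRP", "SCr", "BMI", "Age"):
        res = dv.permanova(dm, clinical.loc[gene.index, idx].to_numpy(),
                           n_perm=999, seed=cfg.SEED)
        perm_rows.append((idx, res.r2, res.p_value))
        print(f"PERMANOVA {idx}: R2={res.r2:.4f} P={res.p_value:.4g}")
    gio.write_matrix(
        pd.DataFrame(perm_rows, columns=["covariate", "r2", "p"]).set_index("covariate"),
        out / "permanova.tsv",
    )

    ent = dv.enterotype(genus, seed=cfg.SEED)
    fisher_p = dv.enterotype_group_test(ent.labels, labels)
    gio.write_matrix(ent.labels.to_frame(), out / "enterotypes.tsv",
                     {"k": ent.k, "metric": ent.metric})
    print(f"enterotypes: optimal k={ent.k} (CH {ent.ch_scores}); "
          f"group distribution Fisher P={fisher_p:.3g}")


if __name__ == "__main__":
    main()
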