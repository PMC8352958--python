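"""Three-pronged associations: species x pathways x clinical indices.

For the significantly differential species, scores each against every
pathway (background-corrected median Spearman), against each clinical index
(plain and BMI-adjusted partial Spearman), and scores pathways against the
clinical indices with the same machinery.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import study_config as cfg

from goutmeta import io as gio
from goutmeta.differential import bh_adjust
from goutmeta.tripartite import (
    feature_clinical_spearman,
    partial_spearman,
    pathway_clinical_matrix,
    species_pathway_matrix,
)

CLINICAL_INDICES = ("SUA", "CRP", "SCr")


def main() -> None:
    out = cfg.RESULTS / "tripartite"
    out.mkdir(parents=True, exist_ok=True)
    species = gio.read_profile(cfg.RESULTS / "profiles" / "discovery_species.tsv").data
    ko = gio.read_profile(cfg.RESULTS / "profiles" / "discovery_ko.tsv").data
    clinical = gio.read_clinical(cfg.DATA / "clinical_discovery.tsv")
    pathways = gio.read_gmt(cfg.DATA / "pathways.gmt")
    diff_sp = gio.read_matrix(cfg.RESULTS / "differential" / "discovery_species.tsv")
    sig_species = list(diff_sp.index[diff_sp["significant"]])
    print(f"scoring {len(sig_species)} differential species against "
          f"{len(pathways)} pathways and {len(CLINICAL_INDICES)} clinical indices")

    cells = species_pathway_matrix(species.loc[:, sig_species], ko, pathways)
    gio.write_matrix(cells.set_index("species"), out / "species_pathway.tsv")
    scored = cells.dropna(subset=["q"])
    print(f"species x pathway: {int((scored['q'] < 0.05).sum())} of {len(scored)} "
          f"cells at q<0.05")

    rows = []
    for idx in CLINICAL_INDICES:
        plain = feature_clinical_spearman(species.loc[:, sig_species], clinical[idx])
        adj_rho, adj_p = [], []
        for sp in plain.index:
            r, p = partial_spearman(
                species.loc[clinical.index, sp], clinical[idx], clinical["BMI"]
            )
            adj_rho.append(r)
            adj_p.append(p)
        plain["rho_bmi_adj"] = adj_rho
        plain["p_bmi_adj"] = adj_p
        plain["q_bmi_adj"] = bh_adjust(np.asarray(adj_p))
        plain["index"] = idx
        rows.append(plain.reset_index(names="species"))
        sig = plain[plain["q"] < 0.05]
        print(f"species x {idx}: {len(sig)} significant "
              f"(strongest rho {plain['rho'].abs().max():.2f}); "
              f"{int((plain['q_bmi_adj'] < 0.05).sum())} after BMI adjustment")
    gio.write_matrix(pd.concat(rows).set_index("species"), out / "species_clinical.tsv")

    pw_cells = pathway_clinical_matrix(clinical, ko, pathways,
                                       indices=list(CLINICAL_INDICES))
    gio.write_matrix(pw_cells.set_index("index"), out / "pathway_clinical.tsv")
    pw_scored = pw_cells.dropna(subset=["q"])
    print(f"pathway x clinical: {int((pw_scored['q'] < 0.05).sum())} of "
          f"{len(pw_scored)} cells at q<0.05")


if __name__ == "__main__":
    main()
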