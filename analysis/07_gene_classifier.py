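"""The random-forest gene classifier with cross-validated feature selection.

Takes the top differentially abundant genes as candidates, builds the
five-trial 10-fold CV error curve, selects the smallest gene set within the
min-plus-SD cutoff, trains the final forest on the discovery cohort, and
evaluates ROC/AUC on both cohorts.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import study_config as cfg

from goutmeta import io as gio
from goutmeta.classifier import (
    candidate_genes,
    cv_error_curve,
    roc_auc,
    score_samples,
    select_features,
    train_and_score,
)

TOP_N = 100
MAX_CURVE_GENES = 15
TREES = 100


def main() -> None:
    out = cfg.RESULTS / "classifier"
    out.mkdir(parents=True, exist_ok=True)
    disc = gio.read_profile(cfg.RESULTS / "profiles" / "discovery_gene.tsv").data
    valid = gio.read_profile(cfg.RESULTS / "profiles" / "validation_gene.tsv").data
    disc_labels = gio.read_clinical(cfg.DATA / "clinical_discovery.tsv")["group"]
    valid_labels = gio.read_clinical(cfg.DATA / "clinical_validation.tsv")["group"]
    diff = gio.read_matrix(cfg.RESULTS / "differential" / "discovery_gene.tsv")

    cands = candidate_genes(diff, top_n=TOP_N)
    print(f"{len(cands)} candidate genes from the differential ranking")
    curve = cv_error_curve(
        disc.loc[:, cands], disc_labels, n_trials=5, n_folds=10,
        seed=cfg.SEED, n_estimators=TREES, max_genes=MAX_CURVE_GENES,
    )
    m, genes = select_features(curve)
    gio.write_matrix(
        pd.DataFrame({"m": curve.ms, "mean_error": curve.mean_error,
                      "sd": curve.sd_error}).set_index("m"),
        out / "cv_error_curve.tsv",
    )
    print(f"feature selection: m={m} gene(s): {genes}")

    model, disc_scores = train_and_score(
        disc.loc[:, cands], disc_labels, genes, seed=cfg.SEED, n_estimators=500
    )
    _, _, disc_auc = roc_auc(disc_scores, disc_labels.loc[disc_scores.index])
    shared = [g for g in genes if g in valid.columns]
    valid_scores = score_samples(model, valid.reindex(columns=genes, fill_value=0.0), genes)
    _, _, valid_auc = roc_auc(valid_scores, valid_labels.loc[valid_scores.index])
    print(f"AUC: discovery (training) {disc_auc:.3f}; validation (held out) "
          f"{valid_auc:.3f} [{len(shared)}/{len(genes)} marker genes present]")

    gio.write_matrix(disc_scores.to_frame(), out / "scores_discovery.tsv")
    gio.write_matrix(valid_scores.to_frame(), out / "scores_validation.tsv")
    gio.write_manifest(
        {"selected_m": m, "selected_genes": genes, "auc_discovery": disc_auc,
         "auc_validation": valid_auc, "seed": cfg.SEED, "trees": 500},
        out / "model.json",
    )


if __name__ == "__main__":
    main()
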