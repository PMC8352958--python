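"""Reporter-score pathway enrichment from the KO differential table.

Converts each KO's Wilcoxon P into a signed Z, aggregates over pathway
members with sqrt(k) normalization, corrects against random same-size KO
sets, and flags pathways with |score| > 1.65.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import study_config as cfg

from goutmeta import io as gio
from goutmeta.reporter import ko_zscore, reporter_score, threshold_pathways


def main() -> None:
    out = cfg.RESULTS / "reporter"
    out.mkdir(parents=True, exist_ok=True)
    pathways = gio.read_gmt(cfg.DATA / "pathways.gmt")
    for cohort in ("discovery", "validation"):
        ko_diff = gio.read_matrix(cfg.RESULTS / "differential" / f"{cohort}_ko.tsv")
        z = ko_zscore(ko_diff["p"], ko_diff["direction"].fillna(""))
        usable = {pw: m for pw, m in pathways.items() if any(k in z.index for k in m)}
        res = reporter_score(z, usable, n_background=1000, seed=cfg.SEED)
        gio.write_matrix(res, out / f"{cohort}_reporter.tsv")
        split = threshold_pathways(res)
        print(f"{cohort}: {len(split['case'])} case-enriched and "
              f"{len(split['control'])} control-enriched pathways "
              f"(|score|>1.65) of {len(res)} scored")


if __name__ == "__main__":
    main()
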