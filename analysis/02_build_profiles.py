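"""Build relative-abundance profiles from the study's read-mapping tables.

Each sample is downsampled to a common matched-read depth, genes seen in
fewer than 10% of discovery samples are dropped, and the gene profile is
aggregated to phylum, genus, species and KO level.  Profiles are written
under results/profiles/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import study_config as cfg

from goutmeta import io as gio
from goutmeta.profiling import aggregate, build_gene_profile, downsample, prevalence_filter


def build(name: str, catalog, out_dir: Path, min_fraction=0.10) -> None:
    samples = gio.read_readmaps(cfg.DATA / f"readmaps_{name}.tsv")
    samples = [downsample(s, cfg.EQUAL_DEPTH, seed=cfg.SEED + i)
               for i, s in enumerate(samples)]
    gene = build_gene_profile(samples, catalog)
    n_before = gene.data.shape[1]
    gene = prevalence_filter(gene, min_fraction)
    print(f"{name}: {len(samples)} samples; {n_before} -> {gene.data.shape[1]} genes "
          f"after the 10% prevalence filter")
    gio.write_profile(gene, out_dir / f"{name}_gene.tsv", {"cohort": name})
    for level in ("phylum", "genus", "species", "ko"):
        prof = aggregate(gene, catalog.rank_map(level), level)
        gio.write_profile(prof, out_dir / f"{name}_{level}.tsv", {"cohort": name})
        print(f"  {level}: {prof.data.shape[1]} features")


def main() -> None:
    out_dir = cfg.RESULTS / "profiles"
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = gio.read_catalog(cfg.DATA / "catalog.tsv")
    for name in ("discovery", "validation", "2W", "4W", "24W"):
        build(name, catalog, out_dir)


if __name__ == "__main__":
    main()
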