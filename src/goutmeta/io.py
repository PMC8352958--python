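"""Tabular I/O: TSV matrices with provenance headers, GMT pathway files,
read-map tables, catalogs, clinical tables, and JSON manifests.

All files are UTF-8 TSV; lines starting with ``#`` form a provenance header
(free-form ``key=value``) and are skipped on read.  Profiles are stored
features x samples, with the sample ids as the header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .catalog import GeneCatalog, empty_catalog, families_from_table
from .profiling import AbundanceProfile, ReadMapSample

__all__ = [
    "write_profile",
    "read_profile",
    "write_gmt",
    "read_gmt",
    "write_catalog",
    "read_catalog",
    "write_readmaps",
    "read_readmaps",
    "write_clinical",
    "read_clinical",
    "write_manifest",
    "read_manifest",
    "write_matrix",
    "read_matrix",
]


def _header_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in provenance.items())


def write_matrix(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(provenance))
        df.to_csv(fh, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def write_profile(profile: AbundanceProfile, path, provenance: dict | None = None) -> None:
    prov = {"level": profile.level, **(provenance or {})}
    write_matrix(profile.data.T, path, provenance=prov)  # features x samples on disk


def read_profile(path, level: str | None = None) -> AbundanceProfile:
    if level is None:
        level = "gene"
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line[1:].strip().startswith("level="):
                    level = line.split("level=", 1)[1].strip()
    data = read_matrix(path).T
    if data.empty and data.columns.empty:
        return AbundanceProfile(data=pd.DataFrame(), level=level)
    data.index.name = "sample_id"
    return AbundanceProfile(data=data, level=level)


def write_gmt(pathways: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for pw, members in pathways.items():
            desc = descriptions.get(pw, "na")
            fh.write("\t".join([pw, desc, *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    pathways: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT rows need id, description and >=1 member")
            pw = parts[0]
            if pw in pathways:
                raise ValueError(f"{path}:{ln}: duplicate pathway id {pw!r}")
            pathways[pw] = [m for m in parts[2:] if m]
    return pathways


def write_catalog(catalog: GeneCatalog, path, provenance: dict | None = None) -> None:
    write_matrix(catalog.table, path, provenance=provenance)


def read_catalog(path) -> GeneCatalog:
    table = pd.read_csv(
        path, sep="\t", comment="#", index_col=0,
        dtype={"phylum": str, "genus": str, "species": str, "ko": str, "family_id": str},
        keep_default_na=False,
    )
    if table.empty and len(table.columns) == 0:
        return empty_catalog()
    table["length"] = table["length"].astype(int)
    table.index.name = "gene_id"
    return GeneCatalog(table=table, paralog_families=families_from_table(table))


def write_readmaps(samples: list[ReadMapSample], path, provenance: dict | None = None) -> None:
    """Long-form TSV: sample_id, gene_set (comma-joined ids), count, is_unique."""
    rows = []
    for s in samples:
        for g, c in sorted(s.unique_counts.items()):
            rows.append((s.sample_id, g, c, 1))
        for genes, c in s.multi_groups:
            rows.append((s.sample_id, ",".join(genes), c, 0))
    df = pd.DataFrame(rows, columns=["sample_id", "gene_set", "count", "is_unique"])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(provenance))
        df.to_csv(fh, sep="\t", index=False)


def read_readmaps(path) -> list[ReadMapSample]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "gene_set": str})
    samples = []
    for sid, grp in df.groupby("sample_id", sort=True):
        unique = {}
        multi = []
        for _, row in grp.iterrows():
            genes = tuple(row["gene_set"].split(","))
            if int(row["is_unique"]):
                if len(genes) != 1:
                    raise ValueError(f"{path}: unique row with multiple genes for {sid}")
                unique[genes[0]] = int(row["count"])
            else:
                multi.append((genes, int(row["count"])))
        samples.append(ReadMapSample(sample_id=str(sid), unique_counts=unique, multi_groups=multi))
    return samples


def write_clinical(table: pd.DataFrame, path, provenance: dict | None = None) -> None:
    write_matrix(table, path, provenance=provenance)


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
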