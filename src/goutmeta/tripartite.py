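"""Three-pronged associations: species x pathways x clinical indices.

The species-pathway statistic correlates a species' abundance with every KO
(Spearman), then contrasts the in-pathway correlation coefficients against the
out-of-pathway background: the reported value is

    median(rho, KOs in pathway) - median(rho, KOs outside pathway)

with a two-sided Wilcoxon rank-sum P between the two rho sets.  The same
machinery scores pathways against clinical indices.  Species-clinical links
use plain Spearman, optionally a first-order partial Spearman adjusting for a
covariate (BMI in the intended use).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from scipy.stats import spearmanr

from .differential import bh_adjust

__all__ = [
    "spearman_against_matrix",
    "species_pathway_score",
    "species_pathway_matrix",
    "feature_clinical_spearman",
    "partial_spearman",
    "pathway_clinical_score",
    "pathway_clinical_matrix",
]

MIN_PATHWAY_KOS = 2


def spearman_against_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho of vector ``x`` against every column of ``y`` (tie-aware)."""
    rx = rankdata(x)
    ry = rankdata(y, axis=0)
    rx = rx - rx.mean()
    ry = ry - ry.mean(axis=0)
    num = rx @ ry
    den = np.sqrt((rx**2).sum() * (ry**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, np.nan)
    return rho


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided P from the t approximation (df = n - 2)."""
    from scipy.stats import t as tdist

    rho = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return 2 * tdist.sf(np.abs(t), n - 2)


def species_pathway_score(
    species_abund: pd.Series,
    ko_profile: pd.DataFrame,
    pathway_kos: list[str],
) -> tuple[float, float]:
    """Background-corrected median Spearman rho of one species against one
    pathway, plus the Wilcoxon P contrasting in- vs out-of-pathway rho sets."""
    members = [k for k in pathway_kos if k in ko_profile.columns]
    outside = [k for k in ko_profile.columns if k not in set(members)]
    if len(members) < MIN_PATHWAY_KOS:
        raise ValueError("pathway needs >= 2 member KOs with data")
    if len(outside) < 2:
        raise ValueError("empty or near-empty background (pathway covers the KO universe)")
    x = species_abund.loc[ko_profile.index].to_numpy(dtype=float)
    rho_all = spearman_against_matrix(x, ko_profile.to_numpy(dtype=float))
    rho = pd.Series(rho_all, index=ko_profile.columns).dropna()
    rin = rho.loc[rho.index.intersection(members)].to_numpy()
    rout = rho.loc[rho.index.intersection(outside)].to_numpy()
    corrected = float(np.median(rin) - np.median(rout))
    if np.array_equal(np.sort(rin), np.sort(rout)):
        return corrected, 1.0
    p = float(mannwhitneyu(rin, rout, alternative="two-sided").pvalue)
    return corrected, p


def species_pathway_matrix(
    species_profile: pd.DataFrame,
    ko_profile: pd.DataFrame,
    pathways: dict[str, list[str]],
) -> pd.DataFrame:
    """All species x pathway cells, BH-adjusted across the whole family.

    Pathways with fewer than 2 scored KOs are reported unscored (NaN).
    """
    ko_mat = ko_profile.to_numpy(dtype=float)
    cols = ko_profile.columns
    recs = []
    for sp in species_profile.columns:
        x = species_profile[sp].loc[ko_profile.index].to_numpy(dtype=float)
        rho = pd.Series(spearman_against_matrix(x, ko_mat), index=cols).dropna()
        for pw, members in pathways.items():
            mem = rho.index.intersection([m for m in members])
            out = rho.index.difference(mem)
            if len(mem) < MIN_PATHWAY_KOS or len(out) < 2:
                recs.append((sp, pw, np.nan, np.nan))
                continue
            rin, rout = rho.loc[mem].to_numpy(), rho.loc[out].to_numpy()
            corrected = float(np.median(rin) - np.median(rout))
            p = float(mannwhitneyu(rin, rout, alternative="two-sided").pvalue)
            recs.append((sp, pw, corrected, p))
    df = pd.DataFrame(recs, columns=["species", "pathway", "corrected_rho", "p"])
    scored = df["p"].notna()
    df["q"] = np.nan
    if scored.any():
        df.loc[scored, "q"] = bh_adjust(df.loc[scored, "p"].to_numpy())
    return df


def feature_clinical_spearman(
    features: pd.DataFrame, clinical: pd.Series
) -> pd.DataFrame:
    """Spearman rho/P/q of every feature column against one clinical index;
    BH family = all features for this index.  Constant features are recorded
    with missing rho."""
    y = clinical.loc[features.index].to_numpy(dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("need n >= 5 paired samples")
    rho = spearman_against_matrix(y, features.to_numpy(dtype=float))
    p = np.where(np.isnan(rho), np.nan, _spearman_p(np.nan_to_num(rho), n))
    out = pd.DataFrame({"rho": rho, "p": p}, index=features.columns)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def partial_spearman(x, y, covariate) -> tuple[float, float]:
    """First-order partial Spearman correlation of x and y given a covariate.

    All three vectors are rank-transformed; x- and y-ranks are residualized on
    the covariate ranks (with intercept) and the Pearson correlation of the
    residuals is returned, with a t-approximation P on n - 3 df.  A constant
    covariate triggers a fallback to plain Spearman with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    n = len(x)
    if n < 6:
        raise ValueError("need n >= 6")
    if np.all(z == z[0]):
        warnings.warn("constant covariate; falling back to plain Spearman")
        rho, p = spearmanr(x, y)
        return float(rho), float(p)
    rx, ry, rz = rankdata(x), rankdata(y), rankdata(z)
    design = np.column_stack([np.ones(n), rz])
    bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
    by, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex, ey = rx - design @ bx, ry - design @ by
    scale = np.sqrt(rx.var() * ry.var()) * n
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    # a residual that is numerically zero (full mediation) has no correlation
    if denom <= 1e-9 * max(scale, 1.0):
        return 0.0, 1.0
    rho = float((ex @ ey) / denom)
    from scipy.stats import t as tdist

    rho_c = min(max(rho, -1 + 1e-15), 1 - 1e-15)
    t = rho_c * np.sqrt((n - 3) / (1 - rho_c**2))
    p = float(2 * tdist.sf(abs(t), n - 3))
    return rho, p


def pathway_clinical_score(
    clinical: pd.Series, ko_profile: pd.DataFrame, pathway_kos: list[str]
) -> tuple[float, float]:
    """Same background-corrected statistic with a clinical index in the
    species slot."""
    return species_pathway_score(clinical, ko_profile, pathway_kos)


def pathway_clinical_matrix(
    clinical_table: pd.DataFrame,
    ko_profile: pd.DataFrame,
    pathways: dict[str, list[str]],
    indices: list[str] | None = None,
) -> pd.DataFrame:
    """All clinical-index x pathway cells (one BH family)."""
    indices = indices or [c for c in clinical_table.columns
                          if clinical_table[c].dtype.kind in "fi"]
    sub = clinical_table.loc[clinical_table.index.intersection(ko_profile.index), indices]
    df = species_pathway_matrix(sub, ko_profile.loc[sub.index], pathways)
    return df.rename(columns={"species": "index"})
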