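"""Reporter-score pathway enrichment from KO-level statistics.

Each KO's two-sided P is converted to a signed Z (inverse normal of 1 - p/2,
sign from the enrichment direction); a pathway with k scored member KOs gets
the aggregate Z_pw = sum(Z)/sqrt(k), which is corrected against the mean and
standard deviation of the same statistic over random size-k KO sets drawn from
all scored KOs.  |corrected score| > 1.65 (the one-sided 95% normal quantile,
as printed) flags a pathway as differentially enriched; the sign carries the
direction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["ko_zscore", "reporter_score", "threshold_pathways", "REPORTER_CUTOFF"]

REPORTER_CUTOFF = 1.65


def ko_zscore(p: pd.Series, direction: pd.Series, case_label: str = "case") -> pd.Series:
    """Signed per-KO Z-score from two-sided P-values.

    Z = Phi^-1(1 - p/2), positive for case-enriched KOs and negative for
    control-enriched ones; p = 1 maps to Z = 0 (as does a missing direction).
    Zero P-values are clipped to the smallest positive float with a warning.
    """
    p = p.astype(float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("zero p-values clipped to float minimum")
        p = p.clip(lower=np.finfo(float).tiny)
    z = norm.isf(p / 2)  # = Phi^-1(1 - p/2), stable for tiny p
    dirs = direction.reindex(p.index).fillna("")
    # an undefined direction ('') carries no sign; its z is 0 anyway when p = 1
    sign = np.where(dirs == case_label, 1.0, np.where(dirs == "", 0.0, -1.0))
    return pd.Series(z * sign, index=p.index, name="z")


def reporter_score(
    ko_z: pd.Series,
    pathways: dict[str, list[str]],
    n_background: int = 1000,
    seed: int = 0,
    cutoff: float = REPORTER_CUTOFF,
) -> pd.DataFrame:
    """Background-corrected reporter score per pathway.

    The KO universe for background sampling is every KO in ``ko_z``; for each
    occurring pathway size k, ``n_background`` random size-k subsets give the
    mean/sd used to standardize sum(Z)/sqrt(k).  Pathways with no scored KO
    are skipped with a warning.
    """
    z = ko_z.dropna()
    universe = z.index
    zv = z.to_numpy()
    rng = np.random.default_rng(seed)

    sizes = {}
    rows = []
    for pw, members in pathways.items():
        if len(set(members)) > len(universe):
            raise ValueError(f"pathway {pw} larger than the scored KO universe")
        k = len([m for m in members if m in universe])
        if k == 0:
            warnings.warn(f"pathway {pw} has no scored KO; skipped")
            continue
        sizes.setdefault(k, None)
        rows.append((pw, k))

    # background moments per occurring size, vectorized subset sampling
    bg: dict[int, tuple[float, float]] = {}
    for k in sizes:
        if k == len(universe):
            stat = np.full(n_background, zv.sum() / np.sqrt(k))
        else:
            keys = rng.random((n_background, len(universe)))
            idx = np.argpartition(keys, k, axis=1)[:, :k]
            stat = zv[idx].sum(axis=1) / np.sqrt(k)
        bg[k] = (float(stat.mean()), float(stat.std(ddof=1)))

    recs = []
    for pw, k in rows:
        members = [m for m in pathways[pw] if m in universe]
        raw = float(z.loc[members].sum() / np.sqrt(k))
        mu, sd = bg[k]
        score = (raw - mu) / sd if sd > 0 else 0.0
        recs.append(
            {
                "pathway": pw,
                "k": k,
                "raw_z": raw,
                "score": score,
                "direction": "case" if score > 0 else "control",
                "significant": abs(score) > cutoff,
            }
        )
    return pd.DataFrame(recs).set_index("pathway")


def threshold_pathways(
    results: pd.DataFrame, cutoff: float = REPORTER_CUTOFF
) -> dict[str, list[str]]:
    """Split pathways with |score| strictly above the cutoff by direction."""
    if len(results) == 0:
        return {"case": [], "control": []}
    sig = results[results["score"].abs() > cutoff]
    return {
        "case": sorted(sig.index[sig["score"] > 0]),
        "control": sorted(sig.index[sig["score"] < 0]),
    }
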