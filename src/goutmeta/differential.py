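"""Feature-wise case-control and longitudinal testing with FDR control.

Two-sided Wilcoxon rank-sum per feature, Benjamini-Hochberg adjustment within
one annotation level, enrichment direction by the higher mean rank, paired
signed-rank tests for longitudinal contrasts, and discovery/validation
replication calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, wilcoxon
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "differential_abundance",
    "paired_differential",
    "replication_check",
]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotonicity enforced)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_abundance(
    profile: pd.DataFrame,
    labels: pd.Series,
    fdr_cutoff: float = 0.05,
    case_label: str = "case",
) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum between the two label groups.

    Returns a table with raw P, BH q (family = all features in ``profile``,
    i.e. one annotation level), enrichment direction by higher mean rank, the
    per-group mean ranks and median abundances, and a ``significant`` flag at
    q < ``fdr_cutoff``.  Constant features get P = 1 and no direction.
    """
    lab = labels.reindex(profile.index)
    groups = pd.unique(lab.dropna())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    other = [g for g in groups if g != case_label]
    if case_label not in list(groups):
        raise ValueError(f"case label {case_label!r} not present")
    control_label = other[0]
    case_mask = (lab == case_label).to_numpy()
    ctrl_mask = (lab == control_label).to_numpy()
    if case_mask.sum() < 3 or ctrl_mask.sum() < 3:
        raise ValueError("each group needs n >= 3")

    x = profile.to_numpy(dtype=float)
    xc, xk = x[case_mask], x[ctrl_mask]
    constant = np.all(x == x[0, :], axis=0)

    pvals = np.ones(x.shape[1])
    var_cols = ~constant
    if var_cols.any():
        res = mannwhitneyu(xc[:, var_cols], xk[:, var_cols], alternative="two-sided", axis=0)
        pvals[var_cols] = np.atleast_1d(res.pvalue)

    ranks = rankdata(x, axis=0)
    mean_rank_case = ranks[case_mask].mean(axis=0)
    mean_rank_ctrl = ranks[ctrl_mask].mean(axis=0)
    direction = np.where(mean_rank_case > mean_rank_ctrl, case_label, control_label)
    direction = np.where(mean_rank_case == mean_rank_ctrl, "", direction)
    direction[constant] = ""

    q = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "feature": profile.columns,
            "p": pvals,
            "q": q,
            "direction": direction,
            "mean_rank_case": mean_rank_case,
            "mean_rank_control": mean_rank_ctrl,
            "median_case": np.median(xc, axis=0),
            "median_control": np.median(xk, axis=0),
        }
    ).set_index("feature")
    out["significant"] = out["q"] < fdr_cutoff
    return out


def paired_differential(
    profile_t0: pd.DataFrame,
    profile_t1: pd.DataFrame,
    pairing: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank test per feature between two timepoints.

    ``pairing`` maps t0 sample ids to t1 sample ids; by default identical ids
    are paired.  Direction is the sign of the median paired difference
    (t1 - t0).  Features whose differences are all zero get P = 1.
    """
    if pairing is None:
        pairing = {s: s for s in profile_t0.index}
    missing0 = [a for a in pairing if a not in profile_t0.index]
    missing1 = [b for b in pairing.values() if b not in profile_t1.index]
    if missing0 or missing1:
        raise KeyError(f"broken pairing ids: t0 {missing0}, t1 {missing1}")
    if len(pairing) < 5:
        raise ValueError("need >= 5 complete pairs")
    cols = profile_t0.columns.intersection(profile_t1.columns)
    a = profile_t0.loc[list(pairing.keys()), cols].to_numpy(dtype=float)
    b = profile_t1.loc[list(pairing.values()), cols].to_numpy(dtype=float)
    diff = b - a
    pvals = np.ones(diff.shape[1])
    for j in range(diff.shape[1]):
        dj = diff[:, j]
        if np.any(dj != 0):
            pvals[j] = float(wilcoxon(dj, zero_method="wilcox").pvalue)
    med = np.median(diff, axis=0)
    direction = np.where(med > 0, "increased", np.where(med < 0, "decreased", ""))
    out = pd.DataFrame(
        {"feature": cols, "p": pvals, "q": bh_adjust(pvals),
         "median_diff": med, "direction": direction}
    ).set_index("feature")
    return out


def replication_check(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    cutoff: float = 0.05,
    use: str = "q",
    use_validation: str | None = None,
) -> list[str]:
    """Features significant in discovery and significant with the same
    direction in validation.

    ``use`` selects the column ('q' or 'p') compared against ``cutoff``;
    ``use_validation`` overrides it for the validation cohort (validation
    arms are often held to a raw-P criterion at smaller n).
    """
    use_validation = use_validation or use
    shared = discovery.index.intersection(validation.index)
    d, v = discovery.loc[shared], validation.loc[shared]
    hit = (
        (d[use] < cutoff)
        & (v[use_validation] < cutoff)
        & (d["direction"] == v["direction"])
        & (d["direction"] != "")
    )
    return sorted(shared[hit])
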