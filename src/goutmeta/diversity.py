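"""Richness, diversity, ordination, community-level testing and enterotyping.

Chao2 incidence richness (bias-corrected by default), rarefaction over sample
resamples, Shannon index (natural log), Bray-Curtis and root Jensen-Shannon
distances, PCA/PCoA ordination, a permutation PERMANOVA that accepts
categorical or continuous covariates, PAM (k-medoids) enterotyping scored by
the Calinski-Harabasz index, and within/between group distance comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon, pdist, squareform
from scipy.stats import fisher_exact, mannwhitneyu
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa
from sklearn.decomposition import PCA
from sklearn.metrics import calinski_harabasz_score

__all__ = [
    "chao2",
    "rarefaction_curve",
    "gene_count",
    "gene_counts",
    "shannon",
    "bray_curtis",
    "rjsd",
    "ordinate",
    "permanova",
    "PermanovaResult",
    "pam",
    "enterotype",
    "EnterotypeResult",
    "group_distance_comparison",
    "distances_from_baseline",
    "enterotype_group_test",
]


def chao2(incidence, bias_corrected: bool = True) -> float:
    """Chao2 incidence-based richness estimate.

    ``incidence``: samples x features array-like; any positive entry counts as
    a detection.  With q1 features seen in exactly one sample and q2 in exactly
    two, the bias-corrected form is S_obs + q1(q1-1)/(2(q2+1)); the classic
    form S_obs + q1^2/(2 q2) is available when q2 > 0.
    """
    inc = np.asarray(incidence) > 0
    if inc.ndim != 2 or inc.shape[0] < 2:
        raise ValueError("chao2 needs an incidence matrix with >= 2 samples")
    det = inc.sum(axis=0)
    s_obs = int((det > 0).sum())
    q1 = int((det == 1).sum())
    q2 = int((det == 2).sum())
    if bias_corrected:
        return s_obs + q1 * (q1 - 1) / (2.0 * (q2 + 1))
    if q2 == 0:
        # classic estimator degenerates; fall back to the bias-corrected value
        return s_obs + q1 * (q1 - 1) / 2.0
    return s_obs + q1 * q1 / (2.0 * q2)


def rarefaction_curve(
    incidence,
    n_resamples: int = 100,
    seed: int = 0,
    bias_corrected: bool = True,
) -> pd.DataFrame:
    """Mean Chao2 estimate vs number of samples drawn with replacement.

    For each k = 1..n, ``n_resamples`` bootstrap draws of k samples are taken
    and Chao2 averaged.  Chao2 is undefined on a single incidence row, so the
    k=1 point reports mean observed richness instead.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    inc = np.asarray(incidence) > 0
    n = inc.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, n + 1):
        vals = np.empty(n_resamples)
        for r in range(n_resamples):
            pick = rng.integers(0, n, size=k)
            sub = inc[pick]
            if k == 1:
                vals[r] = float(sub.sum())
            else:
                vals[r] = chao2(sub, bias_corrected=bias_corrected)
        rows.append((k, vals.mean(), vals.std(ddof=1) if n_resamples > 1 else 0.0))
    return pd.DataFrame(rows, columns=["k", "mean_richness", "sd"])


def gene_count(row) -> int:
    """Number of detected (strictly positive) features in one sample row."""
    return int((np.asarray(row) > 0).sum())


def gene_counts(profile: pd.DataFrame) -> pd.Series:
    return (profile > 0).sum(axis=1).rename("gene_count")


def shannon(row) -> float:
    """Shannon index, natural log, computed over the positive entries."""
    p = np.asarray(row, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be nonnegative")
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def bray_curtis(profile: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis distance matrix, d(x,y) = sum|x-y| / sum(x+y)."""
    x = profile.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValueError("Bray-Curtis undefined between all-zero samples")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in profile.index])


def rjsd(profile: pd.DataFrame) -> DistanceMatrix:
    """Root Jensen-Shannon divergence distance (the canonical enterotype
    metric); rows are renormalized to probability vectors."""
    x = profile.to_numpy(dtype=float)
    x = x / x.sum(axis=1, keepdims=True)
    d = squareform(pdist(x, metric=lambda a, b: jensenshannon(a, b)))
    return DistanceMatrix(d, ids=[str(i) for i in profile.index])


def ordinate(
    profile: pd.DataFrame | None = None,
    dm: DistanceMatrix | None = None,
    method: str = "PCA",
    scale: bool = False,
):
    """Sample ordination.

    method='PCA' decomposes the (centered, optionally scaled) profile;
    method='PCoA' decomposes a distance matrix.  Returns (coordinates
    DataFrame, explained variance ratios).
    """
    if method.upper() == "PCA":
        if profile is None:
            raise ValueError("PCA needs a profile")
        if len(profile) < 3:
            raise ValueError("need >= 3 samples")
        x = profile.to_numpy(dtype=float)
        x = x - x.mean(axis=0)
        if scale:
            sd = x.std(axis=0)
            x = np.divide(x, sd, out=np.zeros_like(x), where=sd > 0)
        n_comp = min(x.shape[0] - 1, x.shape[1])
        model = PCA(n_components=n_comp, svd_solver="full")
        coords = model.fit_transform(x)
        cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
        return (
            pd.DataFrame(coords, index=profile.index, columns=cols),
            model.explained_variance_ratio_,
        )
    if method.upper() == "PCOA":
        if dm is None:
            raise ValueError("PCoA needs a distance matrix")
        res = skbio_pcoa(dm, number_of_dimensions=min(len(dm.ids) - 1, 10))
        coords = res.samples
        coords.columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
        return coords, res.proportion_explained.to_numpy()
    raise ValueError(f"unknown ordination method: {method!r}")


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def permanova(
    dm: DistanceMatrix | np.ndarray,
    covariate,
    n_perm: int = 9999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutation multivariate ANOVA of a distance matrix on one covariate.

    Uses the Gower-centered inner-product matrix G and a hat-matrix pseudo-F,
    F = (tr(HG)/(p-1)) / (tr(G) - tr(HG)) * (n-p)/(p-1-ish); for a categorical
    covariate this is the classic among/within partition.  P-value uses the
    (1 + exceedances)/(1 + n_perm) convention over row/column permutations
    of G.
    """
    d = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    n = d.shape[0]
    cov = np.asarray(covariate)
    if cov.shape[0] != n:
        raise ValueError("covariate length must match distance matrix")
    if len(pd.unique(cov)) < 2:
        raise ValueError("covariate is constant")
    if cov.dtype.kind in "OUSb":  # categorical
        levels, codes = np.unique(cov, return_inverse=True)
        x = np.zeros((n, len(levels)))
        x[np.arange(n), codes] = 1.0
        p_rank = len(levels)
    else:
        x = np.column_stack([np.ones(n), cov.astype(float)])
        p_rank = 2
    g = _gower_center(d)
    h = _hat(x)
    tr_g = np.trace(g)
    df_among = p_rank - 1
    df_within = n - p_rank

    def pseudo_f(g_perm: np.ndarray) -> tuple[float, float]:
        ss_among = float(np.sum(h * g_perm))  # tr(H G) with symmetric G
        ss_within = float(np.trace(g_perm) - ss_among)
        return (ss_among / df_among) / (ss_within / df_within), ss_among

    f_obs, ss_among = pseudo_f(g)
    r2 = ss_among / tr_g
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_p, _ = pseudo_f(g[np.ix_(perm, perm)])
        if f_p >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(pseudo_f=f_obs, r2=r2, p_value=p, n_permutations=n_perm)


def pam(d: np.ndarray, k: int, seed: int = 0, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids on a precomputed distance matrix.

    Greedy BUILD initialization followed by full SWAP passes until no swap
    lowers the total within-cluster distance-to-medoid cost.  Returns
    (labels, medoid indices); deterministic (the seed only breaks exact cost
    ties, which are resolved by lowest index anyway).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if k < 1 or k > n:
        raise ValueError("k must be in 1..n_samples")
    # BUILD: first medoid minimizes total distance; then greedily add
    medoids = [int(np.argmin(d.sum(axis=0)))]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - d, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = list(medoids)
    for _ in range(max_iter):
        best_delta, best_swap = 0.0, None
        base_cost = d[:, medoids].min(axis=1).sum()
        for mi, m in enumerate(medoids):
            others = [x for j, x in enumerate(medoids) if j != mi]
            for h in range(n):
                if h in medoids:
                    continue
                cand = others + [h]
                cost = d[:, cand].min(axis=1).sum()
                delta = cost - base_cost
                if delta < best_delta - 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    medoids = sorted(medoids)
    labels = np.argmin(d[:, medoids], axis=1)
    return labels, np.asarray(medoids)


@dataclass
class EnterotypeResult:
    labels: pd.Series
    k: int
    ch_scores: dict[int, float]
    medoids: np.ndarray
    metric: str


def enterotype(
    genus_profile: pd.DataFrame,
    k_range=range(2, 7),
    seed: int = 0,
    metric: str = "rjsd",
) -> EnterotypeResult:
    """Enterotype samples by PAM on a genus-level distance matrix, choosing k
    by the Calinski-Harabasz index (computed on the PCoA embedding of the same
    distances)."""
    ks = [k for k in k_range]
    if len(genus_profile) < max(ks) + 1:
        raise ValueError("need more samples than the largest k")
    dm = rjsd(genus_profile) if metric == "rjsd" else bray_curtis(genus_profile)
    d = dm.data
    if np.allclose(d, 0):
        raise ValueError("all samples identical; enterotyping undefined")
    coords, _ = ordinate(dm=dm, method="PCoA")
    embed = coords.to_numpy()
    ch: dict[int, float] = {}
    results = {}
    for k in ks:
        labels, medoids = pam(d, k, seed=seed)
        if len(np.unique(labels)) < 2:
            ch[k] = -np.inf
        else:
            ch[k] = float(calinski_harabasz_score(embed, labels))
        results[k] = (labels, medoids)
    best_k = max(ch, key=lambda k: (ch[k], -k))
    labels, medoids = results[best_k]
    return EnterotypeResult(
        labels=pd.Series(labels, index=genus_profile.index, name="enterotype"),
        k=best_k,
        ch_scores=ch,
        medoids=medoids,
        metric=metric,
    )


def enterotype_group_test(enterotypes: pd.Series, groups: pd.Series) -> float:
    """Fisher's exact P for a 2x2 enterotype-by-group table (chi2-free,
    matching the small-table usage); >2 enterotypes are collapsed to the
    largest vs rest."""
    tab = pd.crosstab(enterotypes, groups)
    if tab.shape[0] > 2:
        top = tab.sum(axis=1).idxmax()
        tab = pd.DataFrame(
            [tab.loc[top], tab.drop(index=top).sum(axis=0)], index=[top, "other"]
        )
    _, p = fisher_exact(tab.to_numpy())
    return float(p)


@dataclass
class GroupDistanceResult:
    within: np.ndarray
    between: np.ndarray
    p_value: float
    mean_within: float
    mean_between: float
    median_within: float
    median_between: float


def group_distance_comparison(dm: DistanceMatrix, labels: pd.Series) -> GroupDistanceResult:
    """Within- vs between-group pairwise distance distributions with a
    two-sided Wilcoxon rank-sum comparison."""
    lab = np.asarray(labels)
    groups = pd.unique(lab)
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    if min((lab == g).sum() for g in groups) < 2:
        raise ValueError("each group needs >= 2 samples")
    d = dm.data
    iu = np.triu_indices(d.shape[0], k=1)
    same = lab[iu[0]] == lab[iu[1]]
    within, between = d[iu][same], d[iu][~same]
    if np.allclose(d, 0):
        p = 1.0
    else:
        p = float(mannwhitneyu(within, between, alternative="two-sided").pvalue)
    return GroupDistanceResult(
        within=within,
        between=between,
        p_value=p,
        mean_within=float(within.mean()),
        mean_between=float(between.mean()),
        median_within=float(np.median(within)),
        median_between=float(np.median(between)),
    )


def distances_from_baseline(
    dm: DistanceMatrix, baseline_ids: list[str], timepoint_ids: dict[str, list[str]]
) -> dict[str, np.ndarray]:
    """Longitudinal mode: pairwise distances from each timepoint's samples to
    the baseline samples (all cross pairs)."""
    idx = {sid: i for i, sid in enumerate(dm.ids)}
    base = [idx[s] for s in baseline_ids]
    out = {}
    for tp, ids in timepoint_ids.items():
        rows = [idx[s] for s in ids]
        out[tp] = dm.data[np.ix_(rows, base)].ravel()
    return out
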