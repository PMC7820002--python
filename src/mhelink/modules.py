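"""Correlation modules of serum compounds.

Significant metabolites and cytokines are grouped by their co-variation
across patients: absolute Spearman correlation r, the distance
d = sqrt(2 (1 - r^2)), and k-medoids (PAM) clustering, with k and the
method chosen by mean silhouette width.  K-means (on a classical-MDS
embedding of the distance) and average-linkage hierarchical clustering
are provided as the comparison methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrix import OmicsMatrix


def spearman_abs_corr(matrix: OmicsMatrix) -> pd.DataFrame:
    """Absolute Spearman correlation between features (average-rank ties).

    Constant features have undefined correlations; these are set to 0 with
    a warning (diagonal stays 1).
    """
    vals = matrix.values
    if vals.shape[1] < 3:
        raise ValueError("need at least 3 samples for rank correlations")
    const = vals.std(axis=1, ddof=1) == 0
    if const.any():
        warnings.warn(
            f"constant features, correlations set to 0: "
            f"{list(vals.index[const])}", stacklevel=2)
    rho = stats.spearmanr(vals.to_numpy(float), axis=1).statistic
    rho = np.asarray(rho, float)
    if rho.ndim == 0:  # scipy returns a scalar for exactly two features
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    rho = np.abs(rho)
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=vals.index, columns=vals.index)


def corr_distance(corr: pd.DataFrame) -> pd.DataFrame:
    """Elementwise d = sqrt(2 (1 - r^2)); 0 on the diagonal, max sqrt(2)."""
    r = corr.to_numpy(float)
    if (r < 0).any() or (r > 1 + 1e-12).any():
        raise ValueError("correlation entries must lie in [0, 1]")
    d = np.sqrt(2.0 * np.clip(1.0 - r * r, 0.0, 1.0))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=corr.index, columns=corr.columns)


@dataclass
class ClusteringResult:
    method: str
    k: int
    labels: pd.Series                      # feature -> 1..k
    medoids: list[str]
    silhouette: pd.Series
    mean_silhouette: float
    objective: float = np.nan              # PAM: sum of distances to medoids
    extras: dict = field(default_factory=dict)


def silhouette_width(dist: pd.DataFrame, labels: pd.Series
                     ) -> tuple[pd.Series, float]:
    """Silhouette widths s(i) = (b - a) / max(a, b); singletons get 0."""
    labels = pd.Series(labels).reindex(dist.index)
    uniq = labels.unique()
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = dist.to_numpy(float)
    lab = labels.to_numpy()
    widths = np.zeros(len(lab))
    for i in range(len(lab)):
        own = lab == lab[i]
        n_own = own.sum()
        if n_own == 1:
            widths[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, lab == other].mean() for other in uniq if other != lab[i])
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    s = pd.Series(widths, index=dist.index)
    return s, float(s.mean())


# ---------------------------------------------------------------------------
# PAM (k-medoids): deterministic BUILD + best-improvement SWAP
# ---------------------------------------------------------------------------


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dist_to_nearest = D[:, medoids].min(axis=1)
        gains = np.maximum(dist_to_nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def _pam_objective(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def _pam_swap(D: np.ndarray, medoids: list[int],
              max_iter: int = 200) -> tuple[list[int], float]:
    n = D.shape[0]
    best = _pam_objective(D, medoids)
    for _ in range(max_iter):
        improved = False
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = h
                obj = _pam_objective(D, cand)
                if obj < best - 1e-12:
                    best, medoids, improved = obj, cand, True
        if not improved:
            break
    return medoids, best


def pam_cluster(dist: pd.DataFrame, k: int, seed: int = 0,
                n_restarts: int = 0) -> ClusteringResult:
    """Partitioning Around Medoids on a precomputed distance matrix.

    Deterministic BUILD initialization followed by best-improvement SWAP;
    the objective (total distance to the nearest medoid) is non-increasing
    across swaps.  ``n_restarts`` adds random re-initializations (seeded),
    keeping the best objective.
    """
    n = dist.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < {n}")
    D = dist.to_numpy(float)
    medoids, obj = _pam_swap(D, _pam_build(D, k))
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        cand, cobj = _pam_swap(D, sorted(rng.choice(n, k, replace=False).tolist()))
        if cobj < obj:
            medoids, obj = cand, cobj
    assign = np.argmin(D[:, medoids], axis=1)
    # a medoid always belongs to its own cluster (ties on duplicate
    # points could otherwise empty a cluster)
    for mi, m in enumerate(medoids):
        assign[m] = mi
    # stable label order: medoids sorted by feature index position
    order = np.argsort(medoids)
    relabel = np.empty_like(order)
    relabel[order] = np.arange(len(order))
    labels = pd.Series(relabel[assign] + 1, index=dist.index)
    sil, mean_sil = silhouette_width(dist, labels)
    medoid_ids = [dist.index[medoids[i]] for i in order]
    return ClusteringResult("pam", k, labels, medoid_ids, sil, mean_sil, obj)


# ---------------------------------------------------------------------------
# Alternative methods
# ---------------------------------------------------------------------------


def classical_mds(dist: pd.DataFrame, n_dim: int = 10) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a distance matrix."""
    D = dist.to_numpy(float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1]
    w, v = w[idx], v[:, idx]
    keep = min(n_dim, n - 1, int((w > 1e-10).sum()) or 1)
    return v[:, :keep] * np.sqrt(np.maximum(w[:keep], 0.0))


def _result_from_labels(dist: pd.DataFrame, labels: np.ndarray, method: str,
                        k: int) -> ClusteringResult:
    labels = pd.Series(np.asarray(labels, int), index=dist.index)
    # renumber to 1..k in order of first appearance for determinism
    remap = {old: new + 1 for new, old in
             enumerate(pd.unique(labels.to_numpy()))}
    labels = labels.map(remap)
    D = dist.to_numpy(float)
    medoids = []
    for c in sorted(labels.unique()):
        members = np.where(labels.to_numpy() == c)[0]
        medoids.append(dist.index[members[np.argmin(
            D[np.ix_(members, members)].sum(axis=1))]])
    if labels.nunique() >= 2:
        sil, mean_sil = silhouette_width(dist, labels)
    else:
        sil, mean_sil = pd.Series(0.0, index=dist.index), 0.0
    return ClusteringResult(method, int(labels.nunique()), labels, medoids,
                            sil, mean_sil)


def alt_cluster(dist: pd.DataFrame, k: int, method: str,
                seed: int = 0) -> ClusteringResult:
    """K-means (on a classical-MDS embedding) or average-linkage clustering."""
    n = dist.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= {n}")
    if method == "kmeans":
        from sklearn.cluster import KMeans

        emb = classical_mds(dist)
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(emb)
        return _result_from_labels(dist, km.labels_ + 1, "kmeans", k)
    if method in ("hierarchical", "hierarchical_average"):
        Z = linkage(squareform(dist.to_numpy(float), checks=False),
                    method="average")
        labels = fcluster(Z, t=k, criterion="maxclust")
        return _result_from_labels(dist, labels, "hierarchical", k)
    raise ValueError(f"unknown method {method!r}")


METHOD_ORDER = ("pam", "kmeans", "hierarchical")


@dataclass
class ModuleSelection:
    best: ClusteringResult
    candidates: pd.DataFrame   # method, k, mean_silhouette
    low_signal: bool = False


def select_modules(dist: pd.DataFrame, k_range=None,
                   methods=METHOD_ORDER, seed: int = 0,
                   warn_threshold: float = 0.25) -> ModuleSelection:
    """Choose the clustering method and k maximizing mean silhouette.

    Ties break towards smaller k, then by method order PAM < k-means <
    hierarchical.  A best mean silhouette below ``warn_threshold`` flags
    the partition as low-signal with a warning.
    """
    n = dist.shape[0]
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("empty k range")
    rows = []
    results: dict[tuple[str, int], ClusteringResult] = {}
    for method in methods:
        for k in k_range:
            res = (pam_cluster(dist, k, seed=seed) if method == "pam"
                   else alt_cluster(dist, k, method, seed=seed))
            results[(method, k)] = res
            rows.append({"method": method, "k": k,
                         "mean_silhouette": res.mean_silhouette})
    table = pd.DataFrame(rows)
    method_rank = {m: i for i, m in enumerate(METHOD_ORDER)}
    best_row = min(
        table.itertuples(index=False),
        key=lambda r: (-r.mean_silhouette, r.k, method_rank.get(r.method, 99)))
    best = results[(best_row.method, best_row.k)]
    low = best.mean_silhouette < warn_threshold
    if low:
        warnings.warn(
            f"best mean silhouette {best.mean_silhouette:.3f} < "
            f"{warn_threshold}: weak module structure", stacklevel=2)
    return ModuleSelection(best, table, low)


# ---------------------------------------------------------------------------
# Signed module profiles
# ---------------------------------------------------------------------------


@dataclass
class ModuleProfile:
    name: str
    members: list[str]
    signs: pd.Series        # member -> +1 / -1
    profile: pd.Series      # scaled average across samples


def module_profiles(matrix: OmicsMatrix, result: ClusteringResult,
                    n_passes: int = 2) -> list[ModuleProfile]:
    """Signed, scaled average profile per module.

    Features are z-scored across samples; members anti-correlated with the
    module average are flipped (sign -1) and the average recomputed
    (``n_passes`` refinement passes; a fixed point in practice).
    """
    vals = matrix.values.loc[result.labels.index]
    z = vals.sub(vals.mean(axis=1), axis=0)
    sd = vals.std(axis=1, ddof=1).replace(0.0, 1.0)
    z = z.div(sd, axis=0)
    profiles = []
    for c in sorted(result.labels.unique()):
        members = list(result.labels.index[result.labels == c])
        sub = z.loc[members]
        # seed orientation from the first member: a module of perfectly
        # anti-correlated halves would otherwise average to zero
        ref = sub.iloc[0]
        corr0 = sub.T.corrwith(ref)
        signs = corr0.apply(lambda r: -1 if r < 0 else 1)
        for _ in range(n_passes):
            avg = sub.mul(signs, axis=0).mean(axis=0)
            if avg.std(ddof=1) == 0:
                break
            corr = sub.T.corrwith(avg)
            signs = corr.apply(lambda r: -1 if r < 0 else 1)
        avg = sub.mul(signs, axis=0).mean(axis=0)
        if avg.std(ddof=1) > 0:
            avg = (avg - avg.mean()) / avg.std(ddof=1)
        profiles.append(ModuleProfile(f"M{c}", members, signs, avg))
    return profiles
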