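"""Time-course analysis: replicate-averaged matrices, Pearson-distance
hierarchical clustering, PCA, wave-cluster extraction filters, and the
enrichment / group-difference statistics."""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .io import DesignTable


# ---------------------------------------------------------------------------
# time-course matrices

@dataclass
class TimeCourseMatrix:
    """Row x time-point matrix of replicate-averaged standardized values."""

    values: pd.DataFrame        # rows x ordered time points
    n: pd.DataFrame             # replicate count behind every cell

    @property
    def timepoints(self) -> list[str]:
        return list(self.values.columns)


def build_timecourse_matrix(z_long: pd.DataFrame, design: DesignTable,
                            row_col: str = "row_id", value_col: str = "z"
                            ) -> TimeCourseMatrix:
    """Average replicate Z values per (row, time point).

    Missing replicates reduce the per-cell n; a row with an all-missing
    time point is dropped with a warning. Column order follows the
    design's time ordering.
    """
    tps = design.timepoint_order
    if len(z_long) == 0:
        empty = pd.DataFrame(columns=tps)
        return TimeCourseMatrix(empty, empty.copy())
    df = z_long.copy()
    df["timepoint"] = df["sample_id"].map(design.sample_to_timepoint())
    g = df.groupby([row_col, "timepoint"], observed=True)[value_col]
    values = g.mean().unstack("timepoint").reindex(columns=tps)
    n = g.size().unstack("timepoint").reindex(columns=tps).fillna(0).astype(int)
    complete = values.notna().all(axis=1)
    if (~complete).any():
        warnings.warn(f"build_timecourse_matrix: dropped {int((~complete).sum())} "
                      "rows with an all-missing time point")
    return TimeCourseMatrix(values[complete], n[complete])


# ---------------------------------------------------------------------------
# clustering

@dataclass
class ClusterAssignment:
    labels: pd.Series           # row id -> cluster label (1..k)
    linkage: np.ndarray         # scipy merge matrix (heights = merge distances)
    distance: pd.DataFrame      # 1 - Pearson r, in [0, 2]

    def cut(self, k: int) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.distance.index, name="cluster")


def hca_pearson(matrix: pd.DataFrame, linkage_rule: str = "average",
                n_clusters: int = 2) -> ClusterAssignment:
    """Agglomerative clustering under the Pearson-correlation distance
    d = 1 - r (in [0, 2]); constant rows have no defined correlation and
    are dropped with a warning. Deterministic: scipy's linkage with a fixed
    input order, ties resolved by the lowest-index pair."""
    if len(matrix) < 2 or matrix.shape[1] < 3:
        raise ValueError("hca_pearson: need >= 2 rows and >= 3 time points")
    variances = matrix.var(axis=1, ddof=0)
    keep = variances > 0
    if (~keep).any():
        warnings.warn(f"hca_pearson: dropped {int((~keep).sum())} constant rows "
                      "(Pearson distance undefined)")
    m = matrix[keep]
    r = np.corrcoef(m.to_numpy(dtype=float))
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage_rule)
    dist = pd.DataFrame(d, index=m.index, columns=m.index)
    assignment = ClusterAssignment(labels=pd.Series(dtype=int), linkage=z, distance=dist)
    assignment.labels = assignment.cut(n_clusters)
    return assignment


# ---------------------------------------------------------------------------
# wave extraction

def max_gt(threshold: float):
    """Keep a Z series iff its maximum exceeds *threshold* at >= 1 time point."""
    return ("max_gt", threshold)


def avg_gt(threshold: float):
    """Keep a Z series iff its replicate-averaged value exceeds *threshold*
    at >= 1 time point."""
    return ("avg_gt", threshold)


def extract_wave_cluster(matrix: TimeCourseMatrix, labels: pd.Series, cluster: int,
                         filter_rule=max_gt(0.0)) -> dict:
    """Rows of one cluster surviving the Z filter, with the cluster mean
    series and per-time dispersion."""
    kind, threshold = filter_rule
    if kind not in {"max_gt", "avg_gt"}:
        raise ValueError(f"unknown filter rule {kind!r}")
    rows = labels.index[labels == cluster]
    sub = matrix.values.loc[rows]
    keep = sub.max(axis=1) > threshold
    kept = sub[keep]
    if len(kept) == 0:
        warnings.warn(f"extract_wave_cluster: cluster {cluster} empty after filter")
    return {
        "rows": list(kept.index),
        "mean": kept.mean(axis=0),
        "sd": kept.std(axis=0, ddof=1) if len(kept) > 1 else kept.mean(axis=0) * 0.0,
        "n": len(kept),
    }


def pca_scores(matrix: pd.DataFrame, n_components: int = 2):
    """Column-centered PCA row scores.

    Component signs follow the convention that each component's
    largest-magnitude loading is positive. Returns (scores, loadings,
    explained_variance); the component count is reduced with a warning when
    the matrix has fewer time points."""
    if len(matrix) < 2:
        raise ValueError("pca_scores: need >= 2 rows")
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    max_comp = min(x.shape)
    if n_components > max_comp:
        warnings.warn(f"pca_scores: reducing components {n_components} -> {max_comp}")
        n_components = max_comp
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for i in range(n_components):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = pd.DataFrame(u[:, :n_components] * s[:n_components],
                          index=matrix.index,
                          columns=[f"PC{i + 1}" for i in range(n_components)])
    loadings = pd.DataFrame(vt[:n_components].T, index=matrix.columns,
                            columns=scores.columns)
    explained = (s ** 2) / max(len(matrix) - 1, 1)
    return scores, loadings, explained[:n_components]


# ---------------------------------------------------------------------------
# enrichment

def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ptm_enrichment(cluster_psms: pd.DataFrame, all_psms: pd.DataFrame,
                   min_psms: int = 50,
                   keys: tuple[str, str] = ("ptm_name", "site_residue")
                   ) -> pd.DataFrame:
    """Per-(PTM type, residue) hypergeometric enrichment of a cluster's PSMs
    against the total PTM population; only entries whose population count
    exceeds *min_psms* are reported."""
    pop = all_psms.groupby(list(keys), observed=True).size()
    clu = cluster_psms.groupby(list(keys), observed=True).size()
    N = int(pop.sum())
    n = int(clu.sum())
    rows = []
    for key, K in pop.items():
        if not isinstance(key, tuple):
            key = (key,)
        k = int(clu.get(key if len(key) > 1 else key[0], 0))
        if k > min(K, n):
            raise ValueError(f"ptm_enrichment: inconsistent counts for {key}")
        if K <= min_psms:
            continue
        rows.append((*key, int(K), k, hypergeom_sf(k, N, int(K), n)))
    return pd.DataFrame(rows, columns=[*keys, "population_psms", "cluster_psms", "p"]
                        ).sort_values("p").reset_index(drop=True)


def oxidized_protein_enrichment(protein_psm_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-protein hypergeometric enrichment of oxidized PSMs.

    Input columns: protein, total_psms, oxidized_psms. The population is
    the total PSM count with the total oxidized count as the marked class;
    each protein's PSMs are the draw. BH-adjusted across proteins."""
    df = protein_psm_counts.copy()
    N = int(df["total_psms"].sum())
    K = int(df["oxidized_psms"].sum())
    if (df["oxidized_psms"] > df["total_psms"]).any():
        raise ValueError("oxidized_protein_enrichment: oxidized > total for a protein")
    df["p"] = [hypergeom_sf(int(k), N, K, int(n))
               for k, n in zip(df["oxidized_psms"], df["total_psms"])]
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values("p").reset_index(drop=True)


# ---------------------------------------------------------------------------
# group-difference tests

def _kruskal_h(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def _index_partitions(indices: tuple, sizes: list[int]):
    if len(sizes) == 1:
        yield (indices,)
        return
    for comb in itertools.combinations(indices, sizes[0]):
        taken = set(comb)
        rest = tuple(i for i in indices if i not in taken)
        for tail in _index_partitions(rest, sizes[1:]):
            yield (comb, *tail)


def _kruskal_exact_p(groups: list[np.ndarray]) -> float:
    """Exact permutation p-value P(H >= H_obs), enumerating every distinct
    assignment of the pooled values to the group sizes. The tie-correction
    factor is shared by all permutations of the same pooled sample and
    cancels from the comparison, so raw rank-sum H values are compared."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    ranks = stats.rankdata(pooled)
    n = len(pooled)

    def raw_h(partition):
        return sum(ranks[list(ix)].sum() ** 2 / len(ix) for ix in partition)

    start = 0
    obs_partition = []
    for s in sizes:
        obs_partition.append(tuple(range(start, start + s)))
        start += s
    h_obs = raw_h(obs_partition)
    count = total = 0
    for partition in _index_partitions(tuple(range(n)), sizes):
        total += 1
        count += raw_h(partition) >= h_obs - 1e-12
    return count / total


def group_difference_tests(groups, test: str = "kruskal_wallis",
                           exact_max_n: int = 8):
    """Rank-based comparison of Z values across groups.

    ``mann_whitney`` (two groups): exact two-sided p for <= 10 per group,
    normal approximation with tie correction otherwise. ``kruskal_wallis``
    (>= 2 groups): tie-corrected H; for a pooled n <= *exact_max_n* the
    p-value is an exact permutation enumeration, else the chi-square
    approximation. Returns (statistic, p).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("group_difference_tests: empty group")
    if test == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney requires exactly 2 groups")
        a, b = groups
        method = "exact" if max(len(a), len(b)) <= 10 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal_wallis":
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            return 0.0, 1.0
        h = _kruskal_h(groups)
        if len(pooled) <= exact_max_n:
            return h, _kruskal_exact_p(groups)
        p = float(stats.chi2.sf(h, df=len(groups) - 1))
        return h, p
    raise ValueError(f"unknown test {test!r}")


def monte_carlo_enrichment_p(cluster_mask: np.ndarray, class_mask: np.ndarray,
                             n_permutations: int = 10_000, seed: int = 0) -> float:
    """Label-permutation null for the hypergeometric tail: P(overlap >= k)
    when cluster membership is randomly reassigned."""
    rng = np.random.default_rng(seed)
    k_obs = int(np.sum(cluster_mask & class_mask))
    n = int(cluster_mask.sum())
    idx = np.arange(len(cluster_mask))
    count = 0
    for _ in range(n_permutations):
        pick = rng.choice(idx, size=n, replace=False)
        if int(class_mask[pick].sum()) >= k_obs:
            count += 1
    return (count + 1) / (n_permutations + 1)
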