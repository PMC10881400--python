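"""PCA trajectory embedding and the dot-product maturation score.

Expression samples are embedded in the first three principal components
of variance-stabilized counts.  Per-condition centroids (mean over
replicates) define displacement vectors from the origin condition (the
control at the first neuronal timepoint, e.g. DMSO d25); the vector to
the control condition one step later (DMSO d50) defines the chronological
maturation trajectory.  A condition's maturation score is the dot product
of its displacement vector with this control vector, so score(origin) = 0
and score(control) = ||control vector||^2, and conditions advanced along
the trajectory score higher.

Also here: Pearson / complete-linkage correlation clustering of samples
and the redundancy-stopped k-means used for profiling z-scored rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # sample x (PC1, PC2, PC3)
    explained_variance: np.ndarray  # per retained PC, proportion
    selected_genes: list[str]


@dataclass
class TrajectoryScore:
    condition: tuple[str, str]  # (treatment, day)
    vector: np.ndarray
    score: float


@dataclass
class KMeansRedundancyResult:
    assignments: np.ndarray
    chosen_k: int
    centroids: np.ndarray
    stopped_reason: str


def variance_stabilize(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(median-of-ratios-normalized count + 1).

    Size factors follow the median-of-ratios scheme: the reference is the
    per-gene geometric mean over samples (genes with any zero count are
    excluded from the reference), and each sample's size factor is the
    median ratio of its counts to the reference.  This is a simple
    variance-flattening transform, adequate for within-embedding
    comparisons; it is not a full mean-variance model.
    """
    X = counts.to_numpy(dtype=float)
    if (X.sum(axis=0) == 0).any():
        bad = counts.columns[X.sum(axis=0) == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    positive = (X > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    logref = np.log(X[positive]).mean(axis=1)
    size_factors = np.exp(
        np.median(np.log(X[positive]) - logref[:, None], axis=0)
    )
    normalized = X / size_factors
    return pd.DataFrame(np.log2(normalized + 1.0), index=counts.index, columns=counts.columns)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (exposed for testing and inspection)."""
    X = counts.to_numpy(dtype=float)
    positive = (X > 0).all(axis=1)
    logref = np.log(X[positive]).mean(axis=1)
    sf = np.exp(np.median(np.log(X[positive]) - logref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def embed_pca(
    vst: pd.DataFrame,
    top_n: int = 1000,
    gene_list: Sequence[str] | None = None,
    n_components: int = 3,
) -> EmbeddingResult:
    """Embed samples in the top principal components of selected genes.

    Genes are selected either explicitly (``gene_list``, e.g. a
    differential-expression ranking) or as the ``top_n`` most variable
    (default).  Gene values are centred; components come from SVD.  The
    embedding is deterministic: each component's sign is fixed so that
    its largest-magnitude gene loading is positive.
    """
    n_samples = vst.shape[1]
    if n_samples < 4:
        raise ValueError(f"need >= 4 samples for a 3-PC embedding, got {n_samples}")
    if gene_list is not None:
        selected = [g for g in gene_list if g in vst.index][:top_n]
    else:
        if top_n > vst.shape[0]:
            raise ValueError(f"top_n={top_n} exceeds gene count {vst.shape[0]}")
        variances = vst.var(axis=1, ddof=1)
        selected = variances.sort_values(ascending=False, kind="stable").index[:top_n].tolist()
    X = vst.loc[selected].to_numpy().T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    k = min(n_components, n_samples - 1, len(selected))
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    # sign convention: largest-|loading| positive per component
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[j] *= -1
            coords[:, j] *= -1
    if k < n_components:  # degenerate: pad with zero coordinates
        coords = np.pad(coords, ((0, 0), (0, n_components - k)))
    expl = np.pad(pca.explained_variance_ratio_, (0, n_components - k))
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return EmbeddingResult(
        coordinates=pd.DataFrame(coords[:, :n_components], index=vst.columns, columns=cols),
        explained_variance=expl[:n_components],
        selected_genes=list(selected),
    )


def condition_centroids(
    emb: EmbeddingResult, meta: pd.DataFrame
) -> dict[tuple[str, str], np.ndarray]:
    """Mean replicate coordinates per (treatment, timepoint) condition."""
    centroids: dict[tuple[str, str], list[np.ndarray]] = {}
    for sample in emb.coordinates.index:
        if sample not in meta.index:
            raise KeyError(f"sample {sample!r} lacks metadata")
        key = (meta.loc[sample, "treatment"], meta.loc[sample, "timepoint"])
        centroids.setdefault(key, []).append(emb.coordinates.loc[sample].to_numpy())
    return {k: np.mean(v, axis=0) for k, v in centroids.items()}


def maturation_score(
    centroids: Mapping[tuple[str, str], np.ndarray],
    origin_condition: tuple[str, str],
    control_condition: tuple[str, str],
) -> list[TrajectoryScore]:
    """Dot-product maturation scores relative to the control trajectory.

    vector(c) = centroid(c) - centroid(origin); the score of condition c
    is vector(c) . vector(control).  The origin scores 0 and the control
    scores the squared norm of the control vector.
    """
    for cond in (origin_condition, control_condition):
        if cond not in centroids:
            raise KeyError(f"condition {cond} absent from centroids")
    origin = np.asarray(centroids[origin_condition], dtype=float)
    control_vec = np.asarray(centroids[control_condition], dtype=float) - origin
    if np.linalg.norm(control_vec) == 0:
        raise ValueError("degenerate trajectory: control vector has zero norm")
    out = []
    for cond in centroids:
        vec = np.asarray(centroids[cond], dtype=float) - origin
        out.append(TrajectoryScore(condition=cond, vector=vec, score=float(vec @ control_vec)))
    return out


def correlation_cluster(
    expr: pd.DataFrame, gene_subset: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of samples on 1 - Pearson r, complete linkage.

    Returns the scipy linkage matrix and the leaf order (sample labels).
    Samples are pre-sorted by label so that tie-breaking is deterministic.
    """
    data = expr.loc[gene_subset] if gene_subset is not None else expr
    if data.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    order = sorted(data.columns)
    data = data[order]
    sd = data.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError(f"zero-variance sample(s): {sd.index[sd == 0].tolist()}")
    corr = np.corrcoef(data.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce symmetry
    lk = linkage(squareform(dist, checks=False), method="complete")
    leaves = [order[i] for i in leaves_list(lk)]
    return lk, leaves


def linkage_to_newick(lk: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(lk, list(labels))
    return str(tree).strip()


def kmeans_redundancy(
    zscores: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 10,
    nstart: int = 25,
    seed: int = 0,
    min_cluster_frac: float = 0.01,
    max_centroid_r: float = 0.95,
) -> KMeansRedundancyResult:
    """k-means with k grown until clusters become redundant.

    For k from ``k_min`` upward the best of ``nstart`` random
    initializations (by within-cluster sum of squares) is kept.  Clusters
    are redundant when any cluster holds fewer than ``min_cluster_frac``
    of the rows or two centroid profiles correlate above
    ``max_centroid_r``; the previous k is then returned.  Rows are
    expected to be z-scored (mean ~0, sd ~1).
    """
    if k_min > k_max:
        raise ValueError(f"k_min={k_min} > k_max={k_max}")
    X = zscores.to_numpy(dtype=float)
    n = X.shape[0]
    previous: KMeansRedundancyResult | None = None
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=nstart, random_state=seed)
        labels = km.fit_predict(X)
        sizes = np.bincount(labels, minlength=k)
        redundant = (sizes < max(1, min_cluster_frac * n)).any()
        if not redundant and k >= 2:
            c = km.cluster_centers_
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(c)
            iu = np.triu_indices(k, 1)
            redundant = bool(np.nan_to_num(r[iu], nan=1.0).max() > max_centroid_r)
        current = KMeansRedundancyResult(
            assignments=labels, chosen_k=k, centroids=km.cluster_centers_, stopped_reason=""
        )
        if redundant:
            if previous is None:
                warnings.warn("degenerate data: redundancy already at k_min")
                current.stopped_reason = "redundant_at_k_min"
                return current
            previous.stopped_reason = f"redundancy_at_k={k}"
            return previous
        previous = current
    previous.stopped_reason = "k_max_reached"
    return previous
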