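"""Stage 2: consensus clustering of each interpretable group into subclusters.

Each group's features are clustered by an ensemble of base methods
(affinity propagation, Louvain on a kNN graph, average-linkage
hierarchical clustering with an adaptive tree cut, DBSCAN) under several
distance metrics. Binary co-membership matrices from every run are
averaged into a consensus matrix, whose thresholded graph is clustered by
Louvain to give the final subclusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.cluster import DBSCAN, AffinityPropagation

from .datatypes import OmicsMatrix, RunConfig

logger = logging.getLogger("enodal")

NOISE = -1


def compute_distance(X: np.ndarray, metric: str = "pearson") -> np.ndarray:
    """Pairwise feature distances from profile rows of X.

    Metrics: "pearson" (1 - r), "spearman" (1 - rank r), "euclidean"
    (Euclidean on per-feature z-scores). Zero-variance features get
    distance 1 to every other feature under the correlation metrics.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[0]
    sd = X.std(axis=1)
    flat = sd == 0
    if metric in ("pearson", "spearman"):
        M = np.apply_along_axis(rankdata, 1, X) if metric == "spearman" else X
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(M)
        R = np.nan_to_num(R, nan=0.0)
        D = 1.0 - R
        if flat.any():
            logger.warning("%d zero-variance feature(s): correlation distance set to 1", flat.sum())
            D[flat, :] = 1.0
            D[:, flat] = 1.0
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2, 0.0, 2.0)
    elif metric == "euclidean":
        Zs = (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)[:, None]
        sq = np.einsum("ij,ij->i", Zs, Zs)
        D2 = sq[:, None] + sq[None, :] - 2 * Zs @ Zs.T
        D = np.sqrt(np.clip((D2 + D2.T) / 2, 0.0, None))
        np.fill_diagonal(D, 0.0)
    else:
        raise ValueError(f"unknown distance metric '{metric}'")
    assert D.shape == (p, p)
    return D


def _gap_tree_cut(linkage_matrix: np.ndarray, sensitivity: float) -> np.ndarray:
    """Adaptive cut of a dendrogram at the largest late merge-height gap.

    The cut height is placed inside the widest gap between consecutive
    merge heights among the last ``ceil(sensitivity * m)`` merges, giving a
    data-driven cluster count. A gap below 5% of the total height range is
    treated as structureless (single cluster). ``sensitivity`` plays the
    role of a deep-split knob: larger values examine more of the dendrogram
    and so allow finer splits.
    """
    heights = linkage_matrix[:, 2]
    m = len(heights)
    if m < 2:
        return np.zeros(m + 1, dtype=int)
    tail = max(2, int(np.ceil(sensitivity * m)))
    gaps = np.diff(heights)[-(tail - 1):]
    if gaps.size == 0 or gaps.max() < 0.05 * (heights[-1] - heights[0] + 1e-12):
        return np.zeros(m + 1, dtype=int)
    pos = m - 1 - (tail - 1) + int(np.argmax(gaps))
    cut = (heights[pos] + heights[pos + 1]) / 2
    return hierarchy.fcluster(linkage_matrix, t=cut, criterion="distance") - 1


def _knn_graph(D: np.ndarray, k: int) -> nx.Graph:
    p = D.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(p))
    order = np.argsort(D, axis=1, kind="stable")
    scale = np.median(D[D > 0]) if (D > 0).any() else 1.0
    for i in range(p):
        neighbors = [j for j in order[i] if j != i][:k]
        for j in neighbors:
            G.add_edge(i, j, weight=float(np.exp(-D[i, j] / max(scale, 1e-12))))
    return G


def _labels_from_communities(communities, p: int) -> np.ndarray:
    labels = np.empty(p, dtype=int)
    for c, members in enumerate(sorted(communities, key=lambda s: (-len(s), min(s)))):
        for i in members:
            labels[i] = c
    return labels


@dataclass
class BaseClustering:
    """One base labelling of a group's features; -1 marks noise points."""

    method: str
    metric: str
    labels: np.ndarray
    params: dict


def run_base_clusterers(
    X: np.ndarray, config: RunConfig, seed: int
) -> list[BaseClustering]:
    """Run every (method x metric) base clusterer; individual failures are skipped."""
    p = X.shape[0]
    results: list[BaseClustering] = []
    for metric in config.distance_metrics:
        D = compute_distance(X, metric)
        # sklearn's own euclidean affinity is the negative squared distance
        sim = -(D**2) if metric == "euclidean" else -D

        # affinity propagation on the similarity, preference = median similarity
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ap = AffinityPropagation(
                    affinity="precomputed",
                    preference=float(np.median(sim)),
                    damping=0.9,  # correlation similarities need heavy damping to converge
                    random_state=seed,
                    max_iter=500,
                )
                lab = ap.fit_predict(sim)
            if lab.min() < 0 or np.all(lab == -1):
                raise RuntimeError("affinity propagation did not converge")
            results.append(BaseClustering("affinity_propagation", metric, lab, {}))
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("affinity propagation (%s) skipped: %s", metric, exc)

        # Louvain communities on the kNN graph
        try:
            k = int(np.ceil(np.sqrt(p)))
            G = _knn_graph(D, k)
            comms = nx.community.louvain_communities(
                G, weight="weight", resolution=config.louvain_resolution, seed=seed
            )
            results.append(
                BaseClustering("knn_louvain", metric, _labels_from_communities(comms, p), {"k": k})
            )
        except Exception as exc:  # pragma: no cover
            logger.warning("kNN Louvain (%s) skipped: %s", metric, exc)

        # average-linkage hierarchical clustering with adaptive gap cut
        try:
            Zl = hierarchy.linkage(squareform(D, checks=False), method="average")
            lab = _gap_tree_cut(Zl, config.tree_cut_sensitivity)
            results.append(
                BaseClustering("hierarchical_gapcut", metric, lab,
                               {"sensitivity": config.tree_cut_sensitivity})
            )
        except Exception as exc:  # pragma: no cover
            logger.warning("hierarchical clustering (%s) skipped: %s", metric, exc)

        # DBSCAN with eps at the knee of the k-distance curve
        try:
            kdist = np.sort(np.partition(D, 5, axis=1)[:, 5])
            gaps = np.diff(kdist)
            eps = float(kdist[int(np.argmax(gaps))]) if gaps.size else float(kdist[-1])
            eps = max(eps, 1e-6)
            lab = DBSCAN(eps=eps, min_samples=5, metric="precomputed").fit_predict(D)
            results.append(BaseClustering("dbscan", metric, lab, {"eps": eps}))
        except Exception as exc:  # pragma: no cover
            logger.warning("DBSCAN (%s) skipped: %s", metric, exc)

    return results


def co_membership(labels: np.ndarray) -> np.ndarray:
    """Binary same-cluster indicator; noise points co-member only with themselves."""
    labels = np.asarray(labels)
    M = (labels[:, None] == labels[None, :]).astype(float)
    noise = labels == NOISE
    if noise.any():
        M[noise, :] = 0.0
        M[:, noise] = 0.0
    np.fill_diagonal(M, 1.0)
    return M


def consensus_matrix(co_memberships: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of binary co-membership matrices."""
    if not co_memberships:
        raise ValueError("need at least one co-membership matrix")
    return np.mean(np.stack(co_memberships), axis=0)


def louvain_consensus(
    C: np.ndarray, edge_threshold: float, resolution: float, seed: int
) -> np.ndarray:
    """Louvain communities of the thresholded consensus graph.

    Edges keep pairs whose consensus weight exceeds ``edge_threshold``;
    isolated nodes become singleton subclusters.
    """
    p = C.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(p))
    iu, ju = np.triu_indices(p, k=1)
    mask = C[iu, ju] > edge_threshold
    G.add_weighted_edges_from(
        (int(i), int(j), float(w)) for i, j, w in zip(iu[mask], ju[mask], C[iu, ju][mask])
    )
    if G.number_of_edges() == 0:
        logger.warning("empty consensus graph: every feature becomes a singleton")
        return np.arange(p)
    comms = nx.community.louvain_communities(
        G, weight="weight", resolution=resolution, seed=seed
    )
    return _labels_from_communities(comms, p)


@dataclass
class SubclusterResult:
    """Final subcluster structure of one interpretable group."""

    group: str
    feature_ids: list[str]
    consensus: np.ndarray | None
    labels: np.ndarray                  # int label per feature
    subcluster_ids: list[str]           # "<group>_C<i>", size-descending

    @property
    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {sc: [] for sc in self.subcluster_ids}
        for f, lab in zip(self.feature_ids, self.labels):
            out[self.subcluster_ids[lab]].append(f)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "group": self.group,
                "subcluster": [self.subcluster_ids[lab] for lab in self.labels],
            }
        )


def _order_by_size(labels: np.ndarray, group: str) -> tuple[np.ndarray, list[str]]:
    """Relabel so subcluster 0 is the largest; ties broken by smallest member index."""
    uniq = np.unique(labels)
    order = sorted(uniq, key=lambda c: (-(labels == c).sum(), int(np.flatnonzero(labels == c)[0])))
    remap = {old: new for new, old in enumerate(order)}
    new_labels = np.array([remap[lab] for lab in labels])
    ids = [f"{group}_C{i + 1}" for i in range(len(order))]
    return new_labels, ids


def subcluster_group(
    omics_subset: OmicsMatrix, group: str, config: RunConfig, seed: int | None = None
) -> SubclusterResult:
    """Full consensus pipeline for one interpretable group.

    Groups smaller than ``min_group_size_for_clustering`` are kept whole as
    a single subcluster "<group>_C1".
    """
    seed = config.seed if seed is None else seed
    p = omics_subset.p
    if p < config.min_group_size_for_clustering:
        return SubclusterResult(
            group, list(omics_subset.feature_ids), None,
            np.zeros(p, dtype=int), [f"{group}_C1"],
        )
    base = run_base_clusterers(omics_subset.Z, config, seed)
    if not base:
        logger.warning("all base clusterers failed for group %s; kept as one subcluster", group)
        return SubclusterResult(
            group, list(omics_subset.feature_ids), None,
            np.zeros(p, dtype=int), [f"{group}_C1"],
        )
    C = consensus_matrix([co_membership(b.labels) for b in base])
    labels = louvain_consensus(
        C, config.consensus_edge_threshold, config.louvain_resolution, seed
    )
    labels, ids = _order_by_size(labels, group)
    return SubclusterResult(group, list(omics_subset.feature_ids), C, labels, ids)
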