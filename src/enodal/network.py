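"""Tripartite network over hub features, subclusters, and phenotypes.

Feature-phenotype Spearman correlations are screened at p < .01 (the
non-significant entries are zeroed); each subcluster is linked to a
phenotype when a competitive rank test finds its members' absolute
correlations shifted relative to the rest of the matrix; hub features are
the subcluster members most correlated with the subcluster's first
principal component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import OmicsMatrix, PhenotypeMatrix

logger = logging.getLogger("enodal")


def spearman_filter(
    omics: OmicsMatrix, phenotypes: PhenotypeMatrix, p_cut: float = 0.01
) -> np.ndarray:
    """Feature x phenotype Spearman correlations, zeroing non-significant entries.

    P-values use the t approximation for the rank correlation; entries with
    p >= p_cut are set to zero. Constant features or phenotypes give zero.
    """
    Z, P = omics.Z, phenotypes.P
    n = Z.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for the rank-correlation screen")
    Rz = np.apply_along_axis(stats.rankdata, 1, Z)
    Rp = np.apply_along_axis(stats.rankdata, 0, P)
    Rz = Rz - Rz.mean(axis=1, keepdims=True)
    Rp = Rp - Rp.mean(axis=0, keepdims=True)
    sz = np.sqrt(np.einsum("ij,ij->i", Rz, Rz))
    sp = np.sqrt(np.einsum("ij,ij->j", Rp, Rp))
    flat_z, flat_p = sz == 0, sp == 0
    if flat_z.any() or flat_p.any():
        logger.warning("constant feature/phenotype: correlation set to 0")
    denom = np.outer(np.where(flat_z, 1.0, sz), np.where(flat_p, 1.0, sp))
    rho = (Rz @ Rp) / denom
    rho[flat_z, :] = 0.0
    rho[:, flat_p] = 0.0
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1 - rho**2, 1e-300))
    pvals = 2 * stats.t.sf(np.abs(t), n - 2)
    out = np.where(pvals < p_cut, rho, 0.0)
    return out


def subcluster_phenotype_edges(
    filtered_rho: np.ndarray,
    members_by_subcluster: dict[str, list[str]],
    feature_ids: list[str],
    omics: OmicsMatrix,
    phenotypes: PhenotypeMatrix,
    p_cut: float = 0.01,
    method: str = "ranksum",
) -> list[tuple[str, str, float, int]]:
    """Competitive multiset-style test linking subclusters to phenotypes.

    For each (subcluster J, phenotype m) the absolute screened correlations
    of J's members are compared against those of all other features by a
    two-sided Wilcoxon rank-sum test ("ranksum") or a mean-rank Z test
    ("meanrank"). An edge is emitted when p < p_cut; its sign is the sign
    of the Spearman correlation between the per-sample median abundance of
    J's features and the phenotype. Returns (subcluster, phenotype, p, sign).
    """
    idx = {f: i for i, f in enumerate(feature_ids)}
    oidx = {f: i for i, f in enumerate(omics.feature_ids)}
    edges: list[tuple[str, str, float, int]] = []
    abs_rho = np.abs(filtered_rho)
    p_total = abs_rho.shape[0]
    for sc_id in sorted(members_by_subcluster):
        members = members_by_subcluster[sc_id]
        rows = np.array([idx[m] for m in members])
        if rows.size < 2 or rows.size >= p_total:
            continue
        mask = np.zeros(p_total, dtype=bool)
        mask[rows] = True
        median_profile = np.median(omics.Z[[oidx[m] for m in members]], axis=0)
        for m, ph in enumerate(phenotypes.phenotype_ids):
            x_in, x_out = abs_rho[mask, m], abs_rho[~mask, m]
            if np.all(x_in == 0):
                continue
            if method == "ranksum":
                pval = stats.mannwhitneyu(x_in, x_out, alternative="two-sided").pvalue
            elif method == "meanrank":
                ranks = stats.rankdata(abs_rho[:, m])
                rin = ranks[mask].mean()
                mu = (p_total + 1) / 2
                sd = np.sqrt((p_total - rows.size) * (p_total + 1) / (12 * rows.size))
                pval = 2 * stats.norm.sf(abs(rin - mu) / sd) if sd > 0 else 1.0
            else:
                raise ValueError(f"unknown multiset method '{method}'")
            if pval < p_cut:
                rho_med = stats.spearmanr(median_profile, phenotypes.P[:, m]).statistic
                sign = 1 if rho_med >= 0 else -1
                edges.append((sc_id, ph, float(pval), sign))
    return edges


def hub_features(
    member_ids: list[str], omics: OmicsMatrix, top: int = 5
) -> list[tuple[str, float]]:
    """Top members by |Pearson correlation| with the subcluster's PC1.

    PC1 sample scores come from the SVD of the member x sample matrix after
    per-feature centering and scaling, oriented to correlate non-negatively
    with the members' mean profile. Ties break by feature ID order. Fewer
    than 2 members give an empty list.
    """
    if len(member_ids) < 2:
        return []
    sub = omics.subset(member_ids)
    X = sub.Z
    sd = X.std(axis=1)
    Xs = (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)[:, None]
    _, _, vt = np.linalg.svd(Xs, full_matrices=False)
    pc1 = vt[0]
    mean_profile = Xs.mean(axis=0)
    if mean_profile.std() > 0 and np.corrcoef(pc1, mean_profile)[0, 1] < 0:
        pc1 = -pc1
    cors = []
    for j, f in enumerate(member_ids):
        if Xs[j].std() == 0 or pc1.std() == 0:
            cors.append(0.0)
        else:
            cors.append(float(np.corrcoef(Xs[j], pc1)[0, 1]))
    order = sorted(range(len(member_ids)), key=lambda j: (-abs(cors[j]), member_ids[j]))
    return [(member_ids[j], cors[j]) for j in order[:top]]


@dataclass
class AnnotatedNetwork:
    """Tripartite graph: subcluster-phenotype and subcluster-hub edges."""

    graph: nx.Graph
    pc1_scores: dict[str, np.ndarray] = field(default_factory=dict)

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        for u, v, data in sorted(self.graph.edges(data=True)):
            rows.append(
                (u, v, data["edge_type"], data.get("weight", np.nan),
                 {1: "+", -1: "-"}.get(data.get("sign"), ""), data.get("p", np.nan))
            )
        return pd.DataFrame(rows, columns=["source", "target", "edge_type", "weight", "sign", "p"])

    def write_edges(self, path) -> None:
        self.edge_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def write_graphml(self, path) -> None:
        G = nx.Graph()
        for node, data in self.graph.nodes(data=True):
            G.add_node(node, **{k: str(v) for k, v in data.items()})
        for u, v, data in self.graph.edges(data=True):
            G.add_edge(u, v, **{k: (float(v2) if isinstance(v2, (int, float)) else str(v2))
                                for k, v2 in data.items() if v2 is not None})
        nx.write_graphml(G, path)


def build_network(
    omics: OmicsMatrix,
    phenotypes: PhenotypeMatrix,
    members_by_subcluster: dict[str, list[str]],
    p_cut: float = 0.01,
    multiset_method: str = "ranksum",
) -> AnnotatedNetwork:
    """Assemble the hub-feature / subcluster / phenotype network."""
    feature_ids = [f for members in members_by_subcluster.values() for f in members]
    sub = omics.subset(feature_ids)
    rho = spearman_filter(sub, phenotypes, p_cut)
    sp_edges = subcluster_phenotype_edges(
        rho, members_by_subcluster, feature_ids, omics, phenotypes, p_cut, multiset_method
    )
    G = nx.Graph()
    pc1_scores: dict[str, np.ndarray] = {}
    for ph in phenotypes.phenotype_ids:
        G.add_node(ph, node_type="phenotype")
    for sc_id in sorted(members_by_subcluster):
        members = members_by_subcluster[sc_id]
        G.add_node(sc_id, node_type="subcluster", size=len(members))
        for f, cor in hub_features(members, omics):
            if not G.has_node(f):
                G.add_node(f, node_type="feature")
            G.add_edge(sc_id, f, edge_type="subcluster-hub", weight=cor,
                       sign=1 if cor >= 0 else -1)
        if len(members) >= 2:
            X = omics.subset(members).Z
            sd = X.std(axis=1)
            Xs = (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)[:, None]
            _, _, vt = np.linalg.svd(Xs, full_matrices=False)
            pc1 = vt[0]
            mp = Xs.mean(axis=0)
            if mp.std() > 0 and np.corrcoef(pc1, mp)[0, 1] < 0:
                pc1 = -pc1
            pc1_scores[sc_id] = pc1
    for sc_id, ph, pval, sign in sp_edges:
        G.add_edge(sc_id, ph, edge_type="subcluster-phenotype", p=pval, sign=sign,
                   weight=float(sign))
    return AnnotatedNetwork(G, pc1_scores)
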