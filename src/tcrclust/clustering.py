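"""V/J-stratified Hamming-distance clonotype clustering and clonal networks.

The procedure collapses single-pair cells to clonotypes (chain, V gene,
J gene, junction-aa), stratifies them by V-gene *subgroup*, J gene and
junction length, and clusters junctions within each stratum at a Hamming
distance (HD) cutoff of 1:

* single linkage: connected components of the graph joining clonotypes at
  HD <= 1 (identical junctions carried by different V genes of the same
  subgroup sit at HD 0);
* complete linkage: agglomerative groups whose members are *pairwise*
  within HD 1 (used to dissect superclusters into tightly related
  sub-clusters).

Junctions of different lengths never co-cluster (HD is undefined across
lengths and treated as infinite).  Cluster numbering is deterministic:
strata are sorted lexicographically, clusters within a stratum by
descending clonotype count then lexicographically smallest junction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .io import subgroup
from .usage import PositionWeightMatrix, position_weight_matrix

INF = math.inf


@dataclass
class ClonotypeEntry:
    """One collapsed clonotype with its supporting cells."""

    chain: str
    v_gene: str
    j_gene: str
    junction_aa: str
    n_cells: int
    subjects: frozenset
    subset_counts: dict

    @property
    def key(self) -> tuple:
        return (self.chain, self.v_gene, self.j_gene, self.junction_aa)

    @property
    def label(self) -> str:
        return f"{self.v_gene}|{self.j_gene}|{self.junction_aa}"


@dataclass
class ClonotypeCluster:
    """One cluster within a (V subgroup, J, length) stratum, plus metrics."""

    cluster_id: int
    chain: str
    stratum: tuple  # (v_stratum, j_stratum, junction_length)
    members: list[ClonotypeEntry]
    linkage: str
    # filled by cluster_metrics:
    n_cells: int = 0
    n_clonotypes: int = 0
    density: float = 0.0
    degrees: dict = field(default_factory=dict)  # member index -> degree
    centrality_ranks: dict = field(default_factory=dict)  # member index -> rank (1 = hub)
    max_degree: int = 0
    mean_degree: float = 0.0
    publicity: int = 0
    subset_composition: dict = field(default_factory=dict)
    subclusters: list = field(default_factory=list)


def hamming(a: str, b: str) -> float:
    """Hamming distance; infinite for unequal lengths (never clusterable)."""
    if len(a) != len(b):
        return INF
    return sum(x != y for x, y in zip(a, b))


def collapse_clonotypes(cells: pd.DataFrame, chain: str) -> list[ClonotypeEntry]:
    """Collapse single-pair cells of one chain to clonotypes.

    ``cells`` is the output of :func:`tcrclust.usage.single_pair_cells`.
    Returned entries are sorted by (v_gene, j_gene, junction_aa) so results
    are independent of input row order.
    """
    df = cells.loc[cells["chain"] == chain]
    entries = []
    for (v, j, junc), grp in df.groupby(["v_gene", "j_gene", "junction_aa"], sort=True):
        entries.append(
            ClonotypeEntry(
                chain=chain,
                v_gene=v,
                j_gene=j,
                junction_aa=junc,
                n_cells=len(grp),
                subjects=frozenset(grp["subject_id"]),
                subset_counts=grp["subset_label"].value_counts().to_dict(),
            )
        )
    return entries


def _stratum_key(entry: ClonotypeEntry, v_level: str, j_level: str) -> tuple:
    v = subgroup(entry.v_gene) if v_level == "subgroup" else entry.v_gene
    j = subgroup(entry.j_gene) if j_level == "subgroup" else entry.j_gene
    return (v, j, len(entry.junction_aa))


def _pairwise_hd(junctions: list[str]) -> np.ndarray:
    """All-pairs Hamming distances for equal-length junctions."""
    arr = np.array([list(j.encode()) for j in junctions], dtype=np.uint8)
    m = len(junctions)
    out = np.zeros((m, m), dtype=np.int32)
    # row-chunked to keep memory bounded in large strata
    step = max(1, int(2e7 // max(1, m * arr.shape[1])))
    for i0 in range(0, m, step):
        block = (arr[i0 : i0 + step, None, :] != arr[None, :, :]).sum(axis=2)
        out[i0 : i0 + step] = block
    return out


def _cluster_stratum(
    members: list[ClonotypeEntry], method: str, cutoff: int
) -> list[list[int]]:
    """Group member indices within one stratum; returns lists of indices."""
    m = len(members)
    if m == 1:
        return [[0]]
    dmat = _pairwise_hd([e.junction_aa for e in members])
    if method == "single":
        graph = nx.from_numpy_array(dmat <= cutoff)
        comps = [sorted(c) for c in nx.connected_components(graph)]
    elif method == "complete":
        z = scipy_linkage(squareform(dmat, checks=False), method="complete")
        labels = fcluster(z, t=cutoff, criterion="distance")
        comps = [
            sorted(np.flatnonzero(labels == lab).tolist())
            for lab in np.unique(labels)
        ]
    else:
        raise ValueError(f"unknown linkage {method!r}")
    return comps


def stratified_clusters(
    entries: list[ClonotypeEntry],
    linkage: str = "single",
    cutoff: int = 1,
    v_level: str = "subgroup",
    j_level: str = "gene",
) -> list[ClonotypeCluster]:
    """Cluster clonotypes at an HD cutoff within (V, J, length) strata.

    ``v_level`` / ``j_level`` select the stratification resolution
    (``"subgroup"`` strips the gene-member suffix, ``"gene"`` keeps it).
    Cluster ids are globally unique and deterministic.
    """
    entries = sorted(entries, key=lambda e: (e.v_gene, e.j_gene, e.junction_aa))
    strata: dict[tuple, list[ClonotypeEntry]] = {}
    for e in entries:
        strata.setdefault(_stratum_key(e, v_level, j_level), []).append(e)
    clusters: list[ClonotypeCluster] = []
    next_id = 1
    for key in sorted(strata, key=lambda k: (k[0], k[1], k[2])):
        members = strata[key]
        groups = _cluster_stratum(members, linkage, cutoff)
        groups.sort(key=lambda idx: (-len(idx), min(members[i].junction_aa for i in idx)))
        for idx in groups:
            chain = members[idx[0]].chain
            clusters.append(
                ClonotypeCluster(
                    cluster_id=next_id,
                    chain=chain,
                    stratum=key,
                    members=[members[i] for i in idx],
                    linkage=linkage,
                )
            )
            next_id += 1
    return clusters


def build_network(cluster: ClonotypeCluster, cutoff: int = 1) -> nx.Graph:
    """1-HD relatedness graph over a cluster's clonotypes.

    Nodes are member indices with clonotype attributes; edges join members
    within the HD cutoff (identical junctions on different V genes of the
    stratum subgroup sit at HD 0 and are also joined).
    """
    g = nx.Graph()
    for i, e in enumerate(cluster.members):
        g.add_node(
            i, label=e.label, junction_aa=e.junction_aa, v_gene=e.v_gene,
            j_gene=e.j_gene, n_cells=e.n_cells,
            subjects=sorted(e.subjects), subset_counts=e.subset_counts,
        )
    juncs = [e.junction_aa for e in cluster.members]
    if len(juncs) > 1:
        dmat = _pairwise_hd(juncs)
        for i, j in zip(*np.nonzero(np.triu(dmat <= cutoff, k=1))):
            g.add_edge(int(i), int(j), hd=int(dmat[i, j]))
    return g


def cluster_metrics(
    cluster: ClonotypeCluster, network: nx.Graph | None = None
) -> ClonotypeCluster:
    """Fill size, density, degree centrality, publicity and composition."""
    if network is None:
        network = build_network(cluster)
    n = len(cluster.members)
    cluster.n_clonotypes = n
    cluster.n_cells = sum(e.n_cells for e in cluster.members)
    n_edges = network.number_of_edges()
    cluster.density = (2.0 * n_edges / (n * (n - 1))) if n >= 2 else 0.0
    degrees = {i: int(d) for i, d in network.degree()}
    cluster.degrees = degrees
    order = sorted(degrees, key=lambda i: (-degrees[i], cluster.members[i].junction_aa))
    ranks: dict[int, int] = {}
    rank = 0
    last_deg = None
    for pos, i in enumerate(order, start=1):
        if degrees[i] != last_deg:
            rank = pos
            last_deg = degrees[i]
        ranks[i] = rank
    cluster.centrality_ranks = ranks
    cluster.max_degree = max(degrees.values()) if degrees else 0
    cluster.mean_degree = float(np.mean(list(degrees.values()))) if degrees else 0.0
    cluster.publicity = len(frozenset().union(*(e.subjects for e in cluster.members)))
    comp: dict[str, int] = {}
    for e in cluster.members:
        for subset, k in e.subset_counts.items():
            comp[subset] = comp.get(subset, 0) + k
    cluster.subset_composition = {s: k / cluster.n_cells for s, k in sorted(comp.items())}
    return cluster


def subcluster_complete_linkage(cluster: ClonotypeCluster, cutoff: int = 1) -> list[dict]:
    """Complete-linkage sub-clusters of a single-linkage cluster, ranked.

    Each sub-cluster (all members pairwise within HD 1) gets a PWM flagging
    its variable positions.  Ranking is by clonotype count, ties by the
    lexicographically smallest junction.  The ranked list is also stored on
    ``cluster.subclusters``.
    """
    groups = _cluster_stratum(cluster.members, "complete", cutoff)
    groups.sort(key=lambda idx: (-len(idx), min(cluster.members[i].junction_aa for i in idx)))
    out = []
    for rank, idx in enumerate(groups, start=1):
        juncs = [cluster.members[i].junction_aa for i in idx]
        pwm = position_weight_matrix(juncs)
        out.append(
            {
                "rank": rank,
                "member_indices": idx,
                "junctions": juncs,
                "n_clonotypes": len(idx),
                "n_cells": sum(cluster.members[i].n_cells for i in idx),
                "pwm": pwm,
                "variable_positions": pwm.variable_positions,
            }
        )
    cluster.subclusters = out
    return out


def clusters_to_frame(clusters: list[ClonotypeCluster]) -> pd.DataFrame:
    """Per-cluster metrics table (clusters must have metrics filled)."""
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "chain": c.chain,
                "v_stratum": c.stratum[0],
                "j_stratum": c.stratum[1],
                "junction_length": c.stratum[2],
                "n_clonotypes": c.n_clonotypes,
                "n_cells": c.n_cells,
                "density": c.density,
                "max_degree": c.max_degree,
                "mean_degree": c.mean_degree,
                "publicity": c.publicity,
                "top_subset": max(c.subset_composition, key=c.subset_composition.get)
                if c.subset_composition else "",
            }
            for c in clusters
        ]
    )


def cluster_summary(clusters: list[ClonotypeCluster], n_subjects: int) -> dict:
    """Per-chain repertoire summary: counts, publicity spectrum, top clusters."""
    if not clusters:
        raise ValueError("no clusters")
    df = clusters_to_frame(clusters)
    publicity_counts = df["publicity"].value_counts().sort_index().to_dict()
    top = {
        metric: int(df.sort_values([metric, "cluster_id"], ascending=[False, True])
                    .iloc[0]["cluster_id"])
        for metric in ("n_cells", "n_clonotypes", "density", "max_degree", "publicity")
    }
    return {
        "chain": clusters[0].chain,
        "n_clonotypes": int(df["n_clonotypes"].sum()),
        "n_clusters": len(clusters),
        "publicity_spectrum": publicity_counts,
        "frac_full_publicity": float((df["publicity"] == n_subjects).mean()),
        "top_clusters": top,
        "table": df,
    }


def repertoire_overlap(
    entries: list[ClonotypeEntry], metric: str = "jaccard"
) -> pd.DataFrame:
    """Pairwise subset-by-subset clonotype overlap matrix.

    ``jaccard`` compares clonotype identity sets; ``morisita`` is the
    abundance-weighted Morisita-Horn index on clonotype cell counts.
    Symmetric with unit diagonal.
    """
    subsets = sorted({s for e in entries for s in e.subset_counts})
    if metric == "jaccard":
        sets = {
            s: {e.key for e in entries if s in e.subset_counts} for s in subsets
        }
        mat = pd.DataFrame(0.0, index=subsets, columns=subsets)
        for a in subsets:
            for b in subsets:
                union = sets[a] | sets[b]
                mat.at[a, b] = (
                    len(sets[a] & sets[b]) / len(union) if union else 0.0
                )
    elif metric == "morisita":
        counts = pd.DataFrame(0.0, index=[e.key for e in entries], columns=subsets)
        for e in entries:
            for s, k in e.subset_counts.items():
                counts.at[e.key, s] = k
        x = counts.to_numpy()
        totals = x.sum(axis=0)
        mat = pd.DataFrame(0.0, index=subsets, columns=subsets)
        for i, a in enumerate(subsets):
            for j, b in enumerate(subsets):
                if totals[i] == 0 or totals[j] == 0:
                    mat.at[a, b] = 0.0
                    continue
                num = 2.0 * (x[:, i] * x[:, j]).sum()
                da = (x[:, i] ** 2).sum() / totals[i] ** 2
                db = (x[:, j] ** 2).sum() / totals[j] ** 2
                mat.at[a, b] = num / ((da + db) * totals[i] * totals[j])
    else:
        raise ValueError(f"unknown overlap metric {metric!r}")
    np.fill_diagonal(mat.to_numpy(), 1.0)
    for a in subsets:
        mat.at[a, a] = 1.0
    return mat


def network_edge_table(cluster: ClonotypeCluster, network: nx.Graph) -> pd.DataFrame:
    """Edge list export (source/target clonotype labels, HD)."""
    rows = [
        {
            "cluster_id": cluster.cluster_id,
            "source": cluster.members[i].label,
            "target": cluster.members[j].label,
            "hd": data["hd"],
        }
        for i, j, data in network.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "source", "target", "hd"])
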