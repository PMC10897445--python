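"""Transcription-factor regulon clustering and overlays.

The upstream TF ranking (a ChEA3-style top-N prediction) is consumed as a
binary TF x target table, never computed here.  TFs are clustered on the
Jaccard distance between their target sets (average linkage, k groups,
k = 3 by default); genes inherit the cluster(s) of the TFs that regulate
them, with multi-cluster co-regulation flagged explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_score


@dataclass
class RegulonTable:
    """Binary TF x gene edge matrix with row/column ids."""

    tfs: list[str]
    targets: list[str]
    edges: np.ndarray  # (n_tfs, n_targets) of {0, 1}

    @classmethod
    def from_edges(cls, table: pd.DataFrame) -> "RegulonTable":
        tfs = sorted(table["tf"].unique())
        targets = sorted(table["target"].unique())
        ti = {t: i for i, t in enumerate(tfs)}
        gi = {g: j for j, g in enumerate(targets)}
        m = np.zeros((len(tfs), len(targets)), dtype=int)
        for tf, g in zip(table["tf"], table["target"]):
            m[ti[tf], gi[g]] = 1
        if (m.sum(axis=1) == 0).any():
            raise ValueError("every TF needs at least one target")
        return cls(tfs=tfs, targets=targets, edges=m)

    def target_set(self, tf: str) -> set[str]:
        i = self.tfs.index(tf)
        return {g for g, e in zip(self.targets, self.edges[i]) if e}


@dataclass
class RegClusterResult:
    tf_cluster: dict[str, int]
    gene_cluster: dict[str, tuple[int, ...]]  # sorted cluster memberships
    k: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    def multi_cluster_genes(self) -> list[str]:
        return [g for g, cs in self.gene_cluster.items() if len(cs) > 1]


def _jaccard_distance(edges: np.ndarray) -> np.ndarray:
    inter = edges @ edges.T
    sizes = edges.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        d = 1.0 - inter / np.where(union == 0, 1, union)
    np.fill_diagonal(d, 0.0)
    return d


def cluster_regulons(regulons: RegulonTable, k: int = 3,
                     report_silhouette: bool = True) -> RegClusterResult:
    """Average-linkage Jaccard clustering of TFs into k co-regulatory groups.

    k = 3 follows the study's reported structure but is asserted, not
    derived; a silhouette-over-k diagnostic is attached so the choice can
    be inspected.  Results are invariant to TF and gene input order.
    """
    n = len(regulons.tfs)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available TFs")
    d = _jaccard_distance(regulons.edges)
    z = hierarchy.average(squareform(d, checks=False))
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    # canonical ids: clusters numbered by their first TF in sorted order
    order = {}
    for tf, c in sorted(zip(regulons.tfs, raw)):
        order.setdefault(c, len(order) + 1)
    tf_cluster = {tf: order[c] for tf, c in zip(regulons.tfs, raw)}

    gene_cluster: dict[str, tuple[int, ...]] = {}
    for j, gene in enumerate(regulons.targets):
        cs = {tf_cluster[regulons.tfs[i]] for i in np.nonzero(regulons.edges[:, j])[0]}
        if cs:
            gene_cluster[gene] = tuple(sorted(cs))

    sil: dict[int, float] = {}
    if report_silhouette and n > 3:
        for kk in range(2, min(n - 1, 6) + 1):
            lab = hierarchy.fcluster(z, t=kk, criterion="maxclust")
            if len(set(lab)) > 1:
                sil[kk] = float(silhouette_score(d, lab, metric="precomputed"))
    return RegClusterResult(tf_cluster=tf_cluster, gene_cluster=gene_cluster,
                            k=k, silhouette_by_k=sil)


def cluster_fractions(result: RegClusterResult) -> dict[int, float]:
    """Percentage of gene memberships per cluster (multi-cluster genes count
    once per membership, as in the bar-chart summary)."""
    counts: dict[int, int] = {}
    for cs in result.gene_cluster.values():
        for c in cs:
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    return {c: 100.0 * v / total for c, v in sorted(counts.items())} if total else {}


def overlay_hubs(hubs: pd.DataFrame, result: RegClusterResult) -> pd.DataFrame:
    """Annotate a hub table with the regulon cluster(s) of each gene."""
    out = hubs.copy()
    out["cluster"] = [
        "+".join(str(c) for c in result.gene_cluster[g])
        if g in result.gene_cluster else "none"
        for g in out["gene"]
    ]
    return out


def embed_candidates(expr: pd.DataFrame, result: RegClusterResult | None = None,
                     seed: int = 0) -> tuple[pd.DataFrame, float]:
    """2-D principal-component embedding of candidate genes by whole-brain
    expression (genes as points, samples as features, standardized).

    When a regulon clustering is supplied, returns the adjusted Rand index
    between a seeded k-means (k = number of regulon clusters) on the
    embedding and the single-cluster regulon assignments; NaN otherwise.
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 candidate genes")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=0)
    keep_rows = x.std(axis=1) > 0
    x = x[keep_rows]
    genes = list(expr.index[keep_rows])
    sd = x.std(axis=0)
    z = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    coords = PCA(n_components=2, random_state=seed).fit_transform(z)
    emb = pd.DataFrame(coords, index=genes, columns=["pc1", "pc2"])
    concordance = float("nan")
    if result is not None:
        singles = {g: cs[0] for g, cs in result.gene_cluster.items() if len(cs) == 1}
        shared = [g for g in genes if g in singles]
        if len(shared) >= 3:
            k = len(set(singles[g] for g in shared))
            if k >= 2:
                km = KMeans(n_clusters=k, n_init=10, random_state=seed)
                pred = km.fit_predict(emb.loc[shared].to_numpy())
                concordance = float(
                    adjusted_rand_score([singles[g] for g in shared], pred)
                )
    return emb, concordance
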