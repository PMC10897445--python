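"""WGCNA-style weighted co-expression networks and the module screens built
on them: soft-threshold selection, topological overlap, module detection
with eigengene merging, pattern-gene and gene-set enrichment, the synaptic
up/down split, module conservation, module differential connectivity (MDC)
with permutation significance, and intramodular hub ranking.

Networks are unsigned: adjacency a_ij = |cor(x_i, x_j)|**beta on log2-
normalized expression.  Module detection uses a deterministic static cut of
the average-linkage dendrogram on 1 - TOM followed by iterative eigengene
merging — simpler than dynamic tree cut but fully reproducible and adequate
for planted-block recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .stats_core import bh_fdr, fisher_exact_2x2, hypergeom_upper_tail


# ---------------------------------------------------------------------------
# network construction


@dataclass
class CoexprNetwork:
    """Unsigned weighted network over one expression slice.

    ``expr`` is samples x genes (rows observations), retained so permutation
    nulls can rebuild the adjacency.
    """

    genes: list[str]
    beta: int
    adjacency: np.ndarray
    expr: np.ndarray | None = None
    sample_scope: str = ""
    _tom: np.ndarray | None = field(default=None, repr=False)

    @property
    def tom(self) -> np.ndarray:
        if self._tom is None:
            self._tom = tom_matrix(self.adjacency)
        return self._tom

    def connectivity(self) -> np.ndarray:
        a = self.adjacency.copy()
        np.fill_diagonal(a, 0.0)
        return a.sum(axis=1)


def adjacency_matrix(expr: np.ndarray, beta: int) -> np.ndarray:
    """|cor|**beta with unit diagonal; expr is samples x genes."""
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(expr, rowvar=False)
    c = np.nan_to_num(c, nan=0.0)
    a = np.abs(c) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def build_network(expr: pd.DataFrame, beta: int, sample_scope: str = "") -> CoexprNetwork:
    """Network from a samples x genes expression frame."""
    x = expr.to_numpy(dtype=float)
    return CoexprNetwork(
        genes=list(expr.columns), beta=int(beta),
        adjacency=adjacency_matrix(x, beta), expr=x, sample_scope=sample_scope,
    )


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index.

    R^2 of the regression of log10 frequency on log10 binned connectivity,
    negated when the slope is positive (scale-free topology requires a
    decreasing degree distribution).
    """
    k = connectivity[connectivity > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return 0.0
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - (resid**2).sum() / ss_tot
    return float(-np.sign(slope) * r2)


def pick_power(expr: pd.DataFrame, candidates=range(1, 21),
               r2_target: float = 0.8) -> tuple[int, pd.DataFrame]:
    """Smallest soft-threshold power whose signed fit index reaches target.

    Falls back (flagged via the diagnostics table) to the argmax power when
    no candidate reaches the target.  Constant genes are removed first.
    """
    x = expr.to_numpy(dtype=float)
    if x.shape[0] < 8:
        raise ValueError("need at least 8 samples to pick a power")
    keep = x.std(axis=0) > 0
    if not keep.any():
        raise ValueError("all genes constant")
    x = x[:, keep]
    if x.shape[1] < 30:
        raise ValueError("need at least 30 variable genes")
    c = np.abs(np.corrcoef(x, rowvar=False))
    np.fill_diagonal(c, 0.0)
    rows = []
    for beta in candidates:
        k = (c**beta).sum(axis=1)
        rows.append({"beta": int(beta), "fit_r2": scale_free_fit(k),
                     "mean_k": float(k.mean())})
    diag = pd.DataFrame(rows)
    # the signed index can go negative (positive slope); the target is on
    # the non-negative part, so a zero target trivially keeps power 1
    hit = diag[diag["fit_r2"].clip(lower=0.0) >= r2_target]
    if len(hit):
        beta = int(hit["beta"].iloc[0])
    else:
        beta = int(diag.loc[diag["fit_r2"].idxmax(), "beta"])
        diag.attrs["fallback"] = True
    return beta, diag


def tom_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    L_ij sums shared-neighbor adjacency excluding i and j themselves; k is
    the connectivity without the self-loop.  Diagonal is 1 by convention.
    """
    a = np.asarray(adjacency, dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    # L_ij = sum_u a_iu a_uj over u != i, j  (self-loop-free product)
    L = a0 @ a0 - 0.0
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (L + a0) / denom
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


# ---------------------------------------------------------------------------
# module detection


@dataclass
class ModuleSet:
    labels: pd.Series                      # gene -> module id (0 unassigned)
    eigengenes: pd.DataFrame | None = None  # samples x modules
    kme: pd.DataFrame | None = None         # genes x modules
    merge_trace: list = field(default_factory=list)

    @property
    def sizes(self) -> pd.Series:
        s = self.labels[self.labels != 0].value_counts().sort_index()
        s.name = "size"
        return s

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def module_map(self) -> dict[int, list[str]]:
        return {int(m): self.members(int(m)) for m in self.sizes.index}


def _eigengene(x: np.ndarray) -> np.ndarray:
    """First principal component of standardized gene profiles, sign-oriented
    so that the mean gene-eigengene correlation is non-negative."""
    z = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1.0, x.std(axis=0))
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    e = u[:, 0] * s[0]
    cors = np.array([np.corrcoef(e, z[:, j])[0, 1] for j in range(z.shape[1])])
    if np.nanmean(cors) < 0:
        e = -e
    sd = e.std()
    return e / sd if sd > 0 else e


def detect_modules(tom: np.ndarray, genes, expr: np.ndarray | None = None,
                   min_size: int = 30, merge_height: float = 0.25,
                   cut_quantile: float | None = None,
                   n_cut_candidates: int = 60) -> ModuleSet:
    """Static-cut average-linkage module detection on 1 - TOM.

    The cut height is chosen deterministically by scanning candidate
    quantiles of the merge heights and keeping the cut that yields the most
    clusters of at least ``min_size`` genes (ties: most genes assigned, then
    the lower height).  Pass ``cut_quantile`` to force a fixed quantile
    instead.  Clusters below ``min_size`` go to module 0 (unassigned).
    When expression is supplied, modules whose eigengenes correlate at
    >= 1 - merge_height are merged iteratively and kME is computed.
    Labels are renumbered 1..m by decreasing size (ties by first gene id),
    so the partition is invariant to gene order.
    """
    genes = list(genes)
    n = len(genes)
    if n < min_size:
        return ModuleSet(labels=pd.Series(0, index=genes, name="module"))
    d = 1.0 - np.asarray(tom)
    np.fill_diagonal(d, 0.0)
    z = hierarchy.average(squareform(d, checks=False))
    heights = z[:, 2]
    if cut_quantile is not None:
        cuts = [np.quantile(heights, cut_quantile)]
    else:
        # only cuts strictly below the final merge: cutting at the root
        # yields the degenerate everything-in-one-module partition
        cuts = np.unique(np.quantile(heights,
                                     np.linspace(0.05, 1.0, n_cut_candidates)))
        cuts = cuts[cuts < heights.max() - 1e-12]
    if len(cuts) == 0:
        return ModuleSet(labels=pd.Series(0, index=genes, name="module"))
    best = None
    for cut in cuts:
        raw = hierarchy.fcluster(z, t=cut, criterion="distance")
        sizes = np.bincount(raw)
        big = sizes[sizes >= min_size]
        score = (len(big), int(big.sum()), -cut)
        if best is None or score > best[0]:
            best = (score, raw)
    raw = best[1]
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    labels[labels.map(sizes) < min_size] = 0

    if expr is not None and (labels != 0).any():
        labels = _merge_by_eigengene(labels, np.asarray(expr, dtype=float),
                                     genes, merge_height)
    labels = _renumber(labels)
    ms = ModuleSet(labels=labels.rename("module"))
    if expr is not None:
        _fill_eigengenes(ms, np.asarray(expr, dtype=float), genes)
    return ms


def _renumber(labels: pd.Series) -> pd.Series:
    mods = labels[labels != 0]
    order = sorted(
        mods.unique(),
        key=lambda m: (-(mods == m).sum(), min(labels.index[labels == m])),
    )
    remap = {m: i + 1 for i, m in enumerate(order)}
    remap[0] = 0
    return labels.map(remap)


def _merge_by_eigengene(labels: pd.Series, expr: np.ndarray, genes: list[str],
                        merge_height: float) -> pd.Series:
    gi = {g: j for j, g in enumerate(genes)}
    while True:
        mods = sorted(set(labels.unique()) - {0})
        if len(mods) < 2:
            return labels
        eigs = {m: _eigengene(expr[:, [gi[g] for g in labels.index[labels == m]]])
                for m in mods}
        best = None
        for i, ma in enumerate(mods):
            for mb in mods[i + 1:]:
                r = np.corrcoef(eigs[ma], eigs[mb])[0, 1]
                if r >= 1.0 - merge_height and (best is None or r > best[0]):
                    best = (r, ma, mb)
        if best is None:
            return labels
        _, ma, mb = best
        labels = labels.replace({mb: ma})


def _fill_eigengenes(ms: ModuleSet, expr: np.ndarray, genes: list[str]) -> None:
    gi = {g: j for j, g in enumerate(genes)}
    mods = list(ms.sizes.index)
    if not mods:
        return
    eig = {m: _eigengene(expr[:, [gi[g] for g in ms.members(m)]]) for m in mods}
    ms.eigengenes = pd.DataFrame(eig)
    sd = expr.std(axis=0)
    z = (expr - expr.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    kme = {}
    for m in mods:
        e = eig[m]
        ez = (e - e.mean()) / (e.std() if e.std() > 0 else 1.0)
        kme[m] = (z * ez[:, None]).mean(axis=0)
    ms.kme = pd.DataFrame(kme, index=genes)


# ---------------------------------------------------------------------------
# enrichment


def pattern_enrichment(modules: ModuleSet, pattern_sets: dict[str, set],
                       universe=None) -> pd.DataFrame:
    """Fisher exact enrichment of each planted/observed pattern in each module.

    2x2 table: membership in module x membership in pattern over the network
    gene universe; BH correction within each pattern across modules.
    """
    universe = list(universe) if universe is not None else list(modules.labels.index)
    uset = set(universe)
    rows = []
    for patt, pset in pattern_sets.items():
        pset = set(pset) & uset
        for m in modules.sizes.index:
            mems = set(modules.members(int(m)))
            a = len(mems & pset)
            b = len(mems) - a
            c = len(pset) - a
            d = len(uset) - a - b - c
            if not pset:
                rows.append({"module": int(m), "pattern": patt, "overlap": 0,
                             "odds_ratio": np.nan, "p": 1.0, "empty_pattern": True})
                continue
            p = fisher_exact_2x2([[a, b], [c, d]])
            odds = (a * d) / (b * c) if b * c > 0 else np.inf
            rows.append({"module": int(m), "pattern": patt, "overlap": a,
                         "odds_ratio": odds, "p": p, "empty_pattern": False})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = np.nan
        for patt in out["pattern"].unique():
            mask = out["pattern"] == patt
            out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out


def geneset_enrichment(gene_list, gmt_sets: dict[str, set], universe) -> pd.DataFrame:
    """One-sided over-representation (hypergeometric upper tail) per set."""
    universe = set(universe)
    hits = set(gene_list) & universe
    if not set(gene_list) <= universe:
        raise ValueError("gene list must be contained in the universe")
    rows = []
    for name, members in gmt_sets.items():
        members = set(members) & universe
        if not members:
            continue
        k = len(hits & members)
        tail = hypergeom_upper_tail(k, len(universe), len(members), len(hits))
        rows.append({"set": name, "overlap": k, "set_size": len(members),
                     "p": tail.p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out


def synaptic_split(module_genes, synapse_set, de: pd.DataFrame,
                   fc_thresh: float = 1.2, p_thresh: float = 0.05) -> dict:
    """Direction x significance split of synaptic genes in screened modules.

    Only genes with at least a 20% change (|log2FC| >= log2(fc_thresh)) are
    assigned; the rest are excluded and counted.  Fractions sum to 1 over
    assigned genes.
    """
    genes = set(module_genes) & set(synapse_set)
    d = de.set_index("gene")
    genes &= set(d.index)
    lfc_cut = np.log2(fc_thresh)
    counts = {"sig_down": 0, "ns_down": 0, "sig_up": 0, "ns_up": 0}
    excluded = 0
    for g in genes:
        lfc = float(d.loc[g, "log2fc"])
        p = float(d.loc[g, "p"])
        if abs(lfc) < lfc_cut:
            excluded += 1
            continue
        key = ("sig_" if p <= p_thresh else "ns_") + ("up" if lfc > 0 else "down")
        counts[key] += 1
    total = sum(counts.values())
    fractions = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return {"fractions": fractions, "counts": counts, "n_excluded": excluded,
            "n_genes": len(genes), "empty": len(genes) == 0}


# ---------------------------------------------------------------------------
# module differential connectivity


@dataclass
class MDCResult:
    module: int | str
    mdc: float
    p_perm: float
    q: float
    null_type: str
    n_perm: int


def _module_adjacency_sum(adj: np.ndarray, idx: np.ndarray) -> float:
    sub = adj[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].sum())


def mdc_ratio(netA: CoexprNetwork, netB: CoexprNetwork, module_genes) -> float:
    """Sum of within-module adjacency in A over the same sum in B."""
    if netA.genes != netB.genes:
        raise ValueError("networks must share the gene universe")
    if netA.beta != netB.beta:
        raise ValueError("networks must share beta")
    gi = {g: i for i, g in enumerate(netA.genes)}
    idx = np.array([gi[g] for g in module_genes])
    if len(idx) < 3:
        raise ValueError("module too small for MDC")
    num = _module_adjacency_sum(netA.adjacency, idx)
    den = _module_adjacency_sum(netB.adjacency, idx)
    if den == 0:
        raise ValueError("degenerate network: zero within-module connectivity in B")
    return num / den


def mdc(module_genes, netA: CoexprNetwork, netB: CoexprNetwork, B: int = 200,
        null: str = "sample_permutation",
        rng: np.random.Generator | None = None) -> MDCResult:
    """MDC with permutation significance (two-sided on log MDC, +1 smoothed).

    ``sample_permutation`` reshuffles the group labels of the pooled samples
    and rebuilds both module adjacencies; ``random_geneset`` redraws gene
    sets of the module's size from the shared universe.
    """
    rng = rng or np.random.default_rng(0)
    obs = mdc_ratio(netA, netB, module_genes)
    gi = {g: i for i, g in enumerate(netA.genes)}
    idx = np.array([gi[g] for g in module_genes])
    stat = abs(np.log(obs))
    exceed = 0
    if null == "sample_permutation":
        if netA.expr is None or netB.expr is None:
            raise ValueError("sample-permutation null needs stored expression")
        xa, xb = netA.expr[:, idx], netB.expr[:, idx]
        pooled = np.vstack([xa, xb])
        na = xa.shape[0]
        for _ in range(B):
            perm = rng.permutation(pooled.shape[0])
            pa = adjacency_matrix(pooled[perm[:na]], netA.beta)
            pb = adjacency_matrix(pooled[perm[na:]], netB.beta)
            all_idx = np.arange(len(idx))
            num = _module_adjacency_sum(pa, all_idx)
            den = _module_adjacency_sum(pb, all_idx)
            r = num / den if den > 0 else np.inf
            if abs(np.log(r)) >= stat:
                exceed += 1
    elif null == "random_geneset":
        universe = np.arange(len(netA.genes))
        for _ in range(B):
            pick = rng.choice(universe, size=len(idx), replace=False)
            num = _module_adjacency_sum(netA.adjacency, pick)
            den = _module_adjacency_sum(netB.adjacency, pick)
            r = num / den if den > 0 else np.inf
            if abs(np.log(r)) >= stat:
                exceed += 1
    else:
        raise ValueError(f"unknown null type: {null}")
    p = (1 + exceed) / (B + 1)
    return MDCResult(module="", mdc=obs, p_perm=p, q=np.nan, null_type=null, n_perm=B)


def mdc_screen(modules: dict, netA: CoexprNetwork, netB: CoexprNetwork,
               B: int = 200, null: str = "sample_permutation",
               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """MDC over all modules with BH correction across modules."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for mod, genes in modules.items():
        res = mdc(genes, netA, netB, B=B, null=null, rng=rng)
        rows.append({"module": mod, "mdc": res.mdc, "p": res.p_perm,
                     "null_type": null, "n_perm": B})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# conservation and hubs


def module_conservation(modulesA: ModuleSet, modulesB: ModuleSet,
                        jaccard_threshold: float = 0.3) -> pd.DataFrame:
    """Best-match Jaccard of each A module against the B partition."""
    universe = set(modulesA.labels.index) & set(modulesB.labels.index)
    rows = []
    b_mods = {int(m): set(modulesB.members(int(m))) & universe
              for m in modulesB.sizes.index}
    for m in modulesA.sizes.index:
        a_set = set(modulesA.members(int(m))) & universe
        best_j, best_m, best_p = 0.0, None, 1.0
        for bm, b_set in b_mods.items():
            inter = len(a_set & b_set)
            union = len(a_set | b_set)
            j = inter / union if union else 0.0
            if j > best_j or best_m is None:
                n = len(universe)
                tbl = [[inter, len(a_set) - inter],
                       [len(b_set) - inter, n - len(a_set) - len(b_set) + inter]]
                best_j, best_m, best_p = j, bm, fisher_exact_2x2(tbl)
        rows.append({"module": int(m), "best_match": best_m, "jaccard": best_j,
                     "p": best_p, "preserved": best_j >= jaccard_threshold})
    return pd.DataFrame(rows)


def hub_genes(modules: ModuleSet, network: CoexprNetwork, screened=None,
              n: int = 15) -> pd.DataFrame:
    """Top genes of the screened modules by intramodular connectivity kIN.

    kIN_i sums the adjacency from gene i to the other members of its module;
    ties are broken by gene id.  Requesting more hubs than available returns
    everything (flagged).
    """
    screened = (list(screened) if screened is not None
                else [int(m) for m in modules.sizes.index])
    if not screened:
        raise ValueError("screened module set is empty")
    gi = {g: i for i, g in enumerate(network.genes)}
    rows = []
    for m in screened:
        mems = [g for g in modules.members(int(m)) if g in gi]
        idx = np.array([gi[g] for g in mems])
        sub = network.adjacency[np.ix_(idx, idx)]
        kin = sub.sum(axis=1) - 1.0  # drop the self-loop
        for g, k in zip(mems, kin):
            rows.append({"gene": g, "module": int(m), "kin": float(k)})
    out = pd.DataFrame(rows).sort_values(["kin", "gene"],
                                         ascending=[False, True],
                                         kind="mergesort")
    out["truncated"] = len(out) < n
    return out.head(n).reset_index(drop=True)


# ---------------------------------------------------------------------------
# cross-region expression pooling


def pooled_group_expression(norm: pd.DataFrame, meta: pd.DataFrame, group: str,
                            genes=None, states=None) -> pd.DataFrame:
    """Samples x genes slice for one paternal group, pooled over regions
    (and states unless restricted), expression standardized within region
    first so region means do not dominate the correlations."""
    sel = meta["group"] == group
    if states is not None:
        sel &= meta["state"].isin(states)
    sub = meta[sel]
    genes = list(genes) if genes is not None else list(norm.index)
    blocks = []
    for region in sub["region"].unique():
        cols = sub.loc[sub["region"] == region, "sample"]
        x = norm.loc[genes, cols].to_numpy(dtype=float).T  # samples x genes
        sd = x.std(axis=0)
        z = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        blocks.append(pd.DataFrame(z, columns=genes, index=cols))
    return pd.concat(blocks, axis=0)
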