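"""Stratified rank-rank hypergeometric overlap (RRHO) between two regions'
differential-expression signatures.

Each signature ranks genes by the signed score s = -log10(p) * sign(log2FC).
The stratified variant splits each list at its up/down boundary and scans
threshold pairs within each of the four quadrant combinations (uu, dd, ud,
du), scoring the overlap of the two prefix sets with a hypergeometric tail.
Concordant quadrants (uu, dd) carry the coordinated-regulation signal;
discordant ones (ud, du) carry inversion.  Tails are computed in log space
because coordinated regions in this design reach P below 1e-50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import hypergeom_upper_tail

P_FLOOR = 1e-300

QUADRANTS = ("uu", "dd", "ud", "du")


@dataclass
class RankedSignature:
    """Genes ordered by descending signed score; ties broken by gene id."""

    genes: list[str]
    scores: np.ndarray
    n_up: int

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def up(self) -> list[str]:
        """Up-regulated side, most significant first."""
        return self.genes[: self.n_up]

    @property
    def down(self) -> list[str]:
        """Down-regulated side, most significant first."""
        return self.genes[self.n_up:][::-1]


def make_signature(de: pd.DataFrame) -> RankedSignature:
    """Signed -log10(p) signature from a DE table (columns gene, p, log2fc)."""
    if len(de) == 0:
        raise ValueError("empty DE table")
    p = np.maximum(de["p"].to_numpy(dtype=float), P_FLOOR)
    s = -np.log10(p) * np.sign(de["log2fc"].to_numpy(dtype=float))
    order = sorted(range(len(de)), key=lambda i: (-s[i], str(de["gene"].iloc[i])))
    genes = [str(de["gene"].iloc[i]) for i in order]
    scores = s[order]
    return RankedSignature(genes=genes, scores=scores, n_up=int((s > 0).sum()))


@dataclass
class RRHOMap:
    step: int
    n_genes: int
    grids: dict = field(default_factory=dict)  # quadrant -> signed -log10 p matrix
    max_signal: tuple[str, float] = ("uu", 0.0)

    def quadrant_max(self, quadrant: str) -> float:
        g = self.grids[quadrant]
        return float(g.max()) if g.size else 0.0


def _prefix_thresholds(n: int, step: int) -> list[int]:
    ts = list(range(step, n + 1, step))
    if not ts and n > 0:
        ts = [n]
    return ts


def _quadrant_grid(list1: list[str], list2: list[str], n_total: int,
                   step: int) -> np.ndarray:
    t1 = _prefix_thresholds(len(list1), step)
    t2 = _prefix_thresholds(len(list2), step)
    grid = np.zeros((len(t1), len(t2)))
    set2_members: dict[str, int] = {g: i for i, g in enumerate(list2)}
    # overlap[i, j] computed incrementally: genes of list1 prefix whose
    # position in list2 is below each threshold
    pos = np.array([set2_members.get(g, n_total + 1) for g in list1])
    for i, a in enumerate(t1):
        prefix_pos = pos[:a]
        for j, b in enumerate(t2):
            k = int((prefix_pos < b).sum())
            expected = a * b / n_total
            if k >= expected:
                tail = hypergeom_upper_tail(k, n_total, a, b)
                val = tail.neglog10
            else:
                # depletion: lower tail P(X <= k), reported with negative sign
                upper = hypergeom_upper_tail(k + 1, n_total, a, b)
                low = max(1.0 - upper.p, P_FLOOR)
                val = -(-math.log10(low))
            grid[i, j] = val
    return grid


def rrho_map(sig1: RankedSignature, sig2: RankedSignature,
             step: int | None = None) -> RRHOMap:
    """Stratified RRHO map over the four up/down quadrant pairs.

    ``step`` defaults to ceil(sqrt(N)).  Signatures on different gene
    universes are intersected (order preserved) before mapping.
    """
    g1, g2 = set(sig1.genes), set(sig2.genes)
    if g1 != g2:
        shared = g1 & g2
        sig1 = _restrict(sig1, shared)
        sig2 = _restrict(sig2, shared)
    n = len(sig1)
    if step is None:
        step = math.ceil(math.sqrt(n))
    if step <= 0:
        raise ValueError("step must be positive")
    sides1 = {"u": sig1.up, "d": sig1.down}
    sides2 = {"u": sig2.up, "d": sig2.down}
    grids = {}
    for a in "ud":
        for b in "ud":
            grids[a + b] = _quadrant_grid(sides1[a], sides2[b], n, step)
    best_q, best_v = "uu", -math.inf
    for q in ("uu", "dd"):
        if grids[q].size:
            v = float(grids[q].max())
            if v > best_v:
                best_q, best_v = q, v
    if not math.isfinite(best_v):
        best_v = 0.0
    return RRHOMap(step=step, n_genes=n, grids=grids, max_signal=(best_q, best_v))


def _restrict(sig: RankedSignature, keep: set) -> RankedSignature:
    idx = [i for i, g in enumerate(sig.genes) if g in keep]
    genes = [sig.genes[i] for i in idx]
    scores = sig.scores[idx]
    return RankedSignature(genes=genes, scores=scores, n_up=int((scores > 0).sum()))


def rrho_screen(signatures: dict[str, RankedSignature], step: int | None = None,
                flag_neglog10: float = 50.0) -> pd.DataFrame:
    """All-pairs RRHO screen over regions.

    Returns one row per unordered region pair with the maximal concordant
    and discordant signals; ``flagged`` marks pairs whose concordant maximum
    beats the headline bound (-log10 P > ``flag_neglog10``).
    """
    regions = sorted(signatures)
    rows = []
    for i, ra in enumerate(regions):
        for rb in regions[i + 1:]:
            m = rrho_map(signatures[ra], signatures[rb], step=step)
            disc = max(m.quadrant_max("ud"), m.quadrant_max("du"))
            rows.append(
                {
                    "region_a": ra,
                    "region_b": rb,
                    "max_quadrant": m.max_signal[0],
                    "max_neglog10p": m.max_signal[1],
                    "max_discordant_neglog10p": disc,
                    "flagged": m.max_signal[1] > flag_neglog10,
                }
            )
    return pd.DataFrame(rows)
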