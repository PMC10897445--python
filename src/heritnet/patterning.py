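"""Attribution of genes to paternal-factor patterns from the three pairwise
group contrasts.

The three offspring contrasts x = effect(CSA - SSA), y = effect(CY - SSA)
and x - y = effect(CSA - CY) are arithmetically coupled, so a gene's triple
of significance/direction calls can only take the sign patterns realizable
by real (x, y).  Excluding the all-null triple, exactly 12 such expression
patterns exist; three of them aggregate into the biologically named classes:

* Pattern A ("drug exposure")    — both vs-SSA contrasts significant, same
  direction: the paternal cocaine exposure shared by CSA and CY sires.
* Pattern B ("highly motivated") — significant vs SSA and vs CY, but not
  changed in CY vs SSA: unique to voluntary paternal drug seeking.
* Pattern C ("passive infusion") — the mirror image, unique to yoked sires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_core import pearson_r

SIGNS = ("down", "ns", "up")
_SIGN_OF = {-1: "down", 0: "ns", 1: "up"}
_NUM_OF = {v: k for k, v in _SIGN_OF.items()}


def _realizable(sx: int, sy: int, sd: int) -> bool:
    """Can (sign(x), sign(y), sign(x-y)) = (sx, sy, sd) for real x, y?"""
    for x in (-1.0, -0.5, 0.0, 0.5, 1.0):
        for y in (-1.0, -0.5, 0.0, 0.5, 1.0):
            if np.sign(x) == sx and np.sign(y) == sy and np.sign(x - y) == sd:
                return True
    return False


def enumerate_sign_classes() -> list[tuple[str, str, str]]:
    """All realizable non-null (CSA-SSA, CY-SSA, CSA-CY) sign triples.

    Canonical ordering: lexicographic in (up > ns > down) per component,
    strongest-up first.
    """
    classes = []
    for sx in (1, 0, -1):
        for sy in (1, 0, -1):
            for sd in (1, 0, -1):
                if (sx, sy, sd) == (0, 0, 0):
                    continue
                if _realizable(sx, sy, sd):
                    classes.append((_SIGN_OF[sx], _SIGN_OF[sy], _SIGN_OF[sd]))
    return classes


@dataclass(frozen=True)
class PatternRules:
    """Significance rule used for the pattern calls (raw p by default)."""

    p_rule: str = "raw"
    p_thresh: float = 0.05
    require_a_consistency: bool = True


def _sign_calls(de: pd.DataFrame, rules: PatternRules) -> pd.DataFrame:
    pcol = "p" if rules.p_rule == "raw" else "q"
    sig = de[pcol] <= rules.p_thresh
    s = np.where(~sig, 0, np.sign(de["log2fc"]).astype(int))
    return pd.DataFrame({"gene": de["gene"], "s": s, "pval": de[pcol]}).set_index("gene")


def assign_patterns(de_csa_ssa: pd.DataFrame, de_cy_ssa: pd.DataFrame,
                    de_csa_cy: pd.DataFrame,
                    rules: PatternRules = PatternRules()) -> pd.DataFrame:
    """Per-gene realizable sign triple plus A/B/C/none attribution.

    Observed triples that are unrealizable under the x, y, x-y coupling
    (possible because the three tests are run independently) are coerced to
    the nearest realizable triple by dropping the weakest call — the one
    with the largest p — repeatedly; coerced genes are flagged.
    """
    tabs = [_sign_calls(t, rules) for t in (de_csa_ssa, de_cy_ssa, de_csa_cy)]
    universe = tabs[0].index
    for t in tabs[1:]:
        if not universe.equals(t.index):
            if set(universe) != set(t.index):
                raise ValueError("gene universes differ between contrasts")
    s = np.column_stack([t.loc[universe, "s"].to_numpy() for t in tabs])
    pv = np.column_stack([t.loc[universe, "pval"].to_numpy() for t in tabs])

    realizable = {(x, y, d) for x in (-1, 0, 1) for y in (-1, 0, 1)
                  for d in (-1, 0, 1) if _realizable(x, y, d)}
    realizable.add((0, 0, 0))
    triples, coerced = [], []
    for i in range(len(universe)):
        tri, p3 = list(s[i]), list(pv[i])
        was_coerced = False
        while tuple(tri) not in realizable:
            # drop the weakest (largest p) remaining significant call; a
            # lone significant call is dropped too — the 12 realizable
            # non-null patterns all carry at least two consistent calls
            active = [j for j in range(3) if tri[j] != 0]
            j = max(active, key=lambda j: (p3[j], j))
            tri[j] = 0
            was_coerced = True
        triples.append(tuple(tri))
        coerced.append(was_coerced)

    abc = []
    for (sx, sy, sd) in triples:
        if sx != 0 and sy != 0 and (sx == sy or not rules.require_a_consistency):
            abc.append("A")
        elif sx != 0 and sd != 0 and sy == 0:
            abc.append("B")
        elif sy != 0 and sd != 0 and sx == 0:
            abc.append("C")
        else:
            abc.append("none")
    return pd.DataFrame(
        {
            "gene": universe,
            "triple": ["|".join(_SIGN_OF[v] for v in t) for t in triples],
            "abc": abc,
            "coerced": coerced,
        }
    )


def fc_consistency(de_csa_ssa: pd.DataFrame, de_cy_ssa: pd.DataFrame,
                   deg_union) -> tuple[pd.DataFrame, dict[str, float]]:
    """Fold-change consistency categories over a DEG set.

    Per DEG: ``reverse`` when the CSA and CY log2FCs (each vs SSA) have
    opposite signs; otherwise ``cy_greater``/``csa_greater`` by which
    magnitude wins.  Records are ranked by the CSA-vs-SSA log2FC within each
    category; the returned fractions sum to 1.
    """
    deg_union = list(deg_union)
    if not deg_union:
        raise ValueError("DEG union is empty")
    a = de_csa_ssa.set_index("gene")["log2fc"]
    b = de_cy_ssa.set_index("gene")["log2fc"]
    lfc_csa = a.loc[deg_union].to_numpy(dtype=float)
    lfc_cy = b.loc[deg_union].to_numpy(dtype=float)
    category = np.where(
        (np.sign(lfc_csa) * np.sign(lfc_cy)) < 0,
        "reverse",
        np.where(np.abs(lfc_cy) > np.abs(lfc_csa), "cy_greater", "csa_greater"),
    )
    tied = (lfc_csa == 0) & (lfc_cy == 0)
    rec = pd.DataFrame(
        {"gene": deg_union, "category": category, "lfc_csa": lfc_csa,
         "lfc_cy": lfc_cy, "tie_flag": tied}
    )
    rec = (
        rec.sort_values(["category", "lfc_csa"], ascending=[True, False])
        .reset_index(drop=True)
    )
    fracs = (rec["category"].value_counts() / len(rec)).to_dict()
    for k in ("reverse", "cy_greater", "csa_greater"):
        fracs.setdefault(k, 0.0)
    return rec, fracs


def cross_state_fc_correlation(de_naive: pd.DataFrame, de_cocsa: pd.DataFrame,
                               genes=None) -> tuple[float, float, int]:
    """Pearson correlation of log2FCs for one contrast between the two states.

    ``genes`` defaults to all shared genes; pass the DEG union to reproduce
    the DEG-restricted variant.
    """
    a = de_naive.set_index("gene")["log2fc"]
    b = de_cocsa.set_index("gene")["log2fc"]
    shared = a.index.intersection(b.index) if genes is None else pd.Index(genes)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    r, p = pearson_r(a.loc[shared], b.loc[shared])
    return r, p, len(shared)
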