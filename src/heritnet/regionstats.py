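"""Group comparisons and cross-region correlation structure for analyte
panels (dopamine and metabolites by HPLC, c-Fos densities).

Sample sizes here are 5-7 animals per group, so every comparison is an
exact Wilcoxon rank-sum; correlations are Pearson with the t-transform p.
Per-figure convention, p-values are reported without cross-region
multiplicity correction (a corrected column is available on request).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats_core import bh_fdr, pearson_r, wilcoxon_exact


def group_compare(table: pd.DataFrame, analyte: str, region: str,
                  groups=None, correct: bool = False) -> pd.DataFrame:
    """Pairwise exact Wilcoxon p for every group pair in one (analyte, region)."""
    sub = table[(table["analyte"] == analyte) & (table["region"] == region)]
    groups = list(groups) if groups is not None else sorted(sub["group"].unique())
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            x = sub.loc[sub["group"] == ga, "value"]
            y = sub.loc[sub["group"] == gb, "value"]
            if len(x) == 0 or len(y) == 0:
                rows.append({"group_a": ga, "group_b": gb, "n_a": len(x),
                             "n_b": len(y), "p": np.nan, "absent": True})
                continue
            rows.append({"group_a": ga, "group_b": gb, "n_a": len(x),
                         "n_b": len(y), "p": wilcoxon_exact(x, y),
                         "absent": False})
    out = pd.DataFrame(rows)
    if correct and len(out):
        ok = ~out["p"].isna()
        out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out


def relative_change(table: pd.DataFrame, analyte: str,
                    reference: str = "SSA") -> pd.DataFrame:
    """Percent change of each group's regional mean versus the reference group.

    The reference row is identically 0; a zero reference mean yields NaN
    (undefined marker), never an infinity.
    """
    sub = table[table["analyte"] == analyte]
    if reference not in set(sub["group"]):
        raise ValueError(f"reference group {reference} absent")
    means = sub.groupby(["group", "region"])["value"].mean().unstack("region")
    ref = means.loc[reference]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (means - ref) / ref
    pct.loc[:, (ref == 0).values] = np.nan
    pct.loc[reference] = np.where(ref == 0, np.nan, 0.0)
    return pct


def cross_region_corr(table: pd.DataFrame, analyte: str,
                      min_n: int = 3) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-group region x region Pearson correlation of animal-level values.

    Returns {group: {"r": frame, "p": frame, "n": frame}}; pairs with fewer
    than ``min_n`` complete animals are NaN (absent marker).
    """
    sub = table[table["analyte"] == analyte]
    out = {}
    for group, gsub in sub.groupby("group"):
        wide = gsub.pivot(index="animal", columns="region", values="value")
        regions = list(wide.columns)
        r = pd.DataFrame(np.eye(len(regions)), index=regions, columns=regions)
        p = pd.DataFrame(np.nan, index=regions, columns=regions)
        n = pd.DataFrame(0, index=regions, columns=regions)
        for i, ra in enumerate(regions):
            n.loc[ra, ra] = wide[ra].notna().sum()
            for rb in regions[i + 1:]:
                pair = wide[[ra, rb]].dropna()
                n.loc[ra, rb] = n.loc[rb, ra] = len(pair)
                if len(pair) < min_n:
                    r.loc[ra, rb] = r.loc[rb, ra] = np.nan
                    continue
                try:
                    rr, pp = pearson_r(pair[ra], pair[rb])
                except ValueError:
                    rr, pp = np.nan, np.nan
                r.loc[ra, rb] = r.loc[rb, ra] = rr
                p.loc[ra, rb] = p.loc[rb, ra] = pp
        out[group] = {"r": r, "p": p, "n": n}
    return out


def corr_contrast(structA: dict[str, pd.DataFrame],
                  structB: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.Series]:
    """Elementwise r difference (A - B) plus, per region, the count of pairs
    where |r| is higher in A — a descriptive coupling-strength summary."""
    ra, rb = structA["r"], structB["r"]
    if list(ra.index) != list(rb.index) or list(ra.columns) != list(rb.columns):
        raise ValueError("correlation structures cover different regions")
    diff = ra - rb
    stronger = (ra.abs() > rb.abs())
    np.fill_diagonal(stronger.values, False)
    counts = stronger.sum(axis=1).rename("n_pairs_stronger_in_A")
    return diff, counts
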