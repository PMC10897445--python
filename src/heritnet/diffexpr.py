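"""Normalization and pairwise differential expression across the three
offspring groups (CSA-F1, CY-F1, SSA-F1), one table per (region, state) cell.

The engine is deliberately self-contained and fully specified: median-of-
ratios size factors, log2 transform with a pseudocount, and a per-gene Welch
unequal-variance test.  It is pluggable — anything producing a table with
the same columns can feed the downstream pattern and network stages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats_core import bh_fdr

CONTRASTS = (("CSA", "SSA"), ("CY", "SSA"), ("CSA", "CY"))

DE_COLUMNS = ["gene", "mean_a", "mean_b", "log2fc", "p", "q"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    Reference genes are those with a positive count in every sample.  When
    none exist the factors fall back to library-size scaling (flagged with a
    warning).
    """
    mat = counts.to_numpy(dtype=float)
    if np.any(mat.sum(axis=0) == 0):
        raise ValueError("every sample needs at least one non-zero gene")
    ref = np.all(mat > 0, axis=1)
    if not ref.any():
        warnings.warn("no gene positive in all samples; using library-size factors")
        factors = mat.sum(axis=0)
    else:
        refs = mat[ref]
        geo = np.exp(np.log(refs).mean(axis=1, keepdims=True))
        factors = np.median(refs / geo, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_log(counts: pd.DataFrame, factors: pd.Series | None = None,
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount)."""
    if factors is None:
        factors = size_factors(counts)
    if np.any(np.asarray(factors) <= 0):
        raise ValueError("size factors must be positive")
    return np.log2(counts.div(factors, axis=1) + pseudocount)


def de_test(norm: pd.DataFrame, samples_a, samples_b) -> pd.DataFrame:
    """Per-gene Welch test on normalized log2 values; log2fc = mean_a - mean_b.

    Genes constant on both sides with equal means get p = 1 (no evidence,
    not NaN).  q is Benjamini-Hochberg within the contrast.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need at least 2 samples per side")
    a = norm[samples_a].to_numpy(dtype=float)
    b = norm[samples_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate & (mean_a == mean_b)] = 1.0
    p[degenerate & (mean_a != mean_b)] = np.nan  # constant but unequal: undefined
    # Welch cannot produce p for zero pooled variance with unequal means on
    # real count data; guard anyway.
    p = np.where(np.isnan(p), 1.0, p)
    out = pd.DataFrame(
        {
            "gene": norm.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": mean_a - mean_b,
            "p": p,
        }
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def de_all_cells(norm: pd.DataFrame, meta: pd.DataFrame,
                 contrasts=CONTRASTS) -> pd.DataFrame:
    """DE tables for every (region, state, contrast) cell, concatenated."""
    tables = []
    for region in meta["region"].unique():
        for state in meta["state"].unique():
            cell = meta[(meta["region"] == region) & (meta["state"] == state)]
            for ga, gb in contrasts:
                sa = cell.loc[cell["group"] == ga, "sample"]
                sb = cell.loc[cell["group"] == gb, "sample"]
                if len(sa) < 2 or len(sb) < 2:
                    continue
                tab = de_test(norm, sa, sb)
                tab["region"], tab["state"], tab["contrast"] = region, state, f"{ga}_vs_{gb}"
                tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def call_degs(de: pd.DataFrame, p_rule: str = "raw", p_thresh: float = 0.05,
              fc_thresh: float = 1.2) -> pd.DataFrame:
    """Significance calls: chosen p-type <= p_thresh AND fold change >= fc_thresh.

    ``fc_thresh`` is on the linear scale (1.2 means a 20% change in either
    direction); direction comes from the sign of log2fc.
    """
    if fc_thresh < 1.0:
        raise ValueError("fc_thresh must be >= 1 (linear fold-change scale)")
    if p_rule not in ("raw", "fdr"):
        raise ValueError("p_rule must be 'raw' or 'fdr'")
    pcol = "p" if p_rule == "raw" else "q"
    lfc_cut = np.log2(fc_thresh)
    out = de.copy()
    out["significant"] = (out[pcol] <= p_thresh) & (out["log2fc"].abs() >= lfc_cut)
    out["direction"] = np.where(out["log2fc"] > 0, "up",
                                np.where(out["log2fc"] < 0, "down", "none"))
    out["rule"] = f"{p_rule}<={p_thresh},fc>={fc_thresh}"
    return out


def deg_count_table(calls: pd.DataFrame, flag_cutoff: int = 400,
                    cells=None) -> pd.DataFrame:
    """DEG counts per (region, state, contrast) with a high-count region flag.

    A region is flagged when its DEG count reaches ``flag_cutoff`` in every
    groupwise contrast of at least one state (the 'pervasively changed
    region' screen).  ``cells`` optionally lists the expected
    (region, state, contrast) triples; expected cells absent from ``calls``
    appear with NA counts, never zero.
    """
    grid = (
        calls[calls["significant"]]
        .groupby(["region", "state", "contrast"], sort=True)
        .size()
        .rename("n_deg")
    )
    full = (
        calls.groupby(["region", "state", "contrast"], sort=True)
        .size()
        .rename("present")
        .to_frame()
    )
    table = full.join(grid).drop(columns="present")
    table["n_deg"] = table["n_deg"].fillna(0).astype("Int64")
    if cells is not None:
        wanted = pd.MultiIndex.from_tuples(list(cells),
                                           names=["region", "state", "contrast"])
        table = table.reindex(table.index.union(wanted))
    table = table.reset_index()
    flagged = set()
    for (region, state), sub in table.groupby(["region", "state"]):
        if len(sub) and sub["n_deg"].notna().all() and (sub["n_deg"] >= flag_cutoff).all():
            flagged.add(region)
    table["region_flagged"] = table["region"].isin(flagged)
    return table
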