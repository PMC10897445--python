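"""Progressive-ratio scoring and 'highly motivated' sire selection, plus the
offspring-breakpoint vs paternal-intake correlation.

The founding generation is screened on the breakpoint of a progressive-
ratio session: breakpoints are normalized to a PR score, animals ranked,
and the top k (or top fraction) designated highly motivated.  The study
ranked 47 cocaine self-administering rats and took the top 7 (14.9%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_core import pearson_r, wilcoxon_exact


def pr_score(breakpoints, method: str = "minmax") -> pd.Series:
    """Normalized PR scores; ranking is invariant to the normalization.

    ``minmax`` maps to [0, 1]; ``zscore`` standardizes.  All-equal input is
    degenerate: every score becomes 0.5 (flagged via the series name).
    """
    bp = pd.Series(breakpoints, dtype=float)
    if len(bp) < 2:
        raise ValueError("need at least 2 animals")
    if (bp < 0).any():
        raise ValueError("breakpoints must be non-negative")
    rng = bp.max() - bp.min()
    if rng == 0:
        return pd.Series(0.5, index=bp.index, name="pr_score_degenerate")
    if method == "minmax":
        s = (bp - bp.min()) / rng
    elif method == "zscore":
        s = (bp - bp.mean()) / bp.std(ddof=1)
    else:
        raise ValueError("method must be 'minmax' or 'zscore'")
    return s.rename("pr_score")


@dataclass
class SelectionResult:
    ranked_ids: list
    scores: pd.Series
    selected: list
    fraction: float  # percent, 1 decimal


def select_top(scores: pd.Series, k: int | None = None,
               fraction: float | None = None) -> SelectionResult:
    """Top-k animals by score (ties broken by animal id); fraction reported
    as 100*k/n rounded to one decimal.

    With ``fraction`` given instead of ``k``, k = ceil(fraction * n).
    """
    if (k is None) == (fraction is None):
        raise ValueError("give exactly one of k or fraction")
    n = len(scores)
    if fraction is not None:
        k = int(np.ceil(fraction * n))
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    ranked = scores.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort"
    )
    ranked_ids = list(ranked.index)
    return SelectionResult(
        ranked_ids=ranked_ids,
        scores=ranked,
        selected=ranked_ids[:k],
        fraction=round(100.0 * k / n, 1),
    )


def score_gap(sorted_scores) -> int:
    """Index (1-based position) after which the largest consecutive drop in a
    descending score list occurs; earliest position wins ties."""
    s = np.asarray(sorted_scores, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 scores")
    if np.any(np.diff(s) > 1e-12):
        raise ValueError("scores must be in descending order")
    drops = -np.diff(s)
    return int(np.argmax(drops)) + 1


def breakpoints_by_animal(behavior: pd.DataFrame) -> pd.DataFrame:
    """One breakpoint row per animal from a long behavior table."""
    bp = behavior.dropna(subset=["breakpoint"])
    if bp.groupby("animal").size().max() > 1:
        raise ValueError("multiple breakpoints for one animal")
    return bp[["animal", "litter", "group", "breakpoint"]].reset_index(drop=True)


def group_breakpoint_tests(behavior: pd.DataFrame,
                           per_litter: bool = False) -> pd.DataFrame:
    """Pairwise exact Wilcoxon comparisons of breakpoints between groups.

    ``per_litter`` averages littermates first (the litter, not the animal,
    is the independent unit under a paternal-effect design).
    """
    bp = breakpoints_by_animal(behavior)
    if per_litter:
        bp = (bp.groupby(["group", "litter"], as_index=False)["breakpoint"].mean())
    groups = sorted(bp["group"].unique())
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            x = bp.loc[bp["group"] == ga, "breakpoint"]
            y = bp.loc[bp["group"] == gb, "breakpoint"]
            rows.append({"group_a": ga, "group_b": gb,
                         "n_a": len(x), "n_b": len(y),
                         "p": wilcoxon_exact(x, y)})
    return pd.DataFrame(rows)


def intake_correlation(f1_breakpoints: pd.DataFrame, sire_intake: pd.Series,
                       per_litter: bool = False) -> tuple[float, float, int]:
    """Pearson correlation of F1 breakpoints with paternal total drug intake.

    ``f1_breakpoints`` needs columns animal, litter (= sire id), breakpoint;
    ``sire_intake`` maps sire id -> total intake.  ``per_litter`` correlates
    litter means instead of individual offspring.
    """
    tab = f1_breakpoints.copy()
    missing = set(tab["litter"]) - set(sire_intake.index)
    if missing:
        raise ValueError(f"F1 litters without sire intake: {sorted(missing)[:5]}")
    if per_litter:
        tab = tab.groupby("litter", as_index=False)["breakpoint"].mean()
    x = tab["breakpoint"].to_numpy(dtype=float)
    y = sire_intake.loc[tab["litter"]].to_numpy(dtype=float)
    if len(set(tab["litter"])) < 3:
        raise ValueError("need at least 3 sires")
    r, p = pearson_r(x, y)
    return r, p, len(x)
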