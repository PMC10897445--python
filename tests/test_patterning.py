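"""Sign-triple enumeration, A/B/C attribution, fold-change consistency."""

import numpy as np
import pandas as pd
import pytest

from heritnet import diffexpr as de
from heritnet.patterning import (
    PatternRules,
    assign_patterns,
    cross_state_fc_correlation,
    enumerate_sign_classes,
    fc_consistency,
)
from heritnet.synthetic_data import DesignSpec, PlantedTruth, simulate_counts


def _de_frame(genes, p, lfc):
    return pd.DataFrame({"gene": genes, "p": p, "q": p, "log2fc": lfc})


# ---------------------------------------------------------------------------
# enumeration


def test_twelve_realizable_classes_with_expected_members():
    classes = enumerate_sign_classes()
    assert len(classes) == 12
    assert ("up", "up", "up") in classes
    assert ("up", "down", "down") not in classes
    assert ("ns", "ns", "ns") not in classes


def test_enumeration_matches_random_sampling_oracle():
    rng = np.random.default_rng(0)
    seen = set()
    # dense random (x, y) pairs plus the boundary cases x=0, y=0, x=y
    xs = np.concatenate([rng.normal(size=100000), np.zeros(100)])
    ys = np.concatenate([rng.normal(size=100000), np.zeros(100)])
    for x, y in zip(xs, ys):
        seen.add((int(np.sign(x)), int(np.sign(y)), int(np.sign(x - y))))
    for v in rng.normal(size=200):
        seen.add((int(np.sign(v)), 0, int(np.sign(v))))     # y = 0 boundary
        seen.add((0, int(np.sign(v)), int(np.sign(-v))))    # x = 0 boundary
        seen.add((int(np.sign(v)), int(np.sign(v)), 0))     # x = y boundary
    seen.discard((0, 0, 0))
    sign_of = {-1: "down", 0: "ns", 1: "up"}
    sampled = {tuple(sign_of[s] for s in t) for t in seen}
    assert sampled == set(enumerate_sign_classes())


def test_enumeration_closed_under_contrast_swap():
    classes = set(enumerate_sign_classes())
    flip = {"up": "down", "down": "up", "ns": "ns"}
    for (sx, sy, sd) in classes:
        # (x, y) -> (y, x) relabels the contrasts and flips their difference
        assert (sy, sx, flip[sd]) in classes


# ---------------------------------------------------------------------------
# attribution


def test_abc_attribution_worked_cases():
    genes = ["gA", "gB", "gC", "gN"]
    # columns: CSA_vs_SSA, CY_vs_SSA, CSA_vs_CY
    d1 = _de_frame(genes, [0.01, 0.01, 0.50, 0.50], [-1.0, 1.0, 0.1, 0.0])
    d2 = _de_frame(genes, [0.01, 0.60, 0.01, 0.50], [-1.0, 0.3, 1.0, 0.0])
    d3 = _de_frame(genes, [0.60, 0.01, 0.01, 0.50], [0.1, 1.0, -1.0, 0.0])
    out = assign_patterns(d1, d2, d3).set_index("gene")
    assert out.loc["gA", "abc"] == "A"   # down in both vs-SSA contrasts
    assert out.loc["gB", "abc"] == "B"   # sig vs SSA and vs CY, ns CY-vs-SSA
    assert out.loc["gC", "abc"] == "C"   # mirror image
    assert out.loc["gN", "abc"] == "none"
    assert not out.loc["gN", "coerced"]


def test_partition_covers_gene_universe(small_dataset):
    counts, meta = small_dataset
    norm = de.normalize_log(counts)
    cell = meta[(meta.region == "dStr") & (meta.state == "Naive")]
    tabs = {}
    for ga, gb in (("CSA", "SSA"), ("CY", "SSA"), ("CSA", "CY")):
        tabs[(ga, gb)] = de.de_test(
            norm,
            cell.loc[cell.group == ga, "sample"],
            cell.loc[cell.group == gb, "sample"],
        )
    out = assign_patterns(tabs[("CSA", "SSA")], tabs[("CY", "SSA")],
                          tabs[("CSA", "CY")])
    assert len(out) == len(counts)
    assert set(out["abc"]) <= {"A", "B", "C", "none"}
    counts_by = out["abc"].value_counts()
    assert counts_by.sum() == len(counts)


def test_unrealizable_triple_coerced_by_dropping_weakest():
    # observed (up, down, down) is impossible: x > 0 > y forces x - y > 0.
    # weakest-call dropping cascades to the all-ns triple -> none
    d1 = _de_frame(["g"], [0.001], [1.0])
    d2 = _de_frame(["g"], [0.010], [-1.0])
    d3 = _de_frame(["g"], [0.049], [-1.0])
    out = assign_patterns(d1, d2, d3)
    assert out.loc[0, "coerced"]
    assert out.loc[0, "triple"] == "ns|ns|ns"
    assert out.loc[0, "abc"] == "none"
    # a lone significant call cannot form a realizable non-null pattern
    e1 = _de_frame(["g"], [0.001], [1.0])
    e2 = _de_frame(["g"], [0.30], [0.1])
    e3 = _de_frame(["g"], [0.60], [0.2])
    out2 = assign_patterns(e1, e2, e3)
    assert out2.loc[0, "coerced"]
    assert out2.loc[0, "abc"] == "none"
    # (up, down, up) is realizable as observed: no coercion
    f1 = _de_frame(["g"], [0.001], [1.0])
    f2 = _de_frame(["g"], [0.010], [-1.0])
    f3 = _de_frame(["g"], [0.020], [1.0])
    out3 = assign_patterns(f1, f2, f3)
    assert not out3.loc[0, "coerced"]
    assert out3.loc[0, "triple"] == "up|down|up"


def test_mismatched_universes_rejected():
    d1 = _de_frame(["g1"], [0.5], [0.0])
    d2 = _de_frame(["g2"], [0.5], [0.0])
    with pytest.raises(ValueError):
        assign_patterns(d1, d2, d1)


def test_planted_b_genes_recovered_as_b():
    """>= 80% of planted B genes attributed to B; <= 10% of planted A genes
    mislabeled B (multi-seed)."""
    b_recall, a_as_b = [], []
    for seed in range(5):
        spec = DesignSpec(n_genes=500, seed=seed)
        genes = spec.gene_ids
        planted = {}
        for g in genes[:50]:
            planted[g] = {"pattern": "B",
                          "effects": {r: 1.0 for r in ("dStr", "dHip", "VTA")}}
        for g in genes[50:100]:
            planted[g] = {"pattern": "A",
                          "effects": {r: 1.0 for r in ("dStr", "dHip", "VTA")}}
        counts, meta = simulate_counts(spec, PlantedTruth(pattern_genes=planted))
        norm = de.normalize_log(counts)
        found_b = set()
        for region in ("dStr", "dHip", "VTA"):
            for state in ("Naive", "CocSA"):
                cell = meta[(meta.region == region) & (meta.state == state)]
                tabs = {}
                for ga, gb in (("CSA", "SSA"), ("CY", "SSA"), ("CSA", "CY")):
                    tabs[(ga, gb)] = de.de_test(
                        norm, cell.loc[cell.group == ga, "sample"],
                        cell.loc[cell.group == gb, "sample"])
                out = assign_patterns(tabs[("CSA", "SSA")], tabs[("CY", "SSA")],
                                      tabs[("CSA", "CY")])
                found_b |= set(out.loc[out.abc == "B", "gene"])
        b_recall.append(len(found_b & set(genes[:50])) / 50)
        a_as_b.append(len(found_b & set(genes[50:100])) / 50)
    assert np.mean(b_recall) >= 0.8
    assert np.mean(a_as_b) <= 0.1


# ---------------------------------------------------------------------------
# fold-change consistency


def test_fc_consistency_categories_and_fractions():
    genes = ["g1", "g2", "g3", "g4"]
    d_csa = _de_frame(genes, [0.01] * 4, [1.0, 0.5, -2.0, 0.0])
    d_cy = _de_frame(genes, [0.01] * 4, [-0.5, 1.2, -0.1, 0.0])
    rec, fr = fc_consistency(d_csa, d_cy, genes)
    by_gene = rec.set_index("gene")
    assert by_gene.loc["g1", "category"] == "reverse"
    assert by_gene.loc["g2", "category"] == "cy_greater"
    assert by_gene.loc["g3", "category"] == "csa_greater"
    assert by_gene.loc["g4", "category"] == "csa_greater"
    assert by_gene.loc["g4", "tie_flag"]
    assert sum(fr.values()) == pytest.approx(1.0)
    # ranked by lfc_csa within category
    for _, sub in rec.groupby("category"):
        assert (np.diff(sub["lfc_csa"]) <= 1e-12).all()


def test_fc_consistency_recovers_planted_mixture():
    rng = np.random.default_rng(7)
    n = 2000
    genes = [f"g{i}" for i in range(n)]
    lfc_csa = rng.normal(scale=1.0, size=n)
    bigger = rng.random(n) < 0.76
    scale = np.where(bigger, 1.5, 0.5)
    lfc_cy = np.sign(lfc_csa) * np.abs(lfc_csa) * scale
    rec, fr = fc_consistency(_de_frame(genes, [0.01] * n, lfc_csa),
                             _de_frame(genes, [0.01] * n, lfc_cy), genes)
    assert abs(fr["cy_greater"] - 0.76) < 0.05
    assert fr["reverse"] == 0.0


def test_cross_state_correlation_identity_and_null():
    rng = np.random.default_rng(8)
    genes = [f"g{i}" for i in range(1000)]
    lfc = rng.normal(size=1000)
    d = _de_frame(genes, [0.5] * 1000, lfc)
    r, p, n = cross_state_fc_correlation(d, d)
    assert r == pytest.approx(1.0) and n == 1000
    d2 = _de_frame(genes, [0.5] * 1000, rng.normal(size=1000))
    r_null, _, _ = cross_state_fc_correlation(d, d2)
    assert abs(r_null) < 0.1


def test_cross_state_correlation_attenuation_by_shared_effect():
    # naive and coc-SA effects share a persistent component (share 0.5):
    # expected r = shared_var / total_var = 0.5
    rng = np.random.default_rng(9)
    n = 3000
    genes = [f"g{i}" for i in range(n)]
    shared = rng.normal(size=n)
    a = shared + rng.normal(size=n)
    b = shared + rng.normal(size=n)
    r, _, _ = cross_state_fc_correlation(
        _de_frame(genes, [0.5] * n, a), _de_frame(genes, [0.5] * n, b))
    assert 0.3 < r < 0.7
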