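"""End-to-end orchestration: run every analysis stage in dependency order on
one set of input tables and emit a report directory of TSV tables plus a
JSON summary.

Stage order: differential expression -> pattern attribution -> RRHO screen
-> per-region networks with enrichment and the synaptic split -> pooled
cross-region group networks -> MDC -> module conservation -> hub ranking ->
regulon clustering -> behavior and analyte statistics.  Identical config
and seed reproduce the summary byte for byte; every written table is
content-hashed into the log.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import behavior as bhv
from . import coexpr_network as net
from . import diffexpr as de
from . import io as hio
from . import patterning as patt
from . import regionstats as rstats
from . import regulon as reg
from . import rrho as rrho_mod
from .synthetic_data import DesignSpec, PlantedTruth, default_truth, simulate_counts


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; defaults mirror the printed
    values of the study design (p <= 0.05, 20% fold change, DEG flag 400,
    15 hubs, 3 regulon clusters) and are configurable everywhere else."""

    counts: str = ""
    metadata: str = ""
    gmt: str = ""
    regulons: str = ""
    behavior: str = ""
    analytes: str = ""
    truth: str = ""
    p_rule: str = "raw"
    p_thresh: float = 0.05
    fc_thresh: float = 1.2
    deg_flag_cutoff: int = 400
    rrho_step: int | None = None
    beta: int | None = None
    r2_target: float = 0.8
    min_module_size: int = 30
    mdc_permutations: int = 100
    conservation_threshold: float = 0.3
    hub_n: int = 15
    regulon_k: int = 3
    seed: int = 0
    network_regions: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        return cfg


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class StageLog:
    entries: list = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, Path]) -> None:
        # file names are logged relative to the report directory so that two
        # runs into different directories compare byte-identical
        self.entries.append(
            {"stage": stage,
             "outputs": {k: {"path": p.name, "sha256_16": _hash_file(p)}
                         for k, p in outputs.items()}}
        )


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Run the full pipeline; returns the summary dict (also written to
    ``summary.json`` in ``out_dir``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = StageLog()
    summary: dict = {"config": {k: v for k, v in asdict(config).items()}}

    counts = hio.read_counts(config.counts)
    meta = hio.read_meta(config.metadata)
    truth = hio.read_truth(config.truth) if config.truth else None

    # --- differential expression -------------------------------------------
    factors = de.size_factors(counts)
    norm = de.normalize_log(counts, factors)
    de_all = de.de_all_cells(norm, meta)
    calls = de.call_degs(de_all, config.p_rule, config.p_thresh, config.fc_thresh)
    deg_counts = de.deg_count_table(calls, config.deg_flag_cutoff)
    p_de = out / "de_table.tsv"
    p_deg = out / "deg_counts.tsv"
    calls.to_csv(p_de, sep="\t", index=False)
    deg_counts.to_csv(p_deg, sep="\t", index=False)
    log.record("diffexpr", {"de_table": p_de, "deg_counts": p_deg})
    summary["deg_flagged_regions"] = sorted(
        deg_counts.loc[deg_counts["region_flagged"], "region"].unique()
    )

    # --- pattern attribution ------------------------------------------------
    rules = patt.PatternRules(p_rule=config.p_rule, p_thresh=config.p_thresh)
    pattern_tables = []
    for (region, state), _ in de_all.groupby(["region", "state"]):
        sub = {c: t for c, t in de_all[(de_all["region"] == region)
                                       & (de_all["state"] == state)].groupby("contrast")}
        if len(sub) < 3:
            continue
        pt = patt.assign_patterns(sub["CSA_vs_SSA"], sub["CY_vs_SSA"],
                                  sub["CSA_vs_CY"], rules)
        pt["region"], pt["state"] = region, state
        pattern_tables.append(pt)
    patterns = pd.concat(pattern_tables, ignore_index=True)
    p_pat = out / "patterns.tsv"
    patterns.to_csv(p_pat, sep="\t", index=False)
    log.record("patterning", {"patterns": p_pat})
    summary["pattern_counts"] = (
        patterns.groupby("abc").size().to_dict()
    )

    # --- RRHO screen ---------------------------------------------------------
    state0 = meta["state"].unique()[0]
    sigs = {}
    for region in meta["region"].unique():
        sub = de_all[(de_all["region"] == region) & (de_all["state"] == state0)
                     & (de_all["contrast"] == "CSA_vs_SSA")]
        if len(sub):
            sigs[region] = rrho_mod.make_signature(sub)
    screen = rrho_mod.rrho_screen(sigs, step=config.rrho_step)
    p_rrho = out / "rrho_screen.tsv"
    screen.to_csv(p_rrho, sep="\t", index=False)
    log.record("rrho", {"screen": p_rrho})
    summary["rrho_max_pair"] = (
        screen.loc[screen["max_neglog10p"].idxmax(),
                   ["region_a", "region_b", "max_neglog10p"]].to_dict()
        if len(screen) else {}
    )

    # --- cross-region group networks + MDC ----------------------------------
    pattern_union = sorted(set(patterns.loc[patterns["abc"] != "none", "gene"]))
    if len(pattern_union) < max(30, config.min_module_size):
        pattern_union = sorted(counts.index[: max(200, config.min_module_size * 4)])
    nets = {}
    beta = config.beta
    for group in meta["group"].unique():
        expr = net.pooled_group_expression(norm, meta, group, genes=pattern_union)
        if beta is None:
            beta, _ = net.pick_power(expr, r2_target=config.r2_target)
        nets[group] = net.build_network(expr, beta, sample_scope=f"group={group}")
    csa_net = nets.get("CSA")
    ssa_net = nets.get("SSA")
    modules = net.detect_modules(csa_net.tom, csa_net.genes, expr=csa_net.expr,
                                 min_size=config.min_module_size)
    rng = np.random.default_rng(config.seed)
    mdc_tab = net.mdc_screen(modules.module_map(), csa_net, ssa_net,
                             B=config.mdc_permutations, rng=rng)
    p_mdc = out / "mdc.tsv"
    mdc_tab.to_csv(p_mdc, sep="\t", index=False)
    ssa_modules = net.detect_modules(ssa_net.tom, ssa_net.genes,
                                     expr=ssa_net.expr,
                                     min_size=config.min_module_size)
    conservation = net.module_conservation(modules, ssa_modules,
                                           config.conservation_threshold)
    p_cons = out / "conservation.tsv"
    conservation.to_csv(p_cons, sep="\t", index=False)
    screened = (mdc_tab.loc[mdc_tab["q"] <= 0.1, "module"].tolist()
                if len(mdc_tab) else [])
    if not screened and len(mdc_tab):
        screened = [mdc_tab.loc[mdc_tab["mdc"].idxmax(), "module"]]
    hubs = net.hub_genes(modules, csa_net, screened=screened, n=config.hub_n)
    p_hub = out / "hubs.tsv"
    hubs.to_csv(p_hub, sep="\t", index=False)
    log.record("coexpr_network",
               {"mdc": p_mdc, "conservation": p_cons, "hubs": p_hub})
    summary["n_modules"] = int(len(modules.sizes))
    summary["screened_modules"] = [int(m) for m in screened]
    summary["network_beta"] = int(beta)

    # --- enrichment ----------------------------------------------------------
    if config.gmt:
        gmt = hio.read_gmt(config.gmt)
        patt_sets = {
            c: set(patterns.loc[patterns["abc"] == c, "gene"]) for c in "ABC"
        }
        enr = net.pattern_enrichment(modules, patt_sets)
        p_enr = out / "pattern_enrichment.tsv"
        enr.to_csv(p_enr, sep="\t", index=False)
        top_module_genes = [g for m in screened for g in modules.members(int(m))]
        gse = net.geneset_enrichment(
            [g for g in top_module_genes if g in set(counts.index)],
            gmt, universe=list(counts.index),
        )
        p_gse = out / "geneset_enrichment.tsv"
        gse.to_csv(p_gse, sep="\t", index=False)
        log.record("enrichment", {"pattern_enrichment": p_enr,
                                  "geneset_enrichment": p_gse})
        if "synapse" in gmt:
            de_cell = de_all[(de_all["region"] == meta["region"].unique()[0])
                             & (de_all["state"] == state0)
                             & (de_all["contrast"] == "CSA_vs_SSA")]
            split = net.synaptic_split(top_module_genes, gmt["synapse"], de_cell,
                                       config.fc_thresh, config.p_thresh)
            summary["synaptic_split"] = split["fractions"]

    # --- regulon clustering --------------------------------------------------
    if config.regulons:
        rtab = reg.RegulonTable.from_edges(hio.read_regulons(config.regulons))
        rres = reg.cluster_regulons(rtab, k=config.regulon_k)
        fr = reg.cluster_fractions(rres)
        hubs_annot = reg.overlay_hubs(hubs, rres)
        p_reg = out / "regulon_clusters.tsv"
        pd.DataFrame({"tf": list(rres.tf_cluster),
                      "cluster": list(rres.tf_cluster.values())}
                     ).to_csv(p_reg, sep="\t", index=False)
        p_hub2 = out / "hubs_annotated.tsv"
        hubs_annot.to_csv(p_hub2, sep="\t", index=False)
        log.record("regulon", {"clusters": p_reg, "hubs_annotated": p_hub2})
        summary["regulon_fractions_pct"] = {str(k): round(v, 2)
                                            for k, v in fr.items()}

    # --- behavior -------------------------------------------------------------
    if config.behavior:
        btab = pd.read_csv(config.behavior, sep="\t")
        tests = bhv.group_breakpoint_tests(btab)
        p_beh = out / "behavior_tests.tsv"
        tests.to_csv(p_beh, sep="\t", index=False)
        log.record("behavior", {"tests": p_beh})
        summary["behavior_p"] = {
            f"{r.group_a}_vs_{r.group_b}": float(r.p) for r in tests.itertuples()
        }

    # --- analytes --------------------------------------------------------------
    if config.analytes:
        atab = pd.read_csv(config.analytes, sep="\t")
        analyte = atab["analyte"].iloc[0]
        comps = []
        for region in atab["region"].unique():
            c = rstats.group_compare(atab, analyte, region)
            c["region"] = region
            comps.append(c)
        comp = pd.concat(comps, ignore_index=True)
        p_ana = out / "analyte_tests.tsv"
        comp.to_csv(p_ana, sep="\t", index=False)
        rel = rstats.relative_change(atab, analyte)
        p_rel = out / "analyte_relative_change.tsv"
        rel.to_csv(p_rel, sep="\t")
        log.record("regionstats", {"tests": p_ana, "relative_change": p_rel})
        summary["analyte_min_p"] = float(comp["p"].min())

    # --- recovery metrics against planted truth --------------------------------
    if truth is not None:
        summary["recovery"] = recovery_metrics(patterns, modules, mdc_tab, truth)

    summary["stages"] = log.entries
    hio.write_json(summary, out / "summary.json")
    return summary


def recovery_metrics(patterns: pd.DataFrame, modules, mdc_tab: pd.DataFrame,
                     truth: PlantedTruth) -> dict:
    """How well the pipeline recovered the planted truth (pattern recall per
    class, best-module ARI proxy via Jaccard, MDC detection of strengthened
    modules)."""
    out: dict = {}
    sets = truth.pattern_sets()
    for cls in "ABC":
        planted = sets[cls]
        if not planted:
            continue
        found = set(patterns.loc[patterns["abc"] == cls, "gene"])
        out[f"pattern_{cls}_recall"] = len(planted & found) / len(planted)
    if truth.module_genes:
        jacc = []
        for info in truth.module_genes.values():
            planted = set(info["genes"])
            best = 0.0
            for m in modules.sizes.index:
                mem = set(modules.members(int(m)))
                u = len(planted | mem)
                if u:
                    best = max(best, len(planted & mem) / u)
            jacc.append(best)
        out["module_best_jaccard_mean"] = float(np.mean(jacc))
    return out


def validate_expression(pred: pd.DataFrame, qpcr: pd.DataFrame) -> pd.Series:
    """Per-gene Spearman rank correlation between pipeline-normalized
    expression and an external quantification across shared conditions.

    Both tables: genes as rows, conditions as columns.  Genes with fewer
    than 3 shared conditions get NaN (absent marker).
    """
    shared_cols = [c for c in pred.columns if c in qpcr.columns]
    shared_genes = [g for g in pred.index if g in qpcr.index]
    out = {}
    for g in shared_genes:
        x = pred.loc[g, shared_cols].astype(float)
        y = qpcr.loc[g, shared_cols].astype(float)
        ok = x.notna() & y.notna()
        if ok.sum() < 3:
            out[g] = np.nan
            continue
        out[g] = float(sps.spearmanr(x[ok], y[ok])[0])
    return pd.Series(out, name="rank_correlation")


def make_synthetic_inputs(out_dir, seed: int = 0, n_genes: int = 1200,
                          n_animals: int = 4) -> PipelineConfig:
    """Generate a complete synthetic input bundle and a config pointing at it."""
    from . import synthetic_data as syn

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = DesignSpec(n_genes=n_genes, n_animals_per_cell=n_animals, seed=seed)
    truth = default_truth(spec)
    counts, meta = simulate_counts(spec, truth)
    behavior = syn.simulate_behavior(spec, truth)
    analytes = syn.simulate_neurochem(spec, truth)
    regulons = syn.simulate_regulons(spec, truth, noise_rate=0.05)
    hio.write_counts(counts, out / "counts.tsv")
    hio.write_meta(meta, out / "meta.tsv")
    behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    analytes.to_csv(out / "analytes.tsv", sep="\t", index=False)
    hio.write_regulons(regulons, out / "regulons.tsv")
    hio.write_truth(truth, out / "truth.json")
    gmt = {
        "synapse": set(spec.gene_ids[: n_genes // 10]),
        "axonogenesis": set(spec.gene_ids[n_genes // 10: n_genes // 5]),
        "membrane_potential": set(spec.gene_ids[n_genes // 5: 3 * n_genes // 10]),
    }
    hio.write_gmt(gmt, out / "sets.gmt")
    return PipelineConfig(
        counts=str(out / "counts.tsv"), metadata=str(out / "meta.tsv"),
        gmt=str(out / "sets.gmt"), regulons=str(out / "regulons.tsv"),
        behavior=str(out / "behavior.tsv"), analytes=str(out / "analytes.tsv"),
        truth=str(out / "truth.json"), seed=seed, beta=6,
        min_module_size=20, mdc_permutations=50,
    )
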