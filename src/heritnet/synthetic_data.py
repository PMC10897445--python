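"""Synthetic data with planted ground truth for the three-group inheritance design.

Emulates the study layout: three paternal arms (saline self-administration
SSA, cocaine self-administration CSA, yoked cocaine CY), two offspring
states (Naive, CocSA), seven reward-circuitry regions, a few littermates
per cell.  Four generators cover the data types the pipeline consumes:

* ``simulate_counts``    — negative-binomial RNA-seq counts with planted
  A/B/C pattern genes and latent-factor co-expression modules whose
  loading differs by paternal group (drives differential connectivity).
* ``simulate_behavior``  — lever presses per session and a progressive-
  ratio breakpoint per animal, with planted group shifts.
* ``simulate_neurochem`` — per-animal per-region analyte concentrations
  drawn from group-specific multivariate normals (cross-region
  correlation targets planted).
* ``simulate_regulons``  — a binary TF-by-gene table with planted cluster
  blocks plus uniform noise edges.

All randomness flows from one integer seed through a counter-based
(Philox) stream per table, so a fixed seed fixes every emitted byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

DEFAULT_GROUPS = ("SSA", "CSA", "CY")
DEFAULT_STATES = ("Naive", "CocSA")
DEFAULT_REGIONS = ("OFC", "mPFC", "NAc", "dStr", "dHip", "BLA", "VTA")

# fixed sub-stream ids so each table draws from its own counter-based stream
_STREAMS = {"counts": 0, "behavior": 1, "neurochem": 2, "regulons": 3, "truth": 4}


def table_rng(seed: int, table: str) -> np.random.Generator:
    """Philox stream for one output table, keyed on (seed, table id)."""
    return np.random.Generator(np.random.Philox(key=np.uint64(seed), counter=[_STREAMS[table], 0, 0, 0]))


@dataclass
class DesignSpec:
    """The sampling grid and count-model parameters of the simulated study."""

    n_genes: int = 2000
    groups: tuple[str, ...] = DEFAULT_GROUPS
    states: tuple[str, ...] = DEFAULT_STATES
    regions: tuple[str, ...] = DEFAULT_REGIONS
    n_animals_per_cell: int = 4
    n_litters: int = 7
    nb_dispersion: float = 0.1
    litter_sd: float = 0.1
    region_sd: float = 0.5
    baseline_log2_mean_range: tuple[float, float] = (3.0, 9.0)
    module_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_per_cell < 2:
            raise ValueError("n_animals_per_cell must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.litter_sd < 0:
            raise ValueError("litter_sd must be non-negative")
        for labels in (self.groups, self.states, self.regions):
            if len(set(labels)) != len(labels):
                raise ValueError(f"labels must be unique: {labels}")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class PlantedTruth:
    """Ground truth planted into the simulated tables.

    pattern_genes : gene -> {"pattern": A|B|C, "effects": {region: signed log2 shift}}
        A shifts CSA and CY offspring alike (paternal drug exposure),
        B shifts only CSA (paternal highly-motivated seeking),
        C shifts only CY (paternal passive infusion).
    module_genes : module -> {"genes": [...], "loadings": {group: float in [0,1]}}
        One latent factor per (module, sample); within-module log-scale
        correlation equals loading**2 for that sample's group.
    regulon_truth : {"tf_targets": {tf: [genes]}, "tf_cluster": {tf: label}}
    behavior_effects : group -> breakpoint shift in baseline-SD units.
    analyte_effects : {"mean_shift": {group: {region: fractional shift}},
                       "corr": {group: region-by-region correlation matrix (list of lists)}}
    """

    pattern_genes: dict = field(default_factory=dict)
    module_genes: dict = field(default_factory=dict)
    regulon_truth: dict = field(default_factory=dict)
    behavior_effects: dict = field(default_factory=dict)
    analyte_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        patt = list(self.pattern_genes)
        if len(set(patt)) != len(patt):
            raise ValueError("pattern gene sets overlap")
        seen: set[str] = set()
        for mod, info in self.module_genes.items():
            genes = set(info["genes"])
            if genes & seen:
                raise ValueError(f"module gene sets overlap at module {mod}")
            seen |= genes
            for g, lam in info.get("loadings", {}).items():
                if not 0.0 <= lam <= 1.0:
                    raise ValueError(f"loading out of [0,1] for module {mod}, group {g}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        return cls(**json.loads(text))

    def pattern_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {"A": set(), "B": set(), "C": set()}
        for gene, info in self.pattern_genes.items():
            out[info["pattern"]].add(gene)
        return out


def default_truth(spec: DesignSpec, n_pattern: int = 60, n_modules: int = 3,
                  module_size: int = 40, effect_lfc: float = 1.0) -> PlantedTruth:
    """A reasonable planted truth: A/B/C genes with |log2FC| = effect_lfc in
    the regions the study highlights, plus CSA-strengthened co-expression
    modules planted inside the pattern-gene universe (one per pattern
    class), mirroring a cross-region network built on the pattern union."""
    rng = table_rng(spec.seed, "truth")
    genes = spec.gene_ids
    need = 3 * n_pattern
    if module_size > n_pattern:
        raise ValueError("module_size cannot exceed n_pattern")
    if n_modules > 3:
        raise ValueError("default truth plants at most one module per class")
    if need > len(genes):
        raise ValueError("not enough genes for the requested truth")
    chosen = list(rng.choice(len(genes), size=need, replace=False))
    pattern_genes = {}
    class_members: dict[str, list[str]] = {}
    focus = {"A": ["OFC"], "B": ["dStr", "dHip", "VTA"], "C": ["NAc"]}
    for pi, patt in enumerate("ABC"):
        class_members[patt] = []
        for j in range(n_pattern):
            g = genes[chosen[pi * n_pattern + j]]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            pattern_genes[g] = {
                "pattern": patt,
                "effects": {r: sign * effect_lfc for r in focus[patt]},
            }
            class_members[patt].append(g)
    module_genes = {}
    for m, patt in enumerate("ABC"[:n_modules]):
        module_genes[f"M{m + 1}"] = {
            "genes": class_members[patt][:module_size],
            "loadings": {"SSA": 0.3, "CSA": 0.9, "CY": 0.3},
        }
    return PlantedTruth(
        pattern_genes=pattern_genes,
        module_genes=module_genes,
        regulon_truth={},
        behavior_effects={"SSA": 0.0, "CSA": 1.5, "CY": 0.0},
        analyte_effects={"mean_shift": {"CSA": {"OFC": -0.3, "NAc": -0.25, "dStr": -0.3}}},
    )


# ---------------------------------------------------------------------------
# counts


def _sample_meta(spec: DesignSpec) -> pd.DataFrame:
    rows = []
    animal = 0
    for state in spec.states:
        for group in spec.groups:
            for region in spec.regions:
                for a in range(spec.n_animals_per_cell):
                    litter = a % spec.n_litters if spec.n_litters else 0
                    rows.append(
                        {
                            "sample": f"{group}_{state}_{region}_a{a + 1}",
                            "animal": f"{group}_{state}_a{a + 1}",
                            "litter": f"{group}_L{litter + 1}",
                            "group": group,
                            "state": state,
                            "region": region,
                        }
                    )
                    animal += 1
    return pd.DataFrame(rows)


def _pattern_shift(info: dict, group: str, region: str) -> float:
    patt = info["pattern"]
    eff = info["effects"].get(region, 0.0)
    if patt == "A" and group in ("CSA", "CY"):
        return eff
    if patt == "B" and group == "CSA":
        return eff
    if patt == "C" and group == "CY":
        return eff
    return 0.0


def simulate_counts(spec: DesignSpec, truth: PlantedTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts (genes x samples) plus sample metadata.

    Per-gene expected value is 2**(baseline + litter effect + planted
    group/pattern effect + module latent component); NB dispersion is the
    common ``spec.nb_dispersion`` (variance mu + alpha*mu^2).
    """
    truth.validate()
    unknown = [g for g in truth.pattern_genes if g not in set(spec.gene_ids)]
    for mod in truth.module_genes.values():
        unknown += [g for g in mod["genes"] if g not in set(spec.gene_ids)]
    if unknown:
        raise ValueError(f"planted genes outside the gene universe: {unknown[:5]}")

    rng = table_rng(spec.seed, "counts")
    meta = _sample_meta(spec)
    genes = spec.gene_ids
    n_g, n_s = len(genes), len(meta)
    gi = {g: i for i, g in enumerate(genes)}

    lo, hi = spec.baseline_log2_mean_range
    baseline = rng.uniform(lo, hi, size=n_g)

    litters = sorted(meta["litter"].unique())
    litter_eff = dict(zip(litters, rng.normal(0.0, spec.litter_sd, size=len(litters))))
    # per-gene region offsets: regions express genes at different levels
    region_eff = rng.normal(0.0, spec.region_sd, size=(n_g, len(spec.regions)))
    region_idx = {r: i for i, r in enumerate(spec.regions)}

    log2mu = np.tile(baseline[:, None], (1, n_s))
    log2mu += np.array([litter_eff[l] for l in meta["litter"]])[None, :]
    log2mu += region_eff[:, [region_idx[r] for r in meta["region"]]]

    for gene, info in truth.pattern_genes.items():
        row = gi[gene]
        for j, (group, region) in enumerate(zip(meta["group"], meta["region"])):
            log2mu[row, j] += _pattern_shift(info, group, region)

    # latent factor per (module, sample); loading depends on the sample's group
    for info in truth.module_genes.values():
        rows = np.array([gi[g] for g in info["genes"]])
        lam = np.array([info["loadings"].get(g, 0.0) for g in meta["group"]])
        factor = rng.normal(size=n_s)
        eps = rng.normal(size=(len(rows), n_s))
        comp = lam[None, :] * factor[None, :] + np.sqrt(1.0 - lam**2)[None, :] * eps
        log2mu[rows, :] += spec.module_sd * comp

    mu = np.exp2(log2mu)
    shape = 1.0 / spec.nb_dispersion
    lam = rng.gamma(shape, mu * spec.nb_dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=meta["sample"])
    return counts_df, meta


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(
    spec: DesignSpec,
    truth: PlantedTruth,
    n_sessions: int = 9,
    baseline_breakpoint: float = 120.0,
    breakpoint_sd: float = 40.0,
    baseline_presses: float = 80.0,
) -> pd.DataFrame:
    """Per-animal lever presses per FR session plus one PR breakpoint.

    ``behavior_effects`` are breakpoint shifts in units of ``breakpoint_sd``.
    Negative draws are clipped at 0 (counts cannot be negative).
    """
    rng = table_rng(spec.seed, "behavior")
    rows = []
    for group in spec.groups:
        shift = truth.behavior_effects.get(group, 0.0) * breakpoint_sd
        for a in range(spec.n_animals_per_cell * spec.n_litters):
            animal = f"{group}_b{a + 1}"
            litter = f"{group}_L{a % spec.n_litters + 1}"
            ramp = 1.0 + 0.05 * np.arange(n_sessions)
            active = rng.poisson(np.maximum(baseline_presses * ramp + shift / 2.0, 0.0))
            inactive = rng.poisson(np.full(n_sessions, 8.0))
            bp = max(0.0, rng.normal(baseline_breakpoint + shift, breakpoint_sd))
            for s in range(n_sessions):
                rows.append(
                    {"animal": animal, "litter": litter, "group": group, "session": s + 1,
                     "active_presses": int(active[s]), "inactive_presses": int(inactive[s]),
                     "infusions": int(active[s] // 5), "breakpoint": np.nan}
                )
            rows.append(
                {"animal": animal, "litter": litter, "group": group, "session": n_sessions + 1,
                 "active_presses": 0, "inactive_presses": 0, "infusions": 0,
                 "breakpoint": round(bp, 3)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# neurochemistry


def simulate_neurochem(
    spec: DesignSpec,
    truth: PlantedTruth,
    analyte: str = "dopamine",
    n_per_group: int = 5,
    baseline: float = 10.0,
    cv: float = 0.15,
) -> pd.DataFrame:
    """Per-animal per-region analyte concentrations, group-wise MVN.

    ``analyte_effects['corr'][group]`` is the target cross-region correlation
    (identity when absent); ``mean_shift`` entries are fractional changes of
    the group's regional mean versus baseline.
    """
    if n_per_group < 3:
        raise ValueError("need at least 3 animals per group")
    if cv <= 0:
        raise ValueError("zero or negative variance requested")
    rng = table_rng(spec.seed, "neurochem")
    regions = list(spec.regions)
    k = len(regions)
    rows = []
    for group in spec.groups:
        corr = np.asarray(
            truth.analyte_effects.get("corr", {}).get(group, np.eye(k)), dtype=float
        )
        if corr.shape != (k, k):
            raise ValueError("correlation target has wrong shape")
        eigmin = np.linalg.eigvalsh(corr).min()
        if eigmin <= 1e-10:
            raise ValueError(f"correlation target for {group} is not positive definite")
        shifts = truth.analyte_effects.get("mean_shift", {}).get(group, {})
        means = np.array([baseline * (1.0 + shifts.get(r, 0.0)) for r in regions])
        sds = cv * means
        cov = corr * np.outer(sds, sds)
        draws = rng.multivariate_normal(means, cov, size=n_per_group, method="cholesky")
        draws = np.maximum(draws, 0.0)
        for a in range(n_per_group):
            for ri, region in enumerate(regions):
                rows.append(
                    {"animal": f"{group}_n{a + 1}", "group": group, "region": region,
                     "analyte": analyte, "value": float(draws[a, ri])}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regulons


def simulate_regulons(
    spec: DesignSpec,
    truth: PlantedTruth,
    n_tfs: int = 20,
    n_clusters: int = 3,
    targets_per_tf: int = 30,
    noise_rate: float = 0.0,
) -> pd.DataFrame:
    """Binary TF x gene edge table with planted cluster blocks.

    TFs are split evenly into ``n_clusters`` clusters; each cluster owns a
    disjoint block of target genes shared by its TFs (each TF samples
    ``targets_per_tf`` of them).  Uniform noise edges are added at
    ``noise_rate`` per (tf, non-block gene).  The planted clustering is
    recorded in ``truth.regulon_truth``.
    """
    if n_tfs < 1:
        raise ValueError("need at least one TF")
    if not 0.0 <= noise_rate < 1.0:
        raise ValueError("noise rate must lie in [0, 1)")
    rng = table_rng(spec.seed, "regulons")
    genes = spec.gene_ids
    block_size = max(targets_per_tf, 1)
    if n_clusters * block_size > len(genes):
        raise ValueError("gene universe too small for requested blocks")
    tf_names = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    blocks = [genes[c * block_size:(c + 1) * block_size] for c in range(n_clusters)]
    tf_cluster = {tf: i % n_clusters for i, tf in enumerate(tf_names)}
    edges = []
    tf_targets: dict[str, list[str]] = {}
    for tf in tf_names:
        block = blocks[tf_cluster[tf]]
        take = min(targets_per_tf, len(block))
        targets = sorted(rng.choice(block, size=take, replace=False))
        if noise_rate > 0:
            block_set = set(block)
            outside = [g for g in genes if g not in block_set]
            noise_mask = rng.random(len(outside)) < noise_rate
            targets = sorted(set(targets) | {g for g, m in zip(outside, noise_mask) if m})
        tf_targets[tf] = list(targets)
        edges += [{"tf": tf, "target": g} for g in targets]
    truth.regulon_truth = {
        "tf_targets": tf_targets,
        "tf_cluster": {tf: f"C{c + 1}" for tf, c in tf_cluster.items()},
    }
    return pd.DataFrame(edges)
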