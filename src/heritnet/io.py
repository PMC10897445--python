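"""Readers and writers for the pipeline's plain-text interchange formats:
count and metadata TSVs, GMT gene sets, regulon edge tables, planted-truth
JSON."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synthetic_data import PlantedTruth


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample", "animal", "litter", "group", "state", "region"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks columns: {sorted(missing)}")
    return meta


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description] + sorted(members))
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_regulons(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    if not {"tf", "target"} <= set(tab.columns):
        raise ValueError("regulon table needs columns tf, target")
    return tab


def write_regulons(table: pd.DataFrame, path) -> None:
    table[["tf", "target"]].to_csv(path, sep="\t", index=False)


def write_truth(truth: PlantedTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path) -> PlantedTruth:
    return PlantedTruth.from_json(Path(path).read_text())


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
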