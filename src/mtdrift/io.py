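"""Readers and writers for the pipeline's plain-text formats.

Everything is tab-separated text, bedGraph/BED (0-based half-open) or
JSON/YAML; pandas does the parsing.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from mtdrift.evosim import EffectTable, SimConfig
from mtdrift.synthetic import PlateSet

BEDGRAPH_COLS = ["chrom", "start", "end", "depth"]
BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_curves(path) -> pd.DataFrame:
    """Long-format growth curves: plate, row, col, time_h, cells."""
    return pd.read_csv(path, sep="\t")


def read_layout(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_control"] = df["is_control"].astype(bool)
    return df


def write_plateset(plates: PlateSet, curves_path, layout_path, truth_path=None):
    plates.curves.to_csv(curves_path, sep="\t", index=False)
    plates.layout.to_csv(layout_path, sep="\t", index=False)
    if truth_path is not None:
        plates.truth.to_csv(truth_path, sep="\t", index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=BEDGRAPH_COLS)
    return df


def write_bedgraph(track: pd.DataFrame, path):
    track[BEDGRAPH_COLS].to_csv(path, sep="\t", index=False, header=False)


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLS[: df.shape[1]]
    return df


def write_bed6(genes: pd.DataFrame, path):
    cols = [c for c in BED6_COLS if c in genes.columns]
    genes[cols].to_csv(path, sep="\t", index=False, header=False)


def write_truth_json(truth: dict, path):
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")


def read_qpcr(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_effect_tables(genes_path, chroms_path) -> EffectTable:
    return EffectTable(genes=pd.read_csv(genes_path, sep="\t"),
                       chroms=pd.read_csv(chroms_path, sep="\t"))


def write_effect_tables(table: EffectTable, genes_path, chroms_path):
    table.genes.to_csv(genes_path, sep="\t", index=False)
    table.chroms.to_csv(chroms_path, sep="\t", index=False)


def read_sim_config(path) -> SimConfig:
    """Simulation config from JSON or YAML (by extension)."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return SimConfig(**data)


def write_sim_config(config: SimConfig, path):
    path = Path(path)
    data = asdict(config)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(data))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")
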