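"""Stable on-disk formats and pipeline configuration.

All tables are plain text: TSV for metadata, biogeochemistry, OTU counts and
reports; CSV for gas time series; JSON for ground truth and manifests;
Newick for the annotated UPGMA tree; YAML for configuration. UTF-8, '.'
decimal throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .classify import ClassifiedDendrogram, TreeNode
from .otus import OtuTable
from .synthetic import BIOGEOCHEM_VARIABLES

__all__ = [
    "PipelineConfig",
    "read_metadata_tsv", "write_metadata_tsv",
    "read_biogeochem_tsv", "write_biogeochem_tsv",
    "read_otu_tsv", "write_otu_tsv",
    "read_gas_csv", "write_gas_csv",
    "read_ground_truth", "write_ground_truth",
    "tree_to_newick", "write_newick",
]


class FormatError(ValueError):
    """Raised for schema violations in input files."""


# ------------------------------------------------------------------ tables

def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "block", "treatment", "replicate", "composite_id"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicated sample id {dup!r}")
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


def write_biogeochem_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="composite_id")


def read_biogeochem_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="composite_id")
    if table.index.has_duplicates:
        raise FormatError(f"{path}: duplicated composite ids")
    return table


def write_otu_tsv(
    table: OtuTable | pd.DataFrame, path: str | Path, *, samples_as_rows: bool = False
) -> None:
    """Write an OTU table: rows = OTU ids, columns = samples (+ optional
    trailing ``taxonomy`` column); ``samples_as_rows`` writes the transpose
    without taxonomy."""
    counts = table.counts if isinstance(table, OtuTable) else table
    taxonomy = table.taxonomy if isinstance(table, OtuTable) else None
    if samples_as_rows:
        counts.to_csv(path, sep="\t", index_label="sample_id")
        return
    out = counts.T
    out.index.name = "otu_id"
    if taxonomy is not None:
        out = out.assign(taxonomy=taxonomy.reindex(out.index))
    out.to_csv(path, sep="\t")


def read_otu_tsv(path: str | Path, *, samples_as_rows: bool = False) -> OtuTable:
    """Read an OTU count TSV, validating shape and count integrity.

    Default orientation: rows = OTU ids, columns = sample ids, optional
    trailing ``taxonomy`` column. Ragged rows raise naming the line number.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    width = len(lines[0].split("\t"))
    for lineno, line in enumerate(lines[1:], start=2):
        if line and len(line.split("\t")) != width:
            raise FormatError(f"{path}: ragged row at line {lineno}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    taxonomy = None
    if "taxonomy" in df.columns and not samples_as_rows:
        taxonomy = df.pop("taxonomy")
    counts = df.apply(pd.to_numeric, errors="raise")
    if samples_as_rows:
        counts.index.name = "sample_id"
    else:
        counts = counts.T
        counts.index.name = "sample_id"
    if (counts.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts")
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise FormatError(f"{path}: duplicated sample or OTU identifiers")
    counts = counts.astype("int64")
    return OtuTable(counts=counts, taxonomy=taxonomy)


def write_gas_csv(series: pd.DataFrame, path: str | Path) -> None:
    """Gas time-series CSV with columns sample_id, gas, time_h, ppmv."""
    required = ["sample_id", "gas", "time_h", "ppmv"]
    missing = [c for c in required if c not in series.columns]
    if missing:
        raise FormatError(f"gas series missing columns {missing}")
    series[required].to_csv(path, index=False)


def read_gas_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "gas", "time_h", "ppmv"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing gas columns {sorted(missing)}")
    return df


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True),
                          encoding="utf-8")


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


# ------------------------------------------------------------------ Newick

_NEEDS_QUOTES = set("()[]{}:;,'\" \t")


def _quote(label: str) -> str:
    if any(ch in _NEEDS_QUOTES for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_to_newick(
    root: TreeNode,
    leaf_names: tuple[str, ...],
    node_tests: dict[int, tuple[float, float]] | None = None,
) -> str:
    """Newick string with branch lengths under the merge-height convention
    (branch length = parent height - child height) and per-node SIMPROF
    p-values as bracket comments."""
    node_tests = node_tests or {}

    def render(node: TreeNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{_quote(leaf_names[node.leaves[0]])}:{length:g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        comment = ""
        if node.node_id in node_tests:
            _, p = node_tests[node.node_id]
            comment = f"[&p={p:g}]"
        return f"({inner}){comment}:{length:g}"

    inner = ",".join(render(c, root.height) for c in root.children)
    comment = ""
    if root.node_id in node_tests:
        comment = f"[&p={node_tests[root.node_id][1]:g}]"
    return f"({inner}){comment};"


def write_newick(dendro: ClassifiedDendrogram, path: str | Path) -> None:
    Path(path).write_text(
        tree_to_newick(dendro.root, dendro.leaf_names, dendro.node_tests) + "\n",
        encoding="utf-8",
    )


# ------------------------------------------------------------------ config

@dataclass
class PipelineConfig:
    """Everything the pipeline needs, round-trippable through YAML."""

    metadata: str = "metadata.tsv"
    biogeochem: str = "biogeochem.tsv"
    otu_table: str | None = "otu_table.tsv"
    gas_series: str | None = None
    outdir: str = "results"
    variables: tuple[str, ...] = BIOGEOCHEM_VARIABLES
    transforms: dict = field(default_factory=dict)
    reference_treatment: str = "unlogged"
    alpha: float = 0.05
    n_perm_simprof: int = 999
    n_perm_rda: int = 1000
    n_perm_indval: int = 999
    rarefaction_depth: int | str = "min"
    filter_fraction: float = 0.00005
    indval_mode: str = "group_equalized"
    seed: int = 0
    classify_only: bool = False

    def __post_init__(self) -> None:
        for name in ("n_perm_simprof", "n_perm_rda", "n_perm_indval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.variables = tuple(self.variables)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["variables"] = list(data["variables"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)
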