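"""Readers and writers for the pipeline's plain-text formats.

All tabular data are TSV: feature x sample matrices with the feature
identifier in the first column, a two-column sample/group metadata
table, a SIF-like network table (nodeA <tab> gene_id <tab> nodeB, one
line per edge-gene annotation), GMT feature-set files, and JSON for
ground truth and summaries. Empty metabolite cells denote missing
values and round-trip as NaN, never zero.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import GroundTruth, MetabolicNetwork, SyntheticDataset

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "read_network_sif",
    "write_network_sif",
    "read_gmt",
    "write_gmt",
    "write_ground_truth",
    "load_tables",
    "write_dataset",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Feature x sample TSV; empty cells become NaN (missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature identifiers in {path}: {dupes[:10]}")
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "group"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata {path} must have columns {sorted(required)}")
    if meta["sample"].duplicated().any():
        raise ValueError(f"duplicate sample identifiers in {path}")
    return meta[["sample", "group"]]


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata[["sample", "group"]].to_csv(path, sep="\t", index=False)


def read_network_sif(path: str | Path) -> MetabolicNetwork:
    """SIF-like edge list: nodeA <tab> gene_id <tab> nodeB.

    Multiple lines for the same node pair accumulate gene annotations.
    """
    genes: dict[tuple[str, str], list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            a, gene, b = parts
            key = (a, b) if a <= b else (b, a)
            genes.setdefault(key, [])
            if gene not in genes[key]:
                genes[key].append(gene)
    g = nx.Graph()
    for (a, b), gene_list in genes.items():
        g.add_edge(a, b, genes=tuple(gene_list))
    return MetabolicNetwork(g)


def write_network_sif(network: MetabolicNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, gene_list in network.edge_triples():
            for gene in gene_list:
                fh.write(f"{u}\t{gene}\t{v}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT feature sets: name <tab> description <tab> member..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need name, description and >=1 member"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(parts[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name, *sorted(members)]) + "\n")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "affected_gene_ids": sorted(truth.affected_gene_ids),
        "gene_log2fc": {k: float(v) for k, v in truth.gene_log2fc.items()},
        "suppression": truth.suppression,
        "metabolite_log2fc": {
            k: float(v) for k, v in truth.metabolite_log2fc.items()
        },
        "planted_module_nodes": sorted(truth.planted_module_nodes),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _check_samples(matrix: pd.DataFrame, metadata: pd.DataFrame, label: str) -> None:
    known = set(metadata["sample"])
    missing = [s for s in matrix.columns if s not in known]
    if missing:
        raise ValueError(f"{label} samples absent from metadata: {missing}")


def load_tables(
    counts_path: str | Path | None = None,
    fpkm_path: str | Path | None = None,
    metabolite_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
    network_path: str | Path | None = None,
    gmt_path: str | Path | None = None,
) -> dict:
    """Load whichever inputs are given, cross-validating sample labels
    against the metadata."""
    if metadata_path is None:
        raise ValueError("metadata_path is required")
    metadata = read_metadata(metadata_path)
    out: dict = {"metadata": metadata}
    for key, path in [
        ("counts", counts_path),
        ("fpkm", fpkm_path),
        ("metabolites", metabolite_path),
    ]:
        if path is not None:
            matrix = read_matrix(path)
            _check_samples(matrix, metadata, key)
            out[key] = matrix
    if network_path is not None:
        out["network"] = read_network_sif(network_path)
    if gmt_path is not None:
        out["sets"] = read_gmt(gmt_path)
    return out


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic artefact; returns the path of each file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "fpkm": outdir / "fpkm.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "metadata": outdir / "metadata.tsv",
        "network": outdir / "network.sif",
        "sets": outdir / "metabolite_sets.gmt",
        "truth": outdir / "ground_truth.json",
    }
    write_matrix(dataset.counts, paths["counts"])
    write_matrix(dataset.fpkm, paths["fpkm"])
    write_matrix(dataset.metabolites, paths["metabolites"])
    write_metadata(dataset.metadata, paths["metadata"])
    write_network_sif(dataset.network, paths["network"])
    write_gmt(dataset.metabolite_sets, paths["sets"])
    write_ground_truth(dataset.truth, paths["truth"])
    return paths
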