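"""Readers and writers for the pipeline's text formats.

All matrices travel as TSV: header row of sample IDs, first column of
gene IDs.  Gene sets use GMT (name, description, then genes), ranked
lists use RNK (gene, score), and networks are exported as SIF plus an
edge-attribute TSV loadable in Cytoscape.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_detection_tsv", "write_detection_tsv",
    "read_annotation_tsv", "write_annotation_tsv",
    "read_gmt", "write_gmt", "read_rnk", "write_rnk",
    "write_network", "write_truth_json", "read_truth_json",
]


def _check_unique(index, what: str, path) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated {what}: {dupes[:5]}")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix with validation.

    Raises ValueError naming the offending ID or cell for duplicate
    gene/sample IDs, non-numeric cells, or ragged rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed TSV: {e}") from e
    _check_unique(df.index, "gene IDs", path)
    _check_unique(df.columns, "sample IDs", path)
    try:
        df = df.astype(float)
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric expression cell: {e}") from e
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"{path}: non-finite expression values")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    # 17 significant digits: float64 round-trips exactly
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_detection_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(df.index, "gene IDs", path)
    bad = set(np.unique(df.to_numpy())) - {"P", "M", "A"}
    if bad:
        raise ValueError(f"{path}: invalid detection calls {sorted(bad)}; expected P/M/A")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df


def write_detection_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Sample annotation: columns sample_id, batch, series."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "batch", "series"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(required)}, has {list(df.columns)}")
    df = df.set_index("sample_id")
    _check_unique(df.index, "sample IDs", path)
    return df


def write_annotation_tsv(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> dict:
    """GMT: one set per line -- name TAB description TAB gene TAB gene..."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >= 1 gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicated set name {name!r}")
            sets[name] = fields[2:]
    return sets


def write_gmt(sets: dict, path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description or name] + list(genes)) + "\n")


def read_rnk(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "score"])
    return pd.Series(df["score"].to_numpy(float), index=df["gene_id"].astype(str))


def write_rnk(scores: pd.Series, path: str | Path) -> None:
    scores.sort_values(ascending=False).to_csv(path, sep="\t", header=False)


def write_network(net, sif_path: str | Path, edge_tsv_path: str | Path) -> None:
    """Export a CorrelationNetwork as SIF plus an edge-attribute table."""
    with open(sif_path, "w") as fh:
        connected = set()
        for row in net.edges.itertuples(index=False):
            rel = "pos" if row.sign > 0 else "neg"
            fh.write(f"{row.source}\t{rel}\t{row.target}\n")
            connected.update((row.source, row.target))
        for name in net.node_names:  # isolated nodes still appear
            if name not in connected:
                fh.write(f"{name}\n")
    net.edges.to_csv(edge_tsv_path, sep="\t", index=False, float_format="%.6g")


def write_truth_json(truth, path: str | Path) -> None:
    payload = {
        "W_true": np.asarray(truth.W_true).tolist(),
        "H_true": np.asarray(truth.H_true).tolist(),
        "batch_shift": np.asarray(truth.batch_shift).tolist(),
        "batch_scale": np.asarray(truth.batch_scale).tolist(),
        "noise_sd": truth.noise_sd,
        "absent_genes": sorted(truth.absent_genes),
        "series_design": {s: sorted(m) for s, m in truth.series_design.items()},
        "seed": truth.seed,
        "gene_ids": list(truth.gene_ids),
        "sample_ids": list(truth.sample_ids),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path):
    from .synthetic import SyntheticTruth

    d = json.loads(Path(path).read_text())
    return SyntheticTruth(
        W_true=np.asarray(d["W_true"], float),
        H_true=np.asarray(d["H_true"], float),
        batch_shift=np.asarray(d["batch_shift"], float),
        batch_scale=np.asarray(d["batch_scale"], float),
        noise_sd=float(d["noise_sd"]),
        absent_genes=frozenset(d["absent_genes"]),
        series_design={s: set(m) for s, m in d["series_design"].items()},
        seed=int(d["seed"]),
        gene_ids=list(d["gene_ids"]),
        sample_ids=list(d["sample_ids"]),
    )
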