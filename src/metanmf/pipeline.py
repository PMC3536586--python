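"""End-to-end pipeline driver.

Runs simulate (optional) -> detection filter -> centering -> L2 gene
selection -> EB batch adjustment -> nonnegativity -> (optional rank
scan) -> NMF -> metagene extraction -> series activity -> correlation
network -> cluster overlap, writing every artifact as a text file plus a
JSON manifest of parameters, seeds and file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .batch import correlation_diagnostic, eb_batch_adjust
from .extract import export_ranked_lists, order_and_extract
from .nmf import factorize
from .preprocess import center_genes, detection_filter, l2_select, to_nonnegative
from .rank import scan_ranks
from .stats import activity_matrix, build_network, overlap_heatmap
from .synthetic import derive_cluster_sets, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every pipeline parameter in one validated place.

    Defaults mirror the reference analysis: 80% detection threshold,
    top-7000 L2 gene selection (clamped to the matrix), delta = 0.2,
    alpha = 1e-12, 50 consensus runs per candidate rank.
    """

    outdir: str = "results/pipeline"
    seed: int = 0
    # simulate stage (used when no expression path is given)
    simulate: bool = True
    n_genes: int = 200
    n_samples: int = 60
    k_true: int = 4
    n_batches: int = 3
    noise_sd: float = 0.1
    absent_fraction: float = 0.1
    cluster_top_m: int = 30
    cluster_jitter: float = 0.0
    # input paths (used when simulate is False)
    expression_path: str | None = None
    calls_path: str | None = None
    annotation_path: str | None = None
    clusters_path: str | None = None
    # preprocessing
    detection_threshold: float = 0.8
    top_n: int = 7000
    nonneg_mode: str = "shift"
    run_batch_adjust: bool = True
    diagnostic_genes: int = 50
    # rank scan (optional) and factorization
    k_values: list = field(default_factory=list)
    runs_per_k: int = 50
    k: int = 4
    tol: float = 1e-4
    max_outer: int = 500
    # downstream statistics
    delta: float = 0.2
    alpha: float = 1e-12
    background_n: int | None = None

    def validate(self) -> None:
        """Check every parameter against its stage's preconditions."""
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if not 0 < self.detection_threshold <= 1:
            raise ValueError(f"detection_threshold must be in (0, 1], got {self.detection_threshold}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.top_n < 1:
            raise ValueError(f"top_n must be >= 1, got {self.top_n}")
        if self.nonneg_mode not in ("shift", "clip"):
            raise ValueError(f"nonneg_mode must be 'shift' or 'clip', got {self.nonneg_mode!r}")
        if self.runs_per_k < 1:
            raise ValueError("runs_per_k must be >= 1")
        if self.simulate:
            if not 1 <= self.k_true < min(self.n_genes, self.n_samples):
                raise ValueError("k_true must be < min(n_genes, n_samples)")
            if not 0 <= self.absent_fraction < 1:
                raise ValueError("absent_fraction must be in [0, 1)")
        elif not self.expression_path:
            raise ValueError("expression_path is required when simulate is False")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; return the artifact-path bundle.

    Stage failures raise with the stage name; artifacts written before
    the failure are left in place.  The manifest (parameters, seeds,
    package/library versions, SHA-256 of every artifact) is sufficient to
    re-run the pipeline identically.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"

    def emit(name: str, path: Path):
        artifacts[name] = path

    try:
        stage = "simulate" if config.simulate else "load"
        truth = None
        clusters = None
        if config.simulate:
            expr, calls, ann, truth = generate_dataset(
                config.n_genes, config.n_samples, config.k_true,
                n_batches=config.n_batches, noise_sd=config.noise_sd,
                absent_fraction=config.absent_fraction, seed=config.seed,
            )
            clusters = derive_cluster_sets(
                truth, top_m=config.cluster_top_m,
                jitter=config.cluster_jitter, seed=config.seed,
            )
            io.write_expression_tsv(expr, outdir / "expression.tsv")
            io.write_detection_tsv(calls, outdir / "detection_calls.tsv")
            io.write_annotation_tsv(ann, outdir / "sample_annotation.tsv")
            io.write_gmt(clusters, outdir / "external_clusters.gmt")
            io.write_truth_json(truth, outdir / "truth.json")
            for name in ("expression.tsv", "detection_calls.tsv",
                         "sample_annotation.tsv", "external_clusters.gmt", "truth.json"):
                emit(name, outdir / name)
        else:
            expr = io.read_expression_tsv(config.expression_path)
            calls = io.read_detection_tsv(config.calls_path) if config.calls_path else None
            ann = io.read_annotation_tsv(config.annotation_path) if config.annotation_path else None
            clusters = io.read_gmt(config.clusters_path) if config.clusters_path else None

        stage = "preprocess"
        log.info("preprocess: %d genes x %d samples, detection threshold %.2f",
                 *expr.shape, config.detection_threshold)
        filtered = detection_filter(expr, calls, threshold=config.detection_threshold)
        centered = center_genes(filtered)
        top_n = min(config.top_n, centered.shape[0])
        if top_n < config.top_n:
            log.info("top_n clamped to the %d available genes", top_n)
        selected = l2_select(centered, top_n=top_n)

        stage = "batch_correct"
        if config.run_batch_adjust and ann is not None and ann["batch"].nunique() > 1:
            n_diag = min(config.diagnostic_genes, selected.shape[0])
            before = correlation_diagnostic(selected, n_genes=n_diag, seed=config.seed)
            adjusted = eb_batch_adjust(selected, ann)
            after = correlation_diagnostic(adjusted, n_genes=n_diag, seed=config.seed)
            diag = pd.DataFrame({"mean_corr_before": before.per_gene,
                                 "mean_corr_after": after.per_gene})
            diag.to_csv(outdir / "batch_diagnostic.tsv", sep="\t", index_label="gene_id")
            emit("batch_diagnostic.tsv", outdir / "batch_diagnostic.tsv")
            log.info("batch diagnostic grand mean correlation: %.4f -> %.4f",
                     before.mean, after.mean)
        else:
            adjusted = selected

        V_df = to_nonnegative(adjusted, mode=config.nonneg_mode)
        io.write_expression_tsv(V_df, outdir / "nmf_input.tsv")
        emit("nmf_input.tsv", outdir / "nmf_input.tsv")
        V = V_df.to_numpy()

        if config.k_values:
            stage = "scan_ranks"
            results = scan_ranks(V, config.k_values,
                                 runs_per_k=config.runs_per_k, seed=config.seed)
            prof = pd.DataFrame({"k": [r.k for r in results],
                                 "ccc": [r.ccc for r in results],
                                 "n_runs": [r.n_runs for r in results]})
            prof.to_csv(outdir / "ccc_profile.tsv", sep="\t", index=False)
            emit("ccc_profile.tsv", outdir / "ccc_profile.tsv")

        stage = "factorize"
        fact = factorize(V, config.k, seed=config.seed,
                         tol=config.tol, max_outer=config.max_outer)
        log.info("factorize: k=%d, %d outer iterations, objective %.6g",
                 config.k, fact.n_iter, fact.objective)

        stage = "extract"
        ms = order_and_extract(fact, delta=config.delta,
                               gene_ids=list(V_df.index), sample_ids=list(V_df.columns))
        table = pd.DataFrame(
            [(c + 1, g, coef, rank + 1)
             for c, genes in enumerate(ms.metagenes)
             for rank, (g, coef) in enumerate(genes)],
            columns=["metagene_index", "gene_id", "coefficient", "rank"],
        )
        table.to_csv(outdir / "metagenes.tsv", sep="\t", index=False, float_format="%.10g")
        emit("metagenes.tsv", outdir / "metagenes.tsv")
        exports = export_ranked_lists(ms, outdir / "gsea")
        emit("metagenes.gmt", exports["gmt"])

        stage = "activity"
        if ann is not None:
            groups = ann.loc[V_df.columns, "series"].to_numpy()
            act = activity_matrix(ms.H, groups)
            act.z.to_csv(outdir / "series_activity.tsv", sep="\t", index_label="metagene")
            emit("series_activity.tsv", outdir / "series_activity.tsv")

        stage = "network"
        net = build_network(ms.H, alpha=config.alpha, activity=ms.activity)
        io.write_network(net, outdir / "network.sif", outdir / "network_edges.tsv")
        emit("network.sif", outdir / "network.sif")
        emit("network_edges.tsv", outdir / "network_edges.tsv")

        if clusters:
            stage = "overlap"
            background = list(V_df.index)
            if config.background_n is not None and config.background_n < len(background):
                background = background[: config.background_n]
            ov = overlap_heatmap(ms.gene_sets(), clusters, background)
            ov.p.to_csv(outdir / "overlap_p.tsv", sep="\t", index_label="metagene")
            ov.log10_p.to_csv(outdir / "overlap_log10_p.tsv", sep="\t", index_label="metagene")
            emit("overlap_p.tsv", outdir / "overlap_p.tsv")
            emit("overlap_log10_p.tsv", outdir / "overlap_log10_p.tsv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    stage = "manifest"
    manifest = {
        "package": {"name": "metanmf", "version": __version__},
        "library_versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "config": asdict(config),
        "artifacts": {name: {"path": str(p), "sha256": _sha256(p)}
                      for name, p in artifacts.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    artifacts["manifest.json"] = outdir / "manifest.json"
    return {name: str(p) for name, p in artifacts.items()}
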