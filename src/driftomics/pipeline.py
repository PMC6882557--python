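"""End-to-end orchestration: data -> drift -> differential -> PCA and
clustering -> enrichment -> network module -> capture null.

A :class:`PipelineConfig` (constructible from a YAML file) names either
a synthetic-data configuration or paths to user tables, the contrasts
to test, and every analysis constant: the low-expression percentile for
drift (0.20), the CPM>1-in-half-the-samples expression filter, the
FDR<0.05 and |log2FC|>0.3 gene rule, the top-10% PCA gene subset, the
70% ellipse level, the module significance baseline p0 and the 10
identifier shuffles of the capture null. ``run_pipeline`` writes
per-stage TSV/JSON artefacts plus a machine-readable ``summary.json``
and is byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import differential, dimred, drift, enrichment, io, network, simulate

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "driftomics_out"
    seed: int = 0
    synthetic: bool = True
    synth: simulate.SynthConfig | None = None
    # user-data paths (used when synthetic=False)
    counts_path: str | None = None
    fpkm_path: str | None = None
    metabolite_path: str | None = None
    metadata_path: str | None = None
    network_path: str | None = None
    gmt_path: str | None = None
    # contrasts, (test, reference) group pairs
    contrasts: Sequence[tuple[str, str]] = (
        ("old", "young"),
        ("old+A", "old"),
        ("old+B", "old"),
    )
    reference_group: str = "young"
    old_group: str = "old"
    # analysis constants
    fdr_threshold: float = 0.05
    lfc_threshold: float = 0.3
    min_cpm: float = 1.0
    min_cpm_fraction: float = 0.5
    low_expression_percentile: float = 0.20
    drift_pseudocount: float = 5.0
    top_fraction: float = 0.10
    ellipse_level: float = 0.70
    kmeans_k: int = 6
    p0: float = 0.05
    missing_penalty: float = -0.1
    n_shuffles: int = 10
    query_metabolite: str = "acetyl-CoA"
    network_contrasts: Sequence[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        for name, value in [
            ("fdr_threshold", self.fdr_threshold),
            ("p0", self.p0),
            ("ellipse_level", self.ellipse_level),
        ]:
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be non-negative")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be positive")
        if self.synthetic and self.synth is None:
            self.synth = simulate.SynthConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synth", None)
        contrasts = raw.pop("contrasts", None)
        net_contrasts = raw.pop("network_contrasts", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synth = simulate.SynthConfig(**synth)
        if contrasts is not None:
            cfg.contrasts = [tuple(c) for c in contrasts]
        if net_contrasts is not None:
            cfg.network_contrasts = [tuple(c) for c in net_contrasts]
        return cfg


def _contrast_key(contrast: tuple[str, str]) -> str:
    return f"{contrast[0]}_vs_{contrast[1]}"


def _load_data(config: PipelineConfig) -> dict[str, Any]:
    if config.synthetic:
        assert config.synth is not None
        dataset = simulate.generate_dataset(config.synth)
        return {
            "metadata": dataset.metadata,
            "counts": dataset.counts,
            "fpkm": dataset.fpkm,
            "metabolites": dataset.metabolites,
            "network": dataset.network,
            "sets": dataset.metabolite_sets,
        }
    return io.load_tables(
        counts_path=config.counts_path,
        fpkm_path=config.fpkm_path,
        metabolite_path=config.metabolite_path,
        metadata_path=config.metadata_path,
        network_path=config.network_path,
        gmt_path=config.gmt_path,
    )


def _groups_present(metadata: pd.DataFrame, config: PipelineConfig) -> None:
    known = set(metadata["group"])
    for contrast in config.contrasts:
        for g in contrast:
            if g not in known:
                raise ValueError(f"contrast group {g!r} absent from metadata")


def _drift_stage(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PipelineConfig,
    transcriptome: bool,
) -> dict[str, Any]:
    opts = drift.DriftOptions(
        reference_group=config.reference_group,
        low_expression_percentile=(
            config.low_expression_percentile if transcriptome else 0.0
        ),
        pseudocount=config.drift_pseudocount if transcriptome else 0.0,
    )
    result = drift.compute_drift(matrix, metadata, opts)
    summary = drift.drift_variance(result)
    ordered = [g for g in dict.fromkeys(metadata["group"])]
    f_all, p_all = drift.brown_forsythe([summary.pooled[g] for g in ordered])
    out: dict[str, Any] = {
        "variance": {g: float(summary.variance[g]) for g in ordered},
        "brown_forsythe_all": {"F": f_all, "p": p_all},
    }
    if config.old_group in summary.pooled and config.reference_group in summary.pooled:
        f_ov, p_ov = drift.brown_forsythe(
            [summary.pooled[config.reference_group], summary.pooled[config.old_group]]
        )
        out["brown_forsythe_old_vs_young"] = {"F": f_ov, "p": p_ov}
    out["_result"] = result
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write artefacts under ``config.outdir``.

    Returns the summary dictionary also written to ``summary.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = _load_data(config)
    metadata = data["metadata"]
    _groups_present(metadata, config)
    summary: dict[str, Any] = {
        "seed": config.seed,
        "parameters": {
            "fdr_threshold": config.fdr_threshold,
            "lfc_threshold": config.lfc_threshold,
            "min_cpm": config.min_cpm,
            "low_expression_percentile": config.low_expression_percentile,
            "top_fraction": config.top_fraction,
            "ellipse_level": config.ellipse_level,
            "p0": config.p0,
            "n_shuffles": config.n_shuffles,
        },
    }

    # -- drift ---------------------------------------------------------
    logger.info("stage: drift")
    if "fpkm" in data:
        tdrift = _drift_stage(data["fpkm"], metadata, config, transcriptome=True)
        io.write_matrix(tdrift.pop("_result").drift, outdir / "drift_transcriptome.tsv")
        summary["drift_transcriptome"] = tdrift
    if "metabolites" in data:
        imputed = differential.impute_min(data["metabolites"])
        mdrift = _drift_stage(imputed, metadata, config, transcriptome=False)
        io.write_matrix(mdrift.pop("_result").drift, outdir / "drift_metabolome.tsv")
        summary["drift_metabolome"] = mdrift

    # -- differential --------------------------------------------------
    logger.info("stage: differential")
    gene_results: dict[str, pd.DataFrame] = {}
    if "counts" in data:
        filtered = differential.filter_expressed(
            data["counts"], config.min_cpm, config.min_cpm_fraction
        )
        factors = differential.tmm_factors(filtered)
        for contrast in config.contrasts:
            res = differential.de_genes(
                filtered,
                factors,
                metadata,
                tuple(contrast),
                fdr_threshold=config.fdr_threshold,
                lfc_threshold=config.lfc_threshold,
            )
            key = _contrast_key(tuple(contrast))
            gene_results[key] = res
            res.to_csv(outdir / f"de_genes_{key}.tsv", sep="\t")
        summary["de_gene_counts"] = {
            key: int(res["significant"].sum()) for key, res in gene_results.items()
        }
    met_results: dict[str, pd.DataFrame] = {}
    if "metabolites" in data:
        imputed = differential.impute_min(data["metabolites"])
        for contrast in config.contrasts:
            res = differential.de_metabolites(
                imputed, metadata, tuple(contrast), fdr_threshold=config.fdr_threshold
            )
            key = _contrast_key(tuple(contrast))
            met_results[key] = res
            res.to_csv(outdir / f"de_metabolites_{key}.tsv", sep="\t")
        summary["de_metabolite_counts"] = {
            key: int(res["significant"].sum()) for key, res in met_results.items()
        }

    # -- signature comparisons (aging vs each treatment contrast) ------
    def _comparisons(results: dict[str, pd.DataFrame]) -> dict[str, Any]:
        keys = list(results)
        out = {}
        for other in keys[1:]:
            comp = differential.compare_signatures(results[keys[0]], results[other])
            out[f"{keys[0]}__vs__{other}"] = {
                "shared": len(comp.shared),
                "unique_to_a": len(comp.unique_to_a),
                "unique_to_b": len(comp.unique_to_b),
                "r_shared": comp.r_shared,
                "r_unique_a": comp.r_unique_a,
                "r_unique_b": comp.r_unique_b,
            }
        return out

    if len(gene_results) >= 2:
        summary["gene_signature_comparisons"] = _comparisons(gene_results)
    if len(met_results) >= 2:
        summary["metabolite_signature_comparisons"] = _comparisons(met_results)

    # -- PCA and clustering --------------------------------------------
    logger.info("stage: dimension reduction")
    if "fpkm" in data:
        top, cutoff = dimred.select_top_expressed(data["fpkm"], config.top_fraction)
        pca_res = dimred.pca(np.log2(top + 5.0))
        dimred.group_ellipses(pca_res, metadata, level=config.ellipse_level)
        pca_res.scores.to_csv(outdir / "pca_scores_transcriptome.tsv", sep="\t")
        summary["pca_transcriptome"] = {
            "cutoff": float(cutoff),
            "n_genes": int(top.shape[0]),
            "explained_variance_fraction": [
                float(v) for v in pca_res.explained_variance_fraction[:2]
            ],
            "ellipses": {
                g: {
                    "center": [float(c) for c in e.center],
                    "radius": e.radius,
                    "level": e.level,
                }
                for g, e in pca_res.ellipses.items()
            },
        }
        expressed = data["fpkm"].loc[(data["fpkm"] > 0).any(axis=1)]
        z = dimred.zscore_rows(np.log2(expressed + 5.0))
        k = min(config.kmeans_k, max(2, z.shape[0]))
        labels = dimred.kmeans_clusters(z, k=k, seed=config.seed)
        labels.to_csv(outdir / "kmeans_clusters.tsv", sep="\t")
        summary["kmeans"] = {
            "k": int(k),
            "aging_up_cluster": dimred.aging_up_cluster(
                z, labels, metadata, config.old_group, config.reference_group
            ),
            "cluster_sizes": {
                str(int(label)): int((labels == label).sum())
                for label in sorted(labels.unique())
            },
        }
    if "metabolites" in data:
        imputed = differential.impute_min(data["metabolites"])
        glog = differential.glog_transform(imputed)
        pca_met = dimred.pca(glog)
        dimred.group_ellipses(pca_met, metadata, level=config.ellipse_level)
        pca_met.scores.to_csv(outdir / "pca_scores_metabolome.tsv", sep="\t")
        summary["pca_metabolome"] = {
            "explained_variance_fraction": [
                float(v) for v in pca_met.explained_variance_fraction[:2]
            ]
        }

    # -- metabolite-set enrichment -------------------------------------
    if "sets" in data and met_results:
        logger.info("stage: enrichment")
        aging_key = _contrast_key(tuple(config.contrasts[0]))
        res = met_results[aging_key]
        significant = set(res.index[res["significant"]])
        if significant:
            records = enrichment.metabolite_set_enrichment(
                significant, set(res.index), data["sets"]
            )
            pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False
            )
            summary["enrichment"] = [
                {"set": r.set_name, "score": r.score, "p": r.p, "k": r.k, "m": r.m}
                for r in records[:10]
            ]

    # -- network module and capture null -------------------------------
    if "network" in data and (met_results or gene_results):
        logger.info("stage: network")
        net = data["network"]
        net_contrasts = [
            tuple(c) for c in (config.network_contrasts or [config.contrasts[0]])
        ]
        experiments = {}
        captures = 0
        pnulls = []
        for contrast in net_contrasts:
            key = _contrast_key(contrast)
            mstats = met_results.get(key)
            gstats = gene_results.get(key)
            scored = network.score_network(
                net, mstats, gstats, p0=config.p0, missing_penalty=config.missing_penalty
            )
            module = network.find_module(
                scored, query=config.query_metabolite, seed=config.seed
            )
            null = network.random_sampling_null(
                net,
                mstats,
                gstats,
                query=config.query_metabolite,
                n_shuffles=config.n_shuffles,
                seed=config.seed,
                p0=config.p0,
                missing_penalty=config.missing_penalty,
            )
            captured = bool(module.contains.get(config.query_metabolite, False))
            captures += captured
            pnulls.append(null.pnull)
            experiments[key] = {
                "module_nodes": sorted(module.nodes),
                "module_score": module.total_score,
                "query_captured": captured,
                "pnull": null.pnull,
                "capture_flags": list(null.capture_flags),
            }
            pd.Series(sorted(module.nodes)).to_csv(
                outdir / f"module_nodes_{key}.tsv", sep="\t", index=False, header=False
            )
        na = captures
        nb = len(net_contrasts) - captures
        pnull = max(pnulls)  # conservative across experiments
        summary["network"] = {
            "query": config.query_metabolite,
            "experiments": experiments,
            "na": na,
            "nb": nb,
            "pnull": pnull,
            "random_sampling_p": network.aggregate_capture_p(pnull, na, nb),
        }

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    return summary
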