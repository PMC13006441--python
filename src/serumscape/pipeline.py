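"""Orchestrate the analysis stages into one reproducible run.

Stage order is fixed: qc -> dedup -> diff -> mvar -> profile -> network ->
xplat.  Every output directory carries a summary JSON with the config hash
and seed; a rerun with the same config and seed reproduces the summary.
The top-level seed fans out to per-stage child seeds by stable hashing of
the stage name, so toggling one stage never shifts another's randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from serumscape import dedup, diff, io, multivariate, network, profiling, qc, synth, xplat
from serumscape.types import IntensityMatrix, annotation_frame, metadata_frame

logger = logging.getLogger(__name__)

STAGES = ("qc", "dedup", "diff", "mvar", "profile", "network", "xplat")


@dataclass
class RunConfig:
    intensity_path: Optional[str] = None
    annotation_path: Optional[str] = None
    metadata_path: Optional[str] = None
    covariates: Sequence[str] = ("sex", "age", "bmi", "fasting")
    alpha: float = 0.05
    q_alpha: float = 0.05
    z_cut: float = 1.8
    r_cut: float = 0.3
    consensus: float = 0.8
    max_missing: float = 0.5
    qc_alpha: float = 0.1
    variance_target: float = 0.9
    permutations: int = 999
    seed: int = 0
    stages: Sequence[str] = STAGES
    synthetic: Optional[synth.GeneratorConfig] = None

    def __post_init__(self) -> None:
        for name in ("alpha", "q_alpha", "r_cut", "consensus", "max_missing",
                     "qc_alpha", "variance_target"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2 ** 31)


def config_hash(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    payload["stages"] = list(payload["stages"])
    payload["covariates"] = list(payload["covariates"])
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        cfg = dataclasses.replace(config.synthetic, seed=stage_seed(config.seed, "synth"))
        matrix, annotations, metadata, truth = synth.generate_dataset(cfg)
        return matrix, annotations, metadata
    if not (config.intensity_path and config.annotation_path and config.metadata_path):
        raise ValueError("need either synthetic config or all three input paths")
    matrix = io.load_intensity_matrix(config.intensity_path)
    annotations = io.load_annotations(config.annotation_path)
    metadata = io.load_sample_metadata(config.metadata_path)
    return matrix, annotations, metadata


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the enabled stages in fixed order and write all artifacts.

    Returns the machine-readable summary (also written as summary.json).
    Any stage failure aborts with the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, annotations, metadata = _load_inputs(config)
    md = metadata_frame(metadata)
    summary: dict = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_samples": matrix.shape[0],
        "n_aptamers": matrix.shape[1],
    }
    enabled = set(config.stages)
    stage = "input"
    try:
        if "qc" in enabled:
            stage = "qc"
            report = qc.detect_sample_outliers(
                matrix, alpha=config.qc_alpha, variance_target=config.variance_target)
            matrix = qc.remove_samples(matrix, report.flagged)
            md = md.loc[matrix.values.index]
            matrix, impute_report = qc.mask_and_impute_leverage_points(
                matrix, z_cut=config.z_cut)
            pd.DataFrame({"d2": report.d2, "p": report.p}).to_csv(
                outdir / "qc_samples.tsv", sep="\t", index_label="sample_id")
            io.write_results_table(
                pd.DataFrame(impute_report.imputation_log,
                             columns=["sample_id", "aptamer_id", "old", "new", "side"]),
                outdir / "qc_cells.tsv")
            summary["qc"] = {
                "flagged_samples": list(map(str, report.flagged)),
                "n_components": report.n_components,
                "n_imputed_cells": len(impute_report.imputation_log),
            }

        stage = "diff"
        results = diff.differential_abundance(
            matrix, md, covariates=config.covariates, classifier_metrics=False)
        results.to_csv(outdir / "diff.tsv", sep="\t")
        summary["diff"] = {
            "n_affected_p": int((results["p"] < config.alpha).sum()),
            "n_affected_q": int((results["q"] < config.q_alpha).sum()),
        }

        if "dedup" in enabled:
            stage = "dedup"
            pairs = dedup.correlate_aptamer_pairs(matrix, annotations)
            consensus = dedup.assess_directional_consensus(
                results, annotations, threshold=config.consensus)
            records = dedup.resolve_duplicates(results, consensus, annotations,
                                               alpha=config.alpha)
            io.write_results_table(pairs, outdir / "dedup_pairs.tsv")
            dedup.protein_records_frame(records).to_csv(
                outdir / "dedup_proteins.tsv", sep="\t")
            summary["dedup"] = {
                "n_proteins": len(records),
                "n_mixed": sum(r.mixed for r in records),
                "n_affected_proteins": sum(r.p < config.alpha for r in records),
            }

        if "mvar" in enabled:
            stage = "mvar"
            k = min(5, matrix.shape[0] - 1, matrix.shape[1])
            pca = multivariate.pca_project(matrix, k=k)
            perm = multivariate.permanova(
                matrix, md["group"].to_numpy(),
                permutations=config.permutations,
                seed=stage_seed(config.seed, "mvar"))
            env = multivariate.envfit_covariates(
                pca, md, permutations=config.permutations,
                seed=stage_seed(config.seed, "envfit"),
                covariates=[c for c in config.covariates])
            pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t",
                              index_label="sample_id")
            env.table.to_csv(outdir / "envfit.tsv", sep="\t")
            summary["mvar"] = {
                "permanova_f": perm.f, "permanova_r2": perm.r2, "permanova_p": perm.p,
                "explained": [float(v) for v in pca.explained],
            }

        if "profile" in enabled:
            stage = "profile"
            class_of = profiling.classify_subcellular(annotations)
            profiles = profiling.class_shift_profile(
                results, class_of, alpha=config.alpha, q_alpha=config.q_alpha)
            panels = profiling.panel_memberships(annotations)
            panel_summaries = [
                profiling.summarize_panel_proportions(
                    results, ids, panel_name=name, alpha=config.alpha,
                    q_alpha=config.q_alpha)
                for name, ids in sorted(panels.items())
            ]
            io.write_results_table(profiles + panel_summaries, outdir / "profiles.tsv")
            summary["profile"] = {
                s.panel: {"n_total": s.n_total, "n_affected": s.n_affected,
                          "pct_affected": s.pct_affected,
                          "hl_shift": s.hl_shift}
                for s in profiles
            }

        if "network" in enabled:
            stage = "network"
            clinical = {"ME": (md["group"] == "ME").astype(float).to_numpy()}
            if md["sf36pf"].notna().sum() >= 10:
                clinical["SF36PF"] = md["sf36pf"].astype(float).to_numpy()
            cov_design = diff.build_design(md, config.covariates).drop(
                columns=["intercept", "group"])
            edges = network.correlate_aptamers_to_clinical(
                matrix, md, clinical, covariates=cov_design,
                r_cut=config.r_cut, alpha=config.alpha)
            _, communities, venn = network.build_association_network(edges)
            io.write_results_table(edges, outdir / "network_edges.tsv")
            io.write_results_table(communities, outdir / "network_communities.tsv")
            summary["network"] = {
                "n_edges": len(edges),
                "venn": {",".join(k): v for k, v in venn.items()},
            }

        if "xplat" in enabled:
            stage = "xplat"
            gene_of = {a.aptamer_id: a.gene_symbol for a in annotations if a.gene_symbol}
            proteins = sorted(set(gene_of.values()))[: min(60, len(set(gene_of.values())))]
            mapping = {g: f"LX_{g}" for g in proteins}
            syn_cfg = config.synthetic or synth.GeneratorConfig()
            replicate, flipped = synth.generate_cross_platform_replicate(
                matrix, mapping, syn_cfg, annotations=annotations,
                seed=stage_seed(config.seed, "xplat"))
            immuno_diff = diff.differential_abundance(
                replicate, md, covariates=config.covariates)
            records = xplat.classify_concordance(
                results, immuno_diff, gene_of,
                {v: k for k, v in mapping.items()})
            counts = pd.Series([r.concordance for r in records]).value_counts()
            io.write_results_table(
                pd.DataFrame([{"protein": r.protein, "class": r.concordance,
                               "immuno_sign": r.immunoassay_sign} for r in records]),
                outdir / "xplat_concordance.tsv")
            summary["xplat"] = {
                "n_shared": len(records),
                "classes": {k: int(v) for k, v in counts.items()},
                "n_flipped": len(flipped),
            }
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
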