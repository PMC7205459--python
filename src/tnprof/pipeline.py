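"""End-to-end pipeline: inputs (real or simulated) to profiling outputs.

One :class:`RunConfig` drives every stage — fitness scoring, phenotype
classification, clustering — and the run directory records the full
configuration, a config hash and the package version, so a run can be
reproduced byte-for-byte from its own metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import io as tnio
from .containers import ConditionManifest, FitnessMatrix, GeneAnnotation
from .fitness import (
    GeneIndex,
    compute_condition_fitness,
    filter_sites,
    gene_read_proportions,
    pool_replicates,
)
from .profiling import (
    build_matrix,
    classify_phenotypes,
    cluster_profiles,
    render_heatmap,
)
from .simulate import SimulationConfig, simulate_experiment, write_experiment

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_pipeline"]

log = logging.getLogger("tnprof")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class RunConfig:
    """Parameters of one profiling run.

    Either ``annotation`` + ``manifest`` point at existing inputs, or a
    ``simulate`` block (:class:`~tnprof.simulate.SimulationConfig` fields)
    generates them under the output directory first. Threshold defaults are
    the standard phenotype boundaries (strong outside [0.75, 1.25], moderate
    outside [0.9, 1.1]); ``generations`` defaults to the span the manifest
    declares between t1 and t2 sampling.
    """

    outdir: str = "tnprof_run"
    annotation: str | None = None
    manifest: str | None = None
    simulate: dict[str, Any] | None = None
    seed: int | None = None
    min_reads: int = 2
    generations: int | None = None
    denominator: str = "all"
    pseudocount: float = 0.5
    metric: str = "euclidean"
    linkage: str = "complete"
    strong_low: float = 0.75
    moderate_low: float = 0.9
    moderate_high: float = 1.1
    strong_high: float = 1.25
    heatmap: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(config: RunConfig) -> list[str]:
    """Return every violated invariant; an empty list means the config is valid."""
    problems: list[str] = []
    if config.min_reads < 1:
        problems.append(f"min_reads must be >= 1 (got {config.min_reads})")
    if config.generations is not None and config.generations < 1:
        problems.append(f"generations must be >= 1 (got {config.generations})")
    if config.pseudocount <= 0:
        problems.append("pseudocount must be positive")
    if config.denominator not in {"all", "genic"}:
        problems.append(f"unknown denominator mode {config.denominator!r}")
    if config.metric not in {"euclidean", "correlation"}:
        problems.append(f"unknown metric {config.metric!r}")
    if config.linkage not in {"complete", "average", "ward"}:
        problems.append(f"unknown linkage {config.linkage!r}")
    if not (0 < config.strong_low < config.moderate_low < 1 < config.moderate_high < config.strong_high):
        problems.append(
            "thresholds must satisfy 0 < strong_low < moderate_low < 1 "
            "< moderate_high < strong_high"
        )
    if config.simulate is None:
        if config.annotation is None or config.manifest is None:
            problems.append("need annotation and manifest paths (or a simulate block)")
        else:
            for name in ("annotation", "manifest"):
                p = getattr(config, name)
                if not Path(p).exists():
                    problems.append(f"{name} path does not exist: {p}")
    else:
        if config.seed is None and "seed" not in config.simulate:
            problems.append("simulation requires a seed")
    return problems


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapper
    return deco


@_stage("load_inputs")
def _load_inputs(config: RunConfig, outdir: Path) -> tuple[GeneAnnotation, ConditionManifest, Path]:
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim_config = SimulationConfig(**sim_kwargs)
        exp = simulate_experiment(sim_config)
        inputs = write_experiment(exp, outdir / "inputs")
        log.info(
            "simulate: %d genes (%d essential), %d sites, %d t1 replicates, %d conditions",
            len(exp.annotation), exp.annotation.n_essential, len(exp.library),
            len(exp.t1_tables), len(exp.t2_tables),
        )
        return exp.annotation, exp.manifest, inputs
    annotation = tnio.read_gff(config.annotation)
    manifest = tnio.read_manifest(config.manifest)
    return annotation, manifest, Path(config.manifest).parent


@_stage("fitness")
def _score_conditions(
    config: RunConfig,
    annotation: GeneAnnotation,
    manifest: ConditionManifest,
    input_dir: Path,
) -> FitnessMatrix:
    index = GeneIndex(annotation)
    generations = config.generations if config.generations is not None else manifest.generation_span()

    def load(row) -> "tnio.InsertionTable":
        return tnio.read_insertions(input_dir / row.file, sample_id=row.sample_id)

    t1_tables = [load(r) for r in manifest.t1_samples.itertuples(index=False)]
    t1_pooled = filter_sites(pool_replicates(t1_tables), config.min_reads)
    log.info(
        "t1 reference: %d replicates pooled, %d sites pass the >=%d-read filter (%d reads)",
        len(t1_tables), len(t1_pooled), config.min_reads, t1_pooled.total_reads,
    )
    t1_props = gene_read_proportions(t1_pooled, annotation, config.denominator, index=index)

    scores: dict[str, pd.DataFrame] = {}
    for condition in manifest.conditions:
        rows = manifest.t2_samples[manifest.t2_samples["condition"] == condition]
        pooled = pool_replicates([load(r) for r in rows.itertuples(index=False)])
        filtered = filter_sites(pooled, config.min_reads)
        props = gene_read_proportions(filtered, annotation, config.denominator, index=index)
        result = compute_condition_fitness(
            t1_props, props, generations=generations, pseudocount=config.pseudocount
        )
        n_pseudo = int((result["flag"] == "pseudocounted").sum())
        log.info(
            "condition %s: %d/%d sites pass filter, %d genes scored, %d pseudocounted",
            condition, len(filtered), len(pooled), int(result["W"].notna().sum()), n_pseudo,
        )
        scores[condition] = result
    return build_matrix(scores, condition_order=manifest.conditions)


@_stage("profile")
def _profile(config: RunConfig, matrix: FitnessMatrix, annotation: GeneAnnotation, outdir: Path) -> dict:
    calls, summary = classify_phenotypes(
        matrix,
        strong_bounds=(config.strong_low, config.strong_high),
        moderate_bounds=(config.moderate_low, config.moderate_high),
        annotation=annotation,
    )
    pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "category": [c.category for c in calls],
            "triggering_conditions": [";".join(c.triggering_conditions) for c in calls],
        }
    ).to_csv(outdir / "phenotype_calls.tsv", sep="\t", index=False)
    with open(outdir / "phenotype_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("phenotypes: %s", summary)
    return summary


@_stage("cluster")
def _cluster(config: RunConfig, matrix: FitnessMatrix, outdir: Path) -> None:
    if len(matrix.gene_ids) < 2:
        log.info("cluster: fewer than 2 genes, skipping")
        return
    result = cluster_profiles(matrix, metric=config.metric, method=config.linkage)
    (outdir / "cluster_tree.nwk").write_text(result.to_newick() + "\n", encoding="utf-8")
    pd.DataFrame({"gene_id": result.leaf_order}).to_csv(
        outdir / "leaf_order.tsv", sep="\t", index=False
    )
    if config.heatmap:
        render_heatmap(matrix, result, outdir / "heatmap.png")
    log.info("cluster: %d genes, metric=%s, linkage=%s", len(matrix.gene_ids), config.metric, config.linkage)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the output directory.

    Outputs: ``fitness_matrix.tsv``, ``phenotype_calls.tsv``,
    ``phenotype_summary.json``, ``cluster_tree.nwk``, ``leaf_order.tsv``,
    ``heatmap.png`` (optional), ``run_metadata.json`` (config, config hash,
    version) and ``pipeline.log``. Reruns with an identical config are
    deterministic.
    """
    problems = validate_config(config)
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "pipeline.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("tnprof %s; config hash %s; seed %s", __version__, config.config_hash(), config.seed)
        annotation, manifest, input_dir = _load_inputs(config, outdir)
        matrix = _score_conditions(config, annotation, manifest, input_dir)
        tnio.write_matrix(matrix, outdir / "fitness_matrix.tsv")
        _profile(config, matrix, annotation, outdir)
        _cluster(config, matrix, outdir)
        with open(outdir / "run_metadata.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "package": "tnprof",
                    "version": __version__,
                    "config_hash": config.config_hash(),
                    "config": asdict(config),
                },
                fh, indent=2, sort_keys=True, default=str,
            )
            fh.write("\n")
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
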