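"""Synthetic transposon libraries and post-selection read counts.

The generator emulates the structure of a dense Tn5 mutant library in a
small bacterial genome: a few thousand non-overlapping genes on one contig,
~15% of them essential (and therefore carrying no recoverable insertions),
on the order of 200,000 unique insertion sites placed uniformly outside
essential genes, and sequencing samples taken before and after growth under
selective conditions.

Growth model
------------
Each unique insertion site is one clonal lineage. Over the selection window
separating the two sequencing timepoints the reference population doubles
``generations`` times; a lineage inserted in gene *g* with relative fitness
``w_g`` expands by ``2**(w_g * generations)`` (intergenic lineages are
neutral, ``w = 1``). A sequencing sample of ``depth`` reads is a single
multinomial draw over the expanded lineage masses — sequencing noise is
purely multinomial, with no PCR or mapping artefacts. Essential genes are
modelled as having no insertion sites at all, which is how a saturated
library presents them to the analysis.

Every operation is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ConditionManifest,
    FitnessMatrix,
    GeneAnnotation,
    InsertionTable,
    make_fitness_matrix,
)
from .fitness import GeneIndex
from . import io as tnio

__all__ = [
    "SimulationConfig",
    "SimulatedExperiment",
    "simulate_genome",
    "simulate_library",
    "simulate_selection",
    "expected_site_proportions",
    "simulate_experiment",
    "simulate_pathway_profiles",
    "write_experiment",
]

MIN_GENE_LENGTH = 90  # bases; keeps degenerate tiny genes out of toy genomes


def simulate_genome(
    n_genes: int,
    mean_gene_length: int = 1000,
    intergenic_fraction: float = 0.1,
    essential_fraction: float = 0.15,
    seed: int = 0,
    genome_length: int | None = None,
    contig: str = "chr",
) -> GeneAnnotation:
    """Lay out a toy single-contig genome of non-overlapping genes.

    Gene lengths are gamma-distributed around ``mean_gene_length`` (min 90
    bp, except when the mean itself is smaller); intergenic gaps are sized so
    that roughly ``intergenic_fraction`` of the genome is intergenic.
    ``ceil(essential_fraction * n_genes)`` genes, chosen at random, are
    flagged essential. If ``genome_length`` is given and the genes do not
    fit, a sizing error is raised; otherwise the contig length is derived
    from the layout.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0 <= intergenic_fraction < 1) or not (0 <= essential_fraction < 1):
        raise ValueError("fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    min_len = min(MIN_GENE_LENGTH, mean_gene_length)
    shape = 4.0
    lengths = np.maximum(
        min_len, np.rint(rng.gamma(shape, mean_gene_length / shape, n_genes))
    ).astype(np.int64)
    total_genic = int(lengths.sum())

    if genome_length is not None and total_genic > genome_length:
        raise ValueError(
            f"requested genes span {total_genic} bp but genome_length is {genome_length}"
        )
    if genome_length is not None:
        total_gap = genome_length - total_genic
    else:
        total_gap = int(round(total_genic * intergenic_fraction / (1.0 - intergenic_fraction)))
    # split the intergenic budget over n_genes + 1 gaps
    if total_gap > 0:
        splits = rng.dirichlet(np.ones(n_genes + 1))
        gaps = np.floor(splits * total_gap).astype(np.int64)
        gaps[-1] += total_gap - gaps.sum()
    else:
        gaps = np.zeros(n_genes + 1, dtype=np.int64)

    starts = np.empty(n_genes, dtype=np.int64)
    pos = 0
    for i in range(n_genes):
        pos += gaps[i]
        starts[i] = pos
        pos += lengths[i]
    length = int(pos + gaps[-1])

    n_ess = math.ceil(essential_fraction * n_genes)
    essential = np.zeros(n_genes, dtype=bool)
    if n_ess:
        essential[rng.choice(n_genes, size=n_ess, replace=False)] = True

    width = len(str(n_genes))
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:0{width}d}" for i in range(1, n_genes + 1)],
            "contig": contig,
            "start": starts,
            "end": starts + lengths,
            "strand": np.where(rng.random(n_genes) < 0.5, "+", "-"),
            "feature_type": "gene",
            "essential": essential,
            "excluded": False,
        }
    )
    return GeneAnnotation(genes=genes, contig_lengths={contig: length})


def simulate_library(
    annotation: GeneAnnotation,
    n_sites: int,
    seed: int = 0,
    abundance_mu: float = 0.0,
    abundance_sigma: float = 1.0,
    mass_scale: int = 100,
) -> InsertionTable:
    """Place unique insertion sites uniformly outside essential genes.

    Each site's founding abundance is a log-normal(``abundance_mu``,
    ``abundance_sigma``) mass, stored as an integer read-mass of at least 1
    (after scaling by ``mass_scale``) so the library table doubles as the
    lineage ledger for :func:`simulate_selection`. A Tn5 library shows no
    strong sequence preference, hence the uniform placement.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    contigs = annotation.contig_lengths
    if not contigs:
        raise ValueError("annotation declares no contig lengths")
    rng = np.random.default_rng(seed)

    frames = []
    # capacity check across all contigs first
    masks = {}
    for contig, length in sorted(contigs.items()):
        mask = np.ones(length, dtype=bool)
        ess = annotation.genes[
            (annotation.genes["contig"] == contig) & annotation.genes["essential"]
        ]
        for s, e in zip(ess["start"], ess["end"]):
            mask[s:e] = False
        masks[contig] = np.flatnonzero(mask) + 1  # to 1-based positions
    capacity = sum(len(v) for v in masks.values())
    if n_sites > capacity:
        raise ValueError(
            f"n_sites={n_sites} exceeds the {capacity} positions outside essential genes"
        )
    if n_sites == 0:
        return InsertionTable(
            sample_id="library",
            sites=pd.DataFrame({"contig": [], "position": [], "reads": []}),
        )

    # allocate sites to contigs proportionally to available positions
    names = sorted(masks)
    avail = np.array([len(masks[c]) for c in names], dtype=float)
    counts = rng.multinomial(n_sites, avail / avail.sum())
    while (counts > avail).any():  # redistribute overflow (tiny contigs)
        over = counts > avail
        excess = int((counts - avail)[over].sum())
        counts[over] = avail[over].astype(int)
        room = ~over
        counts[room] += rng.multinomial(excess, (avail[room] - counts[room]) / (avail[room] - counts[room]).sum())
    for contig, k in zip(names, counts):
        if k == 0:
            continue
        positions = np.sort(rng.choice(masks[contig], size=int(k), replace=False))
        mass = rng.lognormal(abundance_mu, abundance_sigma, int(k))
        reads = np.maximum(1, np.rint(mass * mass_scale)).astype(np.int64)
        frames.append(pd.DataFrame({"contig": contig, "position": positions, "reads": reads}))
    sites = pd.concat(frames, ignore_index=True)
    return InsertionTable(sample_id="library", sites=sites)


def _site_fitness(
    library: InsertionTable,
    annotation: GeneAnnotation,
    true_fitness: Mapping[str, float],
    intergenic_fitness: float = 1.0,
    index: GeneIndex | None = None,
) -> np.ndarray:
    idx = index if index is not None else GeneIndex(annotation)
    w = np.empty(len(library), dtype=float)
    for i, rec in enumerate(library.sites.itertuples(index=False)):
        gid = idx.gene_at(rec.contig, rec.position)
        if gid is None:
            w[i] = intergenic_fitness
        else:
            try:
                w[i] = true_fitness[gid]
            except KeyError:
                raise ValueError(
                    f"no fitness entry for gene {gid!r}, which carries insertion sites"
                ) from None
    if (w < 0).any() or not np.all(np.isfinite(w)):
        raise ValueError("fitness values must be finite and >= 0")
    return w


def expected_site_proportions(
    library: InsertionTable,
    annotation: GeneAnnotation,
    true_fitness: Mapping[str, float],
    generations: float,
    index: GeneIndex | None = None,
) -> pd.DataFrame:
    """Deterministic post-selection lineage proportions (no sampling).

    Returns the library sites with an extra ``prob`` column:
    ``m_i * d**w_i / sum_j m_j * d**w_j`` with ``d = 2**generations``.
    """
    w = _site_fitness(library, annotation, true_fitness, index=index)
    mass = library.sites["reads"].to_numpy(float) * np.exp2(generations * w)
    out = library.sites.copy()
    out["prob"] = mass / mass.sum()
    return out


def simulate_selection(
    library: InsertionTable,
    annotation: GeneAnnotation,
    true_fitness: Mapping[str, float],
    generations: float,
    depth: int,
    seed: int = 0,
    bottleneck: int | None = None,
    sample_id: str = "selected",
    index: GeneIndex | None = None,
) -> InsertionTable:
    """Grow the library under selection and sequence it.

    ``generations`` is the number of reference-population doublings between
    the two sampling points (0 means resequencing without growth). The
    returned table contains exactly ``depth`` reads distributed over the
    sites by a multinomial draw on the expanded lineage masses; sites
    receiving zero reads are dropped. ``bottleneck``, if given, first
    subsamples that many founding cells from the library (the experiment is
    normally designed to avoid one).
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if len(library) == 0:
        raise ValueError("cannot sequence an empty library")
    rng = np.random.default_rng(seed)

    w = _site_fitness(library, annotation, true_fitness, index=index)
    mass = library.sites["reads"].to_numpy(float)
    if bottleneck is not None:
        mass = rng.multinomial(bottleneck, mass / mass.sum()).astype(float)
        if mass.sum() == 0:
            raise ValueError("bottleneck left no founders")
    mass = mass * np.exp2(generations * w)
    counts = rng.multinomial(depth, mass / mass.sum())

    keep = counts > 0
    sites = library.sites.loc[keep, ["contig", "position"]].copy()
    sites["reads"] = counts[keep]
    return InsertionTable(sample_id=sample_id, sites=sites.reset_index(drop=True))


# ---------------------------------------------------------------------------
# whole-experiment simulation


@dataclass
class SimulationConfig:
    """Design of a synthetic profiling experiment.

    ``conditions`` maps each condition label to its fitness design: a
    ``default`` w applied to every gene plus optional ``classes`` — a map of
    w values to the fraction of non-essential genes assigned that w (genes
    drawn at random under the experiment seed). Alternatively
    ``true_fitness`` gives explicit per-gene w maps and wins over
    ``conditions``. The defaults mirror the target study's stated structure:
    input library sampled after 1 untreated generation, selected cultures
    after 11 generations, three input replicates.
    """

    seed: int
    n_genes: int = 500
    mean_gene_length: int = 900
    intergenic_fraction: float = 0.1
    essential_fraction: float = 0.15
    genome_length: int | None = None
    n_sites: int = 5000
    depth_t1: int = 200_000
    depth_t2: int = 200_000
    generations_t1: int = 1
    generations_t2: int = 11
    n_input_replicates: int = 3
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    bottleneck: int | None = None
    conditions: dict[str, dict] = field(default_factory=dict)
    true_fitness: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.depth_t1 < 1 or self.depth_t2 < 1:
            raise ValueError("sequencing depths must be positive")
        if self.generations_t2 <= self.generations_t1:
            raise ValueError("generations_t2 must exceed generations_t1")
        if self.n_input_replicates < 1:
            raise ValueError("need at least one input replicate")
        if not self.conditions and not self.true_fitness:
            raise ValueError("config defines no conditions")
        for label, spec in self.conditions.items():
            default = float(spec.get("default", 1.0))
            if default < 0:
                raise ValueError(f"condition {label!r}: default w must be >= 0")
            classes = spec.get("classes", {})
            if any(float(w) < 0 for w in classes):
                raise ValueError(f"condition {label!r}: w values must be >= 0")
            if sum(float(f) for f in classes.values()) > 1.0 + 1e-9:
                raise ValueError(f"condition {label!r}: class fractions exceed 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if "seed" not in data:
            raise ValueError("simulation config must set an explicit seed")
        return cls(**data)

    @property
    def selection_generations(self) -> int:
        """Reference-population doublings between the t1 and t2 samples."""
        return self.generations_t2 - self.generations_t1


@dataclass
class SimulatedExperiment:
    """Everything one synthetic profiling run produced."""

    config: SimulationConfig
    annotation: GeneAnnotation
    library: InsertionTable
    t1_tables: list[InsertionTable]
    t2_tables: dict[str, InsertionTable]
    truth: pd.DataFrame  # columns: gene_id, condition, w
    manifest: ConditionManifest


def _design_fitness(
    config: SimulationConfig, annotation: GeneAnnotation, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    if config.true_fitness is not None:
        return {c: dict(m) for c, m in config.true_fitness.items()}
    genes = annotation.genes
    assignable = genes.loc[~genes["essential"], "gene_id"].to_numpy()
    designs: dict[str, dict[str, float]] = {}
    for label in config.conditions:
        spec = config.conditions[label]
        default = float(spec.get("default", 1.0))
        fitness = {gid: default for gid in genes["gene_id"]}
        classes = spec.get("classes", {})
        if classes:
            order = rng.permutation(assignable)
            cursor = 0
            for w, frac in classes.items():
                k = int(round(float(frac) * len(assignable)))
                for gid in order[cursor : cursor + k]:
                    fitness[gid] = float(w)
                cursor += k
        designs[label] = fitness
    return designs


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Run the full generative model: genome, library, t1 replicates, t2 samples.

    The input-library replicates are multinomial resequencings of the
    library (the single untreated generation before t1 sampling leaves
    proportions unchanged, so it needs no explicit growth step). Each
    condition's t2 sample applies selection over
    ``generations_t2 - generations_t1`` doublings — the expansion window the
    fitness score normalises by.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(
        4 + config.n_input_replicates + max(len(config.conditions), len(config.true_fitness or {})),
        dtype=np.uint32,
    ) % (2**31)
    annotation = simulate_genome(
        n_genes=config.n_genes,
        mean_gene_length=config.mean_gene_length,
        intergenic_fraction=config.intergenic_fraction,
        essential_fraction=config.essential_fraction,
        seed=int(seeds[0]),
        genome_length=config.genome_length,
    )
    library = simulate_library(
        annotation,
        config.n_sites,
        seed=int(seeds[1]),
        abundance_mu=config.abundance_mu,
        abundance_sigma=config.abundance_sigma,
    )
    index = GeneIndex(annotation)
    designs = _design_fitness(
        config, annotation, np.random.default_rng(int(seeds[2]))
    )

    neutral = {gid: 1.0 for gid in annotation.gene_ids}
    t1_tables = []
    for i in range(config.n_input_replicates):
        name = f"input_{chr(ord('A') + i)}" if i < 26 else f"input_{i}"
        t1_tables.append(
            simulate_selection(
                library, annotation, neutral,
                generations=0, depth=config.depth_t1,
                seed=int(seeds[3 + i]), bottleneck=config.bottleneck,
                sample_id=name, index=index,
            )
        )

    t2_tables: dict[str, InsertionTable] = {}
    truth_rows = []
    scorable = set(annotation.scorable_gene_ids())
    for j, (label, fitness) in enumerate(designs.items()):
        t2_tables[label] = simulate_selection(
            library, annotation, fitness,
            generations=config.selection_generations, depth=config.depth_t2,
            seed=int(seeds[3 + config.n_input_replicates + j]),
            bottleneck=config.bottleneck, sample_id=label, index=index,
        )
        truth_rows.extend(
            {"gene_id": gid, "condition": label, "w": w}
            for gid, w in fitness.items()
            if gid in scorable
        )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "condition", "w"])

    rows = [
        {
            "sample_id": t.sample_id,
            "condition": "input",
            "timepoint": "t1",
            "generations": config.generations_t1,
            "replicate": i + 1,
            "file": f"{t.sample_id}.tsv",
        }
        for i, t in enumerate(t1_tables)
    ] + [
        {
            "sample_id": label,
            "condition": label,
            "timepoint": "t2",
            "generations": config.generations_t2,
            "replicate": 1,
            "file": f"{label}.tsv",
        }
        for label in t2_tables
    ]
    manifest = ConditionManifest(rows=pd.DataFrame(rows))
    return SimulatedExperiment(
        config=config,
        annotation=annotation,
        library=library,
        t1_tables=t1_tables,
        t2_tables=t2_tables,
        truth=truth,
        manifest=manifest,
    )


def write_experiment(experiment: SimulatedExperiment, outdir: str | Path) -> Path:
    """Serialise a simulated experiment: GFF3, per-sample TSVs, manifest, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tnio.write_gff(experiment.annotation, outdir / "annotation.gff3")
    tnio.write_insertions(experiment.library, outdir / "library.tsv")
    for t in experiment.t1_tables:
        tnio.write_insertions(t, outdir / f"{t.sample_id}.tsv")
    for label, t in experiment.t2_tables.items():
        tnio.write_insertions(t, outdir / f"{label}.tsv")
    tnio.write_manifest(experiment.manifest, outdir / "manifest.tsv")
    experiment.truth.to_csv(outdir / "true_fitness.tsv", sep="\t", index=False)
    return outdir


def simulate_pathway_profiles(
    n_groups: int = 3,
    genes_per_group: int = 5,
    n_conditions: int = 10,
    noise_sd: float = 0.03,
    n_background: int = 5,
    response_sd: float = 0.25,
    seed: int = 0,
) -> tuple[FitnessMatrix, dict[str, str]]:
    """Fitness fingerprints with planted co-functional ("pathway") structure.

    Each group shares one condition-response vector (fitness 1 plus
    Gaussian condition effects of scale ``response_sd``); member profiles
    are that vector plus i.i.d. N(0, ``noise_sd``) measurement noise.
    Background genes respond to nothing. Returns the matrix and a
    gene -> group-label map (background genes map to ``"background"``).
    """
    rng = np.random.default_rng(seed)
    conditions = [f"cond{j + 1:02d}" for j in range(n_conditions)]
    rows, labels = {}, {}
    for g in range(n_groups):
        group = f"group{g + 1}"
        response = 1.0 + rng.normal(0.0, response_sd, n_conditions)
        for k in range(genes_per_group):
            gid = f"{group}_gene{k + 1}"
            rows[gid] = response + rng.normal(0.0, noise_sd, n_conditions)
            labels[gid] = group
    for k in range(n_background):
        gid = f"bg_gene{k + 1}"
        rows[gid] = 1.0 + rng.normal(0.0, noise_sd, n_conditions)
        labels[gid] = "background"
    values = pd.DataFrame.from_dict(rows, orient="index", columns=conditions)
    return make_fitness_matrix(values), labels
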