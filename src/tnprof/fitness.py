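"""Per-gene conditional fitness from insertion-site read counts.

The fitness score for a gene compares its share of mapped transposon reads
before (``N_t1``) and after (``N_t2``) growth, normalised by the fold
expansion ``d = 2**generations`` of the whole population between the two
sampling points::

    W = ln(N_t2 * d / N_t1) / ln((1 - N_t2) * d / (1 - N_t1))

W = 1 is neutral (the gene's mutants kept pace with the population), W < 1 a
fitness defect, W > 1 an advantage, and W = 0 a lineage that did not divide
at all while the population expanded d-fold. The default ``generations=10``
corresponds to sampling the input library after one generation and the
selected culture after eleven.

Processing order mirrors the experimental pipeline: replicate read counts
are pooled site-wise, sites with fewer than ``min_reads`` reads are dropped,
per-gene read proportions are computed against the genome-wide filtered
total, and the score above is evaluated per gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import (
    FLAG_NO_DATA,
    FLAG_OK,
    FLAG_PSEUDOCOUNTED,
    GeneAnnotation,
    InsertionTable,
)

__all__ = [
    "GeneProportions",
    "filter_sites",
    "pool_replicates",
    "gene_read_proportions",
    "fitness_score",
    "compute_condition_fitness",
    "GeneIndex",
]

DenominatorMode = Literal["all", "genic"]


class GeneIndex:
    """Interval lookup from insertion position to gene_id, per contig.

    Built over non-excluded genes. A position falling in several overlapping
    genes is credited to each of them for read aggregation; for single-gene
    lookups the lexicographically first gene_id wins (deterministic).
    """

    def __init__(self, annotation: GeneAnnotation):
        self._trees: dict[str, IntervalTree] = {}
        genes = annotation.genes[~annotation.genes["excluded"]]
        for contig, sub in genes.groupby("contig", sort=False):
            self._trees[contig] = IntervalTree.from_tuples(
                (s, e, gid) for s, e, gid in zip(sub["start"], sub["end"], sub["gene_id"])
            )

    def genes_at(self, contig: str, position: int) -> list[str]:
        """All gene_ids covering a 1-based position."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(position - 1))

    def gene_at(self, contig: str, position: int) -> str | None:
        hits = self.genes_at(contig, position)
        return hits[0] if hits else None


def filter_sites(table: InsertionTable, min_reads: int = 2) -> InsertionTable:
    """Keep only unique insertion sites with at least ``min_reads`` reads.

    Order of surviving entries is preserved.
    """
    if min_reads < 1:
        raise ValueError(f"min_reads must be >= 1, got {min_reads}")
    kept = table.sites[table.sites["reads"] >= min_reads].reset_index(drop=True)
    return InsertionTable(sample_id=table.sample_id, sites=kept)


def pool_replicates(tables: Sequence[InsertionTable]) -> InsertionTable:
    """Sum read counts site-wise across replicate tables (union of positions).

    Pooling precedes filtering and proportion computation, so a site seen
    once in each of three replicates carries three reads into the filter.
    """
    if not tables:
        raise ValueError("pool_replicates requires at least one table")
    if len(tables) == 1:
        t = tables[0]
        return InsertionTable(sample_id=t.sample_id, sites=t.sites.copy())
    merged = (
        pd.concat([t.sites for t in tables], ignore_index=True)
        .groupby(["contig", "position"], as_index=False, sort=True)["reads"]
        .sum()
    )
    sample_id = "pooled(" + "+".join(t.sample_id for t in tables) + ")"
    return InsertionTable(sample_id=sample_id, sites=merged)


@dataclass
class GeneProportions:
    """Per-gene read proportions for one (filtered) sample.

    ``table`` is indexed by gene_id with columns ``reads`` (filtered reads in
    the gene), ``site_count`` (filtered sites in the gene), ``N`` (the gene's
    fraction of the denominator), ``essential``. Excluded-class features
    (tRNA/rRNA/transposon) have no row. ``N == 0`` exactly when the gene has
    no filtered reads.
    """

    sample_id: str
    table: pd.DataFrame
    total_filtered_reads: int
    denominator: DenominatorMode = "all"

    @property
    def denominator_reads(self) -> int:
        if self.denominator == "genic":
            return int(self.table["reads"].sum())
        return self.total_filtered_reads


def gene_read_proportions(
    table: InsertionTable,
    annotation: GeneAnnotation,
    denominator: DenominatorMode = "all",
    index: GeneIndex | None = None,
) -> GeneProportions:
    """Aggregate filtered reads per gene and normalise to proportions.

    ``denominator="all"`` (default) divides by every filtered read in the
    sample, intergenic reads included — a gene's N is its share of *total*
    transposon reads. ``"genic"`` divides by reads falling inside
    non-excluded genes only.
    """
    if table.total_reads == 0:
        raise ValueError(f"sample {table.sample_id!r}: no filtered reads (empty denominator)")
    idx = index if index is not None else GeneIndex(annotation)
    genes = annotation.genes[~annotation.genes["excluded"]]
    reads = dict.fromkeys(genes["gene_id"], 0)
    site_counts = dict.fromkeys(genes["gene_id"], 0)
    for rec in table.sites.itertuples(index=False):
        for gid in idx.genes_at(rec.contig, rec.position):
            reads[gid] += rec.reads
            site_counts[gid] += 1
    out = pd.DataFrame(
        {
            "reads": pd.Series(reads, dtype=np.int64),
            "site_count": pd.Series(site_counts, dtype=np.int64),
            "essential": genes.set_index("gene_id")["essential"],
        }
    )
    out.index.name = "gene_id"
    total = table.total_reads
    denom = int(out["reads"].sum()) if denominator == "genic" else total
    if denom == 0:
        raise ValueError(f"sample {table.sample_id!r}: denominator is zero")
    out["N"] = out["reads"] / denom
    props = GeneProportions(
        sample_id=table.sample_id,
        table=out,
        total_filtered_reads=total,
        denominator=denominator,
    )
    return props


def fitness_score(n_t1: float, n_t2: float, generations: int = 10) -> float:
    """Evaluate the fitness equation for one gene.

    Parameters
    ----------
    n_t1, n_t2
        The gene's proportion of total filtered reads in the input library
        and the selected sample. ``0 < n_t1 < 1`` and ``0 < n_t2 < 1``:
        a gene absent from the input has no score (no_data), and a true zero
        at t2 is pseudocounted upstream before this function is reached.
    generations
        Doublings of the population between the two sampling points.

    Returns
    -------
    float
        ``W = ln(n_t2*d/n_t1) / ln((1-n_t2)*d/(1-n_t1))`` with
        ``d = 2**generations``. Equal proportions give exactly 1.
    """
    if generations < 1:
        raise ValueError(f"generations must be >= 1, got {generations}")
    if not (0.0 < n_t1 < 1.0):
        raise ValueError(f"n_t1 must lie in (0, 1), got {n_t1}")
    if not (0.0 < n_t2 < 1.0):
        raise ValueError(f"n_t2 must lie in (0, 1), got {n_t2}")
    d = 2.0 ** generations
    return math.log(n_t2 * d / n_t1) / math.log((1.0 - n_t2) * d / (1.0 - n_t1))


def compute_condition_fitness(
    t1: GeneProportions,
    t2: GeneProportions,
    generations: int = 10,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Score every non-essential gene for one condition.

    Returns a DataFrame indexed by gene_id with columns ``W`` and ``flag``:

    - ``ok``: gene observed at both timepoints;
    - ``pseudocounted``: gene present at t1 but extinct at t2 — its t2
      proportion is floored at ``pseudocount / (total_t2 + pseudocount)``
      (a half-read continuity correction by default), giving a conservative
      lower-bound fitness;
    - ``no_data``: gene absent from the input library (``N_t1 == 0``); W is
      NaN.

    Essential genes are omitted entirely. Raises if the two samples were
    aggregated over different gene universes.
    """
    if generations < 1:
        raise ValueError(f"generations must be >= 1, got {generations}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not t1.table.index.equals(t2.table.index):
        raise ValueError(
            f"gene universes differ between {t1.sample_id!r} and {t2.sample_id!r}"
        )
    if t1.denominator != t2.denominator:
        raise ValueError("t1 and t2 use different denominator modes")

    keep = ~t1.table["essential"]
    n1 = t1.table.loc[keep, "N"].to_numpy(float)
    n2 = t2.table.loc[keep, "N"].to_numpy(float)
    gene_ids = t1.table.index[keep]

    d = 2.0 ** generations
    n2_floor = pseudocount / (t2.denominator_reads + pseudocount)

    flags = np.full(len(n1), FLAG_OK, dtype=object)
    flags[n1 == 0.0] = FLAG_NO_DATA
    pseudo = (n1 > 0.0) & (n2 == 0.0)
    flags[pseudo] = FLAG_PSEUDOCOUNTED
    n2_eff = np.where(pseudo, n2_floor, n2)

    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.log(n2_eff * d / n1) / np.log((1.0 - n2_eff) * d / (1.0 - n1))
    w[flags == FLAG_NO_DATA] = np.nan

    return pd.DataFrame({"W": w, "flag": flags}, index=gene_ids)
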