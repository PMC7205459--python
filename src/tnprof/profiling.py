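"""Phenotypic fingerprints: matrix assembly, phenotype calls, clustering.

A gene's fingerprint is its vector of fitness scores across all tested
growth conditions. This module assembles the gene x condition matrix,
classifies genes by fixed fitness thresholds (strong phenotype outside
[0.75, 1.25], moderate outside [0.9, 1.1]), groups similar fingerprints by
agglomerative hierarchical clustering, and ranks Pearson-correlation
neighbors of a query gene — the operation that links an uncharacterised
gene to the characterised genes it behaves like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .containers import (
    FLAG_NO_DATA,
    FitnessMatrix,
    GeneAnnotation,
    make_fitness_matrix,
)

__all__ = [
    "PhenotypeCall",
    "ClusterResult",
    "NeighborRanking",
    "build_matrix",
    "classify_phenotypes",
    "cluster_profiles",
    "correlation_neighbors",
    "render_heatmap",
]

#: fitness thresholds: strong phenotype outside (0.75, 1.25),
#: moderate outside (0.9, 1.1), in at least one condition
STRONG_BOUNDS = (0.75, 1.25)
MODERATE_BOUNDS = (0.9, 1.1)

CORRELATION_MAX_DISTANCE = 2.0  # 1 - r at r = -1


def build_matrix(
    scores: Mapping[str, pd.DataFrame],
    condition_order: list[str] | None = None,
) -> FitnessMatrix:
    """Assemble per-condition score tables into one fitness matrix.

    ``scores`` maps condition label -> DataFrame indexed by gene_id with
    columns ``W`` and ``flag`` (the output of
    :func:`tnprof.fitness.compute_condition_fitness`). Two concentrations of
    one drug are two distinct labels and stay separate columns. All
    conditions must cover the same gene universe; rows are sorted by gene_id
    for deterministic output.
    """
    if not scores:
        raise ValueError("no conditions to assemble")
    labels = condition_order if condition_order is not None else list(scores)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels")
    missing = set(labels) - set(scores)
    if missing:
        raise ValueError(f"conditions without scores: {sorted(missing)}")
    universe = None
    for label in labels:
        idx = set(scores[label].index)
        if universe is None:
            universe = idx
        elif idx != universe:
            raise ValueError(f"condition {label!r} scored a different gene universe")
    gene_ids = sorted(universe)
    values = pd.DataFrame(
        {label: scores[label]["W"].reindex(gene_ids) for label in labels},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    flags = pd.DataFrame(
        {label: scores[label]["flag"].reindex(gene_ids) for label in labels},
        index=values.index,
    )
    return FitnessMatrix(values=values, flags=flags)


@dataclass
class PhenotypeCall:
    gene_id: str
    category: str  # strong | moderate | none | essential
    triggering_conditions: list[str] = field(default_factory=list)


def classify_phenotypes(
    matrix: FitnessMatrix,
    strong_bounds: tuple[float, float] = STRONG_BOUNDS,
    moderate_bounds: tuple[float, float] = MODERATE_BOUNDS,
    annotation: GeneAnnotation | None = None,
) -> tuple[list[PhenotypeCall], dict[str, int]]:
    """Assign each gene one phenotype category from its fingerprint.

    ``strong``: some condition has W below ``strong_bounds[0]`` or above
    ``strong_bounds[1]``; ``moderate``: not strong, but some condition falls
    outside ``moderate_bounds``; ``none`` otherwise. Categories are mutually
    exclusive and exhaustive over the matrix's (non-essential) genes. NA
    cells never trigger a phenotype; an all-NA gene is called ``none`` with
    a warning. The summary adds an ``essential`` count when an annotation is
    supplied (essential genes have no matrix row).
    """
    s_lo, s_hi = strong_bounds
    m_lo, m_hi = moderate_bounds
    if not (0 < s_lo < m_lo < 1 < m_hi < s_hi):
        raise ValueError("thresholds must satisfy strong_low < moderate_low < 1 < moderate_high < strong_high")
    calls: list[PhenotypeCall] = []
    counts = {"strong": 0, "moderate": 0, "none": 0}
    for gid, row in matrix.values.iterrows():
        vals = row.dropna()
        if vals.empty:
            warnings.warn(f"gene {gid!r} has no fitness data in any condition; calling 'none'")
            calls.append(PhenotypeCall(gid, "none"))
            counts["none"] += 1
            continue
        strong = vals[(vals < s_lo) | (vals > s_hi)]
        if len(strong):
            calls.append(PhenotypeCall(gid, "strong", list(strong.index)))
            counts["strong"] += 1
            continue
        moderate = vals[(vals < m_lo) | (vals > m_hi)]
        if len(moderate):
            calls.append(PhenotypeCall(gid, "moderate", list(moderate.index)))
            counts["moderate"] += 1
        else:
            calls.append(PhenotypeCall(gid, "none"))
            counts["none"] += 1
    if annotation is not None:
        counts["essential"] = annotation.n_essential
    return calls, counts


@dataclass
class ClusterResult:
    """An agglomerative clustering of gene fingerprints.

    ``linkage`` is the standard (n-1) x 4 merge table (children, height,
    cluster size); ``leaf_order`` the dendrogram's left-to-right gene order.
    """

    linkage: np.ndarray
    gene_ids: list[str]
    leaf_order: list[str]
    metric: str
    method: str

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge-height branch lengths."""
        if len(self.gene_ids) == 1:
            return f"{self.gene_ids[0]}:0;"
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.gene_ids[node.id]
            left, right = node.get_left(), node.get_right()
            parts = ",".join(
                f"{render(ch)}:{max(node.dist - ch.dist, 0.0):.6g}"
                for ch in (left, right)
            )
            return f"({parts})"

        return render(tree) + ";"


def _profile_distances(profiles: pd.DataFrame, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return pdist(profiles.values, metric="euclidean")
    if metric == "correlation":
        flat = profiles.std(axis=1).values == 0
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} zero-variance profile(s) under the correlation "
                "metric; assigning maximal distance"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            dist = pdist(profiles.values, metric="correlation")
        return np.nan_to_num(dist, nan=CORRELATION_MAX_DISTANCE)
    raise ValueError(f"unknown metric {metric!r}")


def cluster_profiles(
    matrix: FitnessMatrix,
    metric: str = "euclidean",
    method: str = "complete",
) -> ClusterResult:
    """Hierarchically cluster gene fingerprints.

    NA cells are imputed to the neutral fitness 1.0 before computing
    distances, so missing evidence creates no artificial separation. Genes
    are processed in lexicographic gene_id order, making tree and leaf order
    deterministic across platforms. ``metric`` is ``euclidean`` or
    ``correlation`` (1 - Pearson r); ``method`` one of ``complete``,
    ``average``, ``ward`` (ward requires the euclidean metric).
    """
    if method not in {"complete", "average", "ward"}:
        raise ValueError(f"unknown linkage method {method!r}")
    if method == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    profiles = matrix.imputed().sort_index()
    gene_ids = list(profiles.index)
    if len(gene_ids) < 1:
        raise ValueError("empty matrix")
    if len(gene_ids) == 1:
        return ClusterResult(
            linkage=np.empty((0, 4)), gene_ids=gene_ids,
            leaf_order=gene_ids, metric=metric, method=method,
        )
    dist = _profile_distances(profiles, metric)
    linkage = hierarchy.linkage(dist, method=method)
    order = hierarchy.leaves_list(linkage)
    return ClusterResult(
        linkage=linkage,
        gene_ids=gene_ids,
        leaf_order=[gene_ids[i] for i in order],
        metric=metric,
        method=method,
    )


@dataclass
class NeighborRanking:
    query: str
    neighbors: pd.DataFrame  # columns: gene_id, r; sorted by descending r


def correlation_neighbors(matrix: FitnessMatrix, gene_id: str) -> NeighborRanking:
    """Rank all other genes by Pearson correlation with the query fingerprint.

    Correlations are computed across condition columns, pairwise-complete
    over cells where both genes have data. Ties in r are broken
    lexicographically by gene_id; genes with no defined correlation (fewer
    than two overlapping conditions, or zero variance) are dropped.
    """
    if gene_id not in matrix.values.index:
        raise KeyError(f"gene {gene_id!r} not in matrix")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 conditions for meaningful correlations")
    query = matrix.values.loc[gene_id]
    if query.dropna().empty:
        raise ValueError(f"query gene {gene_id!r} has no fitness data")
    others = matrix.values.drop(index=gene_id)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = others.T.corrwith(query)  # pairwise-complete Pearson
    r = r.dropna()
    ranked = (
        pd.DataFrame({"gene_id": r.index, "r": r.values})
        .sort_values(["r", "gene_id"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return NeighborRanking(query=gene_id, neighbors=ranked)


def render_heatmap(
    matrix: FitnessMatrix,
    cluster: ClusterResult | None = None,
    path: str | Path = "heatmap.png",
    vmax: float | None = None,
) -> Path:
    """Draw the clustered fingerprint heatmap.

    Diverging colormap centered at the neutral fitness 1.0: red for
    defects (dark red near 0), white at 1, blue for advantages. Rows follow
    the cluster's leaf order when a cluster is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm

    data = matrix.imputed()
    if cluster is not None:
        data = data.loc[cluster.leaf_order]
    hi = float(vmax) if vmax is not None else max(2.0, float(np.nanmax(data.values)))
    norm = TwoSlopeNorm(vmin=0.0, vcenter=1.0, vmax=hi)
    fig_h = max(2.0, 0.08 * len(data))
    fig, ax = plt.subplots(figsize=(max(3.0, 0.3 * data.shape[1]) + 1.5, fig_h))
    im = ax.imshow(data.values, aspect="auto", cmap="RdBu", norm=norm, interpolation="nearest")
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=6)
    if len(data) <= 60:
        ax.set_yticks(range(len(data)))
        ax.set_yticklabels(data.index, fontsize=5)
    else:
        ax.set_yticks([])
    ax.set_ylabel(f"{len(data)} genes" + ("" if cluster is None else " (cluster leaf order)"))
    fig.colorbar(im, ax=ax, label="fitness score W")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
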