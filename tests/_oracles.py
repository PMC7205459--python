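"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a pipeline quantity by direct enumeration of its
definition, without touching the implementation path it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_gene_reads(sites, genes):
    """Per-gene read/site totals by explicit double loop.

    ``sites``: iterable of (contig, position_1based, reads);
    ``genes``: iterable of (gene_id, contig, start0, end0).
    """
    reads = {g[0]: 0 for g in genes}
    count = {g[0]: 0 for g in genes}
    for contig, pos, n in sites:
        for gid, gcontig, start, end in genes:
            if contig == gcontig and start <= pos - 1 < end:
                reads[gid] += n
                count[gid] += 1
    return reads, count


def pearson(x, y):
    """Textbook Pearson r: covariance over the product of standard deviations."""
    pairs = [(a, b) for a, b in zip(x, y) if not (math.isnan(a) or math.isnan(b))]
    n = len(pairs)
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    cov = sum((a - mx) * (b - my) for a, b in pairs)
    sx = math.sqrt(sum((a - mx) ** 2 for a, _ in pairs))
    sy = math.sqrt(sum((b - my) ** 2 for _, b in pairs))
    return cov / (sx * sy)


def naive_cophenetic(points: np.ndarray, method: str) -> np.ndarray:
    """O(n^3) agglomerative clustering; returns the cophenetic distance matrix.

    Euclidean point distances; ``method`` is ``complete`` or ``average``.
    At every step the pair of active clusters with the smallest linkage
    distance merges, and that distance becomes the cophenetic distance
    between all cross-pair members.
    """
    n = len(points)
    base = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for i_pos, a in enumerate(ids):
            for b in ids[i_pos + 1 :]:
                cross = [base[p, q] for p in clusters[a] for q in clusters[b]]
                d = max(cross) if method == "complete" else sum(cross) / len(cross)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for p in clusters[a]:
            for q in clusters[b]:
                coph[p, q] = coph[q, p] = d
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return coph
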