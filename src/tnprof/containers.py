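"""Shared in-memory containers for the Tn-seq profiling pipeline.

Coordinate convention: gene intervals are stored 0-based half-open
internally; conversion from/to GFF3's 1-based inclusive coordinates happens
once, at the I/O boundary (:mod:`tnprof.io`). Insertion positions are kept
as 1-based point coordinates throughout, matching how they appear on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "InsertionTable",
    "ConditionManifest",
    "FitnessMatrix",
]

#: feature types never scored for fitness (plus anything tagged as a transposon)
EXCLUDED_FEATURE_TYPES = frozenset({"tRNA", "rRNA"})

ANNOTATION_COLUMNS = [
    "gene_id",
    "contig",
    "start",
    "end",
    "strand",
    "feature_type",
    "essential",
    "excluded",
]


@dataclass
class GeneAnnotation:
    """Gene intervals with essentiality and exclusion flags.

    Parameters
    ----------
    genes
        DataFrame with columns ``gene_id, contig, start, end, strand,
        feature_type, essential, excluded``. ``start``/``end`` are 0-based
        half-open. ``excluded`` marks tRNA/rRNA/transposon features that are
        carried through I/O but never receive a fitness score.
    contig_lengths
        Optional declared contig lengths (used for bounds validation and by
        the simulator).
    """

    genes: pd.DataFrame
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        g = self.genes.reset_index(drop=True).copy()
        g["start"] = g["start"].astype(np.int64)
        g["end"] = g["end"].astype(np.int64)
        g["essential"] = g["essential"].astype(bool)
        g["excluded"] = g["excluded"].astype(bool)
        if (g["start"] >= g["end"]).any():
            bad = g.loc[g["start"] >= g["end"], "gene_id"].tolist()
            raise ValueError(f"empty or inverted gene intervals: {bad}")
        if g["gene_id"].duplicated().any():
            dups = g.loc[g["gene_id"].duplicated(), "gene_id"].unique().tolist()
            raise ValueError(f"duplicate gene_ids: {dups}")
        for contig, length in self.contig_lengths.items():
            sub = g[g["contig"] == contig]
            if (sub["end"] > length).any():
                raise ValueError(
                    f"gene interval exceeds declared length of contig {contig!r}"
                )
        self.genes = g

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return self.genes["gene_id"].tolist()

    def profiled_genes(self) -> pd.DataFrame:
        """Genes eligible for fitness scoring: neither essential nor excluded."""
        g = self.genes
        return g[~g["essential"] & ~g["excluded"]].reset_index(drop=True)

    def scorable_gene_ids(self) -> list[str]:
        return self.profiled_genes()["gene_id"].tolist()

    @property
    def n_essential(self) -> int:
        return int((self.genes["essential"] & ~self.genes["excluded"]).sum())


@dataclass
class InsertionTable:
    """Per-sample unique insertion sites with read counts.

    ``sites`` has columns ``contig`` (str), ``position`` (1-based int),
    ``reads`` (int >= 0). Positions are unique per contig: one genomic
    position is one site regardless of the strand reads mapped to.
    """

    sample_id: str
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("contig", "position", "reads"):
            if col not in self.sites.columns:
                raise ValueError(f"insertion table missing column {col!r}")
        s = self.sites.reset_index(drop=True).copy()
        s["position"] = s["position"].astype(np.int64)
        s["reads"] = s["reads"].astype(np.int64)
        if (s["reads"] < 0).any():
            raise ValueError("negative read counts")
        if (s["position"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        if s.duplicated(subset=["contig", "position"]).any():
            dup = s[s.duplicated(subset=["contig", "position"], keep=False)]
            raise ValueError(
                "duplicate insertion positions: "
                + ", ".join(
                    f"{c}:{p}" for c, p in dup[["contig", "position"]].values[:5]
                )
            )
        self.sites = s[["contig", "position", "reads"]]

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def total_reads(self) -> int:
        return int(self.sites["reads"].sum())


@dataclass
class ConditionManifest:
    """Maps sample files to conditions, timepoints and generation counts.

    ``rows`` columns: ``sample_id, condition, timepoint (t1|t2), generations,
    replicate, file``. The t1 rows are the input-library replicates shared by
    every condition; each t2 condition is scored against their pooled counts.
    """

    rows: pd.DataFrame

    REQUIRED = ["sample_id", "condition", "timepoint", "generations", "replicate", "file"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        r = self.rows.reset_index(drop=True).copy()
        r["generations"] = r["generations"].astype(int)
        r["replicate"] = r["replicate"].astype(int)
        bad_tp = set(r["timepoint"]) - {"t1", "t2"}
        if bad_tp:
            raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
        if r["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids in manifest")
        if not (r["timepoint"] == "t1").any():
            raise ValueError("manifest has no t1 (input library) samples")
        g1 = r.loc[r["timepoint"] == "t1", "generations"]
        g2 = r.loc[r["timepoint"] == "t2", "generations"]
        if len(g2) and not (g1.max() < g2.min()):
            raise ValueError("t1 generations must be strictly below t2 generations")
        self.rows = r

    @property
    def t1_samples(self) -> pd.DataFrame:
        return self.rows[self.rows["timepoint"] == "t1"]

    @property
    def t2_samples(self) -> pd.DataFrame:
        return self.rows[self.rows["timepoint"] == "t2"]

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order (t2 samples)."""
        seen: list[str] = []
        for c in self.t2_samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def generation_span(self) -> int:
        """Doublings of the reference population between t1 and t2 sampling."""
        if not len(self.t2_samples):
            raise ValueError("manifest has no t2 samples")
        return int(self.t2_samples["generations"].iloc[0] - self.t1_samples["generations"].iloc[0])


FLAG_OK = "ok"
FLAG_PSEUDOCOUNTED = "pseudocounted"
FLAG_NO_DATA = "no_data"
VALID_FLAGS = frozenset({FLAG_OK, FLAG_PSEUDOCOUNTED, FLAG_NO_DATA})


@dataclass
class FitnessMatrix:
    """Gene x condition matrix of fitness scores (phenotypic fingerprints).

    ``values`` is float with NaN where ``flags == "no_data"``; ``flags`` is a
    string DataFrame with the same index/columns and entries from
    ``{ok, pseudocounted, no_data}``.
    """

    values: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        v, f = self.values, self.flags
        if not (v.index.equals(f.index) and v.columns.equals(f.columns)):
            raise ValueError("values and flags must share index and columns")
        if v.index.duplicated().any():
            raise ValueError("duplicate gene rows")
        if v.columns.duplicated().any():
            raise ValueError("duplicate condition columns")
        bad = set(np.unique(f.values)) - VALID_FLAGS
        if bad:
            raise ValueError(f"unknown flags: {sorted(bad)}")
        scored = f.values != FLAG_NO_DATA
        if not np.all(np.isfinite(v.values[scored])):
            raise ValueError("non-finite fitness value with flag != no_data")
        if np.isfinite(v.values[~scored]).any():
            raise ValueError("no_data cells must be NaN")
        self.values = v.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def imputed(self, fill: float = 1.0) -> pd.DataFrame:
        """Values with NaN cells replaced by the neutral fitness ``fill``."""
        return self.values.fillna(fill)


def make_fitness_matrix(
    values: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    flags: pd.DataFrame | None = None,
) -> FitnessMatrix:
    """Build a :class:`FitnessMatrix` from a plain DataFrame or nested mapping.

    Cells left NaN without an explicit flag are marked ``no_data``; everything
    else is flagged ``ok``.
    """
    v = pd.DataFrame(values, dtype=float) if not isinstance(values, pd.DataFrame) else values.astype(float)
    if flags is None:
        flags = pd.DataFrame(
            np.where(np.isfinite(v.values), FLAG_OK, FLAG_NO_DATA),
            index=v.index,
            columns=v.columns,
        )
    return FitnessMatrix(values=v, flags=flags)
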