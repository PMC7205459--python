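"""On-disk formats: GFF3 annotations, insertion tables, manifests, matrices.

All readers validate and reject malformed input rather than repairing it;
every writer/reader pair round-trips exactly. Text files are UTF-8,
tab-separated where tabular, newline-terminated. GFF3 coordinates (1-based
inclusive) are converted to the internal 0-based half-open convention here
and nowhere else.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .containers import (
    EXCLUDED_FEATURE_TYPES,
    FLAG_NO_DATA,
    FLAG_OK,
    ConditionManifest,
    FitnessMatrix,
    GeneAnnotation,
    InsertionTable,
)

__all__ = [
    "read_gff",
    "write_gff",
    "read_insertions",
    "write_insertions",
    "read_manifest",
    "write_manifest",
    "read_matrix",
    "write_matrix",
]

_GENE_LIKE_TYPES = frozenset({"gene", "pseudogene"}) | EXCLUDED_FEATURE_TYPES


class GFFParseError(ValueError):
    """Raised on malformed GFF3 input; message names the offending line."""


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, val = chunk.partition("=")
            attrs[key.strip()] = val.strip()
    return attrs


def _truthy(val: str) -> bool:
    return val.strip().lower() in {"1", "true", "yes"}


def read_gff(
    path: str | Path,
    feature_types: Iterable[str] = _GENE_LIKE_TYPES,
    transposon_tag: str = "transposon",
) -> GeneAnnotation:
    """Load gene-type features from a GFF3 file.

    Features whose type is tRNA/rRNA, or whose attributes mention
    ``transposon_tag`` (case-insensitive, in ``ID``/``Name``/``gene_biotype``/
    ``product``), are loaded but flagged ``excluded`` so they never enter
    fitness profiling. Essentiality is read from an ``essential=true``
    attribute. Contig lengths are taken from ``##sequence-region`` pragmas
    when present.
    """
    path = Path(path)
    wanted = set(feature_types)
    tag_re = re.compile(re.escape(transposon_tag), re.IGNORECASE)
    records: list[dict] = []
    contig_lengths: dict[str, int] = {}
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    contig_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFParseError(f"{path.name}:{lineno}: expected 9 fields, got {len(fields)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            if ftype not in wanted:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GFFParseError(f"{path.name}:{lineno}: malformed coordinate") from exc
            if start < 1 or end < start:
                raise GFFParseError(
                    f"{path.name}:{lineno}: invalid interval [{start}, {end}]"
                )
            attrs = _parse_attributes(attr_s)
            gene_id = attrs.get("ID") or attrs.get("locus_tag") or attrs.get("Name")
            if gene_id is None:
                raise GFFParseError(f"{path.name}:{lineno}: feature lacks ID")
            if gene_id in seen_ids:
                raise GFFParseError(f"{path.name}:{lineno}: duplicate gene_id {gene_id!r}")
            seen_ids.add(gene_id)
            tagged = any(
                tag_re.search(attrs.get(k, ""))
                for k in ("ID", "Name", "gene_biotype", "product")
            )
            records.append(
                {
                    "gene_id": gene_id,
                    "contig": contig,
                    "start": start - 1,  # to 0-based half-open
                    "end": end,
                    "strand": strand if strand in "+-" else ".",
                    "feature_type": ftype,
                    "essential": _truthy(attrs.get("essential", "")),
                    "excluded": ftype in EXCLUDED_FEATURE_TYPES or tagged,
                }
            )
    genes = pd.DataFrame(
        records,
        columns=[
            "gene_id", "contig", "start", "end", "strand",
            "feature_type", "essential", "excluded",
        ],
    )
    return GeneAnnotation(genes=genes, contig_lengths=contig_lengths)


def write_gff(annotation: GeneAnnotation, path: str | Path, source: str = "tnprof") -> None:
    """Write an annotation as GFF3 (1-based inclusive coordinates)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in sorted(annotation.contig_lengths.items()):
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for rec in annotation.genes.itertuples(index=False):
            attrs = f"ID={rec.gene_id};essential={'true' if rec.essential else 'false'}"
            fh.write(
                f"{rec.contig}\t{source}\t{rec.feature_type}\t{rec.start + 1}\t{rec.end}"
                f"\t.\t{rec.strand}\t.\t{attrs}\n"
            )


def read_insertions(path: str | Path, sample_id: str | None = None) -> InsertionTable:
    """Read a ``contig<TAB>position<TAB>reads`` insertion table.

    A header line is optional (detected by a non-numeric second column).
    Duplicate (contig, position) pairs and negative counts are rejected.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["contig", "position", "reads"],
        dtype={"contig": str},
    )
    if len(df) and not str(df.iloc[0]["position"]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    try:
        df["position"] = df["position"].astype(np.int64)
        df["reads"] = df["reads"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path.name}: non-integer position or read count") from exc
    return InsertionTable(sample_id=sample_id or path.stem, sites=df)


def write_insertions(table: InsertionTable, path: str | Path, header: bool = True) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("contig\tposition\treads\n")
        for rec in table.sites.itertuples(index=False):
            fh.write(f"{rec.contig}\t{rec.position}\t{rec.reads}\n")


def read_manifest(path: str | Path) -> ConditionManifest:
    """Read a condition manifest from TSV or YAML (by file extension)."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        rows = pd.DataFrame(data["samples"] if isinstance(data, dict) else data)
    else:
        rows = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    return ConditionManifest(rows=rows)


def write_manifest(manifest: ConditionManifest, path: str | Path) -> None:
    manifest.rows.to_csv(path, sep="\t", index=False)


def write_matrix(matrix: FitnessMatrix, path: str | Path) -> None:
    """Write a fitness matrix as TSV.

    Layout: one gene per row; one column per condition with the score (``NA``
    for no-data cells) followed by a sidecar flag column ``<condition>__flag``.
    Round-trips exactly through :func:`read_matrix`.
    """
    path = Path(path)
    out = pd.DataFrame(index=matrix.values.index)
    out.index.name = "gene_id"
    for cond in matrix.condition_labels:
        out[cond] = matrix.values[cond]
        out[f"{cond}__flag"] = matrix.flags[cond]
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_matrix(path: str | Path) -> FitnessMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id", comment="#")
    conds = [c for c in df.columns if not c.endswith("__flag")]
    values = df[conds].astype(float)
    flags = df[[f"{c}__flag" for c in conds]].copy()
    flags.columns = conds
    flags = flags.fillna(FLAG_NO_DATA)
    return FitnessMatrix(values=values, flags=flags)
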