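"""Readers and writers for the pipeline's plain-text formats.

Expression matrices are tab-separated with a ``gene_id`` index column and
sample IDs as headers. Gene models come either from a flat TSV
(``gene_id  length_bp  n_introns``) or from a GFF3 file via gffutils
(length = summed exon span of the representative transcript, introns =
exons - 1). Annotation sets use the GMT convention: one set per line,
``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .quantify import ExpressionMatrix

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_gene_models_tsv",
    "gene_models_from_gff3",
    "read_gmt",
    "write_gmt",
    "read_tissue_table",
    "write_yaml",
    "read_yaml",
]


def read_matrix_tsv(
    path,
    unit: str,
    timepoint: str | None = None,
    gene_lengths: pd.Series | None = None,
) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = "gene_id"
    if timepoint is None:
        timepoint = Path(path).stem.split(".")[0]
    return ExpressionMatrix(values, unit, timepoint=timepoint, gene_lengths=gene_lengths)


def write_matrix_tsv(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_gene_models_tsv(path) -> pd.DataFrame:
    """Flat gene-model table: gene_id, length_bp, n_introns."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "length_bp"}
    if not required <= set(df.columns):
        raise ValueError(f"gene model TSV needs columns {sorted(required)}")
    df = df.set_index("gene_id")
    if "n_introns" not in df.columns:
        df["n_introns"] = pd.NA
    return df[["length_bp", "n_introns"]]


def gene_models_from_gff3(path, db_path: str | None = None) -> pd.DataFrame:
    """Derive gene length and intron count from a GFF3 annotation.

    Length is the summed exon span of the first (representative) transcript
    of each gene; intron count is its exon count minus one.
    """
    import gffutils

    db_path = db_path or ":memory:"
    db = gffutils.create_db(
        str(path), db_path, merge_strategy="create_unique", keep_order=True, force=db_path != ":memory:"
    )
    rows = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, level=1))
        target = transcripts[0] if transcripts else gene
        exons = list(db.children(target, featuretype="exon"))
        if exons:
            length = sum(e.end - e.start + 1 for e in exons)
            introns = max(len(exons) - 1, 0)
        else:
            length = gene.end - gene.start + 1
            introns = 0
        rows.append((gene.id, length, introns))
    return pd.DataFrame(rows, columns=["gene_id", "length_bp", "n_introns"]).set_index("gene_id")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_tissue_table(path) -> pd.DataFrame:
    """Tissues x genes expression table (tissues in rows)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def ensure_dir(path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
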