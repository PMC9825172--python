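"""Readers and writers for the TSV/FASTA interfaces.

TSV dialect: UTF-8, tab-separated, ``#`` comment lines, mandatory
header row. TSS coordinates are 1-based inclusive on disk and 0-based
internally. Expression tables carry gene ids in the first column and
sample ids as remaining columns; sample times live in a companion
samples table (columns ``sample_id``, ``time_h``).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    Classification,
    ExpressionMatrix,
    FoldChangeTable,
    FormatError,
    Genome,
    SampleSeries,
    TranscriptionUnit,
)

logger = logging.getLogger(__name__)

TU_COLUMNS = ["tu_id", "replicon", "replicon_class", "strand", "tss_1based", "genes"]


def read_fasta(path) -> Genome:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if rec.id in records:
            raise FormatError(f"{path}: duplicate record {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return Genome(records)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_tu_table(path) -> list[TranscriptionUnit]:
    df = _read_tsv(path)
    missing = set(TU_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing TU columns {sorted(missing)}")
    dup = df["tu_id"][df["tu_id"].duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicate tu_id values: {', '.join(dup)}")
    tus = []
    for _, row in df.iterrows():
        tus.append(
            TranscriptionUnit(
                tu_id=row["tu_id"],
                replicon=row["replicon"],
                replicon_class=row["replicon_class"],
                strand=row["strand"],
                tss=int(row["tss_1based"]) - 1,
                genes=tuple(g.strip() for g in row["genes"].split(",")),
            )
        )
    return tus


def write_tu_table(tus: list[TranscriptionUnit], path) -> None:
    rows = [
        {
            "tu_id": tu.tu_id,
            "replicon": tu.replicon,
            "replicon_class": tu.replicon_class,
            "strand": tu.strand,
            "tss_1based": tu.tss + 1,
            "genes": ",".join(tu.genes),
        }
        for tu in tus
    ]
    pd.DataFrame(rows, columns=TU_COLUMNS).to_csv(path, sep="\t", index=False)


def read_samples_table(path) -> SampleSeries:
    df = _read_tsv(path)
    if not {"sample_id", "time_h"} <= set(df.columns):
        raise FormatError(f"{path}: samples table needs sample_id and time_h columns")
    return SampleSeries(
        tuple(df["sample_id"]), tuple(float(t) for t in df["time_h"])
    )


def write_samples_table(samples: SampleSeries, path) -> None:
    pd.DataFrame(
        {"sample_id": samples.sample_ids, "time_h": samples.times_h}
    ).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path, samples: SampleSeries, unit: str = "TPM") -> ExpressionMatrix:
    """Read a gene x sample expression table.

    Missing cells (empty or NA) are interpreted as 0 with a warning;
    any other non-numeric cell raises with its row/column address.
    """
    df = _read_tsv(path)
    gene_col = df.columns[0]
    genes = list(df[gene_col])
    df = df.drop(columns=[gene_col])
    if list(df.columns) != list(samples.sample_ids):
        raise FormatError(
            f"{path}: expression columns {list(df.columns)} do not match "
            f"sample ids {list(samples.sample_ids)}"
        )
    values = np.empty(df.shape, dtype=float)
    n_missing = 0
    for j, col in enumerate(df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        missing = df[col].isna() | df[col].str.upper().isin(["NA", "NAN", ""])
        bad = parsed.isna() & ~missing
        if bad.any():
            i = int(np.flatnonzero(bad.values)[0])
            raise FormatError(
                f"{path}: non-numeric cell {df[col].iloc[i]!r} at "
                f"gene {genes[i]!r}, sample {col!r}"
            )
        n_missing += int(missing.sum())
        values[:, j] = parsed.fillna(0.0).values
    if n_missing:
        logger.warning("%s: %d missing expression cells interpreted as 0", path, n_missing)
    return ExpressionMatrix(genes, samples, values, unit)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_classification(path) -> Classification:
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: classification needs item and label columns")
    items, labels = df.iloc[:, 0], df.iloc[:, 1]
    if items.duplicated().any():
        dup = items[items.duplicated()].iloc[0]
        raise FormatError(f"{path}: item {dup!r} classified more than once")
    return Classification(dict(zip(items, labels)))


def write_classification(cls: Classification, path, item_col: str = "item_id") -> None:
    pd.DataFrame(
        {item_col: list(cls.labels), "label": list(cls.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_foldchanges(path) -> FoldChangeTable:
    """Read a gene x contrast log2 fold-change table.

    Unlike expression tables there is no imputation rule for fold
    changes, so any non-numeric cell (including NA) is an error.
    """
    df = _read_tsv(path)
    gene_col = df.columns[0]
    genes = list(df[gene_col])
    df = df.drop(columns=[gene_col])
    contrasts = [c for c in df.columns if not c.endswith(".se")]
    out = pd.DataFrame(index=genes, columns=contrasts, dtype=float)
    for col in contrasts:
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            i = int(np.flatnonzero(parsed.isna().values)[0])
            raise FormatError(
                f"{path}: non-numeric fold change {df[col].iloc[i]!r} at "
                f"gene {genes[i]!r}, contrast {col!r}"
            )
        out[col] = parsed.values
    se_cols = [c for c in df.columns if c.endswith(".se")]
    se = None
    if se_cols:
        se = pd.DataFrame(index=genes, columns=contrasts, dtype=float)
        for col in se_cols:
            se[col[:-3]] = pd.to_numeric(df[col], errors="raise").values
    return FoldChangeTable(contrasts, out, se)


def write_foldchanges(fc: FoldChangeTable, path) -> None:
    df = fc.log2fc.copy()
    if fc.se is not None:
        for c in fc.contrasts:
            df[c + ".se"] = fc.se[c]
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
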