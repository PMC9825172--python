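"""Shared domain types and coordinate conventions.

All genomic coordinates are stored 0-based half-open internally; every
TSV interface uses 1-based inclusive coordinates (converted on read and
write). TSS-relative coordinates place 0 on the first transcribed base,
so -1 is the base immediately 5' of the TSS and downstream positions are
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_UNITS = ("counts", "TPM", "arcsinh_TPM")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class SampleSeries:
    """Ordered, timed samples of one experiment.

    ``time_h`` is hours relative to induction; pre-induction samples are
    negative. Times must be non-decreasing when the series is consumed
    as a time series.
    """

    sample_ids: tuple[str, ...]
    times_h: tuple[float, ...]
    replicates: tuple[str, ...] | None = None

    def __post_init__(self):
        if len(self.sample_ids) != len(self.times_h):
            raise ValueError("sample_ids and times_h length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if any(b < a for a, b in zip(self.times_h, self.times_h[1:])):
            raise ValueError("sample times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class ExpressionMatrix:
    """genes x samples expression values with a declared unit."""

    gene_ids: list[str]
    samples: SampleSeries
    values: np.ndarray
    unit: str = "TPM"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.gene_ids)}, {len(self.samples)})"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if np.isnan(self.values).any():
            raise ValueError("missing cells must be imputed to 0 before construction")
        if (self.values < 0).any():
            raise ValueError("expression values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.samples.sample_ids
        )

    def subset_samples(self, idx: list[int]) -> "ExpressionMatrix":
        ss = SampleSeries(
            tuple(self.samples.sample_ids[i] for i in idx),
            tuple(self.samples.times_h[i] for i in idx),
        )
        return ExpressionMatrix(list(self.gene_ids), ss, self.values[:, idx], self.unit)


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    replicon: str
    strand: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptionUnit:
    """An operon-like unit: one promoter, ordered 5'->3' member genes."""

    tu_id: str
    replicon: str
    replicon_class: str  # chromosome | plasmid
    strand: str
    tss: int  # 0-based coordinate of the first transcribed base
    genes: tuple[str, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.replicon_class not in ("chromosome", "plasmid"):
            raise ValueError(f"unknown replicon_class {self.replicon_class!r}")
        if len(self.genes) == 0:
            raise ValueError(f"TU {self.tu_id} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"TU {self.tu_id} lists duplicate genes")
        if self.tss < 0:
            raise ValueError(f"TU {self.tu_id} has negative TSS")


class Genome(dict):
    """Mapping replicon name -> uppercase sequence over {A,C,G,T,N}."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one replicon")
        cleaned = {}
        for name, seq in sequences.items():
            seq = seq.upper().replace("U", "T")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise FormatError(
                    f"replicon {name!r} contains invalid characters: "
                    + ", ".join(sorted(bad))
                )
            if not seq:
                raise FormatError(f"replicon {name!r} is empty")
            cleaned[name] = seq
        super().__init__(cleaned)


@dataclass
class Classification:
    """One categorical label per item."""

    labels: dict[str, str]

    def __post_init__(self):
        self.labels = dict(self.labels)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def items_in(self, cls: str) -> set[str]:
        return {i for i, c in self.labels.items() if c == cls}

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class FoldChangeTable:
    """gene -> contrast -> (log2 fold change, standard error)."""

    contrasts: list[str]
    log2fc: pd.DataFrame  # genes x contrasts
    se: pd.DataFrame | None = None

    def __post_init__(self):
        if list(self.log2fc.columns) != list(self.contrasts):
            raise ValueError("log2fc columns must match contrasts")
        if self.log2fc.isna().any().any():
            raise ValueError("fold-change table contains missing values")
        if self.se is not None and (self.se.values < 0).any():
            raise ValueError("standard errors must be non-negative")

    def get(self, gene: str, contrast: str) -> float:
        return float(self.log2fc.at[gene, contrast])


class WindowOutOfBounds(ValueError):
    """TSS window overruns the replicon; the TU must be excluded, not truncated."""


def tss_window(genome: Genome, tu: TranscriptionUnit, upstream: int, downstream: int) -> str:
    """Extract the sense-strand sequence around a TU's TSS.

    Returns a string of length ``upstream + downstream`` read 5'->3' on
    the sense (transcribed) strand; index ``i`` corresponds to
    TSS-relative position ``i - upstream``, so relative position 0 is
    the first transcribed base.
    """
    seq = genome[tu.replicon]
    n = len(seq)
    if tu.strand == "+":
        lo, hi = tu.tss - upstream, tu.tss + downstream
        if lo < 0 or hi > n:
            raise WindowOutOfBounds(
                f"TU {tu.tu_id}: window [{lo}, {hi}) outside replicon of length {n}"
            )
        return seq[lo:hi]
    lo, hi = tu.tss - downstream + 1, tu.tss + upstream + 1
    if lo < 0 or hi > n:
        raise WindowOutOfBounds(
            f"TU {tu.tu_id}: window [{lo}, {hi}) outside replicon of length {n}"
        )
    return reverse_complement(seq[lo:hi])
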