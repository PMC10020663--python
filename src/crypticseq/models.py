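"""Domain types for exon-bin gene models, sample metadata and count matrices.

Coordinates are stored 0-based half-open internally.  GFF input/output uses
1-based inclusive coordinates and BED output 0-based half-open, so each file
format keeps its native convention with a single conversion site in the IO
layer.

An *exon bin* is a non-overlapping segment of a gene's exonic sequence used
as the counting unit for exon-level statistics (the "collapsed exon counting
bin" produced by flattening a transcript annotation with gene aggregation
disabled).  Bin indices run 1..E in transcriptional (5'->3') order:
ascending genomic start on the '+' strand, descending on '-'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExonBin",
    "GeneModel",
    "transcriptional_order",
    "make_sample_table",
    "validate_sample_table",
    "validate_count_matrix",
    "format_row_key",
    "parse_row_key",
]

STRANDS = ("+", "-")
CONDITIONS = ("control", "treatment")


@dataclass(frozen=True)
class ExonBin:
    """One exon counting bin of a gene (0-based half-open coordinates)."""

    gene_id: str
    bin_index: int
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if ":" in self.gene_id:
            raise ValueError(f"gene_id may not contain ':': {self.gene_id!r}")
        if not (isinstance(self.start, (int, np.integer)) and isinstance(self.end, (int, np.integer))):
            raise ValueError(f"{self.gene_id}: non-integer coordinates ({self.start}, {self.end})")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end, got ({self.start}, {self.end})")
        if self.bin_index < 1:
            raise ValueError(f"{self.gene_id}: bin_index must be >= 1, got {self.bin_index}")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered tuple of exon bins in transcriptional order."""

    gene_id: str
    exons: tuple[ExonBin, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model needs at least one exon bin")
        strands = {e.strand for e in self.exons}
        if len(strands) > 1:
            raise ValueError(f"{self.gene_id}: mixed strands within one gene: {sorted(strands)}")
        if any(e.gene_id != self.gene_id for e in self.exons):
            raise ValueError(f"{self.gene_id}: exon bins carry a different gene_id")
        idx = [e.bin_index for e in self.exons]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError(f"{self.gene_id}: bin_index values must be contiguous 1..E, got {idx}")
        starts = [e.start for e in self.exons]
        ordered = sorted(starts) if self.strand == "+" else sorted(starts, reverse=True)
        if starts != ordered:
            raise ValueError(
                f"{self.gene_id}: exon bins are not in transcriptional order for strand {self.strand}"
            )
        # non-overlap within the gene
        by_pos = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_pos, by_pos[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.gene_id}: overlapping exon bins "
                    f"({a.start},{a.end}) and ({b.start},{b.end})"
                )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def transcriptional_order(bins: Iterable[ExonBin], strand: str) -> list[ExonBin]:
    """Sort exon bins 5'->3' and rewrite bin_index as 1..E.

    '+' genes: ascending genomic start; '-' genes: descending.  Applying the
    operation twice is idempotent.
    """
    if strand not in STRANDS:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    ordered = sorted(bins, key=lambda e: e.start, reverse=(strand == "-"))
    return [
        ExonBin(e.gene_id, i, e.chrom, e.start, e.end, strand)
        for i, e in enumerate(ordered, start=1)
    ]


def make_sample_table(
    sample_ids: Iterable[str],
    conditions: Iterable[str],
    sex: Iterable[str] | None = None,
    replicates: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Assemble a sample metadata table indexed by sample_id."""
    sample_ids = list(sample_ids)
    conditions = list(conditions)
    if sex is None:
        sex = ["NA"] * len(sample_ids)
    if replicates is None:
        reps: dict[str, int] = {}
        replicates = []
        for c in conditions:
            reps[c] = reps.get(c, 0) + 1
            replicates.append(reps[c])
    table = pd.DataFrame(
        {"condition": conditions, "sex": list(sex), "replicate": list(replicates)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    validate_sample_table(table)
    return table


def validate_sample_table(samples: pd.DataFrame, require_two_per_group: bool = False) -> None:
    if samples.index.duplicated().any():
        dup = samples.index[samples.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample_ids: {dup}")
    bad = set(samples["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {sorted(bad)}")
    if require_two_per_group:
        counts = samples["condition"].value_counts()
        for cond in CONDITIONS:
            if counts.get(cond, 0) < 2:
                raise ValueError(f"need at least 2 samples per condition; {cond} has {counts.get(cond, 0)}")


def validate_count_matrix(
    matrix: pd.DataFrame,
    models: Mapping[str, GeneModel] | None = None,
    samples: pd.DataFrame | None = None,
) -> None:
    """Check an exon-by-sample count matrix against models and sample table.

    Rows are indexed by (gene_id, bin_index); values must be non-negative
    integers.
    """
    if not isinstance(matrix.index, pd.MultiIndex) or matrix.index.nlevels != 2:
        raise ValueError("count matrix rows must be indexed by (gene_id, bin_index)")
    values = matrix.to_numpy()
    if values.size and (not np.issubdtype(values.dtype, np.integer)):
        if not np.allclose(values, np.round(values)):
            raise ValueError("count matrix contains non-integer values")
    if values.size and (values < 0).any():
        raise ValueError("count matrix contains negative values")
    if models is not None:
        known = {
            (g, e.bin_index) for g, m in models.items() for e in m.exons
        }
        unknown = [k for k in matrix.index if k not in known]
        if unknown:
            raise ValueError(f"count rows not present in gene models: {unknown[:5]}")
    if samples is not None:
        unknown_cols = [c for c in matrix.columns if c not in samples.index]
        if unknown_cols:
            raise ValueError(f"count columns not present in sample table: {unknown_cols}")


def format_row_key(gene_id: str, bin_index: int) -> str:
    """Row-key dialect ``gene_id:E###`` (zero-padded 3-digit bin index)."""
    if ":" in gene_id:
        raise ValueError(f"gene_id may not contain ':': {gene_id!r}")
    return f"{gene_id}:E{bin_index:03d}"


def parse_row_key(key: str) -> tuple[str, int]:
    gene_id, _, tail = key.rpartition(":")
    if not gene_id or not tail.startswith("E"):
        raise ValueError(f"malformed row key {key!r}; expected gene_id:E###")
    try:
        idx = int(tail[1:])
    except ValueError as exc:
        raise ValueError(f"malformed row key {key!r}; expected gene_id:E###") from exc
    return gene_id, idx
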