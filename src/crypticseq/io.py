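"""Readers and writers for exon-bin annotations, counts, metadata and calls.

File dialects
-------------
* annotation: GFF (1-based inclusive) with ``aggregate_gene`` / ``exonic_part``
  records carrying ``gene_id`` (and optionally ``exonic_part_number``)
  attributes, or a plain TSV with columns gene_id, chrom, start, end, strand
  (1-based inclusive) and an optional exon_index column;
* counts: TSV with row keys ``gene_id:E###`` (zero-padded 3-digit bin index)
  and one column per sample;
* sample table / statistics tables: plain TSV;
* cryptic-TSS export: BED6 (0-based half-open).

All TSVs are tab-separated with a single '#'-prefixed header line, UTF-8,
no quoting.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .models import (
    ExonBin,
    GeneModel,
    format_row_key,
    parse_row_key,
    transcriptional_order,
    validate_sample_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_exon_annotation",
    "write_exon_annotation",
    "read_counts",
    "write_counts",
    "read_sample_table",
    "write_sample_table",
    "read_exon_stats",
    "write_cryptic_bed",
    "read_gene_list",
]


# ---------------------------------------------------------------------------
# generic TSV helpers ('#'-prefixed header line)

def _read_tsv(path: str) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if not first.strip():
        return pd.DataFrame()
    # literal "NA" is a valid value (e.g. sex); only empty cells are missing
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    df.columns = [df.columns[0].lstrip("#"), *df.columns[1:]]
    return df


def _write_tsv(path: str, df: pd.DataFrame, index_name: str | None = None) -> None:
    out = df.reset_index() if index_name else df
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(map(str, out.columns)) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# annotation

def read_exon_annotation(path: str, format: str | None = None) -> dict[str, GeneModel]:
    """Read a flattened exon-bin annotation into validated gene models.

    Parameters
    ----------
    path:
        GFF (1-based inclusive) or TSV file.
    format:
        ``"gff"`` or ``"tsv"``; inferred from the extension when omitted.

    Returns
    -------
    dict mapping gene_id to :class:`GeneModel` with internal 0-based
    half-open coordinates and bin_index in transcriptional order.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "gff" if ext in {".gff", ".gff3", ".gtf"} else "tsv"
    if format == "gff":
        raw = _read_gff_bins(path)
    elif format == "tsv":
        raw = _read_tsv_bins(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if not raw:
        logger.warning("annotation file %s contains no exon bins", path)
        return {}
    return _assemble_models(raw)


def _read_gff_bins(path: str):
    import gffutils

    with open(path, encoding="utf-8") as fh:
        has_records = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_records:
        return []
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    featuretypes = set(db.featuretypes())
    part_type = "exonic_part" if "exonic_part" in featuretypes else "exon"
    rows = []
    for feat in db.features_of_type(part_type):
        gene_id = feat.attributes.get("gene_id", [None])[0]
        if gene_id is None:
            raise ValueError(f"{path}: {part_type} record without gene_id attribute")
        number = feat.attributes.get("exonic_part_number", [None])[0]
        idx = int(number) if number is not None else None
        # GFF is 1-based inclusive; internal is 0-based half-open
        rows.append((gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand, idx))
    return rows


def _read_tsv_bins(path: str):
    df = _read_tsv(path)
    if df.empty:
        return []
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    rows = []
    for i, rec in df.iterrows():
        try:
            start, end = int(rec["start"]), int(rec["end"])
        except ValueError as exc:
            raise ValueError(
                f"{path}: non-integer coordinates on row {i + 1} "
                f"({rec['start']!r}, {rec['end']!r})"
            ) from exc
        idx = None
        if "exon_index" in df.columns and pd.notna(rec.get("exon_index")):
            idx = int(rec["exon_index"])
        rows.append((rec["gene_id"], rec["chrom"], start - 1, end, rec["strand"], idx))
    return rows


def _assemble_models(rows) -> dict[str, GeneModel]:
    by_gene: dict[str, list] = {}
    for row in rows:
        by_gene.setdefault(row[0], []).append(row)
    models: dict[str, GeneModel] = {}
    for gene_id in sorted(by_gene):
        recs = by_gene[gene_id]
        strands = {r[4] for r in recs}
        if len(strands) > 1:
            raise ValueError(f"gene {gene_id}: mixed strands {sorted(strands)}")
        strand = strands.pop()
        have_idx = [r[5] for r in recs]
        if all(i is not None for i in have_idx):
            recs = sorted(recs, key=lambda r: r[5])
            bins = [
                ExonBin(gene_id, r[5], r[1], r[2], r[3], strand) for r in recs
            ]
        else:
            bins = transcriptional_order(
                [ExonBin(gene_id, 1, r[1], r[2], r[3], strand) for r in recs], strand
            )
        try:
            models[gene_id] = GeneModel(gene_id, tuple(bins))
        except ValueError as exc:
            raise ValueError(f"invalid gene model for {gene_id}: {exc}") from exc
    return models


def write_exon_annotation(
    path: str, models: Mapping[str, GeneModel], format: str | None = None
) -> None:
    """Write gene models back out (GFF 1-based inclusive, or TSV)."""
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "gff" if ext in {".gff", ".gff3", ".gtf"} else "tsv"
    if format == "gff":
        with open(path, "w", encoding="utf-8") as fh:
            for gene_id in sorted(models):
                m = models[gene_id]
                gstart = min(e.start for e in m.exons) + 1
                gend = max(e.end for e in m.exons)
                fh.write(
                    f"{m.chrom}\tcrypticseq\taggregate_gene\t{gstart}\t{gend}\t.\t"
                    f'{m.strand}\t.\tgene_id "{gene_id}"\n'
                )
                for e in m.exons:
                    fh.write(
                        f"{e.chrom}\tcrypticseq\texonic_part\t{e.start + 1}\t{e.end}\t.\t"
                        f'{e.strand}\t.\tgene_id "{gene_id}"; '
                        f'exonic_part_number "{e.bin_index:03d}"\n'
                    )
    elif format == "tsv":
        rows = [
            {
                "gene_id": e.gene_id,
                "chrom": e.chrom,
                "start": e.start + 1,
                "end": e.end,
                "strand": e.strand,
                "exon_index": e.bin_index,
            }
            for gene_id in sorted(models)
            for e in models[gene_id].exons
        ]
        _write_tsv(path, pd.DataFrame(rows))
    else:
        raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# counts

def read_counts(
    path: str,
    models: Mapping[str, GeneModel],
    samples: pd.DataFrame,
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Read an exon-by-sample count TSV aligned to models and samples.

    Missing bins raise unless ``allow_missing`` is set (they are then simply
    absent, never zero-filled, so downstream denominators stay honest).
    """
    df = _read_tsv(path)
    if df.empty:
        raise ValueError(f"{path}: empty counts file")
    key_col = df.columns[0]
    unknown_cols = [c for c in df.columns[1:] if c not in samples.index]
    if unknown_cols:
        raise ValueError(f"{path}: unknown sample columns {unknown_cols}")
    keys = [parse_row_key(k) for k in df[key_col]]
    known = {(g, e.bin_index) for g, m in models.items() for e in m.exons}
    bad = [k for k in keys if k not in known]
    if bad:
        raise ValueError(f"{path}: count rows not in gene models: {bad[:5]}")
    values = df[df.columns[1:]].to_numpy()
    try:
        counts = values.astype(np.int64)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer count value") from exc
    if (values.astype(float) != counts).any():
        raise ValueError(f"{path}: non-integer count value")
    if (counts < 0).any():
        raise ValueError(f"{path}: negative count value")
    matrix = pd.DataFrame(
        counts,
        index=pd.MultiIndex.from_tuples(keys, names=["gene_id", "bin_index"]),
        columns=df.columns[1:].tolist(),
    )
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate count rows {dup[:5]}")
    expected = pd.MultiIndex.from_tuples(
        sorted(known), names=["gene_id", "bin_index"]
    )
    missing = expected.difference(matrix.index)
    if len(missing) and not allow_missing:
        raise ValueError(
            f"{path}: {len(missing)} exon bins from the annotation are missing "
            f"(first: {missing[:3].tolist()}); pass allow_missing=True to accept"
        )
    order = [k for k in expected if k in set(matrix.index)]
    return matrix.loc[order, list(samples.index)]


def write_counts(path: str, matrix: pd.DataFrame) -> None:
    keys = [format_row_key(g, b) for g, b in matrix.index]
    out = matrix.copy()
    out.insert(0, "feature_id", keys)
    _write_tsv(path, out)


# ---------------------------------------------------------------------------
# sample table

def read_sample_table(path: str) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"sample_id", "condition", "sex", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing sample-table columns {sorted(missing)}")
    df["replicate"] = df["replicate"].astype(int)
    table = df.set_index("sample_id")[["condition", "sex", "replicate"]]
    validate_sample_table(table)
    return table


def write_sample_table(path: str, samples: pd.DataFrame) -> None:
    _write_tsv(path, samples.reset_index())


# ---------------------------------------------------------------------------
# imported per-exon statistics (adapter for external exon-usage tools)

def read_exon_stats(
    path: str,
    column_map: Mapping[str, str],
    expressed_min_mean: float = 10.0,
) -> pd.DataFrame:
    """Adapt a per-exon statistics table from an external exon-usage tool.

    ``column_map`` maps internal names to file columns; required keys are
    ``p`` and ``log2fc`` plus either ``row_key`` or both ``gene_id`` and
    ``bin_index``.  When a ``mean_count`` column is mapped the expressed flag
    is ``mean_count > expressed_min_mean``; otherwise every exon is flagged
    expressed with a logged warning.
    """
    df = _read_tsv(path)
    if df.empty:
        raise ValueError(f"{path}: empty statistics table")
    for key in ("p", "log2fc"):
        if key not in column_map:
            raise ValueError(f"column_map must map {key!r}")
    if "row_key" in column_map:
        keys = [parse_row_key(k) for k in df[column_map["row_key"]]]
        gene_ids = [g for g, _ in keys]
        bin_idx = [b for _, b in keys]
    else:
        if "gene_id" not in column_map or "bin_index" not in column_map:
            raise ValueError("column_map must map row_key, or gene_id and bin_index")
        gene_ids = df[column_map["gene_id"]].tolist()
        bin_idx = [_parse_exon_index(v) for v in df[column_map["bin_index"]]]

    def _numeric(colkey: str) -> np.ndarray:
        col = pd.to_numeric(df[column_map[colkey]], errors="coerce")
        bad = np.nonzero(col.isna().to_numpy())[0]
        if len(bad):
            raise ValueError(
                f"{path}: unparseable {colkey} on rows {(bad + 2).tolist()[:10]}"
            )
        return col.to_numpy(dtype=float)

    p = _numeric("p")
    lfc = _numeric("log2fc")
    if ((p < 0) | (p > 1)).any():
        bad = np.nonzero((p < 0) | (p > 1))[0]
        raise ValueError(f"{path}: p outside [0, 1] on rows {(bad + 2).tolist()[:10]}")
    if "mean_count" in column_map:
        expressed = _numeric("mean_count") > expressed_min_mean
    else:
        logger.warning(
            "%s: no mean-count column mapped; flagging all exons expressed", path
        )
        expressed = np.ones(len(p), dtype=bool)
    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "bin_index": bin_idx,
            "log2fc": lfc,
            "p": p,
            "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
            "expressed": expressed,
            "source": "imported",
        }
    )
    dup = out.duplicated(subset=["gene_id", "bin_index"])
    if dup.any():
        pairs = out.loc[dup, ["gene_id", "bin_index"]].itertuples(index=False)
        raise ValueError(f"{path}: duplicate (gene, exon) rows: {list(pairs)[:5]}")
    return out.sort_values(["gene_id", "bin_index"]).reset_index(drop=True)


def _parse_exon_index(value) -> int:
    s = str(value)
    if s.startswith("E"):
        s = s[1:]
    return int(s)


# ---------------------------------------------------------------------------
# BED export

def write_cryptic_bed(path: str, calls, models: Mapping[str, GeneModel]) -> None:
    """Write one BED6 record per PASS call spanning the cryptic-TSS exon bin.

    Score is round(1000 * downstream fraction); coordinates are 0-based
    half-open; strand is the gene's.
    """
    lines = ["# crypticseq cryptic transcription start sites (BED6)"]
    for call in calls:
        if call.decision != "PASS":
            continue
        if call.gene_id not in models:
            raise ValueError(f"call references unknown gene {call.gene_id}")
        model = models[call.gene_id]
        exon = model.exons[call.ctss_index - 1]
        score = int(round(1000 * call.downstream_frac))
        lines.append(
            f"{exon.chrom}\t{exon.start}\t{exon.end}\t{call.gene_id}\t{score}\t{model.strand}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gene_list(path: str) -> set[str]:
    """Read a gene list: one id per line, '#' comments ignored."""
    out: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
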