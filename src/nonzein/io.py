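"""Readers and writers for the pipeline's plain-text formats.

Counts and result tables travel as TSV, sequences as FASTA (parsed with
Biopython), configuration as JSON.  All readers validate against the data
model and fail with coordinates, never silently.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    AbundanceTable,
    BinMap,
    ProteinCatalog,
    SpectralCountMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)


def read_counts(path: str | Path, meta_path: str | Path) -> SpectralCountMatrix:
    """Read a protein x sample count TSV plus its sample-metadata TSV.

    The count file has a header row of sample identifiers and protein
    identifiers in the first column.  The metadata file maps sample_id ->
    genotype, replicate.  Ordering from the files is preserved.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate protein identifiers {dups}")
    if counts.columns.has_duplicates:
        dups = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: header repeats sample identifiers {dups}")
    for col in counts.columns:
        if not pd.api.types.is_numeric_dtype(counts[col]):
            bad = counts[col][pd.to_numeric(counts[col], errors="coerce").isna()]
            raise ValidationError(
                f"{path}: non-numeric cell at protein {bad.index[0]!r}, sample {col!r}"
            )
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, comment="#")
    return SpectralCountMatrix(counts=counts.astype(float), sample_meta=meta)


def write_counts(matrix: SpectralCountMatrix, path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write a count matrix (and optionally its metadata) back to TSV."""
    out = matrix.counts.copy()
    if not matrix.zero_corrected:
        out = out.astype(int)
    out.to_csv(path, sep="\t", index_label="protein_id")
    if meta_path is not None:
        matrix.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def _extract_identifier(header: str, dialect: str) -> str:
    first = header.split()[0]
    if dialect == "uniprot" and "|" in first:
        parts = first.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return first


def read_fasta(path: str | Path, dialect: str = "bare") -> ProteinCatalog:
    """Read protein sequences from FASTA into a catalog.

    ``dialect`` controls identifier extraction: "uniprot" takes the middle
    token of pipe-separated headers (``sp|P24067|BIP2_MAIZE`` -> P24067);
    "bare" takes the first whitespace-delimited token.
    """
    if dialect not in ("bare", "uniprot"):
        raise ValidationError(f"unknown FASTA header dialect {dialect!r}")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = _extract_identifier(rec.description, dialect)
        if pid in records:
            raise ValidationError(f"{path}: duplicate identifier {pid!r}")
        records[pid] = str(rec.seq)
    if not records:
        raise ValidationError(f"{path}: no FASTA records")
    return ProteinCatalog(records)


def write_fasta(catalog: ProteinCatalog, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in catalog.records.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def align_inputs(
    counts: SpectralCountMatrix, catalog: ProteinCatalog
) -> SpectralCountMatrix:
    """Restrict the count matrix to proteins present in the catalog.

    Proteins without a sequence (Scaffold clusters, contaminants) are
    dropped with a warning rather than failing the run; catalog entries
    absent from the matrix are reported too.  Idempotent.
    """
    keep = [p for p in counts.counts.index if p in catalog]
    dropped = [p for p in counts.counts.index if p not in catalog]
    unused = [p for p in catalog.protein_ids if p not in counts.counts.index]
    if not keep:
        raise ValidationError("no overlap between count matrix and sequence catalog")
    if dropped:
        logger.warning(
            "dropping %d proteins without sequences (first: %s)", len(dropped), dropped[:5]
        )
    if unused:
        logger.info("%d catalog sequences unused by the count matrix", len(unused))
    return SpectralCountMatrix(
        counts=counts.counts.loc[keep],
        sample_meta=counts.sample_meta,
        zero_corrected=counts.zero_corrected,
    )


def read_bins(path: str | Path, min_bin_size: int = 3) -> BinMap:
    """Read a protein -> functional-bin TSV (columns: protein_id, bin)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: bin map needs protein_id and bin columns")
    pid_col, bin_col = df.columns[:2]
    bins: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        bins.setdefault(str(row[bin_col]), set()).add(str(row[pid_col]))
    return BinMap(bins=bins, min_bin_size=min_bin_size)


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    """Write an abundance table with a provenance header comment."""
    with open(path, "w") as fh:
        fh.write(f"# kind={table.kind} scale={table.scale!r}\n")
        table.values.to_csv(fh, sep="\t", index_label="protein_id")


def read_abundance(path: str | Path) -> AbundanceTable:
    kind, scale = "nsaf", 1.0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        fields = dict(tok.split("=", 1) for tok in first[1:].split())
        kind = fields.get("kind", kind)
        scale = float(fields.get("scale", scale))
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return AbundanceTable(values=values, scale=scale, kind=kind)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "protein_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: run configuration must be a JSON object")
    return cfg


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
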