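"""Spectral-count normalization.

The abundance proxy is the normalized spectral abundance factor (NSAF):
for protein i in sample j,

    NSAF_ij = (SpC_ij / L_i) / sum_k (SpC_kj / L_k)

where SpC is the exclusive spectral count and L the protein length in
residues.  Dividing by length corrects for the greater peptide yield of
long proteins; the column normalization corrects for per-run sampling
depth.  A small spectral fraction (default 0.05) is added to every raw
count first so that zeros survive log transformation.

Columns of NSAF and total-normalized tables sum exactly to a configurable
output scale (default 1e6, parts-per-million).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    AbundanceTable,
    ProteinCatalog,
    SpectralCountMatrix,
    ValidationError,
)


@dataclass(frozen=True)
class NormalizationConfig:
    spectral_fraction: float = 0.05
    scale: float = 1e6
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.spectral_fraction < 0:
            raise ValidationError("spectral fraction must be >= 0")
        if self.scale <= 0:
            raise ValidationError("scale must be > 0")


def add_spectral_fraction(
    counts: SpectralCountMatrix, fraction: float = 0.05
) -> SpectralCountMatrix:
    """Add a constant spectral fraction to every cell (zero-correction)."""
    if fraction < 0:
        raise ValidationError(f"spectral fraction must be >= 0, got {fraction}")
    return SpectralCountMatrix(
        counts=counts.counts + fraction,
        sample_meta=counts.sample_meta,
        zero_corrected=counts.zero_corrected or fraction > 0,
    )


def nsaf(
    counts: SpectralCountMatrix,
    catalog: ProteinCatalog,
    scale: float = 1e6,
) -> AbundanceTable:
    """Length-corrected, depth-normalized abundances (NSAF).

    Expects zero-corrected counts; every protein must have a catalog
    sequence.  Each output column sums to ``scale``.
    """
    missing = [p for p in counts.protein_ids if p not in catalog]
    if missing:
        raise ValidationError(f"proteins without sequences: {missing[:5]}")
    lengths = catalog.lengths(counts.protein_ids)
    spc_over_l = counts.counts.to_numpy(dtype=float) / lengths[:, None]
    col_sums = spc_over_l.sum(axis=0)
    if (col_sums <= 0).any():
        bad = counts.counts.columns[np.argmax(col_sums <= 0)]
        raise ValidationError(f"sample {bad!r} has zero total SpC/L; cannot normalize")
    values = pd.DataFrame(
        spc_over_l / col_sums * scale,
        index=counts.counts.index,
        columns=counts.counts.columns,
    )
    return AbundanceTable(values=values, scale=scale, kind="nsaf", sample_meta=counts.sample_meta)


def total_normalize(raw: AbundanceTable | pd.DataFrame, scale: float = 1e6) -> AbundanceTable:
    """Divide each column by its total and multiply by ``scale``.

    This is the normalization behind the per-sample relative abundances of
    the contribution analysis (raw abundance over total abundance in one
    sample).  Idempotent for a fixed scale.
    """
    if isinstance(raw, AbundanceTable):
        values, meta = raw.values, raw.sample_meta
    else:
        values, meta = raw, None
    col_sums = values.sum(axis=0)
    if (col_sums <= 0).any():
        bad = col_sums.index[col_sums <= 0][0]
        raise ValidationError(f"sample {bad!r} has non-positive column sum")
    return AbundanceTable(
        values=values / col_sums * scale, scale=scale, kind="total_normalized", sample_meta=meta
    )


def genotype_means(table: AbundanceTable, meta: pd.DataFrame | None = None) -> AbundanceTable:
    """Arithmetic mean of biological-replicate columns per genotype."""
    meta = meta if meta is not None else table.sample_meta
    if meta is None:
        raise ValidationError("genotype_means needs sample metadata")
    genotypes: list[str] = []
    cols = {}
    for sample in table.values.columns:
        if sample not in meta.index:
            raise ValidationError(f"sample {sample!r} absent from metadata")
        g = meta.loc[sample, "genotype"]
        cols.setdefault(g, []).append(sample)
        if g not in genotypes:
            genotypes.append(g)
    means = pd.DataFrame(
        {g: table.values[cols[g]].mean(axis=1) for g in genotypes},
        index=table.values.index,
    )
    return AbundanceTable(values=means, scale=table.scale, kind="genotype_mean")


def log_transform(table: AbundanceTable, base: float = 2.0) -> AbundanceTable:
    """Elementwise logarithm; requires strictly positive values."""
    arr = table.values.to_numpy()
    if (arr <= 0).any():
        r, c = np.argwhere(arr <= 0)[0]
        raise ValidationError(
            f"non-positive abundance at protein {table.values.index[r]!r}, "
            f"column {table.values.columns[c]!r}; zero-correct first"
        )
    values = pd.DataFrame(
        np.log(arr) / np.log(base), index=table.values.index, columns=table.values.columns
    )
    return AbundanceTable(values=values, scale=table.scale, kind="log", sample_meta=table.sample_meta)
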