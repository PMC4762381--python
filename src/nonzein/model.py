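"""Shared data model for the non-zein proteome analysis.

The central objects are a protein x sample spectral-count matrix with
genotype/replicate metadata, a protein sequence catalog, and normalized
abundance tables.  All tabular data is held in pandas DataFrames; the
wrapper classes enforce the invariants the downstream statistics rely on
(unique identifiers, complete metadata, non-negative values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_RESIDUES: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity codes tolerated in input sequences.  They are excluded from
#: both the numerator and the denominator of composition calculations,
#: which are defined over the 20 standard residues only.
AMBIGUITY_CODES: frozenset[str] = frozenset("BZXU")

#: The seven genotypes of the opaque endosperm study design.
DEFAULT_GENOTYPES: tuple[str, ...] = ("WT", "o1", "o2", "fl1", "fl2", "Mc", "DeB30")


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass(frozen=True)
class Contrast:
    """A mutant-vs-reference comparison with its significance thresholds.

    Significance requires p < alpha AND fold change strictly > fc_hi or
    strictly < fc_lo (a fold change of exactly 2.0 is not significant).
    """

    mutant: str
    reference: str = "WT"
    alpha: float = 0.01
    fc_hi: float = 2.0
    fc_lo: float = 0.5

    def __post_init__(self) -> None:
        if self.mutant == self.reference:
            raise ValidationError("contrast mutant and reference must differ")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not self.fc_lo < 1.0 < self.fc_hi:
            raise ValidationError(
                f"fold-change cutoffs must bracket 1: fc_lo={self.fc_lo}, fc_hi={self.fc_hi}"
            )

    @property
    def name(self) -> str:
        return f"{self.mutant}_vs_{self.reference}"


@dataclass
class SpectralCountMatrix:
    """Protein x sample spectral counts with sample metadata.

    ``counts`` is indexed by protein identifier with one column per sample.
    ``sample_meta`` is indexed by sample identifier with columns
    ``genotype`` and ``replicate``.  Raw matrices hold non-negative
    integers; after zero-correction cells carry counts + fraction.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    zero_corrected: bool = False

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein identifiers: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        missing_meta = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing_meta:
            raise ValidationError(f"samples absent from metadata: {missing_meta}")
        for col in ("genotype", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample metadata lacks required column {col!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("count matrix contains non-numeric cells")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing cell at protein {self.counts.index[r]!r}, sample {self.counts.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at protein {self.counts.index[r]!r}, sample {self.counts.columns[c]!r}"
            )
        if not self.zero_corrected and not np.allclose(values, np.round(values)):
            r, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ValidationError(
                f"non-integer raw count at protein {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genotypes(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            g = self.sample_meta.loc[s, "genotype"]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, genotype: str) -> list[str]:
        """Sample identifiers belonging to one genotype, in column order."""
        out = [
            s for s in self.counts.columns if self.sample_meta.loc[s, "genotype"] == genotype
        ]
        if not out:
            raise ValidationError(f"no samples for genotype {genotype!r}")
        return out


class ProteinCatalog:
    """Identifier -> amino-acid sequence, the source of composition values.

    Lengths and residue frequencies are computed over the 20 standard
    residues; tolerated ambiguity codes (B, Z, X, U) are retained in the
    stored sequence but ignored by composition arithmetic.
    """

    def __init__(self, records: dict[str, str]):
        if not records:
            raise ValidationError("catalog is empty")
        self.records: dict[str, str] = {}
        for pid, seq in records.items():
            seq = seq.upper()
            if not seq:
                raise ValidationError(f"empty sequence for protein {pid!r}")
            bad = set(seq) - set(STANDARD_RESIDUES) - AMBIGUITY_CODES
            if bad:
                raise ValidationError(
                    f"protein {pid!r} contains unknown residue characters {sorted(bad)}"
                )
            if pid in self.records:
                raise ValidationError(f"duplicate protein identifier {pid!r}")
            self.records[pid] = seq
        self._lengths: dict[str, int] = {
            pid: sum(seq.count(r) for r in STANDARD_RESIDUES)
            for pid, seq in self.records.items()
        }
        for pid, n in self._lengths.items():
            if n < 1:
                raise ValidationError(f"protein {pid!r} has no standard residues")

    def __contains__(self, pid: str) -> bool:
        return pid in self.records

    def __len__(self) -> int:
        return len(self.records)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.records)

    def sequence(self, pid: str) -> str:
        return self.records[pid]

    def length(self, pid: str) -> int:
        """Residue count over the 20 standard amino acids."""
        return self._lengths[pid]

    def lengths(self, pids) -> np.ndarray:
        return np.array([self.length(p) for p in pids], dtype=float)

    def residue_counts(self, pid: str) -> dict[str, int]:
        seq = self.records[pid]
        return {r: seq.count(r) for r in STANDARD_RESIDUES}

    def residue_fraction(self, pid: str, residue: str) -> float:
        """Frequency of one residue over the protein's standard-residue length."""
        if residue not in STANDARD_RESIDUES:
            raise ValidationError(f"not a standard residue: {residue!r}")
        return self.records[pid].count(residue) / self._lengths[pid]


@dataclass
class AbundanceTable:
    """Normalized abundances, per sample or per genotype mean.

    ``kind`` records the provenance: ``nsaf`` and ``total_normalized``
    columns each sum to ``scale``; ``genotype_mean`` columns are replicate
    averages and need not.
    """

    values: pd.DataFrame
    scale: float
    kind: str
    sample_meta: pd.DataFrame | None = None

    _COLUMN_SUM_KINDS = ("nsaf", "total_normalized")

    def __post_init__(self) -> None:
        if self.kind not in ("nsaf", "total_normalized", "genotype_mean", "log"):
            raise ValidationError(f"unknown abundance kind {self.kind!r}")
        arr = self.values.to_numpy()
        if self.kind != "log" and (arr < 0).any():
            raise ValidationError("abundance values must be non-negative")
        if self.kind in self._COLUMN_SUM_KINDS:
            sums = arr.sum(axis=0)
            if not np.allclose(sums, self.scale, rtol=1e-9):
                raise ValidationError(
                    f"columns of a {self.kind} table must sum to scale={self.scale}"
                )


@dataclass
class BinMap:
    """Functional-bin membership: bin label -> set of protein identifiers."""

    bins: dict[str, set[str]]
    min_bin_size: int = 3

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValidationError("bin map is empty")
        for label, members in self.bins.items():
            if not members:
                raise ValidationError(f"bin {label!r} is empty")

    @property
    def mapped_proteins(self) -> set[str]:
        out: set[str] = set()
        for members in self.bins.values():
            out |= members
        return out
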