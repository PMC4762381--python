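"""Amino-acid content of top-ranked proteins and the lysine-contribution score.

Proteome rebalancing in opaque maize mutants raises seed lysine not only
by increasing total non-zein protein but by selectively accumulating
lysine-rich proteins and depleting lysine-poor ones.  This module
quantifies that qualitative shift:

* the *pooled* percentage content of each residue in a protein set
  (residue frequency over the summed length of the set),
* the log2 ratio of up-set to down-set content per residue across a
  sweep of top-n cutoffs,
* the per-protein lysine-contribution score

      Con = (Norm_MU - Norm_WT) x (K_protein - K_avg)

  the product of the total-normalized abundance change and the protein's
  lysine-content deviation from the proteome-wide average K_avg = 5.91%.
  Con is positive when an up-regulated protein is lysine-rich or a
  down-regulated protein is lysine-poor — both shifts raise seed lysine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import top_ranked
from .model import (
    AbundanceTable,
    Contrast,
    ProteinCatalog,
    STANDARD_RESIDUES,
    ValidationError,
)

#: average lysine content of UniProt proteins, the contribution baseline
K_AVG_DEFAULT = 0.0591


@dataclass(frozen=True)
class CompositionProfile:
    """Pooled residue composition of a protein set.

    ``percent`` maps each of the 20 standard residues to
    100 x (residue frequency / total standard-residue length of the set).
    """

    percent: pd.Series
    n_proteins: int
    total_length: int

    def fraction(self, residue: str) -> float:
        return self.percent[residue] / 100.0


def composition(proteins, catalog: ProteinCatalog) -> CompositionProfile:
    """Aggregate composition of a set, pooled over concatenated sequences.

    This is the length-weighted pooling (total residue counts over total
    length), not the mean of per-protein percentages.
    """
    proteins = list(proteins)
    if not proteins:
        raise ValidationError("cannot compute composition of an empty protein set")
    counts = dict.fromkeys(STANDARD_RESIDUES, 0)
    total = 0
    for pid in proteins:
        if pid not in catalog:
            raise ValidationError(f"protein {pid!r} absent from catalog")
        for residue, c in catalog.residue_counts(pid).items():
            counts[residue] += c
        total += catalog.length(pid)
    percent = pd.Series(
        {r: 100.0 * counts[r] / total for r in STANDARD_RESIDUES}, name="percent"
    )
    return CompositionProfile(percent=percent, n_proteins=len(proteins), total_length=total)


def topn_lysine_sweep(
    diff: pd.DataFrame,
    catalog: ProteinCatalog,
    n_values=None,
    residue: str = "K",
) -> pd.DataFrame:
    """Mean residue content of up/down sets across top-n cutoffs.

    For each n, the n best-ranked proteins (ascending p_rank) are split
    by direction and the pooled content of ``residue`` computed for each
    side; the "average" column is the pooled content of every protein in
    the experiment.  Empty sides yield NaN for that cell and the sweep
    continues.
    """
    if n_values is None:
        n_values = range(10, 101, 10)
    experiment_proteins = [p for p in diff.index if p in catalog]
    overall = composition(experiment_proteins, catalog).percent[residue]
    rows = []
    for n in n_values:
        up, down = top_ranked(diff, int(n))
        up_pct = composition(up, catalog).percent[residue] if up else np.nan
        down_pct = composition(down, catalog).percent[residue] if down else np.nan
        rows.append(
            {
                "n": int(n),
                "up_percent": up_pct,
                "down_percent": down_pct,
                "average_percent": overall,
                "n_up": len(up),
                "n_down": len(down),
            }
        )
    return pd.DataFrame(rows).set_index("n")


def log2_updown_ratio(up: CompositionProfile, down: CompositionProfile) -> pd.Series:
    """Per-residue log2(up% / down%); degenerate cells are NaN, never inf."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(up.percent / down.percent)
    return ratio.replace([np.inf, -np.inf], np.nan)


def lysine_contribution(
    lysine_content: float,
    norm_ref: float,
    norm_mut: float,
    k_avg: float = K_AVG_DEFAULT,
) -> float:
    """Per-protein contribution to the mutant's lysine increase.

    Both factors are signed: the total-normalized abundance difference
    (mutant minus reference) and the lysine-content deviation from the
    proteome-average baseline.  Contents are fractions in [0, 1].
    """
    for name, value in (("lysine_content", lysine_content), ("k_avg", k_avg)):
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"{name} must be a fraction in [0, 1], got {value}")
    if norm_ref < 0 or norm_mut < 0:
        raise ValidationError("normalized abundances must be non-negative")
    return (norm_mut - norm_ref) * (lysine_content - k_avg)


def contribution_table(
    diff: pd.DataFrame,
    norm: AbundanceTable,
    catalog: ProteinCatalog,
    contrast: Contrast,
    k_avg: float = K_AVG_DEFAULT,
    top_n: int = 30,
) -> pd.DataFrame:
    """Contribution scores for the top_n best-ranked proteins of a contrast.

    ``norm`` holds total-normalized genotype means with one column per
    genotype.  Rows are grouped up-set first, each side sorted by
    descending contribution.  ``top_n = 0`` yields an empty table.
    """
    if norm.kind not in ("genotype_mean", "total_normalized"):
        raise ValidationError("contribution_table expects genotype-mean normalized abundances")
    for g in (contrast.reference, contrast.mutant):
        if g not in norm.values.columns:
            raise ValidationError(f"genotype {g!r} absent from abundance table")
    columns = ["p_rank", "lysine_pct", "norm_ref", "norm_mut", "direction", "contribution"]
    if top_n == 0:
        return pd.DataFrame(columns=columns)
    up, down = top_ranked(diff, top_n)
    rows = []
    for side, members in (("up", up), ("down", down)):
        for pid in members:
            if pid not in catalog:
                raise ValidationError(f"protein {pid!r} absent from catalog")
            lys = catalog.residue_fraction(pid, "K")
            ref_ab = float(norm.values.loc[pid, contrast.reference])
            mut_ab = float(norm.values.loc[pid, contrast.mutant])
            rows.append(
                {
                    "protein_id": pid,
                    "p_rank": float(diff.loc[pid, "p_rank"]),
                    "lysine_pct": 100.0 * lys,
                    "norm_ref": ref_ab,
                    "norm_mut": mut_ab,
                    "direction": side,
                    "contribution": lysine_contribution(lys, ref_ab, mut_ab, k_avg),
                }
            )
    out = pd.DataFrame(rows).set_index("protein_id")
    out["_side"] = (out["direction"] == "down").astype(int)
    out = out.sort_values(by=["_side", "contribution"], ascending=[True, False], kind="mergesort")
    return out.drop(columns="_side")
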