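"""Differential abundance between a mutant and the wild type.

Two complementary tests are computed per contrast:

* ``pairwise_ttest`` — two-sample t-test on log2 NSAF replicate values,
  with the fold change taken from linear genotype means.  The design is
  balanced (equal biological replicates per genotype), so the pooled
  (Student) t with n1 + n2 - 2 degrees of freedom is used by default; at
  these tiny group sizes the Welch-Satterthwaite approximation is
  measurably conservative even for normal data, while the pooled t is
  exact under normality and its statistic coincides with Welch's when
  group sizes are equal.  A protein is *significant* when p < alpha and
  the fold change is strictly above fc_hi or strictly below fc_lo.
* ``rank_by_count_test`` — a negative-binomial Wald test on the raw
  counts (library-size factors by median-of-ratios, per-protein
  dispersion by method of moments with a small floor).  Its p-values are
  used only to ORDER proteins for the amino-acid content analysis.

``top_ranked`` selects the n best-ranked proteins and splits them into
increased/decreased sets, with deterministic tie handling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model import AbundanceTable, Contrast, SpectralCountMatrix, ValidationError

#: floor on the method-of-moments NB dispersion estimate
DISPERSION_FLOOR = 0.01


def _group_columns(columns, meta: pd.DataFrame, contrast: Contrast):
    ref = [s for s in columns if meta.loc[s, "genotype"] == contrast.reference]
    mut = [s for s in columns if meta.loc[s, "genotype"] == contrast.mutant]
    if len(ref) < 2 or len(mut) < 2:
        raise ValidationError(
            f"contrast {contrast.name} needs >=2 replicates per group "
            f"(got {len(ref)} reference, {len(mut)} mutant)"
        )
    return ref, mut


def pairwise_ttest(
    table: AbundanceTable,
    contrast: Contrast,
    meta: pd.DataFrame | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """t-test per protein on log2 replicate abundances.

    ``table`` holds zero-corrected, replicate-level NSAF values on the
    linear scale; the test operates on their log2, while the fold change
    is the ratio of linear replicate means (mutant / reference).
    ``equal_var=False`` switches to Welch's variant.
    """
    meta = meta if meta is not None else table.sample_meta
    if meta is None:
        raise ValidationError("pairwise_ttest needs sample metadata")
    ref_cols, mut_cols = _group_columns(table.values.columns, meta, contrast)
    ref = table.values[ref_cols].to_numpy(dtype=float)
    mut = table.values[mut_cols].to_numpy(dtype=float)
    if (ref <= 0).any() or (mut <= 0).any():
        raise ValidationError("abundances must be positive (zero-correct first)")

    mean_ref = ref.mean(axis=1)
    mean_mut = mut.mean(axis=1)
    fold_change = mean_mut / mean_ref

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(np.log2(mut), np.log2(ref), axis=1, equal_var=equal_var)
    # constant rows in both groups give an undefined statistic: untestable
    p = np.where(np.isnan(p), 1.0, p)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)

    direction = np.where(fold_change > 1.0, "up", "down")
    significant = (p < contrast.alpha) & (
        (fold_change > contrast.fc_hi) | (fold_change < contrast.fc_lo)
    )
    return pd.DataFrame(
        {
            "mean_ref": mean_ref,
            "mean_mut": mean_mut,
            "fold_change": fold_change,
            "p_t": p,
            "direction": direction,
            "significant": significant,
        },
        index=table.values.index,
    )


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library-size factors (total-count fallback).

    The reference is the per-protein geometric mean across samples,
    restricted to proteins observed in every sample; when fewer than 10
    such proteins exist the factors fall back to scaled column totals.
    """
    positive = (counts > 0).all(axis=1)
    if positive.sum() >= 10:
        log_ref = np.log(counts[positive]).mean(axis=1)
        ratios = np.log(counts[positive]) - log_ref[:, None]
        sf = np.exp(np.median(ratios, axis=0))
    else:
        totals = counts.sum(axis=0).astype(float)
        if (totals <= 0).any():
            raise ValidationError("sample with zero total count; cannot size-normalize")
        sf = totals / np.exp(np.log(totals).mean())
    return sf


def rank_by_count_test(
    counts: SpectralCountMatrix,
    contrast: Contrast,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Negative-binomial Wald test on raw counts, for ranking.

    Counts are scaled by median-of-ratios size factors; the per-protein
    dispersion alpha (variance = mu + alpha mu^2) is estimated by pooled
    method of moments with a floor of 0.01; the Wald statistic tests the
    log ratio of group means, with a delta-method standard error.
    All-zero proteins are untestable and receive p_rank = 1.
    """
    meta = counts.sample_meta
    ref_cols, mut_cols = _group_columns(counts.counts.columns, meta, contrast)
    cols = ref_cols + mut_cols
    raw = counts.counts[cols].to_numpy(dtype=float)
    sf = _size_factors(raw)
    q = raw / sf  # size-normalized counts
    n_ref = len(ref_cols)
    q_ref, q_mut = q[:, :n_ref], q[:, n_ref:]

    m_ref = q_ref.mean(axis=1)
    m_mut = q_mut.mean(axis=1)

    # pooled within-group method-of-moments dispersion
    var_within = (q_ref.var(axis=1, ddof=1) + q_mut.var(axis=1, ddof=1)) / 2.0
    m_within = (m_ref + m_mut) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = (var_within - m_within) / np.square(m_within)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    mr = m_ref + pseudocount
    mm = m_mut + pseudocount
    log2_fc = np.log2(mm / mr)
    # delta-method variance of log(mean) for NB replicate means
    se2 = (1.0 / mr + alpha) / len(ref_cols) + (1.0 / mm + alpha) / len(mut_cols)
    z = np.log(mm / mr) / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)

    untestable = (raw.sum(axis=1) == 0) | np.isclose(m_ref, m_mut)
    p = np.where(untestable, 1.0, p)

    return pd.DataFrame(
        {
            "base_mean": q.mean(axis=1),
            "mean_ref": m_ref,
            "mean_mut": m_mut,
            "log2_fc": log2_fc,
            "p_rank": p,
            "direction": np.where(log2_fc > 0, "up", "down"),
        },
        index=counts.counts.index,
    )


def top_ranked(diff: pd.DataFrame, n: int) -> tuple[list[str], list[str]]:
    """The n proteins with smallest p_rank, partitioned by direction.

    Ties in p_rank are broken by larger |log2 fold change|, then by
    identifier, so the selection is deterministic.  Returns (up, down)
    lists whose union has exactly n members.
    """
    if not 1 <= n <= len(diff):
        raise ValidationError(f"n must lie in [1, {len(diff)}], got {n}")
    # mergesort is stable; pre-sorting by identifier gives the final tie level
    order = (
        diff.loc[sorted(diff.index)]
        .assign(_abs_lfc=lambda d: d["log2_fc"].abs())
        .sort_values(by=["p_rank", "_abs_lfc"], ascending=[True, False], kind="mergesort")
    )
    chosen = order.head(n)
    up = [p for p in chosen.index if chosen.loc[p, "direction"] == "up"]
    down = [p for p in chosen.index if chosen.loc[p, "direction"] == "down"]
    return up, down


def benjamini_hochberg(p: np.ndarray | pd.Series) -> np.ndarray:
    """Optional BH-adjusted p-values (the headline thresholds stay raw)."""
    arr = np.asarray(p, dtype=float)
    n = arr.size
    order = np.argsort(arr, kind="mergesort")
    adjusted = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, arr[idx] * n / rank)
        adjusted[idx] = running
    return adjusted
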