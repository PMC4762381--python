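"""Cross-genotype structure statistics.

* ``enrichment_score`` — the annotation-cluster score, -log10 of the
  geometric mean of member p-values (1.3 corresponds to p = 0.05).
* ``binwise_wilcoxon`` — over-representation of functional bins by a
  two-sided rank-sum test of a bin's fold changes against all other
  mapped proteins, raw p-values with no multiple-test correction.
* ``indicator_analysis`` — indicator-species analysis: for every
  genotype combination, a group-size-corrected point-biserial
  correlation between a protein's abundance vector and the combination's
  membership indicator, with a permutation p-value.
* ``pca`` / ``hcluster`` — sample-space principal components and
  average-linkage (UPGMA) clustering under the Pearson correlation
  distance 1 - r.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

from .model import AbundanceTable, BinMap, ValidationError


def enrichment_score(p_values) -> float:
    """-log10 of the geometric mean of member p-values.

    Algebraically the arithmetic mean of -log10(p_i); monotone decreasing
    in every member p-value.
    """
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        raise ValidationError("enrichment score needs at least one p-value")
    if (arr <= 0).any() or (arr > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return float(np.mean(-np.log10(arr)))


def binwise_wilcoxon(
    fold_changes: pd.Series,
    bins: BinMap,
    alpha: float = 0.05,
    exact_max_background: int = 50,
) -> pd.DataFrame:
    """Rank-sum over-representation test per functional bin.

    Each bin's member fold changes are compared two-sided against the
    fold changes of all other mapped proteins.  Exact enumeration of the
    rank-sum null is used for backgrounds up to ``exact_max_background``
    (tie-free case); larger backgrounds use the normal approximation with
    tie correction.  Bins below the minimum size are skipped.  P-values
    are raw; significance at ``alpha`` with no correction.
    """
    if not np.isfinite(fold_changes.to_numpy(dtype=float)).all():
        raise ValidationError("fold changes must be finite")
    mapped = sorted(bins.mapped_proteins & set(fold_changes.index))
    rows = []
    for label in sorted(bins.bins):
        members = sorted(bins.bins[label] & set(fold_changes.index))
        rest = [p for p in mapped if p not in bins.bins[label]]
        if len(members) < bins.min_bin_size or not rest:
            continue
        x = fold_changes.loc[members].to_numpy(dtype=float)
        y = fold_changes.loc[rest].to_numpy(dtype=float)
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        if len(rest) <= exact_max_background and not has_ties:
            method = "exact"
        else:
            method = "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        direction = float(np.median(x) - np.median(y))
        rows.append(
            {
                "bin": label,
                "size": len(members),
                "background": len(rest),
                "direction": "up" if direction > 0 else ("down" if direction < 0 else "none"),
                "p_value": float(res.pvalue),
                "significant": bool(res.pvalue < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("bin") if rows else pd.DataFrame(
        columns=["size", "background", "direction", "p_value", "significant"]
    )


# ---------------------------------------------------------------------------
# indicator species analysis


def _combination_design(labels: np.ndarray, genotypes, max_combo_size: int):
    """Weight and indicator matrices for all genotype combinations.

    For a combination, samples are weighted so the member and non-member
    sides contribute total weight 1/2 each (the unequal-group-size
    correction).  Returns (combos, W, V) with W and V of shape
    (n_samples, n_combos).
    """
    genotypes = list(genotypes)
    combos = []
    for k in range(1, max_combo_size + 1):
        for combo in itertools.combinations(genotypes, k):
            if len(combo) == len(genotypes):
                continue  # the full set carries no contrast
            combos.append(combo)
    n = labels.size
    W = np.empty((n, len(combos)))
    V = np.empty((n, len(combos)))
    for j, combo in enumerate(combos):
        member = np.isin(labels, combo)
        n_in, n_out = member.sum(), (~member).sum()
        W[:, j] = np.where(member, 0.5 / n_in, 0.5 / n_out)
        V[:, j] = member.astype(float)
    return combos, W, V


def _corrected_pointbiserial(A: np.ndarray, W: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation of each abundance row with each indicator.

    With the group-balanced weights the indicator has weighted mean 1/2
    and variance 1/4 for every combination, so
    r = 2 * cov_w(a, v) / sd_w(a).
    Rows with zero weighted variance yield NaN.
    """
    mean_a = A @ W                      # (P, C)
    e_av = A @ (W * V)                  # (P, C)
    cov = e_av - 0.5 * mean_a
    var_a = (A * A) @ W - mean_a**2
    with np.errstate(invalid="ignore", divide="ignore"):
        r = 2.0 * cov / np.sqrt(var_a)
    return r


@dataclass
class IndicatorResult:
    """Per-protein best genotype combination with permutation p-value."""

    table: pd.DataFrame
    n_permutations: int


def indicator_analysis(
    table: AbundanceTable,
    meta: pd.DataFrame | None = None,
    max_combo_size: int = 6,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
    alpha: float = 0.05,
) -> IndicatorResult:
    """Indicator-species analysis of proteins over genotype combinations.

    For each protein the group-corrected point-biserial correlation is
    evaluated against every non-empty genotype combination of size up to
    ``max_combo_size`` (never the full set); the best combination is
    reported with a permutation p-value.  The null permutes the
    sample-to-genotype assignment and recomputes the maximum statistic
    over combinations, so the p-value accounts for combination selection;
    p = (b + 1) / (n_perm + 1).  With ``exhaustive=True`` every distinct
    label arrangement is enumerated instead (small designs only) and
    p is the exact proportion of arrangements at least as extreme.
    Constant abundance vectors are reported with a missing statistic and
    p = 1.
    """
    meta = meta if meta is not None else table.sample_meta
    if meta is None:
        raise ValidationError("indicator_analysis needs sample metadata")
    samples = list(table.values.columns)
    labels = np.array([meta.loc[s, "genotype"] for s in samples])
    genotypes = list(dict.fromkeys(labels))
    if len(genotypes) < 2:
        raise ValidationError("indicator analysis needs at least 2 genotypes")
    if not exhaustive and n_perm < 99:
        raise ValidationError("need at least 99 permutations")
    max_combo_size = min(max_combo_size, len(genotypes) - 1)

    combos, W, V = _combination_design(labels, genotypes, max_combo_size)
    A = table.values.to_numpy(dtype=float)
    obs = _corrected_pointbiserial(A, W, V)
    constant = np.isnan(obs).all(axis=1)
    obs_filled = np.where(np.isnan(obs), -np.inf, obs)
    best_idx = np.argmax(obs_filled, axis=1)
    best_stat = obs_filled[np.arange(len(A)), best_idx]

    if exhaustive:
        arrangements = sorted(set(itertools.permutations(labels)))
        null_ge = np.zeros(len(A))
        for arrangement in arrangements:
            _, Wp, Vp = _combination_design(np.array(arrangement), genotypes, max_combo_size)
            stat = _corrected_pointbiserial(A, Wp, Vp)
            stat = np.where(np.isnan(stat), -np.inf, stat)
            null_ge += np.max(stat, axis=1) >= best_stat - 1e-12
        p = null_ge / len(arrangements)
        n_eff = len(arrangements)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(A))
        for _ in range(n_perm):
            perm = rng.permutation(len(samples))
            stat = _corrected_pointbiserial(A[:, perm], W, V)
            stat = np.where(np.isnan(stat), -np.inf, stat)
            exceed += np.max(stat, axis=1) >= best_stat - 1e-12
        p = (exceed + 1.0) / (n_perm + 1.0)
        n_eff = n_perm

    p = np.where(constant, 1.0, p)
    out = pd.DataFrame(
        {
            "combination": ["+".join(combos[i]) for i in best_idx],
            "statistic": np.where(constant, np.nan, best_stat),
            "p_value": p,
            "significant": (p < alpha) & ~constant,
        },
        index=table.values.index,
    )
    out.loc[constant, "combination"] = ""
    return IndicatorResult(table=out, n_permutations=n_eff)


# ---------------------------------------------------------------------------
# PCA and hierarchical clustering


def pca(
    table: AbundanceTable,
    meta: pd.DataFrame | None = None,
    scale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of samples in protein space.

    Columns of ``table`` (samples) are the observations.  Data is
    centered, optionally variance-scaled.  Returns (scores, ratios):
    scores indexed by sample with one column per component, and the
    variance-explained fractions, which sum to 1 over all components.
    """
    X = table.values.to_numpy(dtype=float).T  # samples x proteins
    if X.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    model = _SKPCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    scores = model.fit_transform(X)
    ratios = model.explained_variance_ratio_
    index = list(table.values.columns)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    out = pd.DataFrame(scores, index=index, columns=cols)
    if meta is not None:
        out.insert(0, "genotype", [meta.loc[s, "genotype"] for s in index])
    return out, ratios


@dataclass
class Dendrogram:
    """UPGMA merge tree.

    ``merges`` lists (left, right, height, new_label) in merge order,
    where left/right are leaf labels or earlier new_labels.
    """

    leaves: list[str]
    merges: list[tuple[str, str, float, str]]

    def to_newick(self) -> str:
        subtree: dict[str, tuple[str, float]] = {
            leaf: (leaf, 0.0) for leaf in self.leaves
        }
        for left, right, height, new in self.merges:
            ltxt, lh = subtree.pop(left)
            rtxt, rh = subtree.pop(right)
            node_h = height / 2.0  # ultrametric node height
            subtree[new] = (
                f"({ltxt}:{node_h - lh:.10g},{rtxt}:{node_h - rh:.10g})",
                node_h,
            )
        root, _ = next(iter(subtree.values()))
        return root + ";"

    def cophenetic(self) -> pd.DataFrame:
        """Pairwise merge heights between leaves."""
        members: dict[str, list[str]] = {leaf: [leaf] for leaf in self.leaves}
        n = len(self.leaves)
        coph = pd.DataFrame(np.zeros((n, n)), index=self.leaves, columns=self.leaves)
        for left, right, height, new in self.merges:
            for a in members[left]:
                for b in members[right]:
                    coph.loc[a, b] = coph.loc[b, a] = height
            members[new] = members.pop(left) + members.pop(right)
        return coph


def pearson_distance(values: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between columns; constant columns error."""
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    if (sd == 0).any():
        bad = values.columns[np.argmax(sd == 0)]
        raise ValidationError(f"column {bad!r} is constant; Pearson distance undefined")
    corr = np.corrcoef(arr, rowvar=False)
    return pd.DataFrame(1.0 - corr, index=values.columns, columns=values.columns)


def hcluster(table: AbundanceTable | pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of columns, distance 1 - r.

    Among equal merge distances the pair with the smallest lexicographic
    label pair is merged first, so the tree is deterministic.
    """
    values = table.values if isinstance(table, AbundanceTable) else table
    if values.shape[1] < 2:
        raise ValidationError("clustering needs at least 2 columns")
    dist = pearson_distance(values)
    labels = list(values.columns)
    # active clusters: label -> (member leaf count, distance row key)
    sizes = {lab: 1 for lab in labels}
    d = {(a, b): float(dist.loc[a, b]) for a in labels for b in labels if a < b}
    merges: list[tuple[str, str, float, str]] = []
    active = sorted(labels)
    counter = 0
    while len(active) > 1:
        best = min(
            ((a, b) for i, a in enumerate(active) for b in active[i + 1 :]),
            key=lambda ab: (d[tuple(sorted(ab))], tuple(sorted(ab))),
        )
        a, b = sorted(best)
        height = d[(a, b)]
        counter += 1
        new = f"node{counter}"
        merges.append((a, b, height, new))
        # UPGMA update: size-weighted mean of distances to the merged pair
        for c in active:
            if c in (a, b):
                continue
            dac = d[tuple(sorted((a, c)))]
            dbc = d[tuple(sorted((b, c)))]
            d[tuple(sorted((new, c)))] = (sizes[a] * dac + sizes[b] * dbc) / (
                sizes[a] + sizes[b]
            )
        sizes[new] = sizes[a] + sizes[b]
        active = sorted([c for c in active if c not in (a, b)] + [new])
    return Dendrogram(leaves=labels, merges=merges)
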