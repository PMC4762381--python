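"""End-to-end pipeline: io -> normalization -> differential -> composition
-> group statistics, with a machine-readable run summary.

The run summary records per-genotype identified-protein counts (proteins
with any nonzero raw count in that genotype), per-contrast significance
counts, checksums of every file written, and full provenance (config
echo, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import (
    K_AVG_DEFAULT,
    composition,
    contribution_table,
    log2_updown_ratio,
    topn_lysine_sweep,
)
from .differential import pairwise_ttest, rank_by_count_test, top_ranked
from .groupstats import hcluster, indicator_analysis, pca
from .io import (
    align_inputs,
    read_bins,
    read_counts,
    read_fasta,
    write_abundance,
    write_json,
    write_table,
)
from .groupstats import binwise_wilcoxon
from .model import Contrast, SpectralCountMatrix, ValidationError
from .normalize import (
    NormalizationConfig,
    add_spectral_fraction,
    genotype_means,
    log_transform,
    nsaf,
    total_normalize,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    counts_path: str
    fasta_path: str
    meta_path: str
    out_dir: str
    bins_path: str | None = None
    fasta_dialect: str = "bare"
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    reference: str = "WT"
    mutants: list[str] | None = None
    alpha: float = 0.01
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    n_values: list[int] = field(default_factory=lambda: list(range(10, 101, 10)))
    top_n: int = 30
    k_avg: float = K_AVG_DEFAULT
    run_isa: bool = True
    isa_max_combo: int = 6
    isa_n_perm: int = 999
    isa_max_proteins: int = 500
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        norm = NormalizationConfig(**d.pop("normalization", {}))
        return cls(normalization=norm, **d)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _identified_per_genotype(counts: SpectralCountMatrix) -> dict[str, int]:
    out = {}
    for g in counts.genotypes:
        cols = counts.samples_of(g)
        out[g] = int((counts.counts[cols].sum(axis=1) > 0).sum())
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run summary (also written to JSON)."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df, name, **kw):
        path = out_dir / name
        write_table(df, path, **kw)
        written.append(path)
        return path

    stage = "io"
    try:
        counts = read_counts(config.counts_path, config.meta_path)
        catalog = read_fasta(config.fasta_path, dialect=config.fasta_dialect)
        counts = align_inputs(counts, catalog)
        bins = read_bins(config.bins_path) if config.bins_path else None

        stage = "normalization"
        ncfg = config.normalization
        corrected = add_spectral_fraction(counts, ncfg.spectral_fraction)
        nsaf_table = nsaf(corrected, catalog, scale=ncfg.scale)
        nsaf_means = genotype_means(nsaf_table)
        totnorm = total_normalize(corrected.counts, scale=ncfg.scale)
        totnorm.sample_meta = counts.sample_meta
        totnorm_means = genotype_means(totnorm, counts.sample_meta)
        for tab, name in ((nsaf_table, "nsaf.tsv"), (totnorm, "total_normalized.tsv")):
            path = out_dir / name
            write_abundance(tab, path)
            written.append(path)

        mutants = config.mutants or [g for g in counts.genotypes if g != config.reference]
        contrasts = [
            Contrast(m, config.reference, config.alpha, config.fc_hi, config.fc_lo)
            for m in mutants
        ]

        stage = "differential"
        diff_tables: dict[str, pd.DataFrame] = {}
        significance_counts: dict[str, int] = {}
        for contrast in contrasts:
            ttest = pairwise_ttest(nsaf_table, contrast, counts.sample_meta)
            ranked = rank_by_count_test(counts, contrast)
            merged = ttest.join(ranked[["log2_fc", "p_rank"]])
            diff_tables[contrast.mutant] = merged
            significance_counts[contrast.name] = int(merged["significant"].sum())
            emit(merged, f"differential_{contrast.name}.tsv")

        stage = "aa_content"
        for contrast in contrasts:
            diff = diff_tables[contrast.mutant]
            n_values = [n for n in config.n_values if n <= len(diff)]
            sweep = topn_lysine_sweep(diff, catalog, n_values)
            emit(sweep, f"lysine_sweep_{contrast.name}.tsv", index_label="n")
            n_top = min(max(config.n_values), len(diff))
            up, down = top_ranked(diff, n_top)
            if up and down:
                ratios = log2_updown_ratio(
                    composition(up, catalog), composition(down, catalog)
                )
                emit(
                    ratios.to_frame("log2_up_down"),
                    f"aa_log2_ratio_{contrast.name}.tsv",
                    index_label="residue",
                )
            contrib = contribution_table(
                diff, totnorm_means, catalog, contrast, config.k_avg, config.top_n
            )
            emit(contrib, f"contribution_{contrast.name}.tsv")

        stage = "group_stats"
        if bins is not None:
            for contrast in contrasts:
                fc = diff_tables[contrast.mutant]["fold_change"]
                emit(
                    binwise_wilcoxon(fc, bins),
                    f"bins_{contrast.name}.tsv",
                    index_label="bin",
                )
        scores, ratios = pca(nsaf_table, counts.sample_meta)
        emit(scores, f"pca_scores.tsv", index_label="sample_id")
        write_json(
            {"variance_explained": ratios.tolist()}, out_dir / "pca_variance.json"
        )
        written.append(out_dir / "pca_variance.json")
        tree = hcluster(nsaf_means.values)
        (out_dir / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
        written.append(out_dir / "dendrogram.nwk")
        isa_summary = None
        if config.run_isa:
            # ISA is quadratic in permutations x combinations; restrict to the
            # most variable proteins to keep desk-scale runs fast
            variances = nsaf_table.values.var(axis=1)
            keep = variances.sort_values(ascending=False).index[: config.isa_max_proteins]
            sub = nsaf_table.values.loc[keep]
            from .model import AbundanceTable

            isa = indicator_analysis(
                AbundanceTable(sub, nsaf_table.scale, "genotype_mean", counts.sample_meta),
                counts.sample_meta,
                max_combo_size=config.isa_max_combo,
                n_perm=config.isa_n_perm,
                seed=config.seed,
            )
            emit(isa.table, "indicator_analysis.tsv")
            sig = isa.table[isa.table["significant"]]
            isa_summary = {
                "n_tested": int(len(isa.table)),
                "n_significant": int(len(sig)),
                "by_combination_size": {
                    str(k): int(v)
                    for k, v in sig["combination"]
                    .str.count(r"\+")
                    .add(1)
                    .value_counts()
                    .sort_index()
                    .items()
                },
            }
    except ValidationError as err:
        raise ValidationError(f"stage {stage!r} failed: {err}") from err

    summary = {
        "version": __version__,
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 2),
        "n_proteins": len(counts.protein_ids),
        "n_samples": len(counts.sample_ids),
        "identified_per_genotype": _identified_per_genotype(counts),
        "significant_per_contrast": significance_counts,
        "isa": isa_summary,
        "pca_variance_explained": ratios.tolist(),
        "config": {
            "spectral_fraction": config.normalization.spectral_fraction,
            "scale": config.normalization.scale,
            "alpha": config.alpha,
            "fc_hi": config.fc_hi,
            "fc_lo": config.fc_lo,
            "k_avg": config.k_avg,
            "top_n": config.top_n,
            "reference": config.reference,
        },
        "outputs": {p.name: _checksum(p) for p in written},
    }
    write_json(summary, out_dir / "run_summary.json")
    return summary
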