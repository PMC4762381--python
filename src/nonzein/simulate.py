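"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the shape of a label-free spectral-counting study
of maize endosperm: ~2000 proteins across 7 genotypes (wild type plus
six opaque mutants) with 4 biological replicates each; overdispersed
negative-binomial counts with many zeros; spectral yield increasing with
protein length; and a planted *rebalancing* effect in selected mutant
genotypes, where a protein's log2 abundance shift is coupled to its
lysine-content deviation from the proteome average (lysine-rich proteins
up, lysine-poor "zein-like" proteins suppressed).

Identical seeds reproduce identical FASTA/TSV bytes.

``table1_fixture`` returns the printed top-contributor rows (lysine
content, normalized WT/mutant abundances, contribution score) used as a
golden reference for the contribution arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_GENOTYPES,
    ProteinCatalog,
    SpectralCountMatrix,
    STANDARD_RESIDUES,
    ValidationError,
)

#: Swiss-Prot-like background residue frequencies (fractions), used for
#: the 19 non-lysine residues; lysine is pinned per protein.
BACKGROUND_FREQUENCIES = {
    "A": 0.0825, "C": 0.0138, "D": 0.0545, "E": 0.0672, "F": 0.0386,
    "G": 0.0707, "H": 0.0227, "I": 0.0591, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0393, "R": 0.0553,
    "S": 0.0663, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}

#: default per-genotype coupling between lysine deviation and log2 effect;
#: strong rebalancing in o2/fl2, moderate in the UPR mutants Mc/DeB30,
#: none in o1/fl1, mirroring the study's phenotypic groups
DEFAULT_COUPLING = {
    "WT": 0.0, "o1": 0.0, "fl1": 0.0,
    "o2": 30.0, "fl2": 25.0, "Mc": 15.0, "DeB30": 15.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of the generator."""

    n_proteins: int = 2000
    genotypes: tuple[str, ...] = DEFAULT_GENOTYPES
    n_replicates: int = 4
    mean_count: float = 10.0          # expected raw count of a median protein
    dispersion: float = 0.3           # NB alpha: var = mu + alpha mu^2
    zero_inflation: float = 0.2       # dropout probability of a near-limit cell
    dropout_scale: float = 10.0       # expected-count scale of the detection limit
    abundance_log2_sd: float = 1.5    # protein-to-protein abundance spread
    libsize_log2_sd: float = 0.2      # sample library-size spread
    lysine_mean: float = 0.0591
    lysine_sd: float = 0.025
    coupling: dict = field(default_factory=lambda: dict(DEFAULT_COUPLING))
    zein_like_fraction: float = 0.05
    zein_like_lysine: float = 0.005
    zein_like_log2_suppression: float = 3.0
    length_median: float = 350.0
    length_log_sd: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if not 0 <= self.zero_inflation < 1:
            raise ValidationError("zero_inflation must lie in [0, 1)")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        # coupling entries for genotypes outside the design are simply unused


def protein_truth(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic per-protein ground truth derived from the seed.

    Columns: assigned lysine content (fraction), standard-residue length,
    zein-like flag, and base log2 abundance.  Both the catalog and the
    count simulator derive from this table, so they are consistent.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_proteins
    pids = [f"SYN{i:05d}" for i in range(n)]
    n_zein = int(round(config.zein_like_fraction * n))
    zein_like = np.zeros(n, dtype=bool)
    zein_like[rng.choice(n, size=n_zein, replace=False)] = True
    lysine = rng.normal(config.lysine_mean, config.lysine_sd, size=n)
    lysine = np.clip(lysine, 0.002, 0.30)
    lysine[zein_like] = config.zein_like_lysine
    lengths = np.maximum(
        30,
        np.round(
            np.exp(rng.normal(np.log(config.length_median), config.length_log_sd, size=n))
        ).astype(int),
    )
    # spectral observability grows with length; extra lognormal spread
    base_log2 = (
        np.log2(config.mean_count)
        + np.log2(lengths / config.length_median)
        + rng.normal(0.0, config.abundance_log2_sd, size=n)
    )
    return pd.DataFrame(
        {
            "lysine_content": lysine,
            "length": lengths,
            "zein_like": zein_like,
            "base_log2": base_log2,
        },
        index=pd.Index(pids, name="protein_id"),
    )


def simulate_catalog(config: SimulationConfig) -> ProteinCatalog:
    """Protein sequences whose lysine frequency equals the assigned content.

    The 19 non-lysine residues follow Dirichlet-perturbed background
    frequencies renormalized to 1 - content, so only the lysine
    coordinate is controlled.
    """
    truth = protein_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    others = [r for r in STANDARD_RESIDUES if r != "K"]
    bg = np.array([BACKGROUND_FREQUENCIES[r] for r in others])
    bg = bg / bg.sum()
    records: dict[str, str] = {}
    residues = np.array(others)
    for pid, row in truth.iterrows():
        k = float(row["lysine_content"])
        length = int(row["length"])
        probs = rng.dirichlet(bg * 200.0) * (1.0 - k)
        full_probs = np.concatenate([[k], probs])
        seq_idx = rng.choice(len(full_probs), size=length, p=full_probs)
        seq = "".join("K" if i == 0 else residues[i - 1] for i in seq_idx)
        records[pid] = seq
    return ProteinCatalog(records)


def _sample_ids(config: SimulationConfig) -> tuple[list[str], pd.DataFrame]:
    samples, rows = [], []
    for g in config.genotypes:
        for r in range(1, config.n_replicates + 1):
            sid = f"{g}_r{r}"
            samples.append(sid)
            rows.append({"sample_id": sid, "genotype": g, "replicate": r})
    meta = pd.DataFrame(rows).set_index("sample_id")
    return samples, meta


def simulate_counts(
    config: SimulationConfig, catalog: ProteinCatalog | None = None
) -> SpectralCountMatrix:
    """Overdispersed spectral counts with planted rebalancing effects.

    Expected count of protein i in a sample of genotype g:

        mu = libsize * 2^(base_log2_i + coupling_g * (K_i - 0.0591)
                          - suppression * [zein-like and coupling_g > 0])

    drawn negative-binomially (variance mu + alpha mu^2).  Dropout is
    detection-limit-driven: a cell is zeroed with probability
    zero_inflation * exp(-mu / dropout_scale), so missingness
    concentrates in low-abundance proteins as in real label-free data
    and abundant proteins are never spuriously absent.  The catalog
    argument only checks consistency; the truth table drives effects.
    """
    truth = protein_truth(config)
    if catalog is not None:
        missing = [p for p in truth.index if p not in catalog]
        if missing:
            raise ValidationError(f"catalog lacks simulated proteins: {missing[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    samples, meta = _sample_ids(config)
    libsize = 2.0 ** rng.normal(0.0, config.libsize_log2_sd, size=len(samples))
    base = truth["base_log2"].to_numpy()
    dev = truth["lysine_content"].to_numpy() - 0.0591
    zein = truth["zein_like"].to_numpy()

    mu = np.empty((config.n_proteins, len(samples)))
    for j, sid in enumerate(samples):
        g = meta.loc[sid, "genotype"]
        coupling = float(config.coupling.get(g, 0.0))
        effect = coupling * dev
        if coupling > 0:
            effect = effect - config.zein_like_log2_suppression * zein
        mu[:, j] = libsize[j] * 2.0 ** (base + effect)

    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    if config.zero_inflation > 0:
        p_drop = config.zero_inflation * np.exp(-mu / config.dropout_scale)
        counts = np.where(rng.random(counts.shape) < p_drop, 0, counts)
    df = pd.DataFrame(counts.astype(int), index=truth.index, columns=samples)
    return SpectralCountMatrix(counts=df.astype(float), sample_meta=meta)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[SpectralCountMatrix, ProteinCatalog, pd.DataFrame]:
    """Convenience wrapper: (counts, catalog, truth) from one config."""
    catalog = simulate_catalog(config)
    counts = simulate_counts(config, catalog)
    return counts, catalog, protein_truth(config)


# ---------------------------------------------------------------------------
# printed reference rows for the contribution arithmetic

_TABLE1_TSV = """\
block\tprotein_id\tdescription\tp_value\tlysine_pct\tnorm_wt\tnorm_mut\tcon
Up_o2\tC5XX52\tGlyceraldehyde-3-phosphate dehydrogenase\t1.17e-05\t8.31\t1434.91\t3561.00\t51.03
Up_o2\tB6SHW9\tUbiquitin fusion protein\t8.13e-04\t13.18\t307.84\t549.44\t17.56
Up_o2\tB4FAL9\tFructose-bisphosphate aldolase\t9.88e-06\t8.45\t853.65\t1313.69\t11.68
Up_o2\tB4FT23\t14-3-3-like protein\t1.05e-05\t7.54\t934.66\t1551.91\t10.06
Up_o2\tC0PHR4\tAdenosylhomocysteinase\t1.69e-04\t7.63\t393.92\t933.63\t9.28
Down_o2\tB6SIX6\tProlamin PPROL 17\t6.02e-09\t0.56\t198.48\t6.89\t10.25
Down_o2\tP04698\tZein-alpha PZ22.3\t2.99e-10\t0.37\t192.40\t23.41\t9.36
Down_o2\tB6SI09\tAquaporin TIP3.1\t5.57e-06\t1.12\t229.87\t53.70\t8.44
Down_o2\tB6SJ53\t22kDa alpha-zein\t3.00e-07\t0.38\t95.19\t5.51\t4.96
Down_o2\tB6TIK6\tSarcosine oxidase\t4.02e-11\t3.13\t179.24\t24.79\t4.29
Up_fl2\tB6TNF1\tCalnexin\t5.01e-19\t11.61\t91.14\t504.55\t23.56
Up_fl2\tP24067\tLuminal-binding protein 2\t1.73e-16\t9.35\t325.06\t910.99\t20.16
Up_fl2\tA5A5E7\tProtein disulfide isomerase\t1.13e-05\t9.36\t930.61\t1512.57\t20.08
Up_fl2\tB4FT23\t14-3-3-like protein\t1.81e-07\t7.54\t934.66\t1624.69\t11.25
Up_fl2\tQ5EUD5\tProtein disulfide isomerase\t4.24e-21\t8.66\t89.11\t448.49\t9.88
Down_fl2\tQ09HU3\tTrypsin inhibitor (fragment)\t7.18e-11\t1.57\t747.33\t141.23\t26.30
Down_fl2\tQ946V2\tLegumin 1\t5.14e-12\t2.48\t1094.66\t416.15\t23.27
Down_fl2\tQ43706\tSucrose synthase\t6.57e-07\t5.15\t1581.74\t635.00\t7.20
Down_fl2\tB6TIK6\tSarcosine oxidase\t1.71e-15\t3.13\t179.24\t1.08\t4.95
Down_fl2\tC0LNQ9\tUDP-glucosyltransferase\t1.48e-06\t2.34\t179.24\t60.37\t4.24
"""


def table1_fixture() -> pd.DataFrame:
    """The printed top-contributor rows (golden reference).

    Twenty rows in four blocks (Up/Down for the o2 and fl2 contrasts)
    with lysine content in percent, total-normalized WT and mutant
    abundances, and the published contribution score ``con``.
    """
    return pd.read_csv(StringIO(_TABLE1_TSV), sep="\t")
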