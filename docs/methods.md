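# Methods

## Abundance model

Label-free spectral counting treats the number of exclusive MS/MS spectra
assigned to a protein (SpC) as a proxy for its abundance. Two corrections
are applied. First, longer proteins yield more tryptic peptides and hence
more spectra, so counts are divided by the protein length L in residues.
Second, runs differ in sampling depth, so each sample column is divided by
its total SpC/L. The result is the normalized spectral abundance factor

    NSAF_ij = (SpC_ij / L_i) / Σ_k (SpC_kj / L_k),

reported on a configurable column scale (default 10^6, i.e. ppm). Before
normalization a spectral fraction of 0.05 is added to every cell so that
proteins undetected in a run keep a finite log abundance. The fraction is
added to raw per-replicate counts *before* NSAF and before replicate
averaging; replicate averaging acts on NSAF values. Whether the upstream
acquisition software applies the fraction before or after its internal
normalization is not knowable from the outside; the order here is fixed,
documented, and configurable (`NormalizationConfig.spectral_fraction`).

Lengths are counted over the 20 standard residues. The ambiguity codes
B, Z, X, U are tolerated in input sequences but excluded from both the
numerator and denominator of every composition calculation, which are
defined over the standard alphabet.

The total-normalized abundance (`total_normalize`) divides a column by its
sum without the length correction; it is the scale on which the
contribution score (below) is defined.

## Differential abundance

Each mutant is compared with the wild type on two parallel tracks.

**Significance calls** use a two-sample t-test on log2 NSAF replicate
values, with the fold change computed from linear replicate means.
A protein is significant when p < alpha (default 0.01) and the fold change
is strictly greater than 2 or strictly less than 0.5. The design is
balanced (equal biological replicates per genotype), so the pooled
(Student) t with n1+n2-2 degrees of freedom is the default: at n = 4 per
group the Welch–Satterthwaite degrees-of-freedom approximation is
measurably conservative even on exactly normal data (rejection ~0.006 at
nominal 0.01 in simulation), whereas the pooled t is exact under normality
and shares Welch's statistic when group sizes are equal. Welch's variant
remains available via `equal_var=False` for unbalanced designs.

**Ranking** for the amino-acid content analysis uses a negative-binomial
Wald test on the raw counts: per-sample size factors by median-of-ratios
(falling back to scaled totals when fewer than 10 proteins are observed in
every sample), a pooled within-group method-of-moments dispersion estimate
alpha with floor 0.01 (variance = mu + alpha mu^2), and a Wald statistic
on the log ratio of group means with a delta-method standard error and a
0.5 pseudocount. This test exists to *order* proteins by evidence of
change — its p-values are never interpreted as calibrated significance
levels, and no attempt is made to reproduce any particular external
count-model implementation. All-zero and exactly-tied proteins receive
p = 1 (untestable), never NaN.

Raw p-value thresholds are used throughout, matching the published
procedure (no correction was applied there either); a Benjamini–Hochberg
column is available for users who want it.

Ties in the ranking are broken by larger |log2 fold change|, then by
identifier, so `top_ranked` is deterministic and nested
(top_ranked(n) ⊆ top_ranked(n+k)).

## Amino-acid content and the contribution score

The composition of a protein set is *pooled*: residue counts are summed
over the concatenated sequences and divided by the summed length — the
length-weighted mean of per-protein compositions, not their plain mean.
For each top-n cutoff (default n = 10, 20, …, 100), the n best-ranked
proteins are split into increased and decreased sets and the pooled lysine
content of each side is compared with the pooled content of all proteins
in the experiment (the "average" curve). Per-residue log2(up%/down%)
ratios use the same pooled profiles; a residue absent from the denominator
set yields a missing value, never infinity and never a fabricated
pseudo-count.

The per-protein lysine-contribution score is

    Con = (Norm_MU − Norm_WT) × (K − K_avg),

the product of the total-normalized abundance change and the protein's
lysine-content deviation from the proteome-wide average K_avg = 5.91%
(0.0591 as a fraction). K_avg is a configurable constant, not recomputed
from any sequence database. Con is positive exactly when the change is
lysine-enriching: an up-regulated lysine-rich protein, or a down-regulated
lysine-poor one. The score is linear in the normalization scale
(doubling the scale doubles every contribution), so comparisons are only
meaningful within one scale; the package verifies the arithmetic against
the twenty published reference rows, which it reproduces within ±0.02
(the slack covers rounding of the printed inputs).

## Grouping statistics

**Enrichment score.** For an annotation cluster with member p-values p_i,
the score is −log10 of their geometric mean, equal to the arithmetic mean
of −log10 p_i; 1.3 corresponds to p = 0.05.

**Bin-wise over-representation.** Each functional bin's fold changes are
compared against all other mapped proteins with a two-sided rank-sum test:
exact enumeration of the null when the background is ≤ 50 and tie-free,
otherwise the normal approximation with tie correction. Minimum bin size
3; smaller bins are skipped with a log note. P-values are raw and
significance is at 0.05, with no multiple-test correction, mirroring the
published procedure.

**Indicator-species analysis.** For every genotype combination of size 1
to `max_combo_size` (default 6 of 7; never the full set, which carries no
contrast), the association between a protein's abundance vector and the
combination is the *group-size-corrected point-biserial correlation*: a
weighted Pearson correlation between abundance and the 0/1 membership
indicator in which member and non-member samples each receive total weight
1/2 (weight 1/(2·n_in) or 1/(2·n_out) per sample). With these weights the
indicator has weighted mean 1/2 and variance 1/4, so
r = 2·cov_w(a, v)/sd_w(a). The best combination per protein is reported
with a permutation p-value: sample-to-genotype assignments are permuted
(samples, not genotypes, are the permutation units) and the *maximum*
statistic over all combinations is recomputed each time, so the p-value
accounts for the selection of the best combination and is super-uniform
under the null; p = (b + 1)/(n_perm + 1) with n_perm ≥ 99 (default 999)
and a mandatory seed. An exhaustive mode enumerates every distinct label
arrangement for small designs and is used as its own oracle in tests.
Constant abundance vectors are reported with a missing statistic and
p = 1. Because cost grows as proteins × permutations × combinations, the
pipeline applies ISA to the most variable proteins (default 500) — a
problem-size choice, configurable via `isa_max_proteins`.

**PCA** treats samples as observations in protein space, centered but not
variance-scaled by default (abundances share units; scaling is a flag).
Variance-explained fractions sum to 1 over all retained components.

**Hierarchical clustering** of samples or genotype means uses the
distance 1 − r (Pearson) and average linkage (UPGMA). The implementation
is written out rather than delegated so that equal merge distances are
broken deterministically by the smallest lexicographic label pair; an
established average-linkage implementation serves as the independent
cross-check in the test suite. The dendrogram exports to Newick with
ultrametric branch lengths (leaf-to-node height = merge distance / 2).

## Synthetic-data generator

The generator emulates the deposited study's *structure* so the pipeline
can be exercised end to end: 7 genotypes (WT, o1, o2, fl1, fl2, Mc,
DeB30) × 4 biological replicates, default 2000 proteins. Per protein it
draws a length (log-normal, median 350 residues), a lysine content
(normal, mean 0.0591, sd 0.025, clipped to [0.002, 0.30]), and a base
abundance whose expected count scales with length (longer proteins yield
more spectra — so NSAF's length correction is genuinely exercised) around
a median count of 10 with 1.5 log2 units of protein-to-protein spread.
A 5% subset of "zein-like" proteins is pinned to 0.5% lysine. Sequences
draw residues i.i.d. with the lysine probability pinned to the assigned
content and the other 19 residues following Dirichlet-perturbed
background frequencies, so only the quantity the analysis measures is
controlled.

Counts are negative binomial (dispersion alpha = 0.3; variance
mu + alpha·mu²) with log-normal library-size factors (sd 0.2 log2 units).
The planted rebalancing effect in genotype g shifts a protein's log2
abundance by coupling_g × (K − 0.0591), with defaults 30 (o2), 25 (fl2),
15 (Mc, DeB30), 0 (o1, fl1) — chosen so the strongest planted effects
reach the 2–30-fold range observed for top-ranked proteins in real
rebalancing contrasts — plus a uniform 3-log2 suppression of the
zein-like subset in coupled genotypes. Missingness is detection-limit
driven: a cell is zeroed with probability 0.2 × exp(−mu/10), so dropout
concentrates in sparsely observed proteins, as in real label-free data,
and abundant proteins are never spuriously absent. Identical seeds
reproduce identical FASTA/TSV bytes.

What the generator does *not* emulate: peptide-level digestion and
ionization efficiency, shared-peptide protein inference, correlated
protein modules, or compositional coupling beyond lysine. Passing tests
therefore demonstrate that the statistics recover the planted
lysine–abundance structure under realistic count noise — not that they
would behave identically on any particular real dataset.

## Calibration findings and limitations

Under the null generator (no coupling, 2000 proteins, 4 vs 4), the
pooled-t rejection rate at p < 0.01 is ~0.007 rather than 0.010. The
shortfall is confined to sparsely observed proteins: stratifying by mean
raw count, proteins with mean ≥ 20 reject at ~0.0098, while the 5–20
band rejects at ~0.0055 because dropout zeros map to log2(0.05) outliers
that inflate the within-group variance. This mild conservativeness is a
property of t-testing log-transformed, zero-corrected counts at n = 4 —
the procedure itself — and should be kept in mind when interpreting
significance counts near the threshold. The count-based ranking test is
similarly approximate and is used only for ordering.

Numerical conventions: p-values are clipped into (0, 1]; fold changes are
always finite because means are computed on zero-corrected values;
degenerate cells in ratio outputs are missing values, never ±inf;
permutation p-values use the add-one rule so they are never 0.

Problem sizes in the shipped tests and examples (300–2000 proteins,
99–999 permutations, 20-seed replications) were chosen to exercise every
code path at desk scale while keeping the default suite fast.
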