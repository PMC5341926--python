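# Methods

This note documents the statistical model behind `lfqdelta`, the
choices made where the workflow's conventions are genuinely open, and
the limits of what the synthetic-data tests demonstrate.

## The data model

A label-free experiment arrives as a protein-group × sample intensity
matrix with an explicit missingness mask. Intensities are treated as
log-normal: all modeling happens on the log2 scale, and a zero in a
MaxQuant-style table is "not quantified", never a measured zero. The
`QuantMatrix` container carries a stage flag (`raw → log2 → imputed →
zscored`) and refuses out-of-order operations, because the stages are
not interchangeable: filtering counts valid values before imputation,
tests run on the imputed matrix, and z-scoring exists only to put
protein profiles on a common scale for clustering.

## Preprocessing

**Valid-value filter.** A protein is kept iff it has at least
`min_valid` (default 3) quantified values in at least one experimental
group. With three replicates per group this demands a complete profile
in some condition — proteins quantified only sporadically carry no
testable signal.

**Imputation.** Missing LFQ values are assumed missing-not-at-random:
the protein fell near or below the detection limit. Each masked cell in
column *c* is replaced by a draw from

    Normal(m_c − d·s_c, (w·s_c)²),   defaults d = 1.8, w = 0.3,

where m_c, s_c are the mean and SD of the column's *observed* values
(computed before any imputation). The defaults are the de-facto
standard of this workflow style; both are configurable. Imputation is
performed once, immediately after filtering, and the downstream tests
see imputed values as ordinary data (their q-values inherit whatever
error the imputation model makes — see Limitations). Columns need at
least two observed values; unmasked cells are never touched, and the
returned matrix records which cells were imputed.

**z-scoring** uses the population SD (divisor n). The convention
matters because clustering distances scale with it, so it is fixed
rather than left to a library default.

## Moderated statistics and permutation FDR

The pairwise statistic is d = Δ/(se + s0) with Δ the log2 fold change
and se the pooled two-sample standard error; s0 ≥ 0 (default 0.5)
prevents proteins with minuscule variance from reaching huge
significance at negligible fold change. At s0 = 0, d is exactly the
classical pooled t (tested to 1e-10). The multi-group statistic is
F′ = MS_between/(√MS_within + s0)², the classical one-way F at the
default s0 = 0.

Parametric p-values (t reference with n_A + n_B − 2 df; F reference
with k − 1, N − k df) are reported for volcano plots only; significance
calls come exclusively from the permutation q-values.

The FDR estimator is the SAM-style plug-in without a π0 multiplier:
candidate thresholds at the observed |d| values (ties share a
threshold), FDR(t) = min(1, V̄(t)/R(t)) with V̄ the mean permutation
exceedance count, q-values as the running minimum over thresholds so
they are monotone in |d|, and the significance cutoff c\* the smallest
observed |d| with q ≤ q\*. Permutations are column-wise — one label
reassignment shared by all proteins — because the null hypothesis being
simulated is "sample labels are arbitrary", and per-protein shuffling
would destroy the correlation structure that makes V̄ honest.

**Exclusion of observed-equivalent relabelings.** The null set excludes
the observed assignment, its mirror in a two-group contrast (identical
|d|), and any multi-group labeling that induces the observed partition
of samples. Including them adds the observed rejections themselves to
V̄ at every threshold: in a 3-vs-3 design FDR(t) would be at least
2/20 = 0.1 everywhere and *no protein could ever be significant at a 5%
FDR* — the workflow would be powerless in exactly the minimal balanced
designs it is routinely applied to, which visibly produce hundreds of
significant proteins in practice. Exhaustive enumeration therefore
triggers when the count of distinct reassignments (C(6,3) = 20 for
3-vs-3) is within the permutation budget, and then uses the 18
informative splits; Monte-Carlo mode rejection-samples uniformly from
the same set.

**The granularity limit this buys.** A 3-vs-3 contrast has only 10
distinct unordered splits. Under a *global null* (no affected proteins
at all), the procedure rejects precisely when the observed split
dominates the other nine — probability exactly 1/10 by exchangeability
— so the realized false-discovery proportion concentrates near 0.10
for any q\* below 1/18, not at q\*. This is intrinsic: any permutation
procedure over 10 distinct splits has a global-null family-wise floor
of 1/10 if it can reject at all. The `scripts/acceptance.py` output
shows this honestly (t1 ≈ 0.10). With more samples the granularity
vanishes (the three-group test, with 1,680 distinct partitions and 250
Monte-Carlo draws, calibrates at ≈ 0.05), and under realistic
alternatives (many true positives) the estimator's conservatism—true
effects inflate V̄ under permuted labels—pushes the realized FDP among
rejections down, not up.

## Structure analysis

PCA treats samples as observations and proteins as centered,
unscaled variables; scores are checked against a brute-force
eigendecomposition oracle in the tests. The Pearson correlogram
reports the full sample × sample matrix plus group-pair averages
(within-group averages exclude the diagonal). Hierarchical clustering
of z-scored profiles uses Euclidean distance with average linkage by
default (complete and Ward available) and cuts the tree into exactly k
clusters (default 6, a config parameter with no claim of optimality);
scipy's deterministic nearest-neighbor-chain agglomeration makes runs
reproducible for a given input order.

Concordance classification takes the multi-group-significant proteins
and labels each by the sign of its log2 fold change under the two
treatments versus control: concordant-up, concordant-down, or
discordant; an exactly zero fold change lands in a separate
"undirected" bucket. Direction is taken from the fold-change sign
regardless of per-contrast significance (the classified set was already
selected by the multi-group test); an option gates direction on the
per-contrast call instead.

## Enrichment

Terms are intersected with the universe (default: all gene symbols of
the filtered, quantified matrix — the detectable proteome is the
correct background for a proteomics query; a whole-genome universe can
be supplied instead). Significance is the exact two-sided
hypergeometric probability as the doubled smaller tail capped at 1 —
the simple, conservative resolution of "two-sided" for a discrete
statistic (minimum-likelihood two-sided is a noted alternative, not
implemented). Terms with overlap < 2 genes or coverage < 10% are
filtered before Holm (Bonferroni step-down) adjustment, which runs only
across the passing terms. Ontology-tree-level selection is out of
scope; an optional term-size window (K_min, K_max) is the flat
replacement. Gene symbols match by exact uppercase string; no alias
resolution.

## The synthetic-data generator

The generator emulates the statistical structure of a three-condition
LFQ experiment, with defaults chosen to mirror a typical study design:

| parameter | default | meaning |
|---|---|---|
| n_proteins | 2,000 | quantified proteome scale (study-scale ~5,600 available by config; 2,000 preserves the multiple-testing regime at test speed) |
| groups | CTR/IFNG/IL27 × 3 | three biological replicates per condition |
| baseline_mean, baseline_sd | 25, 2 (log2) | typical MaxQuant LFQ intensity scale |
| noise_sd | 0.3 (log2) | replicate scatter |
| affected_fraction | 0.10 | proteins receiving a treatment effect |
| effect magnitude | Uniform(1, 3) log2, random sign | clearly detectable shifts at n = 3 |
| concordance_fraction | 0.8 | probability the two treatments share direction |
| missing_midpoint, missing_slope | 21, 1.0 | logistic MNAR: P(missing) = 1/(1+exp(slope·(x − midpoint))) |

A cell's log2 value is baseline + group effect + noise; export is on
the linear scale (2^x) so the reader's zero-masking and log2 path is
exercised. Missingness is logistic in intensity rather than a hard
detection threshold, deliberately: the downshifted-normal imputation is
then neither exactly right nor absurd, matching real LFQ data where
imputation is an approximation. The ground-truth object records every
baseline, effect, concordance class and masked cell, and a helper
builds gene-set collections with one term spiked with affected genes
plus uniform decoys.

What the generator does **not** emulate: peptide-level quantification
and shared-peptide protein inference, intensity-dependent variance
(noise is homoscedastic on the log2 scale), batch effects, and
correlated protein modules beyond what treatment effects induce.
Passing tests on this generator therefore demonstrate the pipeline's
statistical correctness under its stated model, not robustness to every
real-data pathology.

## Numerical and reproducibility choices

- A single config seed drives a `SeedSequence` that spawns independent
  child seeds for imputation, the multi-group test and each contrast;
  identical config + inputs give byte-identical result tables (floats
  are written with 17 significant digits, which round-trips doubles).
- Monte-Carlo permutation draws are uniform over admissible
  relabelings via rejection sampling; enumeration order is the
  lexicographic combination order, so both modes are deterministic.
- se = 0 cases: d = 0 and p = 1 when Δ = 0; p = 0 (and finite d via
  s0) when Δ ≠ 0; an error only when s0 = 0 would leave d undefined.
- Holm adjustment follows the step-down formula directly and is
  cross-checked against statsmodels in the tests.
- Null-calibration simulations (`scripts/acceptance.py`, the FDR tests)
  use *complete* null data. With MNAR missingness a global-null dataset
  measures the imputation artifact instead (see Limitations), not the
  test.

## Known limitations

- **Imputation-driven false positives.** Under MNAR missingness, a
  protein that by chance has complete values in one group and imputed
  (down-shifted) values in the other acquires a large artificial fold
  change that label permutation cannot calibrate — the permutation null
  assumes exchangeable columns, and group-structured missingness breaks
  that. On simulated global-null data with default missingness the
  realized FDP of the pairwise test rises to ~0.6. This is a real
  property of the downshifted-imputation workflow, worth remembering
  when a hit's values are mostly imputed; the per-cell `imputed_mask`
  is retained so such hits can be audited.
- **3-vs-3 granularity.** See above: q-values in a 3-vs-3 contrast take
  at most ~10 effective levels, and global-null FDP concentrates at
  1/10 rather than q*.
- **No Welch option.** The pooled-variance statistic assumes equal
  group variances; unequal-variance designs are out of scope.
- Plot methods (`plot_volcano`, `plot_pca`) are best-effort
  conveniences and intentionally untested.
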