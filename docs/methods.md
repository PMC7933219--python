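# Methods

## Setting

The package implements the desk side of a two-condition transcriptome
study: human umbilical vein endothelial cells alone (EC) versus the same
cells after prostate tumor-cell adhesion (TC-EC), profiled on a log2-scale
expression microarray that carries both coding mRNAs and long non-coding
RNAs.  Input matrices are assumed RMA-normalized upstream (log2, complete,
no missing cells); normalization itself is out of scope.  The deposited
array data are not required: a synthetic generator reproduces the
statistical structure the analysis assumes, with ground truth for recovery
tests.

## Differential expression

Per feature, log2 fold change is the difference of condition means on the
log2 data (not a ratio of antilogs).  Significance uses the two-sided
pooled-variance Student's t-test (Welch behind a flag), with
Benjamini–Hochberg step-up FDR across features.  The FDR procedure is not
named in the original description beyond "FDR"; BH is used as the standard
microarray default.  A feature is a DEG iff P < 0.05 AND FDR < 0.05 AND
|log2FC| > 1, all strict, matching the study's stated filter.  Degenerate
features (zero pooled variance) get p = 1 when group means agree and p = 0
(logged) when they differ.

## Co-expression networks and |Diffk|

Within each condition, pairwise Pearson correlation (Spearman optional) is
computed over a user-selected feature set; an edge is kept iff
|r| >= threshold.  The threshold is an explicit, recorded parameter; the
default is 0.8, a common hard-threshold choice for log2 array data.
Zero-variance features have undefined correlations and never form edges.
With <= 2 samples per condition every correlation is ±1; the code warns
loudly and proceeds.

Differential connectivity of feature g between networks A and B is

    |Diffk|(g) = | k_A(g) / kmax_A − k_B(g) / kmax_B |

where kmax is the maximum node degree of each network.  The normalization
is validated rather than assumed: `infer_normalizers` exhaustively
searches integer (kmax_A, kmax_B) pairs and shows that (36, 45) is the
unique pair reproducing all ten published (k_EC, k_TC-EC, |Diffk|) rows of
the reference table to their printed 3 decimals (the EC maximum, 36,
appears in the table itself; the TC-EC maximum, 45, is recovered by the
search).  Features missing from one network take degree 0 there (absence
means no retained edges); whether the original networks shared a node
universe is unstated, so this union-with-zero convention is documented as
ours.  Ranking is descending |Diffk|, ties broken by larger |k_A − k_B|,
then feature id — deterministic, so tied printed rows (e.g. DGAT1 /
ST6GALNAC3 at 0.733) may order differently than in the source table.
Comparisons against printed values round half-up to 3 decimals; computed
values are otherwise kept at full precision.

## Interaction-network hubs

Degree and betweenness centrality are the two hub indicators on
user-supplied edge lists (SIF or TSV), treated as undirected and
unweighted.  Betweenness uses Brandes' algorithm; normalized values divide
by (n−1)(n−2)/2, consistent with the sub-0.01 magnitudes of the published
hub table.  Disconnected pairs contribute nothing.  The published
pathway-derived edge list is not reconstructible (external database), so
those printed values are treated as non-reproducible; the implementation
is instead verified against exhaustive shortest-path enumeration on small
random graphs.

## miRNA targets

Target-set intersection reports the common set and all 2^k − 1 exclusive
Venn region counts; the published per-database counts (67/372/1715, 26
common) are database-version-dependent and are exercised only as sizes in
the arithmetic.  The seed scanner classifies canonical sites on a 5'→3'
UTR (DNA or RNA, U/T equivalent, N never matches): with the seed hexamer
(reverse complement of miRNA nt 2–7) anchored at a locus, pairing of the
adjacent base to miRNA nt 8 and/or an A across from nt 1 upgrade the site
to 7mer-m8, 7mer-A1, or 8mer; one site (the longest applicable) is
reported per hexamer locus; coordinates are 1-based inclusive.  The
published PRKAA2 3'UTR positions (6166–6172, 6893–6899) require the UTR
sequence itself; `analysis/07_mirna_targets.py --utr-fasta` scans a
user-supplied FASTA to check them.

## Enrichment

Over-representation uses the one-sided (upper-tail) hypergeometric test
against user-supplied GMT sets, intersected with the universe first, with
BH FDR across sets and a strict −log10(p) filter.  This deliberately does
not replicate DAVID's EASE-modified score.

## Validation arithmetic

2^−ΔΔCt quantification references each sample's ΔCt (target − reference
gene) to the *mean* ΔCt of the control group (per-pair referencing is the
other convention; the source does not state one), so the control group's
mean log2 fold is exactly 0.  Dual-luciferase activity is firefly/Renilla
per well, normalized to the control group's mean ratio.  Group comparisons
are the two-tailed pooled t-test (2 groups) or one-way ANOVA (more).

## Synthetic data generator

Per feature g and sample s:

    x_gs = mu_g + beta_g·I[s in B] + lambda_g(c(s))·f_{m(g),s} + eps_gs

with mu_g ~ N(8, 1.5) log2 units, DE effects beta_g ~ ±N(2.0, 0.5) on a
random 5% of features (chosen to mirror the 1.2–4.7 |log2FC| range of the
published DEG tables and a typical array DE rate), module factors
f ~ N(0,1) per (module, sample), loading 1.0 for module members, noise
eps ~ N(0, 1).  Default scale: 2,000 features (10% non-coding ids in the
lncRNA "n######" style), 20 samples/condition (larger than a typical
3-replicate array design, deliberately, so recovery tests have power), 10
modules of 25 members, 10 rewired hubs.  Rewiring is loading knock-out
(lambda = 0) in one condition — the mechanism that reproduces the
published pattern of hub degrees collapsing from the ~30s to single digits
— rather than a sign flip.  All draws flow from one seeded generator, so
runs are byte-reproducible.

What the generator emulates: mean shifts, latent-factor co-expression,
condition-specific decoupling of single features.  What it does not:
probe-level noise, batch effects, heavy-tailed intensities, correlated DE,
count (RNA-seq) sampling.  Passing recovery tests therefore show the
statistics behave as designed under their own assumptions, not that the
original biological conclusions are reproduced.

### A known sensitivity: hub recovery under a hard |r| >= 0.8 rule

With loading 1.0 and noise 1.0 the population correlation between two
members of the same module is lambda²/(lambda² + sigma²) = 0.5.  At n = 20
samples per condition the Fisher-z sampling spread of r is ≈ 0.24, so
P(sample r >= 0.8 | rho = 0.5) ≈ 0.01: a hub's expected wired-condition
degree under the default 0.8 edge rule is ~0.3 of its 24 possible
within-module edges, and the thresholded networks contain essentially no
module structure.  Top-|Diffk| recovery of planted hubs under these exact
settings therefore fails, and the corresponding end-to-end test is
expected to fail; `analysis/04_coexpression_rewiring.py` prints the
measured recovery.  Recovering hubs at this sample size requires either a
lower threshold (below the population within-module correlation, at the
cost of a dense background) or a stronger loading (loading 2.0 puts the
population correlation exactly at 0.8).  The defaults are kept as the
documented study conditions rather than tuned.

## Numerical choices

- BH is computed via statsmodels' `fdr_bh`; tests verify it against a
  direct step-up implementation.
- Betweenness via networkx (Brandes); verified against brute-force path
  enumeration.
- Correlations via `numpy.corrcoef` (rank-transformed for Spearman),
  clipped to [−1, 1] against rounding.
- Rounding for printed-value comparison: 3 decimals, half-up.
- Ties everywhere break deterministically (documented per function).

## Problem sizes

Recovery and calibration analyses run at 2,000 features × 40 samples with
20 seeded replicates; oracle-equivalence checks use 200 random graphs
(≤ 7 nodes), 1,000 random p-vectors, 500 random UTRs (100–5,000 nt) and
1,000 random qPCR/luciferase tables.  These sizes were chosen as the
smallest at which the Monte-Carlo error of each check is well below its
tolerance.
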