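# Methods

This note records the models behind each pipeline stage, the parameters
that matter, the numerical conventions, and what the synthetic data does
and does not emulate.

## Domain detection

The kinase-domain screen reduces a full profile-HMM architecture to a
position-specific log-odds profile with affine gap penalties. The screen's
job here is presence/absence detection of one well-conserved domain family,
for which the discriminative content lives in the match-state emission
odds; transition probabilities add little and cost determinism and speed at
desk scale.

**Profile construction.** Columns of the seed alignment with less than 50%
occupancy are dropped. Per retained column `i` and residue `a` the match
score is `log2((c_ia + w·bg_a) / (n_i + w) / bg_a)` — counts with a
background-proportional pseudocount of total weight `w` (default 1),
against background frequencies estimated from the seed with Laplace
smoothing. The wildcard X scores 0 bits everywhere (neutral: no evidence
for or against). Gap penalties default to 5.0 bits open, 0.5 bits extend;
the planted synthetic domains carry no indels, so these only have to be
large enough that random gapped paths never out-score direct matches.

**Alignment mode.** Scanning uses *glocal* dynamic programming: the entire
profile must be consumed, any substring of the protein may carry it, and
sequence prefix/suffix are free. Insertion and deletion states are affine;
transitions between the two gap states are disallowed (the standard
three-state recurrence). Traceback ties resolve in the fixed order
match > deletion > insertion, so identical inputs always give identical
hits. Multiple domains are recovered greedily: best hit first, its
residues masked, repeat until the E-value cutoff fails.

**E-value calibration.** Karlin–Altschul-style statistics are fitted
empirically once per profile: 1,000 background-distributed random sequences
of 400 residues are scanned (fixed internal seed 20831), a Gumbel law is
fitted to the score maxima, and its location/scale give
`lambda = 1/scale` and `K = exp(loc/scale)/(400·L)`. The reported bit
score is `lambda·raw/ln 2`, and `E = K·m·L·2^(−bits)` for a search of `m`
residues. By construction a random sequence's best hit sits near `E ≈ 1`,
which the calibration-sanity test checks. The screening cutoff defaults to
`E ≤ 10⁻²` — deliberately non-stringent, since classification applies a far
stricter threshold downstream.

## Homology classification

Detected domains are aligned to every entry of the labeled reference
catalog with Smith–Waterman local alignment (Biopython's `PairwiseAligner`;
BLOSUM62, gap open 11, extend 1 — the classic protein-search defaults).
E-values use the published gapped-regime constants `lambda = 0.267`,
`K = 0.041`. The best hit is the minimum E-value, ties broken by bit score
then lexicographic subject id, which makes the result invariant to catalog
order. Labels transfer at `E ≤ 10⁻¹⁰`; the species-specific threshold
equals the classification cutoff (no separate band). A protein whose
distinct domains (distinct scan intervals) each confidently hit different
groups is flagged ambiguous for phylogenetic resolution. Annotation
reconciliation at `E ≤ 10⁻²` only annotates notes ("annotation improved" /
"kinase call not supported"); it never changes labels.

## Phylogenetic reclassification

Maximum-likelihood inference is deliberately replaced by distance methods:
each domain is aligned independently to the profile match states (giving a
shared column space; insertions relative to the profile are discarded),
columns under 80% occupancy are removed — an explicit, deterministic
stand-in for manual alignment curation — and a neighbor-joining tree is
built. Distances are p-distance or the Kimura protein correction
`d = −ln(1 − p − p²/5)`, computed over columns where both rows are non-gap
and capped (default 10, with a warning) when `p ≥ 0.85` where the
correction diverges.

NJ follows Saitou–Nei exactly: join the pair minimizing
`Q(i,j) = (n−2)·D(i,j) − ΣD(i,·) − ΣD(j,·)`, ties broken by the smallest
index pair; branch lengths by the standard split formula with negative
estimates clamped to zero and the deficit moved to the sibling (at the
final trifurcation, clamped only). On additive matrices this recovers the
generating tree exactly, which the suite verifies against path-length
matrices and against scikit-bio's independent NJ.

Bootstrap support resamples alignment columns with replacement
(deterministic per seed), rebuilds, and counts bipartitions, encoded
rooting-independently as the side of each internal edge not containing the
lexicographically smallest leaf. Note that supports are only guaranteed
invariant to leaf-order permutation when pairwise distances are distinct;
replicates of degenerate alignments can tie, and ties resolve by index.

Clade-based relabeling roots the tree on the designated outgroup, then
gives each unlabeled leaf the majority label of its smallest enclosing
clade with at least `k = 3` labeled leaves and bootstrap support at least
`s = 50` (both configurable; majority ties break lexicographically). In a
tree without support annotation every clade passes the support gate; in an
annotated tree, clades without a value (e.g. the root) do not.
Reclassification is only ever applied to ambiguous or species-specific
proteins — a homology-supported label is never overwritten.

## Expression mining

**RPKM** is `10⁹·count/(library_size·length_bp)` with the library size
taken as total mapped reads (not the column sum). Genes below 1 RPKM are
non-expressed; the boundary value 1.0 counts as expressed.

**TMM.** The scaling factor between two samples excludes genes zero in
either, trims the top and bottom 30% by `M = log2((x/Nx)/(r/Nr))` and 5%
by `A = ½·log2(x·r/(Nx·Nr))`, and returns `2**` of the mean of the
surviving M values weighted by inverse delta-method variances
`1/x − 1/Nx + 1/r − 1/Nr`. A sample against itself gives exactly 1. For a
multi-sample matrix the reference is the sample whose upper quartile of
depth-scaled counts is closest to the mean upper quartile; for a single
contrast the factor is computed directly between treatment and control and
multiplies the treatment's effective library size.

**Differential expression.** Conditional on `x` reads in library 1, the
count in library 2 follows the Audic–Claverie distribution
`P(Y=y|x) = (N2/N1)^y (x+y)! / (x!·y!·(1+N2/N1)^(x+y+1))` — negative
binomial with `x+1` successes and success probability `N1/(N1+N2)`. The
two-sided p-value doubles the smaller of the lower tail `P(Y≤y)` and the
*strict* upper tail `P(Y>y)`. These two tails are exact complements of the
swapped-library tails (an incomplete-beta identity), so the p-value is
exactly exchangeable between the two libraries — the inclusive-tail variant
is not, which is why the strict tail was chosen. A gene with zero counts in
both libraries carries no information and gets p = 1 by convention.
Per contrast, p-values are Benjamini–Hochberg adjusted; a call requires
adjusted p ≤ alpha (default 0.001) and a normalized rate ratio of at least
2-fold. These defaults are declared, not inferred from the source
transcriptome study, which does not state its thresholds.

## Tabulation conventions

Percentages round half-away-from-zero (Decimal arithmetic), the convention
consistent with printed figures such as 47.7→48, 18.87→19, 92.7→93 and
1.42→1.4. One printed figure (salinity, 35/371 = 9.43% printed as 9.5%) is
inconsistent with every rounding rule tried and is excluded from the
reproduced quantities. The in-text STE count (29) conflicts with the
tabulated 28; the tabulation fixtures follow the table. Up/down aggregation
across a stressor's timepoints and tissues is a gene-level union per
direction, so one gene may legitimately appear on both sides; this also
reconciles the thermal-stress text count (53) with the temperature column
sums (21 + 31 = 52) if one gene switched direction across timepoints.

## Synthetic data

The proteome generator plants one mutated copy of a per-group consensus
domain (shipped synthetic fixtures: 120 residues, 10 groups, pairwise
identity ≤ 60%, all derived from one master sequence so a single profile
detects every group) inside uniform-random flanks of 50–400 residues;
decoys are background-random sequences. The count generator draws gene
lengths uniformly in [500, 5000] bp, expressed baselines log-uniformly in
[2, 200] RPKM, silent genes below 0.5 RPKM, and nests expression across
stages via one uniform draw per gene compared to per-stage expressed
fractions (defaults follow the developmental series 70%…93%). DE genes are
chosen among control-expressed genes and scaled by folds from the
configured range; counts are Poisson.

What this does *not* emulate: overdispersed (negative-binomial) counts —
the generator matches the DE test's own Poisson model, so the power and
type-I results characterize the statistic under its assumptions, not its
robustness; sequence indels inside planted domains; compositional biases or
homology between decoys and real non-kinase domain families. Passing tests
therefore demonstrate correct implementation and calibrated behaviour under
the stated model, not performance on real proteomes or real RNA-seq.

## Problem sizes

The test and acceptance runs use a 100-kinase + 50-decoy proteome at 15%
domain mutation, 2,000-gene null and recovery simulations, bootstrap at
25–100 replicates on 12-leaf alignments, and 1,000-sequence score
calibration — sizes chosen so the full suite completes in well under a
minute per stage while keeping binomial standard errors small relative to
the thresholds being checked (e.g. ±1% on a 2,000-gene type-I rate).

## Known limitations

- The profile scan has no insert-state emission model; long insertions
  inside a domain are penalized linearly and can split a hit in two.
- Karlin–Altschul constants for the local aligner are fixed published
  values, not recalibrated per matrix; E-values are comparative, not
  frequentist guarantees.
- NJ tie-breaking by index makes degenerate-distance topologies dependent
  on input order (see above).
- TMM here is the two-sample factor; no library-size-adaptive trimming
  refinements are applied.
- The DE test assumes Poisson sampling with no biological replication;
  replicate-aware negative-binomial modelling is out of scope.
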