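# Methods

## Problem and pipeline

`il2kit` classifies MHC-presented peptides as IL-2 inducers or non-inducers
and localises inducing regions in proteins. The pipeline is: curate a
labeled peptide pool → hold out 20% for external validation → compute
sequence descriptors → grid-search a classical classifier under 5-fold
stratified cross-validation (ROC AUC objective) → mine discriminative
motifs from the training split → combine model probability and motif
evidence into a hybrid score.

## Curation and splitting

Curation keeps lengths in [8, 25] (the range suitable for MHC antigen
processing) and removes redundancy: exact, case-insensitive sequence
duplicates across both classes, first occurrence kept. A sequence observed
with both labels is contradictory evidence and is dropped entirely,
reported as a conflict rather than a duplicate.

Split sizes follow |test| = round(ratio·N) with half-up rounding, train =
remainder; this reproduces both published pairs 5259/1315 (N=6574) and
5486/1372 (N=6858). One published table prints 5487+1372 for a 6858-peptide
set, which is arithmetically inconsistent (sums to 6859); the toolkit keeps
its single rounding rule. Splits are stratified by label by default (class
test counts by largest-remainder apportionment) with seed 42; the original
protocol states neither stratification nor a seed, so both are explicit,
reproducible choices here.

## Descriptors

Composition sets (AAC, DPC) are percentages; DPC_LEN appends the raw
residue count, unscaled. The remaining families have no published closed
form, so the following definitions are fixed and versioned (group/class
tables ship as editable CSVs under `il2kit/data/`, so they can be swapped
wholesale for parity with any external descriptor server):

- **CTD (147)** — the classical 7-property, 3-group partitions
  (hydrophobicity, van der Waals volume, polarity, polarizability, charge,
  secondary-structure propensity, solvent accessibility). Per property:
  3 group compositions, 3 between-group transition percentages (of the L−1
  adjacent pairs), and per group the positions of the first, 25%, 50%, 75%
  and last occurrence as % of L (ceil-indexing into the occurrence list;
  zeros when a group is absent).
- **PCP (29)** — percent membership in 29 binary physicochemical classes
  (charge, polarity, size, aromaticity, propensities, accessibility, …).
- **DDR (20)** — 100·(last − first occurrence index)/L per residue, i.e.
  the summed gaps between successive occurrences; 0 for ≤1 occurrence.
- **RRI (20)** — Σ(run length²)/L over maximal runs per residue
  (e.g. "AAAC": RRI_A = 9/4).
- **AAB (320)** — one-hot profile of the 8 N-terminal and 8 C-terminal
  positions. Windows are defined independently and overlap for peptides
  shorter than 16; the C window is anchored at the C terminus, and
  positions beyond a short peptide's span stay all-zero (no padding
  symbol).

## Motif mining

Motifs are contiguous symbol strings; each symbol is a literal residue or a
group from the active classification scheme (NONE = 20 singletons;
BETTS-RUSSELL = polar/hydrophobic/small, overlapping; KOOLMAN = aliphatic/
aromatic/sulfur/hydroxyl/basic/acidic+amide/imino). Mixed residue/class
symbols are allowed; gapped motifs are not (every published motif of
interest is contiguous).

The miner runs breadth-first from single symbols, extending rightward,
maintaining occurrence posting lists. Support is the number of distinct
positive sequences containing the pattern (sequence-count, not
occurrence-count), which is anti-monotone under extension and is the
pruning criterion (`min_pos`, default 2% of the positive set — the original
support threshold is unpublished, so it is exposed as a parameter). A
pattern is emitted when its support ≥ `min_pos` and it occurs in ≤ `fp`
negative sequences; `fp` is not used for pruning (it is not monotone in a
useful direction), only for emission. Output ordering: positive count
descending, then shorter length, then lexicographic symbols. `max_len`
defaults to 7, the longest motif of interest. The test suite checks the
miner against a brute-force enumerator on dozens of random small instances
across all three schemes.

## Models and evaluation

Eight algorithms (decision tree, random forest, extra trees, k-NN,
multi-layer perceptron, RBF-kernel SVM as a probability-calibrated
classifier, XGBoost, L1-penalised logistic regression) share one protocol:
exhaustive search over a small documented grid (default grids in
`models.DEFAULT_GRIDS`; the original grids are unpublished), mean ROC AUC
over 5 stratified folds, best point refit on all training rows.
Scale-sensitive models (KNN, MLP, SVM, logistic) are standardised inside
the CV pipeline. Training rows are internally sorted by record id before
the seeded fold shuffle, so results are invariant to input row order.

Metrics: sensitivity, specificity and MCC on their natural scales,
accuracy in percent, AUC as the rank-based Mann-Whitney statistic with
ties counted ½. MCC returns 0 when any denominator factor vanishes.
Thresholding counts a score exactly at the threshold (default 0.5) as a
positive call.

Feature selection: mRMR (greedy relevance-minus-mean-redundancy, mutual
information on decile-discretised columns), L1 (absolute coefficients of a
linear SVM whose penalty budget is grown until ≥ k features survive), RFE
(extra-trees ranker, 10% elimination per step), and impurity importance
from an extra-trees ensemble — the last is a transparent, deterministic
stand-in for model-explanation scores, whose exact values are library- and
version-dependent while the downstream quantity of interest is only the
selected subset.

The BLAST annotator shells out to NCBI `blastp-short` (database built with
`makeblastdb`), drops self-hits by id, takes the first remaining hit per
query and book-keeps correct/incorrect positive/negative annotations.

## Hybrid scoring

final = clamp(base + 0.5·[any inducer-motif hit] − 0.5·[any non-inducer-
motif hit], 0, 1). The published rule adds/subtracts 0.5 from a probability
without stating range handling; clamping keeps the probability reading and
is the default (configurable). Hits do not stack. The classification
threshold on the final score defaults to 0.5.

## Synthetic data

The generator emulates three statistical features of curated IL-2 peptide
sets: (1) lengths on [8, 25] with a mode at 15, via a discrete
Laplace-shaped weight exp(−|L−15|/2.5) — unimodal with realistic spread;
(2) class-biased composition — inducers up-weight A/F/L/P/Y and
non-inducers up-weight C/D/T by a factor 2 over uniform, roughly doubling
mean composition, the effect-size scale seen in class-wise composition
contrasts; (3) a 7-mer motif (default ALEGSLQ) overwriting a uniform random
offset in 60% of positives — overwriting rather than inserting preserves
the length distribution. Duplicates are rejected and redrawn so curation
is a no-op on synthetic data. Defaults are 400 peptides per class.

What the generator does **not** emulate: MHC-allele structure and binding
biology, positional anchor preferences, host-organism composition biases,
label noise, and homology clusters (every peptide is drawn independently).
Passing tests on this data therefore demonstrate that the machinery —
descriptors, miner, CV protocol, hybrid rule — behaves correctly on data
with the assumed statistical structure, not that the published real-data
performance is reproduced; that requires the originally deposited dataset.

## Problem sizes and numerical choices

The validation suite and the acceptance script run at 400 peptides per
class with an 80:20 split (640 train / 160 test), ten seeded replicates
for stochastic claims, and 50+ random tiny instances for the miner-oracle
equivalence — sizes at which every stage's behaviour is already stable and
the planted signal is comfortably detectable. Two-sample t-tests on 0/1
positional indicators with zero variance in both groups report p = 1 for
equal means and p = 0 for unequal means (perfect separation). BH adjustment
uses the standard step-up. All randomness flows through explicit integer
seeds; trained models, splits, mining and CSV outputs are bit-reproducible
under a fixed seed.

## Known limitations

- Descriptor definitions for PCP/DDR/RRI/CTD are explicit stand-ins for an
  external descriptor server's unpublished formulas; swap the data tables
  for exact parity if needed.
- Deep and language-model classifiers are out of scope, as are gapped
  motifs, motif p-values, and learned (rather than fixed ±0.5) motif
  weights.
- The hybrid adjustment can leave AUC unchanged when the base classifier
  already captures the motif's composition signal; its benefit is a
  majority-of-seeds property, not a per-dataset guarantee.
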