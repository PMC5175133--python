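# Methods

This note records what each stage of `profam` computes, the defaults and why
they were chosen, and what the synthetic-data studies do and do not
demonstrate.

## Sequence handling

Feature extraction and distance computation assume the 20 canonical
amino-acid letters. Database-derived sequences routinely contain ambiguity
codes, so every read passes through a sanitization policy. The default,
`map-common`, applies the conventional substitutions B→N, Z→Q, U→C, O→K,
J→L and drops the remaining placeholders (X, `*`); `error` and
`drop-residue` are available for stricter workflows. Sanitization is
idempotent under every policy. Record ids are the first whitespace-delimited
header token and must be unique within a dataset.

## Redundancy removal

Clustering is the classic greedy incremental scheme: sort by length
(descending, stable), then each sequence joins the first cluster whose
*representative* it matches at ≥ threshold (default 0.90), else founds a new
cluster. Only representative comparisons are made, so representatives end up
pairwise below the threshold and the result is deterministic for a fixed
input order.

Identity is `matches / len(shorter)` where `matches` is the maximum number
of identical aligned pairs in a global alignment scored match = +1,
mismatch = 0, gap = 0 (equivalently, the longest common subsequence). A
composition prefilter skips pairs whose residue-count overlap
`Σ_a min(count_x(a), count_y(a))` — an exact upper bound on the match
count — cannot reach the threshold. Because the bound is exact, the
prefilter can only skip comparisons that would have failed anyway: it
changes speed, never results. (A shared-k-mer filter was rejected: a single
insertion every k−1 residues yields identity 1.0 with no shared k-mer, so
k-mer screening cannot guarantee result invariance under this identity
definition.)

## 188D features

The 188D vector is AAC (alphabetical A..Y) followed by 21 CTD features for
each of 8 physicochemical properties, in a fixed documented order
(composition C1–C3, transitions T12, T13, T23, then for each class the five
distribution quantiles: first, 25 %, 50 %, 75 %, last occurrence position
divided by L). Conventions:

- Distribution quantile index: `ceil(q·n_g)` (1-based); all five features are
  0 for an absent class. Values are fractions in [0, 1], not percentages.
- Transitions count unordered adjacent cross-class pairs over L−1; length-1
  sequences get zeros rather than an error (datasets should filter such
  sequences upstream — 188D extraction itself requires L ≥ 2).
- The 3-class property partitions are the canonical CTD groupings shipped as
  auditable constants in `ctd_groupings.py`. Published variants differ
  slightly in the surface-tension partition; the shipped one
  (GQDNAHR / KTSEC / ILMFPWYV) is the variant used by the common
  188D implementations, and users can substitute their own partition (the
  module validates the partition axioms).

Correctness is established against an independently coded brute-force
extractor (plain loops and dictionaries, no shared code) on random sequences
of lengths 2–500, plus the block laws: composition blocks sum to 1,
transition blocks sum to ≤ 1, distribution blocks are non-decreasing within
class.

## SMOTE

`percent` follows the Weka-filter convention this pipeline is modelled on:
`percent=700` *adds* `7n` synthetic rows to an n-row minority class (total
8n). k = 5 neighbours by Euclidean distance on raw feature values (no
scaling), with n−1 used when n−1 < k. Each synthetic point is verified in
tests to lie on the segment between its parent and one of that parent's k
nearest neighbours, and the count law `|synthetic| = floor(percent/100)·n`
holds exactly. Generation is deterministic given the seed.

## Cross-validation protocols

Two protocols are provided because they answer different questions:

- `within-fold` (default): SMOTE is applied to each training split only.
  Synthetic points never influence the fold they are tested in; the pooled
  confusion matrix covers exactly the original instances.
- `paper-mode`: the whole dataset is oversampled first and then folded —
  the workbench-style oversample-then-cross-validate workflow. It is
  optimistic, because synthetic points interpolated from test-fold
  originals can appear in training folds, and its confusion-matrix totals
  include the synthetic instances. It exists to reproduce results produced
  under that protocol, and the two modes coincide when no oversampling is
  requested.

Folds are stratified with a logged seed. When a class is smaller than the
fold count (e.g. leave-one-out) and no within-fold SMOTE is requested, plain
shuffled K-fold is used instead so every instance is still scored exactly
once; with within-fold SMOTE this situation is an error, since a training
split could lose the minority class. The forest itself is scikit-learn's
`RandomForestClassifier` (bootstrap trees, `sqrt(d)` features per split,
majority vote; vote fraction as the score) — the contract tested is the
ensemble behaviour, not the tree internals. Per-fold seeds are derived as
`seed + fold_index` so folds are independent but reproducible.

## Metrics

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/N, and MCC with the usual
convention MCC = 0 when any factor under the square root vanishes. Sn/Sp
raise on undefined denominators rather than guessing. Metrics are reported
as fractions and as one-decimal percentages. AUC uses the rank-sum identity
`P(s⁺ > s⁻) + ½P(tie)` with midranks, which equals tie-aware trapezoidal
integration of the empirical ROC curve (asserted to 1e-12 in tests).

## Phylogeny

p-distance is the proportion of differing sites over comparable sites.
`pairwise-deletion` (default — the common default of the desktop tree
programs for this distance) compares per-pair gap-free columns;
`complete-deletion` drops every column containing any gap first. A pair with
no comparable sites is an error (or, inside a bootstrap replicate, drops the
replicate — see below).

Neighbor joining is the standard Saitou–Nei agglomeration with Q-matrix
selection, tie-broken toward the lowest index pair for determinism. Negative
limb lengths are clamped to zero with the deficit moved to the sister limb
(preserving the pair's summed length), the standard remedy. NJ is exact on
additive matrices; the test suite verifies topology and all pairwise path
lengths to 1e-9 on 50 random additive trees of 4–12 taxa, and cross-checks
topology against an independent NJ implementation.

Midpoint rooting places the root halfway along the longest leaf-to-leaf
path; diameter ties are resolved by the lexicographically first leaf-name
pair, and an all-zero-length tree roots on the first preorder edge, so the
operation is deterministic. Bootstrap supports resample alignment columns
with replacement (L columns per replicate), rebuild the NJ tree, and report
for each internal edge of the reference tree the fraction of successful
replicates containing the same leaf bipartition. Degenerate replicates (a
pair with no comparable sites) are dropped and counted, not errored —
with 500 replicates a handful of drops barely widens the support's
uncertainty, whereas aborting would discard the whole analysis.

## qPCR statistics

Relative expression is 2^−ΔCt with ΔCt = Ct_target − Ct_reference, both
measured within the same sample. Group comparison reports per-group mean and
standard error of 2^−ΔCt and an unpaired two-sided Mann–Whitney U test
(U = #{x > y} + ½ #ties). For pooled sizes ≤ 16 the p-value is exact, by
enumerating all C(m+n, m) label arrangements via the midrank-sum identity
`U = Σ ranks(x) − m(m+1)/2` (valid under ties); larger samples use the
normal approximation with tie-corrected variance and a 0.5 continuity
correction. Two-sided p is `min(1, 2·min(P(U′≤U), P(U′≥U)))`. Significance
stars follow the usual convention: `*` p < 0.05, `**` p < 0.01. Paired
designs are deliberately not exploited (the unpaired test is what this
pipeline's protocol prescribes); a paired Wilcoxon is out of scope. Primer
%GC is `100·(G+C)/length`, displayed at one decimal; it is always computed
from the sequence, never trusted from a panel table.

## Synthetic data

The generators are pure functions of their specification and seed.

- **Families**: i.i.d. sequences from a background distribution (uniform by
  default), optionally shifted by moving `bias_strength` of probability mass
  onto a designated residue subset, and/or carrying an embedded motif. The
  default two-family study (n = 200 + 200, bias 0.18 toward K/R/H, lengths
  80–300) produces a compositional separation comparable to a real
  family-vs-background task that 188D features classify at ≥ 0.98 accuracy;
  the permuted-label control stays at chance. What this does *not* show:
  real families differ by motif architecture and domain order, not only
  composition, and real negatives are other structured proteins, not i.i.d.
  strings — passing these studies demonstrates the pipeline's mechanics, not
  field performance on any particular family.
- **Alignments**: clade ancestors evolve along a chain (each mutated from
  the previous at the between-clade rate), leaves from their ancestor at the
  within-clade rate; substitutions go to a uniformly random different
  residue, no indels and no rate heterogeneity. The chain (rather than a
  star) makes every internal edge of the true tree resolved, so strong
  signal can legitimately yield bootstrap supports of 1.0 on all edges.
  Gapped behaviour is exercised by separately crafted fixtures.
- **Ct tables**: control ΔCt ~ Normal(5, σ), case shifted by the per-gene
  effect, reference Ct fixed at 20 cycles. With effect −3 (≈ 8-fold), σ=0.5
  and 8 samples per group, the exact rank test detects the shift in ≥ 90 %
  of seeds (verified by simulation over 100 seeds).

## Problem sizes

The default test and reproduction runs use n = 200 + 200 sequences for the
classification study, 8-leaf alignments with 300 columns and 500 bootstrap
replicates, and 8 + 8 qPCR samples — sizes chosen so a study of each stage,
including its controls, completes in seconds while leaving the statistical
conclusions (separability, chance-level nulls, support saturation,
rank-test power) unambiguous.

## Known limitations

- The greedy clustering reproduces the classic strategy, not any particular
  tool's banded-alignment heuristics; cluster counts on real data will
  differ from tool-specific output.
- `paper-mode` cross-validation is intentionally optimistic (documented
  above); use `within-fold` for honest performance estimates.
- p-distance trees ignore multiple substitutions; no model-based distances
  (Poisson, JTT) are provided.
- Exact Mann–Whitney enumeration is limited to pooled sizes ≤ 16 by
  combinatorial growth; beyond that the tie-corrected normal approximation
  is used (agreement within 0.02 at the boundary).
- Motif discovery, MSA construction, and primer melting-temperature
  prediction are out of scope.
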