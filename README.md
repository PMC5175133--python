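# profam

Binary classification of protein families from sequence alone, with the
supporting analyses such a study needs: redundancy removal, composition-based
feature extraction, class rebalancing, cross-validated random-forest
evaluation, distance-based phylogenetics, and comparative-Ct qPCR statistics.

## The problem

Given a set of proteins known to belong to a family (for example, proteins
carrying a particular structural domain such as the ~80-residue DEP domain)
and a background set that does not, can the family be recognised from the
amino-acid sequence alone? `profam` implements the standard recipe for this
question:

1. **Redundancy removal** — greedy incremental clustering at a fractional
   identity threshold (default 0.90), so near-duplicate database entries do
   not inflate the evaluation. Identity is `matches / len(shorter)` under a
   global alignment that maximises matches (match = +1, mismatch = gap = 0).
2. **Feature extraction** — either the simple 20D amino-acid composition
   (AAC) or the full **188D vector**: AAC plus, for each of 8 physicochemical
   properties (hydrophobicity, van der Waals volume, polarity, polarizability,
   charge, secondary structure, solvent accessibility, surface tension), the
   21 CTD descriptors — 3 class **C**ompositions, 3 class-pair **T**ransition
   frequencies, and 15 **D**istribution quantile positions.
   20 + 8 × 21 = 188.
3. **Class rebalancing** — SMOTE: each synthetic minority point is
   `x + u·(z − x)` for a minority row `x`, one of its k = 5 nearest minority
   neighbours `z`, and `u ~ U(0,1)`. `percent=700` adds 7n synthetic points.
4. **Evaluation** — a random forest (100 trees, majority vote) under
   stratified 10-fold cross-validation, reporting the pooled confusion matrix
   and Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/N, Matthews
   correlation MCC, plus rank-based ROC AUC. SMOTE may be applied inside each
   training fold (sound, the default) or to the whole dataset before folding
   (the optimistic workbench-style protocol, kept for comparability).

Companion modules build neighbor-joining trees from p-distances with midpoint
rooting and column-bootstrap supports, and analyse qPCR Ct tables with the
2^−ΔCt comparative-Ct method and exact Mann–Whitney U tests.

## Worked example

Using the checked-in synthetic fixtures (see `examples/README.md`):

```sh
profam crossval --folds 5 --smote 100 --trees 100 --seed 1 \
    examples/positive.fasta examples/negative.fasta
```

prints (abridged):

```json
{"tp": 18, "fn": 2, "fp": 2, "tn": 18,
 "accuracy_pct": 90.0, "mcc": 0.8, "auc": 0.94375}
```

Of the 20 positive-family sequences, 18 were recognised out-of-fold (2 false
negatives) and 18 of 20 background sequences were rejected, i.e. 90 %
accuracy and an AUC of 0.94 on a deliberately small 20 + 20 example; at
n = 200 + 200 the same pipeline exceeds 0.98 accuracy.

```sh
profam qpcr compare --ct examples/ct.csv --gene DEPDC1B
```

```json
{"gene": "DEPDC1B", "n_case": 8, "n_control": 8,
 "mean_case": 0.1793, "mean_control": 0.0297,
 "U": 64.0, "p": 0.0001554, "stars": "**"}
```

The case group's mean 2^−ΔCt is about 6-fold the control mean; U = 64 is the
maximum for 8-vs-8 (complete separation) and the exact two-sided p is
2/12870 ≈ 0.00016, flagged `**` (p < 0.01).

```sh
profam njtree --bootstrap 100 --seed 1 examples/alignment.fasta tree.nwk
```

writes a midpoint-rooted Newick tree in which every clade of the simulated
alignment appears with bootstrap support 1.0.

Classifier metrics can also be computed directly from counts, e.g. a
confusion matrix with TP=11027, FN=523, FP=301, TN=10062 gives:

```sh
profam evaluate --cm 11027 523 301 10062   # -> "accuracy_pct": 96.2
```

## Layout

- `src/profam/seqio.py` — FASTA/CLUSTAL/Newick I/O, alphabet sanitization
- `src/profam/redundancy.py` — greedy identity clustering
- `src/profam/features.py`, `ctd_groupings.py` — 20D/188D extraction
- `src/profam/balance.py` — SMOTE
- `src/profam/model.py` — random forest + cross-validation
- `src/profam/metrics.py` — Sn/Sp/Acc/MCC, ROC AUC
- `src/profam/phylo.py` — p-distance, NJ, midpoint rooting, bootstrap
- `src/profam/qpcr.py` — 2^−ΔCt, Mann–Whitney U, primer %GC
- `src/profam/synthetic.py` — seeded generators for all of the above
- `src/profam/cli.py` — the `profam` command

See `docs/methods.md` for the modelling choices and their rationale.
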