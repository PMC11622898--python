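# Methods

## Scope and model

The package embeds individual CDR3 amino-acid sequences — the
hypervariable loop of the TCR beta chain that dominates antigen
specificity — into fixed-width numeric vectors and evaluates how well
those vectors separate disease classes. Everything operates at the
single-sequence level: diversity indices here describe residue usage
*within* one sequence, not clonal diversity across a repertoire.

## The 26-dimensional feature embedding

Each sequence yields seven features concatenated in a fixed order
(1 + 20 + 1 + 1 + 1 + 1 + 1 = 26):

1. **Distinct residue count.** The number of distinct residue types. This
   is deliberately the distinct count, not the sequence length; a
   `cdr3_mode="length"` switch returns `len(s)` for users who want the
   conventional CDR3-length feature.
2. **Composition** (20 values). `count(r)/len(s)` per residue, in the fixed
   alphabetical order `ACDEFGHIKLMNPQRSTVWY`. Sums to 1 by construction.
3. **Hydrophobicity.** The arithmetic mean of Kyte–Doolittle hydropathy
   values (the GRAVY statistic). Units are Kyte–Doolittle scale units
   (−4.5 … 4.5). The mean rather than the sum keeps the feature
   length-invariant.
4. **Charge.** Default `counting` mode: (#K + #R) − (#D + #E), an integer
   in elementary-charge units counting the side chains ionized at neutral
   pH. A `henderson_hasselbalch` mode computes the fractional net charge
   at a configurable pH from side-chain (K, R, H positive; D, E, C, Y
   negative) and terminal pKa values (EMBOSS table by default). The two
   modes answer slightly different questions (residue census vs titration
   state); counting is the default because it is parameter-free.
5. **Motif similarity.** For each motif in a configurable set (default:
   the single germline-encoded beta-chain prefix `CASS`), the
   position-wise BLOSUM62 score of the sequence's length-matched *prefix*
   against the motif, divided by the motif's BLOSUM62 self-score, averaged
   over motifs. An exact prefix match scores 1; unrelated prefixes can go
   negative. Prefix anchoring (rather than a sliding window) reflects
   that the motif of interest is positionally fixed at the CDR3 start;
   both the motif set and the normalization are configurable. Motifs
   longer than the sequence are skipped; if every motif is skipped this is
   an error rather than a silent 0.
6. **Shannon entropy** of the residue-frequency distribution, in bits
   (log base 2). Range [0, log₂ min(20, len)].
7. **Gini–Simpson index** 1 − Σ p², the probability that two residues
   drawn at random from the sequence differ. Range [0, 1 − 1/min(20, len)].
   Note the *Gini* form: larger values mean more diversity.

All seven are deterministic; the embedding of a set is the row-stack in
input order with fixed column names.

## Baseline embeddings

Variable-length sequences must map to fixed-width rows; where a padding
convention was needed we pad to the dataset maximum length
(`max_len`, default 30).

- **One-hot**: 20-way indicator per position, flattened to 20·max_len;
  positions past the end are zero blocks (no explicit pad symbol).
- **k-mer counts** (k = 3 default): occurrence counts of each contiguous
  k-mer in the full 20³ = 8000 vocabulary, base-20 indexed in alphabet
  order. Row sums equal len − k + 1.
- **Per-sequence PWM scores**: from each sequence's k-mers a 20 × k
  position frequency matrix is counted, column-normalized to a
  probability matrix, a 0.1 pseudocount is added to every cell, and a
  log₂-odds weight matrix against a background (uniform 1/20 by default,
  configurable) is formed. Each k-mer is scored as the sum of its
  per-position weights; scores are right-padded with zeros to
  max_len − k + 1. One PWM per sequence, not per dataset.
- **Spaced k-mers** (g = 9, k = 3 default): a length-g window slides with
  stride 1; each window contributes the single subsequence at evenly
  spaced offsets round(i·(g−1)/(k−1)) (0, 4, 8), counted into the 20^k
  vocabulary. Sequences shorter than g are one whole-sequence window with
  offsets spread over their own length (Python banker's rounding decides
  half-way offsets), so no record is dropped.
- **Autoencoder**: one dense encoder layer (ReLU, default width 50) and
  one dense decoder layer back to the input width, trained on the one-hot
  rows with mean-squared reconstruction error and the Adam update rule
  (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), implemented in plain numpy. Defaults
  lr = 1e-3, 300 epochs, batch 64, small-uniform seeded initialization:
  at these settings the loss curve is monotone to numerical tolerance and
  a constant dataset is fit to MSE < 1e-3, while larger learning rates
  make Adam overshoot transiently. Fixed seed ⇒ bit-identical output.

## Evaluation protocol

Per repeat (default 5): a stratified 70/30 train/test split, then 10 % of
the train split held out again (stratified) as a tuning set. The tuning
set is *reserved but unused* by the default fits — the classifiers run
with library defaults — because no specific hyperparameter search is part
of the protocol; the hold-out keeps the training fraction honest and
leaves a hook for grid search. Split indices are a deterministic function
of (seed, repeat).

Features are z-scored with train-fit statistics by default: concatenations
mix counts, log-odds and fractions, and distance- or margin-based
classifiers (SVM, KNN, MLP) degrade badly on unscaled mixtures. This is
toggleable (`scale_features=False`).

Metrics per (classifier, repeat): accuracy; support-weighted precision,
recall and F1; macro F1; one-vs-rest ROC-AUC averaged with class-support
weights (macro available via `roc_average`), computed from
`predict_proba` where available, `decision_function` otherwise, and an
indicator-of-prediction score as a last resort; and wall-clock fit time.
Aggregation is mean ± sd over repeats. Run-level comparisons use a Welch
two-sample t-test (Welch–Satterthwaite df), with the conventions p = 1
for two identical constant samples and p = 0 for distinct constant
samples.

## Compactness analysis

Class labels are integer-coded in lexicographic class-name order — the
coding is arbitrary for nominal labels, so the mapping is always returned
and reported. Per embedding column, Pearson r and Spearman ρ against the
codes; constant columns get correlation 0 so the fraction's denominator
stays the full embedding width d. For thresholds over [−1, 1] (step 0.1)
the profile reports |{r > t}|/d for t > 0 and |{r < t}|/d for t < 0; at
t = 0, where the two one-sided curves meet, the fraction of nonzero
correlations is reported, which preserves monotonicity on both half-grids.
No p-values are attached and no pruning is performed — the curves are
descriptive.

## Synthetic repertoire generator

The generator emulates the shape of a five-cancer TCRdb beta-chain
export: class priors proportional to 13 970 / 12 616 / 17 063 / 1 453 /
5 629 (glioblastoma, lung, melanoma, osteosarcoma, pancreatic — including
the rare bone-cancer class, which exercises stratification and weighted
metrics), lengths on [6, 30] from a discrete triangular distribution
peaked at 15, and a "CASS" prefix overwritten onto the first four
residues with probability 0.5. Each class's residue distribution is one
Dirichlet(α·1₂₀) draw; the concentration α controls separability
(default 0.1 — spiky, well-separated compositions; α ≥ 100 makes classes
nearly indistinguishable). Residues are i.i.d. within a sequence.

What this does *not* emulate: V(D)J recombination, germline gene usage,
positional grammar beyond the prefix, or sequence sharing between
classes. Passing tests on this generator therefore demonstrate that the
pipeline is correct and that the protocol detects planted class signal —
not that any particular accuracy is attainable on real repertoires, where
class-conditional composition differences are far subtler (real-data
accuracies for this task sit in the 0.34–0.49 range across methods).

Calibration, verified in the test suite: at α = 0.1, n = 1000, a
brute-force nearest-centroid classifier on composition alone reaches
macro F1 ≈ 0.99, so requiring the protocol's random forest to exceed 0.8
tests the pipeline, not the classifier's strength.

## Numerical and design notes

- All embeddings are float64; embedding CSVs are written with 17
  significant digits and read back with round-trip float parsing, so I/O
  is bit-exact.
- Validation is strict by default (exactly the 20 standard residues,
  uppercased on read); a skip-invalid mode drops and counts bad records.
  Duplicate sequences are retained (real exports contain them), with an
  explicit `deduplicate()`.
- Degenerate inputs: length-1 sequences are legal (entropy 0, Simpson 0);
  empty sequences, sequences shorter than k, and sequences shorter than
  every motif raise errors naming the record.
- Problem sizes in the test suite and the acceptance script (n = 1000
  repertoires, 5 repeats, single-classifier panels where only one
  classifier's behavior is under test) were chosen so the full pipeline
  runs end-to-end in seconds while keeping every statistical check
  well-powered.

## Known limitations

- The tuning hold-out has no default consumer; results equal
  library-default classifier settings.
- Compactness correlations depend on the arbitrary label coding; curves
  for different codings can differ.
- The counting charge ignores histidine and termini; the
  Henderson–Hasselbalch mode depends on the chosen pKa table, and no
  single published table should be expected to match other software's
  charge outputs exactly.
- The autoencoder is a fixed two-layer dense architecture; it is a
  dimensionality-reduction baseline, not a tuned representation learner.
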