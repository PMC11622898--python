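# tcrembed

Feature embeddings and classification protocols for T-cell receptor (TCR)
CDR3 amino-acid sequences.

TCR repertoires carry a record of what a patient's immune system can
recognize, and classifying CDR3 sequences by disease context (here: five
cancer types) is a standard repertoire-analysis task. Raw sequence
encodings such as one-hot or k-mer counts are wide and sparse; this
package implements a compact 26-dimensional biochemical/diversity
embedding (TCellR2Vec) that can be used alone or concatenated onto the
usual baselines, together with the machinery to evaluate any of them.

## What it computes

For each CDR3 sequence *s* over the 20-letter amino-acid alphabet the
feature embedding concatenates, in order:

| block | width | definition |
|---|---|---|
| distinct residues | 1 | number of distinct residue types in *s* |
| composition | 20 | count(r)/len(s) for each residue r, alphabetical order |
| hydrophobicity | 1 | mean Kyte–Doolittle hydropathy (GRAVY) |
| charge | 1 | (#K + #R) − (#D + #E); optional Henderson–Hasselbalch mode |
| motif similarity | 1 | per-position BLOSUM62 score of the prefix vs "CASS", normalized by the motif self-score |
| Shannon entropy | 1 | −Σ p<sub>r</sub> log₂ p<sub>r</sub> over residue frequencies (bits) |
| Gini–Simpson index | 1 | 1 − Σ p<sub>r</sub>² |

Baseline embeddings: position-wise one-hot (20·max_len), k-mer counts over
the full 20^k vocabulary (k = 3 → 8000), per-sequence PWM k-mer scores
(PFM → PPM → +0.1 pseudocount → log₂-odds vs a uniform background), spaced
k-mers (one evenly spaced length-k subsequence per sliding length-g
window, g = 9), and a dense two-layer autoencoder (numpy, Adam, MSE loss)
over the one-hot encoding.

Evaluation follows a repeated stratified protocol: 70/30 train/test splits
(10 % of train held out for tuning), 5 seeded repeats, seven standard
classifiers (SVM, naive Bayes, MLP, 3-NN, random forest, logistic
regression, decision tree), and accuracy, weighted precision/recall,
weighted and macro F1, one-vs-rest ROC-AUC and training time, plus a
Welch t-test on run-level metrics. A compactness analysis reports, per
embedding, the fraction of features whose Pearson/Spearman correlation
with the integer-coded class label exceeds each threshold in a grid over
[−1, 1].

A synthetic repertoire generator (five imbalanced cancer-type classes,
lengths 6–30 peaked at 15, Dirichlet-drawn per-class residue
distributions, optional "CASS" germline-like prefixes) makes the whole
pipeline testable without any data download.

## Worked example

```python
>>> from tcrembed import feature_vector, hydrophobicity_score, shannon_entropy, simpson_index, motif_similarity
>>> seq = "CASSATGNEQFF"
>>> hydrophobicity_score(seq)
-0.125
>>> shannon_entropy(seq)
3.0849625007211556
>>> simpson_index(seq)
0.875
>>> motif_similarity(seq)   # exact "CASS" prefix -> self-score ratio 1
1.0
>>> feature_vector(seq).shape
(26,)
```

The hydrophobicity −0.125 is the mean Kyte–Doolittle value of the 12
residues; 3.085 bits of entropy and a Gini–Simpson index of 0.875 say the
sequence's residue usage is fairly even (9 distinct residue types); the
motif score 1.0 flags the canonical beta-chain "CASS" start.

From the shell:

```bash
tcrembed simulate --n 1000 --seed 7 --out synth.tsv
tcrembed embed --method spike2vec --with-tcellr2vec --input synth.tsv --out emb.csv
tcrembed evaluate --embedding tcellr2vec --input synth.tsv --repeats 5 --out report.csv
tcrembed compactness --embedding tcellr2vec --input synth.tsv --out profile.csv
```

`emb.csv` has 1000 rows × 8026 named columns (26 features + 8000 k-mer
counts); `report.csv` holds per-classifier mean ± sd of every metric over
the five splits.

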