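"""Embedding-compactness analysis.

For each embedding column, the Pearson and Spearman correlation with the
(integer-coded) class label is computed; the profile reports, for a grid
of thresholds over [-1, 1], the fraction of all d features whose
correlation exceeds each positive threshold or falls below each negative
threshold. A compact embedding concentrates label-relevant signal in few
columns, giving higher fractions at large |t|.

Class labels are nominal; the integer coding (lexicographic class-name
order) is arbitrary, and correlations depend on it. The coding is
returned so reports can state it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seqio import EmbeddingMatrix, SequenceSet


@dataclass
class CorrelationProfile:
    thresholds: np.ndarray
    fraction_pearson: np.ndarray
    fraction_spearman: np.ndarray
    d: int
    pearson: np.ndarray
    spearman: np.ndarray


def label_encode(sequences: SequenceSet) -> tuple[np.ndarray, dict[str, int]]:
    """Integer-code labels 0..C-1 in lexicographic class-name order."""
    labels = sequences.labels
    if labels is None:
        raise ValueError("label_encode requires labeled sequences")
    classes = sorted(set(labels))
    mapping = {c: i for i, c in enumerate(classes)}
    return np.array([mapping[l] for l in labels], dtype=int), mapping


def default_thresholds(step: float = 0.1) -> np.ndarray:
    n = int(round(1.0 / step))
    return np.linspace(-1.0, 1.0, 2 * n + 1)


def _column_correlations(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = values.shape[1]
    pearson = np.zeros(d)
    spearman = np.zeros(d)
    y = y.astype(float)
    if np.ptp(y) == 0:
        return pearson, spearman  # constant label: all correlations undefined -> 0
    for j in range(d):
        col = values[:, j]
        if np.ptp(col) == 0:
            continue  # constant feature: correlation undefined, counted as 0
        pearson[j] = stats.pearsonr(col, y).statistic
        spearman[j] = stats.spearmanr(col, y).statistic
    return pearson, spearman


def _fractions(corr: np.ndarray, thresholds: np.ndarray, d: int) -> np.ndarray:
    out = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        if t > 0:
            out[i] = np.count_nonzero(corr > t) / d
        elif t < 0:
            out[i] = np.count_nonzero(corr < t) / d
        else:
            # shared point of the two one-sided curves; nonzero count keeps
            # both monotonicity directions valid
            out[i] = np.count_nonzero(corr != 0) / d
    return out


def correlation_fractions(
    embedding: EmbeddingMatrix,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> CorrelationProfile:
    """Correlation-fraction profile of an embedding against label codes.

    The denominator of every fraction is the embedding width d, so
    constant columns (correlation set to 0) dilute the curve rather than
    being dropped.
    """
    labels = np.asarray(labels)
    if embedding.shape[0] != labels.shape[0]:
        raise ValueError("embedding rows and labels are misaligned")
    if embedding.shape[0] < 3:
        raise ValueError("need n >= 3 rows to correlate")
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = np.asarray(thresholds, dtype=float)
    pearson, spearman = _column_correlations(embedding.values, labels)
    d = embedding.shape[1]
    return CorrelationProfile(
        thresholds=thresholds,
        fraction_pearson=_fractions(pearson, thresholds, d),
        fraction_spearman=_fractions(spearman, thresholds, d),
        d=d,
        pearson=pearson,
        spearman=spearman,
    )


def profile_to_frame(profile: CorrelationProfile):
    import pandas as pd

    return pd.DataFrame(
        {
            "threshold": profile.thresholds,
            "fraction_pearson": profile.fraction_pearson,
            "fraction_spearman": profile.fraction_spearman,
        }
    )


def plot_profile(profile: CorrelationProfile, path: str) -> None:
    """Optional curve plot (threshold vs fraction, both measures)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.thresholds, profile.fraction_pearson, marker="o", label="Pearson")
    ax.plot(profile.thresholds, profile.fraction_spearman, marker="s", label="Spearman")
    ax.set_xlabel("correlation threshold")
    ax.set_ylabel(f"fraction of {profile.d} features")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
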