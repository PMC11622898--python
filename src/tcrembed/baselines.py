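"""Non-neural baseline sequence embeddings.

Four fixed-width embeddings of variable-length amino-acid sequences:

* one-hot: per-position 20-way indicator blocks, zero-padded to ``max_len``;
* k-mer counts (Spike2Vec-style): occurrence counts of every contiguous
  k-mer in a 20^k vocabulary;
* per-sequence PWM scores (PWM2Vec-style): each k-mer scored against the
  sequence's own position weight matrix (PFM -> PPM -> +pseudocount ->
  log2 odds vs a background), zero-padded to ``max_len - k + 1``;
* spaced k-mers: one evenly spaced length-k subsequence per sliding
  length-g window, counted in the 20^k vocabulary.

All four are deterministic and row-aligned with the input SequenceSet.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .seqio import ALPHABET, ALPHABET_INDEX, EmbeddingMatrix, SequenceSet


@dataclass(frozen=True)
class KmerConfig:
    """Shared k-mer / padding configuration.

    ``k`` is the k-mer length, ``g`` the spaced-k-mer window length, and
    ``max_len`` the padding length for position-dependent embeddings
    (default 30, a typical repertoire's maximum CDR3 length).
    """

    k: int = 3
    g: int = 9
    max_len: int = 30

    def __post_init__(self) -> None:
        if not (1 <= self.k <= self.g):
            raise ValueError(f"need 1 <= k <= g, got k={self.k}, g={self.g}")
        if self.max_len < 1:
            raise ValueError("max_len must be positive")


@dataclass(frozen=True)
class PwmSet:
    """PFM/PPM/PWM triple built from one sequence's k-mers.

    Rows follow the canonical residue order, columns are k-mer positions.
    ``pwm[r, j] = log2(ppm_adj[r, j] / background[r])``.
    """

    pfm: np.ndarray
    ppm: np.ndarray
    ppm_adj: np.ndarray
    pwm: np.ndarray
    pseudocount: float
    background: np.ndarray


@lru_cache(maxsize=None)
def kmer_vocabulary(k: int) -> tuple[str, ...]:
    """All 20^k k-mers in base-20 canonical-alphabet order."""
    return tuple("".join(t) for t in itertools.product(ALPHABET, repeat=k))


def _kmer_index(kmer: str) -> int:
    idx = 0
    for ch in kmer:
        idx = idx * 20 + ALPHABET_INDEX[ch]
    return idx


def one_hot_embed(sequences: SequenceSet, config: KmerConfig | None = None) -> EmbeddingMatrix:
    """Position-wise one-hot encoding padded to ``max_len`` positions.

    Row dimension is 20 * max_len; position j of a sequence sets a single 1
    in its 20-length block (canonical residue order); positions past the
    sequence end stay all-zero.
    """
    config = config or KmerConfig()
    d = 20 * config.max_len
    rows = np.zeros((sequences.n, d), dtype=float)
    for i, rec in enumerate(sequences):
        if len(rec.sequence) > config.max_len:
            raise ValueError(
                f"record {rec.id!r}: length {len(rec.sequence)} exceeds "
                f"max_len={config.max_len}"
            )
        for j, ch in enumerate(rec.sequence):
            rows[i, 20 * j + ALPHABET_INDEX[ch]] = 1.0
    names = [
        f"pos{j}_{aa}" for j in range(config.max_len) for aa in ALPHABET
    ]
    return EmbeddingMatrix(rows, names, sequences.ids)


def spike2vec_embed(sequences: SequenceSet, config: KmerConfig | None = None) -> EmbeddingMatrix:
    """Contiguous k-mer occurrence counts in the full 20^k vocabulary."""
    config = config or KmerConfig()
    k = config.k
    rows = np.zeros((sequences.n, 20**k), dtype=float)
    for i, rec in enumerate(sequences):
        s = rec.sequence
        if len(s) < k:
            raise ValueError(
                f"record {rec.id!r}: length {len(s)} shorter than k={k}"
            )
        for start in range(len(s) - k + 1):
            rows[i, _kmer_index(s[start : start + k])] += 1.0
    return EmbeddingMatrix(rows, list(kmer_vocabulary(k)), sequences.ids)


def pwm_build(
    sequence: str,
    config: KmerConfig | None = None,
    background: np.ndarray | None = None,
    *,
    pseudocount: float = 0.1,
) -> PwmSet:
    """Build the PFM/PPM/PWM triple from one sequence's contiguous k-mers.

    The PFM counts residues at each of the k positions across all
    ``len - k + 1`` k-mers; the PPM column-normalizes it; ``pseudocount``
    (default 0.1) is added to every PPM cell before the log-odds step
    against ``background`` (default uniform 1/20).
    """
    config = config or KmerConfig()
    k = config.k
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} shorter than k={k}")
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or np.any(background <= 0):
        raise ValueError("background must be 20 positive frequencies")
    pfm = np.zeros((20, k), dtype=float)
    for start in range(len(sequence) - k + 1):
        for j in range(k):
            pfm[ALPHABET_INDEX[sequence[start + j]], j] += 1.0
    ppm = pfm / pfm.sum(axis=0, keepdims=True)
    ppm_adj = ppm + pseudocount
    pwm = np.log2(ppm_adj / background[:, None])
    return PwmSet(pfm, ppm, ppm_adj, pwm, pseudocount, background)


def pwm2vec_embed(
    sequences: SequenceSet,
    config: KmerConfig | None = None,
    background: np.ndarray | None = None,
    *,
    pseudocount: float = 0.1,
) -> EmbeddingMatrix:
    """Per-sequence PWM k-mer scores, zero-padded to ``max_len - k + 1``.

    Each sequence gets its own PwmSet; its i-th k-mer scores
    ``sum_j pwm[kmer[j], j]``; scores are laid out in k-mer order and
    right-padded with zeros to the fixed width.
    """
    config = config or KmerConfig()
    k = config.k
    width = config.max_len - k + 1
    rows = np.zeros((sequences.n, width), dtype=float)
    for i, rec in enumerate(sequences):
        s = rec.sequence
        try:
            pwm = pwm_build(s, config, background, pseudocount=pseudocount).pwm
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
        n_kmers = len(s) - k + 1
        if n_kmers > width:
            raise ValueError(
                f"record {rec.id!r}: {n_kmers} k-mers exceed width {width}; "
                f"raise max_len"
            )
        for start in range(n_kmers):
            rows[i, start] = sum(
                pwm[ALPHABET_INDEX[s[start + j]], j] for j in range(k)
            )
    names = [f"kmerscore_{i}" for i in range(width)]
    return EmbeddingMatrix(rows, names, sequences.ids)


def spaced_offsets(window_len: int, k: int) -> list[int]:
    """Evenly spaced offsets round(i*(L-1)/(k-1)) for i = 0..k-1."""
    if k == 1:
        return [0]
    return [round(i * (window_len - 1) / (k - 1)) for i in range(k)]


def spaced_kmers(sequence: str, config: KmerConfig) -> list[str]:
    """Spaced k-mers of a sequence: one per sliding length-g window.

    Each window contributes the subsequence at evenly spaced offsets
    (0, 4, 8 for g=9, k=3). Sequences shorter than g are treated as a
    single window with offsets spread over their own length.
    """
    k, g = config.k, config.g
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} shorter than k={k}")
    if len(sequence) < g:
        offs = spaced_offsets(len(sequence), k)
        return ["".join(sequence[o] for o in offs)]
    offs = spaced_offsets(g, k)
    out = []
    for start in range(len(sequence) - g + 1):
        window = sequence[start : start + g]
        out.append("".join(window[o] for o in offs))
    return out


def spaced_kmer_embed(sequences: SequenceSet, config: KmerConfig | None = None) -> EmbeddingMatrix:
    """Spaced k-mer occurrence counts in the full 20^k vocabulary."""
    config = config or KmerConfig()
    rows = np.zeros((sequences.n, 20**config.k), dtype=float)
    for i, rec in enumerate(sequences):
        try:
            kmers = spaced_kmers(rec.sequence, config)
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
        for kmer in kmers:
            rows[i, _kmer_index(kmer)] += 1.0
    return EmbeddingMatrix(rows, list(kmer_vocabulary(config.k)), sequences.ids)
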