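"""Embedding method registry shared by the CLI and scripts.

Methods are addressed by name so concatenation combinations compose
freely; ``with_features=True`` appends the 26-dim biochemical feature
block to any baseline.
"""

from __future__ import annotations

from .autoencoder import AutoencoderConfig, autoencoder_embed
from .baselines import (
    KmerConfig,
    one_hot_embed,
    pwm2vec_embed,
    spaced_kmer_embed,
    spike2vec_embed,
)
from .evaluate import concat_embeddings
from .features import tcellr2vec_embed
from .seqio import EmbeddingMatrix, SequenceSet

EMBEDDING_METHODS = ("tcellr2vec", "ohe", "spike2vec", "pwm2vec", "spaced", "autoencoder")


def compute_embedding(
    method: str,
    sequences: SequenceSet,
    *,
    kmer_config: KmerConfig | None = None,
    ae_config: AutoencoderConfig | None = None,
    with_features: bool = False,
) -> EmbeddingMatrix:
    """Compute a named embedding, optionally concatenating the feature block."""
    kmer_config = kmer_config or KmerConfig()
    if method == "tcellr2vec":
        emb = tcellr2vec_embed(sequences)
        with_features = False  # already the feature block
    elif method == "ohe":
        emb = one_hot_embed(sequences, kmer_config)
    elif method == "spike2vec":
        emb = spike2vec_embed(sequences, kmer_config)
    elif method == "pwm2vec":
        emb = pwm2vec_embed(sequences, kmer_config)
    elif method == "spaced":
        emb = spaced_kmer_embed(sequences, kmer_config)
    elif method == "autoencoder":
        emb = autoencoder_embed(one_hot_embed(sequences, kmer_config), ae_config)
    else:
        raise ValueError(f"unknown embedding method {method!r}; choose from {EMBEDDING_METHODS}")
    if with_features:
        emb = concat_embeddings([tcellr2vec_embed(sequences), emb])
    return emb
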