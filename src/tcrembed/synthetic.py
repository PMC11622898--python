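"""Synthetic CDR3-like repertoire generator.

Emulates the shape of a TCRdb-style five-cancer beta-chain export:
class-imbalanced priors, lengths on [6, 30] peaked near 15, a 20-letter
alphabet, and frequent germline-like "CASS" prefixes. Each class draws a
residue distribution from a Dirichlet; lower concentration gives spikier,
more separable class compositions. Residues are i.i.d. within a sequence
(no positional grammar beyond the optional prefix), which keeps
closed-form oracles for the downstream features analyzable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import ALPHABET, SequenceRecord, SequenceSet

#: Class names and per-class sequence totals of the emulated five-cancer
#: repertoire (imbalanced, incl. a rare bone-cancer class).
DEFAULT_CLASS_TOTALS: dict[str, int] = {
    "Glioblastoma": 13970,
    "Lung": 12616,
    "Melanoma": 17063,
    "Osteosarcoma": 1453,
    "Pancreatic": 5629,
}


def _default_priors() -> tuple[float, ...]:
    totals = np.array(list(DEFAULT_CLASS_TOTALS.values()), dtype=float)
    return tuple(totals / totals.sum())


@dataclass(frozen=True)
class SyntheticConfig:
    n: int = 1000
    n_classes: int = 5
    class_names: tuple[str, ...] = tuple(DEFAULT_CLASS_TOTALS)
    class_priors: tuple[float, ...] = field(default_factory=_default_priors)
    length_min: int = 6
    length_max: int = 30
    length_mode: int = 15
    concentration: float = 0.1
    motif_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < self.n_classes:
            raise ValueError("need n >= n_classes")
        if len(self.class_names) != self.n_classes or len(self.class_priors) != self.n_classes:
            raise ValueError("class_names/class_priors must match n_classes")
        if not np.isclose(sum(self.class_priors), 1.0):
            raise ValueError("class priors must sum to 1")
        if not (1 <= self.length_min <= self.length_mode <= self.length_max):
            raise ValueError("need 1 <= length_min <= length_mode <= length_max")
        if self.concentration <= 0 or not (0 <= self.motif_prob <= 1):
            raise ValueError("concentration > 0 and motif_prob in [0, 1] required")


def _length_pmf(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Discrete triangular length distribution peaked at length_mode."""
    lengths = np.arange(cfg.length_min, cfg.length_max + 1)
    up = (lengths - cfg.length_min + 1) / (cfg.length_mode - cfg.length_min + 1)
    down = (cfg.length_max - lengths + 1) / (cfg.length_max - cfg.length_mode + 1)
    w = np.where(lengths <= cfg.length_mode, up, down)
    return lengths, w / w.sum()


def class_residue_distributions(config: SyntheticConfig) -> np.ndarray:
    """The per-class residue distributions the generator draws (C x 20).

    Re-derivable from the seed: this consumes the same leading RNG stream
    as :func:`generate`, so callers can recover the exact distributions a
    generated set was sampled from.
    """
    rng = np.random.default_rng(config.seed)
    return rng.dirichlet(np.full(20, config.concentration), size=config.n_classes)


def generate(config: SyntheticConfig | None = None) -> SequenceSet:
    """Generate a labeled synthetic repertoire, reproducible from the seed."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    class_dists = rng.dirichlet(np.full(20, config.concentration), size=config.n_classes)
    lengths_grid, length_p = _length_pmf(config)
    alphabet = np.array(list(ALPHABET))

    klass = rng.choice(config.n_classes, size=config.n, p=np.asarray(config.class_priors))
    lengths = rng.choice(lengths_grid, size=config.n, p=length_p)
    has_motif = rng.random(config.n) < config.motif_prob

    records = []
    for i in range(config.n):
        residues = rng.choice(alphabet, size=lengths[i], p=class_dists[klass[i]])
        if has_motif[i]:
            residues[:4] = list("CASS")
        records.append(
            SequenceRecord(
                id=f"synth{i}",
                sequence="".join(residues),
                label=config.class_names[klass[i]],
            )
        )
    return SequenceSet(records)
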