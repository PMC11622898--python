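"""Per-sequence biochemical and diversity features for CDR3 sequences.

Seven features are computed for each sequence and concatenated into a
26-dimensional embedding: distinct-residue count (1), amino-acid
composition (20), mean Kyte-Doolittle hydrophobicity (1), net charge (1),
BLOSUM62 motif similarity (1), Shannon entropy in bits (1), and the
Gini-Simpson diversity index (1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .seqio import ALPHABET, ALPHABET_INDEX, EmbeddingMatrix, SequenceSet

#: Kyte-Doolittle hydropathy scale (positive = hydrophobic).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: EMBOSS pKa values for the Henderson-Hasselbalch charge mode.
EMBOSS_PKA: dict[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}

_POSITIVE_SIDECHAINS = ("K", "R", "H")
_NEGATIVE_SIDECHAINS = ("D", "E", "C", "Y")

#: Column names of the 26-dim embedding, in concatenation order.
FEATURE_NAMES: list[str] = (
    ["cdr3_unique_aa"]
    + [f"comp_{aa}" for aa in ALPHABET]
    + ["hydrophobicity_kd", "charge", "motif_similarity", "shannon_bits", "simpson"]
)


@dataclass(frozen=True)
class ChargeModel:
    """How net charge is computed.

    ``counting`` (default) returns the integer count (#K + #R) - (#D + #E).
    ``henderson_hasselbalch`` returns the fractional net charge at ``pH``
    from side-chain and terminal pKa values (K/R/H and the N-terminus
    positive; D/E/C/Y and the C-terminus negative).
    """

    mode: str = "counting"
    pH: float = 7.0
    pka_table: dict[str, float] = field(default_factory=lambda: dict(EMBOSS_PKA))


@dataclass(frozen=True)
class MotifConfig:
    """Motif set and scoring scheme for the similarity feature.

    Each motif is scored position-by-position with a substitution matrix
    against the length-matched prefix of the sequence; with
    ``normalize_by_self_score`` the score is divided by the motif's
    self-alignment score, so an exact prefix match scores 1. The default
    single motif "CASS" is the germline-encoded start of most beta-chain
    CDR3s.
    """

    motifs: tuple[str, ...] = ("CASS",)
    matrix: str = "BLOSUM62"
    normalize_by_self_score: bool = True


@lru_cache(maxsize=None)
def _substitution_matrix(name: str):
    from Bio.Align import substitution_matrices

    return substitution_matrices.load(name)


def _check_nonempty(sequence: str) -> None:
    if not sequence:
        raise ValueError("feature undefined for an empty sequence")


def cdr3_feature(sequence: str, *, mode: str = "unique") -> int:
    """Scalar CDR3 feature: distinct residue count (default) or length.

    ``mode="unique"`` counts the number of distinct residue types present;
    ``mode="length"`` returns len(sequence) for users who want the
    conventional CDR3-length definition.
    """
    _check_nonempty(sequence)
    if mode == "unique":
        return len(set(sequence))
    if mode == "length":
        return len(sequence)
    raise ValueError(f"unknown cdr3 mode {mode!r}")


def residue_counts(sequence: str) -> np.ndarray:
    """Integer counts of each residue, in canonical alphabet order."""
    _check_nonempty(sequence)
    counts = np.zeros(20, dtype=float)
    for ch in sequence:
        counts[ALPHABET_INDEX[ch]] += 1
    return counts


def aa_composition(sequence: str) -> np.ndarray:
    """Residue frequencies count(r)/len, a 20-vector summing to 1."""
    counts = residue_counts(sequence)
    return counts / counts.sum()


def hydrophobicity_score(sequence: str) -> float:
    """Mean Kyte-Doolittle hydropathy over the sequence (GRAVY)."""
    _check_nonempty(sequence)
    return sum(KYTE_DOOLITTLE[ch] for ch in sequence) / len(sequence)


def charge_feature(sequence: str, model: ChargeModel | None = None) -> float:
    """Net charge of the sequence under the given model (see ChargeModel)."""
    _check_nonempty(sequence)
    model = model or ChargeModel()
    if model.mode == "counting":
        pos = sequence.count("K") + sequence.count("R")
        neg = sequence.count("D") + sequence.count("E")
        return float(pos - neg)
    if model.mode == "henderson_hasselbalch":
        pka = model.pka_table
        pH = model.pH

        def positive(pk: float) -> float:
            return 1.0 / (1.0 + 10.0 ** (pH - pk))

        def negative(pk: float) -> float:
            return -1.0 / (1.0 + 10.0 ** (pk - pH))

        charge = positive(pka["Nterm"]) + negative(pka["Cterm"])
        for aa in _POSITIVE_SIDECHAINS:
            charge += sequence.count(aa) * positive(pka[aa])
        for aa in _NEGATIVE_SIDECHAINS:
            charge += sequence.count(aa) * negative(pka[aa])
        return charge
    raise ValueError(f"unknown charge mode {model.mode!r}")


def motif_similarity(sequence: str, config: MotifConfig | None = None) -> float:
    """Mean substitution-matrix similarity of the sequence to the motif set.

    For each motif no longer than the sequence, sums the matrix score of
    sequence[i] vs motif[i] over the motif length (i.e. against the
    sequence prefix), optionally normalized by the motif self-score;
    returns the mean over scoreable motifs. Motifs longer than the
    sequence are skipped; if all are skipped a ValueError is raised.
    """
    _check_nonempty(sequence)
    config = config or MotifConfig()
    if not config.motifs:
        raise ValueError("motif set is empty")
    matrix = _substitution_matrix(config.matrix)
    scores = []
    for motif in config.motifs:
        if len(motif) > len(sequence):
            continue
        score = sum(matrix[sequence[i], motif[i]] for i in range(len(motif)))
        if config.normalize_by_self_score:
            self_score = sum(matrix[c, c] for c in motif)
            score /= self_score
        scores.append(score)
    if not scores:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than every motif"
        )
    return float(np.mean(scores))


def shannon_entropy(sequence: str) -> float:
    """Shannon entropy of the residue frequency distribution, in bits."""
    p = aa_composition(sequence)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def simpson_index(sequence: str) -> float:
    """Gini-Simpson index 1 - sum(p^2): probability two residues drawn at
    random from the sequence are of different types. 0 for a single residue
    type; approaches 1 - 1/20 for maximal diversity."""
    p = aa_composition(sequence)
    return float(1.0 - (p * p).sum())


def feature_vector(
    sequence: str,
    *,
    charge_model: ChargeModel | None = None,
    motif_config: MotifConfig | None = None,
    cdr3_mode: str = "unique",
) -> np.ndarray:
    """The 26-vector [cdr3, composition x20, hydrophobicity, charge,
    similarity, shannon, simpson] for one sequence."""
    return np.concatenate(
        [
            [cdr3_feature(sequence, mode=cdr3_mode)],
            aa_composition(sequence),
            [
                hydrophobicity_score(sequence),
                charge_feature(sequence, charge_model),
                motif_similarity(sequence, motif_config),
                shannon_entropy(sequence),
                simpson_index(sequence),
            ],
        ]
    )


def tcellr2vec_embed(
    sequences: SequenceSet,
    *,
    charge_model: ChargeModel | None = None,
    motif_config: MotifConfig | None = None,
    cdr3_mode: str = "unique",
) -> EmbeddingMatrix:
    """Compute the 26-dimensional feature embedding for every sequence.

    Rows follow input order; the computation is fully deterministic.
    Per-sequence failures are re-raised with the record id attached.
    """
    rows = np.empty((sequences.n, 26), dtype=float)
    for i, rec in enumerate(sequences):
        try:
            rows[i] = feature_vector(
                rec.sequence,
                charge_model=charge_model,
                motif_config=motif_config,
                cdr3_mode=cdr3_mode,
            )
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    return EmbeddingMatrix(rows, list(FEATURE_NAMES), sequences.ids)
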