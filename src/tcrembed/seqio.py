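"""Sequence and embedding I/O.

Reads amino-acid sequence sets from FASTA or delimited tables (TCRdb-style
beta-chain exports with ``sequence``/``label`` columns), validates them
against the 20-letter amino-acid alphabet, and serializes embedding
matrices as CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical residue order used by every composition / one-hot / k-mer index
#: in this package: the 20 standard one-letter codes, alphabetical.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)
#: residue -> rank in the canonical order
ALPHABET_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the amino-acid alphabet."""


class FastaParseError(ValueError):
    """Input is not parseable as FASTA."""


def _validate_sequence(seq: str, record_id: str) -> None:
    if not seq:
        raise SequenceValidationError(f"record {record_id!r}: empty sequence")
    for ch in seq:
        if ch not in ALPHABET_SET:
            raise SequenceValidationError(
                f"record {record_id!r}: invalid residue {ch!r} "
                f"(alphabet is {ALPHABET})"
            )


@dataclass(frozen=True)
class SequenceRecord:
    """One CDR3 amino-acid sequence with an optional class label."""

    id: str
    sequence: str
    label: str | None = None


@dataclass
class SequenceSet:
    """Ordered, validated collection of sequence records.

    Record order is stable and defines the row order of every embedding
    matrix computed from the set.
    """

    records: list[SequenceRecord] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return SequenceSet(self.records[i])
        return self.records[i]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str] | None:
        """Labels in record order, or None when no record carries one."""
        labs = [r.label for r in self.records]
        if all(l is None for l in labs):
            return None
        return labs

    def subset(self, indices: Iterable[int]) -> "SequenceSet":
        return SequenceSet([self.records[i] for i in indices])

    def deduplicate(self) -> "SequenceSet":
        """Keep the first record for each distinct sequence string."""
        seen: set[str] = set()
        out = []
        for r in self.records:
            if r.sequence not in seen:
                seen.add(r.sequence)
                out.append(r)
        return SequenceSet(out)


@dataclass
class EmbeddingMatrix:
    """n x d numeric matrix with named columns, row-aligned to a SequenceSet."""

    values: np.ndarray
    feature_names: list[str]
    source_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, d = self.values.shape
        if d != len(self.feature_names):
            raise ValueError(
                f"{d} columns but {len(self.feature_names)} feature names"
            )
        if n != len(self.source_ids):
            raise ValueError(f"{n} rows but {len(self.source_ids)} source ids")
        if n and not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, columns=self.feature_names, index=pd.Index(self.source_ids, name="id")
        )


def read_fasta(path: str | Path, *, skip_invalid: bool = False) -> SequenceSet:
    """Read a FASTA file into a SequenceSet (labels absent).

    Sequences are uppercased then validated against the 20-letter alphabet.
    In strict mode (default) an invalid residue raises
    :class:`SequenceValidationError`; with ``skip_invalid`` the offending
    records are dropped and their count logged.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno} is not a FASTA header"
                    )
                break
    records: list[SequenceRecord] = []
    skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            _validate_sequence(seq, rec.id)
        except SequenceValidationError:
            if skip_invalid:
                skipped += 1
                continue
            raise
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    if skipped:
        logger.warning("read_fasta: skipped %d invalid record(s) in %s", skipped, path)
    return SequenceSet(records)


def read_table(
    path: str | Path,
    *,
    sequence_column: str = "sequence",
    label_column: str | None = "label",
    delimiter: str = "\t",
    skip_invalid: bool = False,
) -> SequenceSet:
    """Read a delimited table (header row required) into a SequenceSet.

    Records keep file order; duplicate sequences on different rows are all
    retained. ``label_column`` may be None, or name a column absent from
    the file only if explicitly set to None.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if sequence_column not in df.columns:
        raise KeyError(
            f"{path}: missing sequence column {sequence_column!r} "
            f"(found {list(df.columns)})"
        )
    labels: Sequence[str | None]
    if label_column is not None:
        if label_column not in df.columns:
            raise KeyError(f"{path}: missing label column {label_column!r}")
        labels = df[label_column].tolist()
    else:
        labels = [None] * len(df)
    records: list[SequenceRecord] = []
    skipped = 0
    for i, (seq, lab) in enumerate(zip(df[sequence_column], labels)):
        rid = f"row{i}"
        seq = str(seq).upper()
        try:
            _validate_sequence(seq, rid)
        except SequenceValidationError:
            if skip_invalid:
                skipped += 1
                continue
            raise
        records.append(SequenceRecord(id=rid, sequence=seq, label=lab))
    if skipped:
        logger.warning("read_table: skipped %d invalid row(s) in %s", skipped, path)
    return SequenceSet(records)


def write_table(seqs: SequenceSet, path: str | Path, *, delimiter: str = "\t") -> None:
    """Write a SequenceSet in the read_table format."""
    data = {"sequence": seqs.sequences}
    labels = seqs.labels
    if labels is not None:
        data["label"] = labels
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False)


def write_matrix(matrix: EmbeddingMatrix, path: str | Path) -> None:
    """Write an embedding as CSV: header = feature names, first column = ids.

    Floats are printed with 17 significant digits so a read-back is
    bit-identical.
    """
    matrix.to_dataframe().to_csv(path, float_format="%.17g")


def read_matrix(path: str | Path) -> EmbeddingMatrix:
    """Read back a CSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return EmbeddingMatrix(
        values=df.to_numpy(dtype=float) if len(df) else np.empty((0, df.shape[1])),
        feature_names=[str(c) for c in df.columns],
        source_ids=[str(i) for i in df.index],
    )
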