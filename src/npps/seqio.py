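"""Reading, validating and writing fixed-length labeled RNA windows.

Input windows are the standard m6A-benchmark shape: every sequence has the same
length (51 nt in the published benchmarks, the candidate adenosine flanked by
25 nt on each side) and carries a class label — ``positive`` (methylated),
``negative`` (non-methylated) or ``unknown`` (to be predicted).

DNA-style input is accepted and silently normalised: lowercase is uppercased
and ``T`` is mapped to ``U``, because public m6A datasets circulate in both
alphabets. Ambiguous IUPAC codes (N, R, Y, ...) are hard errors by default;
``skip_invalid=True`` drops the offending records with a logged warning
instead. All user-facing positions are reported 1-based; internal indexing is
0-based throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO as _bio_seqio

from .exceptions import ContractError, FastaParseError, ValidationError

logger = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"
_VALID = frozenset(RNA_ALPHABET)
_LABELS = ("positive", "negative", "unknown")


@dataclass(frozen=True)
class SequenceRecord:
    """One fixed-length RNA window with a class label."""

    id: str
    sequence: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ContractError(
                f"label must be one of {_LABELS}, got {self.label!r}"
            )


def normalize_sequence(seq: str) -> str:
    """Uppercase and map T to U. Does not validate the alphabet."""
    return seq.upper().replace("T", "U")


def validate_sequence(record_id: str, seq: str) -> None:
    """Raise :class:`ValidationError` naming id and 1-based position of the
    first non-ACGU symbol."""
    for pos, base in enumerate(seq, start=1):
        if base not in _VALID:
            raise ValidationError(
                f"record {record_id!r}: invalid base {base!r} at position {pos} "
                f"(only A/C/G/U allowed after T→U normalization)"
            )


class SequenceDataset:
    """Ordered collection of equal-length :class:`SequenceRecord` windows."""

    def __init__(
        self,
        records: Iterable[SequenceRecord],
        window_length: int | None = None,
    ) -> None:
        self.records: list[SequenceRecord] = list(records)
        if window_length is None:
            if not self.records:
                raise ContractError(
                    "window_length must be given for an empty dataset"
                )
            window_length = len(self.records[0].sequence)
        if window_length <= 0:
            raise ContractError("window_length must be a positive integer")
        self.window_length = int(window_length)
        for rec in self.records:
            if len(rec.sequence) != self.window_length:
                raise ValidationError(
                    f"record {rec.id!r}: length {len(rec.sequence)} != "
                    f"window length {self.window_length}"
                )

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> SequenceRecord:
        return self.records[idx]

    # -- views -------------------------------------------------------------
    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.records if r.label == "positive")

    @property
    def n_negative(self) -> int:
        return sum(1 for r in self.records if r.label == "negative")

    def label_vector(self) -> np.ndarray:
        """Labels encoded +1 (positive) / -1 (negative).

        Raises :class:`ContractError` if any record is unlabeled.
        """
        out = np.empty(len(self.records), dtype=np.int64)
        for i, rec in enumerate(self.records):
            if rec.label == "positive":
                out[i] = 1
            elif rec.label == "negative":
                out[i] = -1
            else:
                raise ContractError(
                    f"record {rec.id!r} has label 'unknown'; "
                    "a +1/-1 label vector requires labeled records"
                )
        return out

    def subset(self, indices: Sequence[int]) -> "SequenceDataset":
        return SequenceDataset(
            [self.records[i] for i in indices], self.window_length
        )

    def restrict(self, label: str) -> "SequenceDataset":
        """Records of one class, order preserved."""
        return SequenceDataset(
            [r for r in self.records if r.label == label], self.window_length
        )

    @staticmethod
    def concatenate(*datasets: "SequenceDataset") -> "SequenceDataset":
        if not datasets:
            raise ContractError("need at least one dataset")
        l = datasets[0].window_length
        for ds in datasets[1:]:
            if ds.window_length != l:
                raise ValidationError(
                    f"window lengths differ: {l} vs {ds.window_length}"
                )
        records: list[SequenceRecord] = []
        for ds in datasets:
            records.extend(ds.records)
        return SequenceDataset(records, l)


def read_fasta(
    path,
    label: str = "unknown",
    window_length: int | None = None,
    skip_invalid: bool = False,
    require_center_a: bool = False,
) -> SequenceDataset:
    """Read a FASTA file into a validated :class:`SequenceDataset`.

    Parameters
    ----------
    path
        FASTA file (multi-record; wrapped or single-line).
    label
        Class label assigned to every record.
    window_length
        If given, every record must have exactly this length.
    skip_invalid
        Drop records with ambiguous bases or wrong length instead of raising;
        each skip is logged as a warning.
    require_center_a
        Demand an A at the window center (the m6A candidate position). Off
        by default: benchmark windows are A-centered by construction, but
        that is a dataset convention, not a format rule.
    """
    # Biopython silently yields nothing for leading junk; make that a parse
    # error so truncated/garbled files are caught.
    with open(path) as handle:
        head = handle.read(4096)
    stripped = head.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FastaParseError(
            f"{path}: not a FASTA file (content before the first '>' header)"
        )

    records: list[SequenceRecord] = []
    for rec in _bio_seqio.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq))
        try:
            validate_sequence(rec.id, seq)
            if window_length is not None and len(seq) != window_length:
                raise ValidationError(
                    f"record {rec.id!r}: length {len(seq)} != required "
                    f"window length {window_length}"
                )
            if require_center_a and seq[len(seq) // 2] != "A":
                raise ValidationError(
                    f"record {rec.id!r}: center position {len(seq) // 2 + 1} "
                    f"is {seq[len(seq) // 2]!r}, expected the candidate 'A'"
                )
        except ValidationError:
            if skip_invalid:
                logger.warning("skipping record %r (failed validation)", rec.id)
                continue
            raise
        records.append(SequenceRecord(rec.id, seq, label))

    if window_length is None and records:
        window_length = len(records[0].sequence)
    if not records:
        # empty FASTA is not an error; pick a harmless placeholder length
        return SequenceDataset([], window_length or 1)
    return SequenceDataset(records, window_length)


def write_fasta(dataset: SequenceDataset, path, line_width: int = 70) -> None:
    """Write records as wrapped FASTA, preserving order."""
    with open(path, "w") as fh:
        for rec in dataset:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")


def write_feature_table(
    features,
    ids: Sequence[str],
    labels: Sequence,
    path,
    format: str = "tsv",
) -> None:
    """Write an encoded feature matrix as TSV or sparse libsvm-style text.

    TSV columns are ``id``, ``label``, ``f_1`` ... ``f_D`` in the canonical
    joined-feature order (ascending ξ block, ascending position within block).
    Values are written with shortest round-trippable float repr, so a TSV
    round trip is bit-identical. The libsvm format writes
    ``label index:value`` lines with 1-based indices, omitting exact zeros.
    """
    values = getattr(features, "values", features)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ContractError(f"feature matrix must be 2-D, got shape {values.shape}")
    n = values.shape[0]
    if len(ids) != n or len(labels) != n:
        raise ContractError(
            f"row-count mismatch: {n} feature rows, {len(ids)} ids, "
            f"{len(labels)} labels"
        )
    if format == "tsv":
        header = ["id", "label"] + [f"f_{j + 1}" for j in range(values.shape[1])]
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for i in range(n):
                row = [str(ids[i]), str(labels[i])] + [
                    repr(float(v)) for v in values[i]
                ]
                fh.write("\t".join(row) + "\n")
    elif format == "libsvm-sparse":
        with open(path, "w") as fh:
            for i in range(n):
                parts = [str(labels[i])]
                for j, v in enumerate(values[i], start=1):
                    if v != 0.0:
                        parts.append(f"{j}:{float(v)!r}")
                fh.write(" ".join(parts) + "\n")
    else:
        raise ContractError(f"unknown format {format!r}")


def read_feature_table(path):
    """Read a TSV feature table back into ``(values, ids, labels)``."""
    import pandas as pd

    df = pd.read_csv(
        path, sep="\t", dtype={"id": str, "label": str},
        float_precision="round_trip",
    )
    if df.shape[1] < 2 or list(df.columns[:2]) != ["id", "label"]:
        raise FastaParseError(f"{path}: not a feature table (bad header)")
    values = df.iloc[:, 2:].to_numpy(dtype=float)
    return values, df["id"].tolist(), df["label"].tolist()
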