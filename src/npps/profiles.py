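"""Nucleotide pair position specificity (NPPS) feature encoding.

The encoder turns a fixed-length RNA window into a vector of class-conditional
probability differences. For each interval ξ ≥ 0 and each position
k = 1 … l−ξ−1, consider the ordered nucleotide pair formed by positions
(k, k+ξ+1) — ξ counts the nucleotides *between* the two, so ξ = 0 is the
contiguous dinucleotide and a window of length l yields l−ξ−1 pairs.

From each training class (positive = m6A, negative = non-m6A) two positional
frequency matrices are fitted:

* ``single_freq`` — 4 × l, rows A,C,G,U: per-position single-nucleotide
  occurrence probabilities f_{i,k};
* ``pair_freq`` — 16 × (l−ξ−1), rows AA,AC,…,UU (lexicographic over
  {A,C,G,U}²): per-position ordered-pair occurrence probabilities F_{j,k}.

A query position k with pair (a, b) is scored per class with the conditional
probability of the upstream nucleotide given the downstream one,

    p_k = F[pair(a,b), k] / f[b, k+ξ+1],

and the feature is the class difference p_k⁺ − p_k⁻. Because the pair count
can never exceed the count of its downstream nucleotide, each conditional lies
in [0, 1] and each feature in [−1, 1]. If a class never saw nucleotide b at
position k+ξ+1 (zero denominator, hence zero numerator too), the conditional
for that class is defined as 0 — the α→0 limit under additive smoothing.

Optional additive smoothing with pseudocount α replaces counts c by
(c + α) / (n + 4α) for singles and (c + α) / (n + 16α) for pairs; the default
α = 0 matches the plain relative-frequency definition.

Multi-interval ("joined") features concatenate the per-ξ vectors in ascending
ξ order; for l = 51 and ξ ∈ {0,…,6} the joined dimension is
50+49+48+47+46+45+44 = 329.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import (
    ContractError,
    FitError,
    ParameterError,
    ValidationError,
)
from .seqio import SequenceDataset, SequenceRecord

ALPHABET = "ACGU"
NT_INDEX = {nt: i for i, nt in enumerate(ALPHABET)}
#: Ordered-pair row labels, lexicographic over {A,C,G,U}²; 'CG' is row 6
#: (0-based), i.e. the 7th row, and 'G' is the 3rd nucleotide row.
PAIR_LABELS = [a + b for a in ALPHABET for b in ALPHABET]

_COLSUM_TOL = 1e-9


def _as_int_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Sequences → (n, l) int8 matrix of nucleotide indices."""
    try:
        return np.array(
            [[NT_INDEX[c] for c in s] for s in sequences], dtype=np.int8
        )
    except KeyError as exc:  # pragma: no cover - upstream validation
        raise ValidationError(f"invalid base {exc.args[0]!r}") from exc


def pair_dimension(window_length: int, interval: int) -> int:
    """Number of (k, k+ξ+1) pairs in a window: l − ξ − 1."""
    return window_length - interval - 1


def joined_dimension(window_length: int, intervals: Iterable[int]) -> int:
    """Total joined feature dimension Σ_ξ (l − ξ − 1)."""
    return sum(pair_dimension(window_length, xi) for xi in intervals)


@dataclass(frozen=True)
class ClassProfile:
    """Per-class positional frequency matrices for one interval ξ."""

    interval: int
    window_length: int
    single_freq: np.ndarray  # (4, l)
    pair_freq: np.ndarray  # (16, l - ξ - 1)
    n_sequences: int
    pseudocount: float

    def __post_init__(self) -> None:
        l, xi = self.window_length, self.interval
        if self.single_freq.shape != (4, l):
            raise ContractError(
                f"single_freq shape {self.single_freq.shape} != (4, {l})"
            )
        if self.pair_freq.shape != (16, pair_dimension(l, xi)):
            raise ContractError(
                f"pair_freq shape {self.pair_freq.shape} != "
                f"(16, {pair_dimension(l, xi)})"
            )
        for name, mat in (("single_freq", self.single_freq),
                          ("pair_freq", self.pair_freq)):
            if np.any(mat < -1e-15) or np.any(mat > 1 + 1e-15):
                raise ContractError(f"{name} entries outside [0, 1]")
            colsums = mat.sum(axis=0)
            if np.any(np.abs(colsums - 1.0) > _COLSUM_TOL):
                raise ContractError(f"{name} columns do not sum to 1")


def fit_class_profile(
    dataset: SequenceDataset | Sequence[str],
    interval: int,
    pseudocount: float = 0.0,
) -> ClassProfile:
    """Fit single-nucleotide and pair frequency matrices on one class.

    ``single_freq[i, k] = (count of nucleotide i at position k + α) / (n + 4α)``
    and ``pair_freq[j, k] = (count of pair (s_k, s_{k+ξ+1}) = j + α) /
    (n + 16α)``. The result is independent of record order.
    """
    sequences = (
        dataset.sequences if isinstance(dataset, SequenceDataset) else list(dataset)
    )
    if not sequences:
        raise FitError("cannot fit a class profile on an empty dataset")
    l = len(sequences[0])
    if any(len(s) != l for s in sequences):
        raise ValidationError("all sequences must share one window length")
    if interval < 0 or interval > l - 2:
        raise ParameterError(
            f"interval ξ={interval} out of range for window length {l} "
            f"(need 0 ≤ ξ ≤ {l - 2})"
        )
    if pseudocount < 0:
        raise ParameterError("pseudocount must be non-negative")

    mat = _as_int_matrix(sequences)
    n = mat.shape[0]
    alpha = float(pseudocount)

    single_counts = np.zeros((4, l), dtype=np.int64)
    for k in range(l):
        single_counts[:, k] = np.bincount(mat[:, k], minlength=4)
    single_freq = (single_counts + alpha) / (n + 4 * alpha)

    d = pair_dimension(l, interval)
    pair_idx = 4 * mat[:, :d].astype(np.int64) + mat[:, interval + 1 :]
    pair_counts = np.zeros((16, d), dtype=np.int64)
    for k in range(d):
        pair_counts[:, k] = np.bincount(pair_idx[:, k], minlength=16)
    pair_freq = (pair_counts + alpha) / (n + 16 * alpha)

    return ClassProfile(
        interval=interval,
        window_length=l,
        single_freq=single_freq,
        pair_freq=pair_freq,
        n_sequences=n,
        pseudocount=alpha,
    )


@dataclass(frozen=True)
class FeatureMatrix:
    """Encoded feature rows plus the (ξ, block-dimension) layout."""

    values: np.ndarray  # (n, D)
    interval_layout: tuple  # ((ξ, l-ξ-1), ...)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block(self, interval: int) -> np.ndarray:
        """Columns belonging to one ξ block."""
        start = 0
        for xi, dim in self.interval_layout:
            if xi == interval:
                return self.values[:, start : start + dim]
            start += dim
        raise ParameterError(f"interval ξ={interval} not in layout")


class NPPSProfileSet:
    """The fitted encoder: positive and negative profiles over intervals Ξ."""

    def __init__(
        self,
        positive_profiles: Mapping[int, ClassProfile],
        negative_profiles: Mapping[int, ClassProfile],
    ) -> None:
        pos = dict(sorted(positive_profiles.items()))
        neg = dict(sorted(negative_profiles.items()))
        if set(pos) != set(neg):
            raise ContractError(
                "positive and negative profiles must cover the same intervals"
            )
        if not pos:
            raise ContractError("profile set needs at least one interval")
        lengths = {p.window_length for p in (*pos.values(), *neg.values())}
        if len(lengths) != 1:
            raise ContractError("all profiles must share one window length")
        self.positive_profiles = pos
        self.negative_profiles = neg
        self.intervals = tuple(sorted(pos))
        self.window_length = lengths.pop()

    # -- construction ------------------------------------------------------
    @classmethod
    def fit(
        cls,
        positives: SequenceDataset | Sequence[str],
        negatives: SequenceDataset | Sequence[str],
        intervals: Iterable[int] = range(7),
        pseudocount: float = 0.0,
    ) -> "NPPSProfileSet":
        """Fit both class profiles for every interval in ``intervals``."""
        intervals = sorted(set(int(x) for x in intervals))
        pos = {xi: fit_class_profile(positives, xi, pseudocount) for xi in intervals}
        neg = {xi: fit_class_profile(negatives, xi, pseudocount) for xi in intervals}
        return cls(pos, neg)

    @classmethod
    def fit_dataset(
        cls,
        dataset: SequenceDataset,
        intervals: Iterable[int] = range(7),
        pseudocount: float = 0.0,
    ) -> "NPPSProfileSet":
        """Fit from a mixed dataset using its positive/negative labels."""
        return cls.fit(
            dataset.restrict("positive"),
            dataset.restrict("negative"),
            intervals,
            pseudocount,
        )

    @property
    def joined_dimension(self) -> int:
        return joined_dimension(self.window_length, self.intervals)

    @property
    def interval_layout(self) -> tuple:
        return tuple(
            (xi, pair_dimension(self.window_length, xi)) for xi in self.intervals
        )

    # -- encoding ----------------------------------------------------------
    def _conditional(self, profile: ClassProfile, idx: np.ndarray) -> np.ndarray:
        xi = profile.interval
        d = pair_dimension(profile.window_length, xi)
        first = idx[:d].astype(np.int64)
        second = idx[xi + 1 :].astype(np.int64)
        k = np.arange(d)
        num = profile.pair_freq[4 * first + second, k]
        den = profile.single_freq[second, k + xi + 1]
        out = np.zeros(d)
        np.divide(num, den, out=out, where=den > 0)
        return out

    def encode_single(
        self, sequence: SequenceRecord | str, interval: int
    ) -> np.ndarray:
        """Encode one window for one ξ: vector of p_k⁺ − p_k⁻, length l−ξ−1."""
        if interval not in self.positive_profiles:
            raise ParameterError(
                f"interval ξ={interval} not fitted (have {self.intervals})"
            )
        seq = sequence.sequence if isinstance(sequence, SequenceRecord) else sequence
        if len(seq) != self.window_length:
            raise ValidationError(
                f"sequence length {len(seq)} != window length {self.window_length}"
            )
        idx = _as_int_matrix([seq])[0]
        p_pos = self._conditional(self.positive_profiles[interval], idx)
        p_neg = self._conditional(self.negative_profiles[interval], idx)
        return p_pos - p_neg

    def encode_joined(self, sequence: SequenceRecord | str) -> np.ndarray:
        """Concatenate encode_single over all fitted intervals, ascending ξ."""
        return np.concatenate(
            [self.encode_single(sequence, xi) for xi in self.intervals]
        )

    def encode_dataset(self, dataset: SequenceDataset) -> FeatureMatrix:
        """Encode every record; row i is the joined encoding of record i."""
        if len(dataset) and dataset.window_length != self.window_length:
            raise ValidationError(
                f"dataset window length {dataset.window_length} != "
                f"profile window length {self.window_length}"
            )
        if len(dataset) == 0:
            values = np.empty((0, self.joined_dimension))
        else:
            values = np.vstack([self.encode_joined(r) for r in dataset])
        return FeatureMatrix(values=values, interval_layout=self.interval_layout)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def profile_dict(p: ClassProfile) -> dict:
            return {
                "interval": p.interval,
                "n_sequences": p.n_sequences,
                "single_freq": {
                    "rows": list(ALPHABET),
                    "values": p.single_freq.tolist(),
                },
                "pair_freq": {
                    "rows": PAIR_LABELS,
                    "values": p.pair_freq.tolist(),
                },
            }

        any_profile = next(iter(self.positive_profiles.values()))
        return {
            "format": "npps-profiles",
            "version": 1,
            "window_length": self.window_length,
            "intervals": list(self.intervals),
            "pseudocount": any_profile.pseudocount,
            "positive": {str(xi): profile_dict(p)
                         for xi, p in self.positive_profiles.items()},
            "negative": {str(xi): profile_dict(p)
                         for xi, p in self.negative_profiles.items()},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @property
    def checksum(self) -> str:
        """SHA-256 of the canonical JSON form; embedded in trained models."""
        canonical = json.dumps(
            self.to_dict(), sort_keys=True, separators=(",", ":")
        )
        return hashlib.sha256(canonical.encode()).hexdigest()

    @classmethod
    def from_dict(cls, doc: dict) -> "NPPSProfileSet":
        if not isinstance(doc, dict) or doc.get("format") != "npps-profiles":
            raise ContractError("not a profile-set document")
        l = int(doc["window_length"])
        alpha = float(doc["pseudocount"])

        def load_side(side: dict) -> dict:
            out = {}
            for key, pd in side.items():
                xi = int(key)
                out[xi] = ClassProfile(
                    interval=xi,
                    window_length=l,
                    single_freq=np.array(pd["single_freq"]["values"], dtype=float),
                    pair_freq=np.array(pd["pair_freq"]["values"], dtype=float),
                    n_sequences=int(pd["n_sequences"]),
                    pseudocount=alpha,
                )
                if pd["single_freq"]["rows"] != list(ALPHABET):
                    raise ContractError("unexpected single_freq row order")
                if pd["pair_freq"]["rows"] != PAIR_LABELS:
                    raise ContractError("unexpected pair_freq row order")
            return out

        return cls(load_side(doc["positive"]), load_side(doc["negative"]))

    @classmethod
    def from_json(cls, path) -> "NPPSProfileSet":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ContractError(f"{path}: not valid JSON: {exc}") from exc
        return cls.from_dict(doc)


# Spec-level functional aliases -------------------------------------------

def encode_single(profiles: NPPSProfileSet, sequence, interval: int) -> np.ndarray:
    return profiles.encode_single(sequence, interval)


def encode_joined(profiles: NPPSProfileSet, sequence) -> np.ndarray:
    return profiles.encode_joined(sequence)


def encode_dataset(profiles: NPPSProfileSet, dataset: SequenceDataset) -> FeatureMatrix:
    return profiles.encode_dataset(dataset)
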