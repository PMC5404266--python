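"""Shared fixtures: tiny hand-checkable datasets and a brute-force encoder.

The brute-force encoder recounts single-nucleotide and pair frequencies from
the raw training sequences for every query position. It is deliberately
independent of the package's vectorized profile/encoding path and serves as
the oracle in equivalence tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from npps import SequenceDataset, SequenceRecord


def brute_force_encode(pos_seqs, neg_seqs, query, interval, pseudocount=0.0):
    """Independent re-count of the conditional-probability difference vector.

    Pair = positions (k, k+ξ+1); conditional on the downstream nucleotide;
    zero denominator → 0 for that class.
    """
    l = len(query)
    out = []
    for k in range(l - interval - 1):
        a, b = query[k], query[k + interval + 1]
        per_class = []
        for seqs in (pos_seqs, neg_seqs):
            n = len(seqs)
            pair_count = sum(
                1 for s in seqs if s[k] == a and s[k + interval + 1] == b
            )
            single_count = sum(1 for s in seqs if s[k + interval + 1] == b)
            big_f = (pair_count + pseudocount) / (n + 16 * pseudocount)
            small_f = (single_count + pseudocount) / (n + 4 * pseudocount)
            per_class.append(0.0 if small_f == 0 else big_f / small_f)
        out.append(per_class[0] - per_class[1])
    return np.array(out)


def random_sequences(rng, n, length):
    return [
        "".join(rng.choice(list("ACGU"), size=length)) for _ in range(n)
    ]


def make_dataset(pos_seqs, neg_seqs):
    records = [
        SequenceRecord(f"p{i}", s, "positive") for i, s in enumerate(pos_seqs)
    ] + [
        SequenceRecord(f"n{i}", s, "negative") for i, s in enumerate(neg_seqs)
    ]
    return SequenceDataset(records)


@pytest.fixture
def toy_training():
    """The 4-sequence set whose encoding is fully checkable by hand."""
    return ["ACGU", "ACGA"], ["UGCA", "UGCC"]


@pytest.fixture
def toy_dataset(toy_training):
    return make_dataset(*toy_training)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
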