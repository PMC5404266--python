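"""Synthetic labeled RNA window generator.

Emulates the shape of m6A benchmark data — fixed-length windows (51 nt by
default, the candidate adenosine at the center) — with a controllable,
position-specific class signal so every other module is testable without
external downloads:

* positives draw the positions under a motif block from a mixture
  ``strength · motif + (1 − strength) · background`` and all other positions
  from the background composition;
* negatives draw every position from the background.

The default motif is a 5-column soft DRACH-like consensus (D = A/G/U,
R = A/G, A, C, H = A/C/U, uniform within each degenerate set) centered on the
window with the A column at the center, mirroring the known m6A sequence
context. By default the center position is forced to A in *both* classes,
because real benchmark negatives are windows around non-methylated
adenosines. The generator makes no attempt to model transcriptome context,
conservation or secondary structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ContractError, ParameterError
from .seqio import SequenceDataset, SequenceRecord, write_fasta

ALPHABET = "ACGU"

_THIRD = 1.0 / 3.0


def drach_motif() -> np.ndarray:
    """Default 5×4 motif block: D, R, A, C, H columns (rows = positions,
    columns = A,C,G,U probabilities)."""
    return np.array(
        [
            [_THIRD, 0.0, _THIRD, _THIRD],  # D = A/G/U
            [0.5, 0.0, 0.5, 0.0],           # R = A/G
            [1.0, 0.0, 0.0, 0.0],           # A (the candidate site)
            [0.0, 1.0, 0.0, 0.0],           # C
            [_THIRD, _THIRD, 0.0, _THIRD],  # H = A/C/U
        ]
    )


def _uniform_background() -> tuple:
    return (0.25, 0.25, 0.25, 0.25)


@dataclass
class SyntheticSpec:
    """Full description of one synthetic dataset draw."""

    n_pos: int = 300
    n_neg: int = 300
    window_length: int = 51
    background: tuple = field(default_factory=_uniform_background)
    motif: np.ndarray = field(default_factory=drach_motif)
    motif_offset: int | None = None  # 0-based start; None → centered
    motif_strength: float = 1.0
    #: optional motif block for negatives (same offset/strength machinery);
    #: None keeps the default easy regime of pure-background negatives
    negative_motif: np.ndarray | None = None
    center_a: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ParameterError("n_pos and n_neg must be non-negative")
        if self.window_length < 1:
            raise ParameterError("window_length must be positive")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg < 0) or abs(bg.sum() - 1) > 1e-9:
            raise ParameterError("background must be a 4-vector summing to 1")
        self.background = tuple(bg)
        motif = np.asarray(self.motif, dtype=float)
        if motif.ndim != 2 or motif.shape[1] != 4:
            raise ParameterError("motif must be an m×4 probability block")
        if np.any(motif < 0) or np.any(np.abs(motif.sum(axis=1) - 1) > 1e-9):
            raise ParameterError("every motif column must sum to 1")
        self.motif = motif
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ParameterError("motif_strength must lie in [0, 1]")
        if self.motif_offset is None:
            # place the middle motif row at the window center
            self.motif_offset = self.window_length // 2 - motif.shape[0] // 2
        if self.motif_offset < 0 or (
            self.motif_offset + motif.shape[0] > self.window_length
        ):
            raise ParameterError("motif placement does not fit in the window")
        if self.negative_motif is not None:
            nm = np.asarray(self.negative_motif, dtype=float)
            if nm.ndim != 2 or nm.shape[1] != 4:
                raise ParameterError("negative_motif must be an m×4 block")
            if np.any(nm < 0) or np.any(np.abs(nm.sum(axis=1) - 1) > 1e-9):
                raise ParameterError("every negative_motif column must sum to 1")
            if self.motif_offset + nm.shape[0] > self.window_length:
                raise ParameterError(
                    "negative_motif placement does not fit in the window"
                )
            self.negative_motif = nm

    # -- per-class positional distributions --------------------------------
    def class_distributions(self) -> tuple[np.ndarray, np.ndarray]:
        """(l, 4) per-position nucleotide distributions for (positive,
        negative) windows, center-A forcing applied."""
        l = self.window_length
        bg = np.asarray(self.background)
        pos = np.tile(bg, (l, 1))
        neg = np.tile(bg, (l, 1))
        w = self.motif_strength
        m = self.motif.shape[0]
        pos[self.motif_offset : self.motif_offset + m] = (
            w * self.motif + (1 - w) * bg
        )
        if self.negative_motif is not None:
            mn = self.negative_motif.shape[0]
            neg[self.motif_offset : self.motif_offset + mn] = (
                w * self.negative_motif + (1 - w) * bg
            )
        if self.center_a:
            center = l // 2
            pos[center] = neg[center] = np.array([1.0, 0.0, 0.0, 0.0])
        return pos, neg

    def to_dict(self) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "window_length": self.window_length,
            "background": list(self.background),
            "motif": self.motif.tolist(),
            "motif_offset": self.motif_offset,
            "motif_strength": self.motif_strength,
            "negative_motif": (
                None if self.negative_motif is None
                else self.negative_motif.tolist()
            ),
            "center_a": self.center_a,
            "seed": self.seed,
        }


def _draw(rng: np.random.Generator, probs: np.ndarray, n: int) -> list[str]:
    """Draw n sequences from per-position distributions (l, 4).

    Inverse-CDF sampling with a fixed traversal order keeps output
    byte-identical for a given seed across platforms.
    """
    l = probs.shape[0]
    if n == 0:
        return []
    cdf = np.cumsum(probs, axis=1)
    cdf[:, -1] = 1.0
    u = rng.random((n, l))
    idx = (u[:, :, None] > cdf[None, :, :]).sum(axis=2)
    lut = np.array(list(ALPHABET))
    return ["".join(row) for row in lut[idx]]


def generate(spec: SyntheticSpec) -> SequenceDataset:
    """Draw the labeled dataset described by ``spec``; deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    pos_probs, neg_probs = spec.class_distributions()
    pos_seqs = _draw(rng, pos_probs, spec.n_pos)
    neg_seqs = _draw(rng, neg_probs, spec.n_neg)
    width = max(4, len(str(max(spec.n_pos, spec.n_neg, 1))))
    records = [
        SequenceRecord(f"pos_{i + 1:0{width}d}", s, "positive")
        for i, s in enumerate(pos_seqs)
    ] + [
        SequenceRecord(f"neg_{i + 1:0{width}d}", s, "negative")
        for i, s in enumerate(neg_seqs)
    ]
    return SequenceDataset(records, spec.window_length)


def generate_files(spec: SyntheticSpec, outdir) -> dict:
    """Write positives.fasta / negatives.fasta plus a JSON spec sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = generate(spec)
    paths = {
        "positives": outdir / "positives.fasta",
        "negatives": outdir / "negatives.fasta",
        "spec": outdir / "spec.json",
    }
    write_fasta(dataset.restrict("positive"), paths["positives"])
    write_fasta(dataset.restrict("negative"), paths["negatives"])
    with open(paths["spec"], "w") as fh:
        json.dump(spec.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
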