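"""Planted-motif synthetic corpora for end-to-end offline testing.

Positive-class sequences carry a short (width-3) and a broad (width-7)
consensus motif at uniform non-overlapping positions, optionally degraded
by per-position substitution noise; negatives are pure background.  The
two widths match the receptive fields of the model's two convolutional
branches, so the generator provides ground truth for both detection and
attribution tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .sequence_io import (
    CANONICAL_RESIDUES,
    LabeledDataset,
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    ProteinSequence,
)

DEFAULT_MOTIF_SHORT = "WHK"
DEFAULT_MOTIF_BROAD = "CPFYWMD"


@dataclass(frozen=True)
class MotifSpec:
    consensus: str
    insert_prob: float = 1.0
    substitution_rate: float = 0.0

    def __post_init__(self):
        if len(self.consensus) < 1:
            raise ValueError("motif consensus must be non-empty")
        if not set(self.consensus) <= set(CANONICAL_RESIDUES):
            raise ValueError(f"non-canonical residues in motif {self.consensus!r}")
        for p in (self.insert_prob, self.substitution_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def width(self) -> int:
        return len(self.consensus)


def default_motifs(insert_prob: float = 1.0,
                   substitution_rate: float = 0.0) -> tuple[MotifSpec, MotifSpec]:
    return (
        MotifSpec(DEFAULT_MOTIF_SHORT, insert_prob, substitution_rate),
        MotifSpec(DEFAULT_MOTIF_BROAD, insert_prob, substitution_rate),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    n_total: int = 1600
    class_balance: float = 0.5
    length_range: tuple[int, int] = (200, 600)
    background: str = "dirichlet"  # or "uniform"
    background_alpha: float = 5.0
    motifs: tuple[MotifSpec, ...] = field(default_factory=default_motifs)
    seed: int = 0

    def __post_init__(self):
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must lie in (0, 1)")
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise ValueError(f"bad length range: {self.length_range}")
        max_width = max((m.width for m in self.motifs), default=0)
        if max_width > lo:
            raise ValueError(
                f"motif width {max_width} exceeds minimum length {lo}"
            )
        if sum(m.width for m in self.motifs) > lo:
            raise ValueError("motifs cannot fit without overlap at minimum length")


def _background_probs(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.background == "uniform":
        return np.full(20, 1 / 20)
    if cfg.background == "dirichlet":
        return rng.dirichlet(np.full(20, cfg.background_alpha))
    raise KeyError(f"unknown background model: {cfg.background!r}")


def _place_motifs(
    seq: list[str],
    motifs: tuple[MotifSpec, ...],
    rng: np.random.Generator,
    letters: np.ndarray,
) -> list[tuple[str, int, int]]:
    """Plant motifs at uniform non-overlapping positions; returns 0-based spans.

    Positions are drawn uniformly from the explicitly enumerated feasible
    starts (wider motifs first), which matches rejection sampling but cannot
    deadlock in tight sequences.
    """
    occupied: list[tuple[int, int]] = []
    truth: list[tuple[str, int, int]] = []
    order = sorted(range(len(motifs)), key=lambda i: -motifs[i].width)
    for motif_idx in order:
        motif = motifs[motif_idx]
        if rng.random() >= motif.insert_prob:
            continue
        width = motif.width
        feasible = [
            start
            for start in range(len(seq) - width + 1)
            if all(start + width <= s or start >= e for s, e in occupied)
        ]
        if not feasible:
            raise ValueError(
                f"no non-overlapping position left for motif {motif.consensus!r}"
            )
        start = int(feasible[rng.integers(0, len(feasible))])
        span = (start, start + width)
        occupied.append(span)
        planted = list(motif.consensus)
        for i in range(width):
            if rng.random() < motif.substitution_rate:
                planted[i] = str(rng.choice(letters))
        seq[span[0] : span[1]] = planted
        truth.append((motif.consensus, span[0], span[1]))
    return truth


def generate_dataset(
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[LabeledDataset, dict[str, list[tuple[str, int, int]]]]:
    """Generate a balanced labeled corpus plus motif ground truth.

    Ground truth maps sequence id to a list of (consensus, start, end)
    spans, 1-based and inclusive.  Output is fully determined by the seed;
    the class split is exact, not stochastic.
    """
    rng = np.random.default_rng(cfg.seed)
    probs = _background_probs(cfg, rng)
    letters = np.array(list(CANONICAL_RESIDUES))
    n_pos = round(cfg.n_total * cfg.class_balance)
    n_neg = cfg.n_total - n_pos
    lo, hi = cfg.length_range

    sequences: list[ProteinSequence] = []
    truth: dict[str, list[tuple[str, int, int]]] = {}
    width = len(str(cfg.n_total))
    for i in range(n_pos):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(letters, size=length, p=probs))
        spans = _place_motifs(seq, cfg.motifs, rng, letters)
        sid = f"CML_{i + 1:0{width}d}"
        sequences.append(ProteinSequence(sid, "".join(seq), POSITIVE_LABEL))
        truth[sid] = [(m, s + 1, e) for m, s, e in spans]
    for i in range(n_neg):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(letters, size=length, p=probs)
        sid = f"CTRL_{i + 1:0{width}d}"
        sequences.append(ProteinSequence(sid, "".join(seq), NEGATIVE_LABEL))
        truth[sid] = []
    return LabeledDataset(sequences), truth


def difficulty_sweep(
    base: GeneratorConfig, substitution_rates: list[float]
) -> list[tuple[LabeledDataset, dict]]:
    """One dataset per substitution rate; seeds derived as base.seed + index."""
    if not substitution_rates:
        raise ValueError("substitution_rates must be non-empty")
    out = []
    for i, rate in enumerate(substitution_rates):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"substitution rate out of range: {rate}")
        motifs = tuple(replace(m, substitution_rate=rate) for m in base.motifs)
        cfg = replace(base, motifs=motifs, seed=base.seed + i)
        out.append(generate_dataset(cfg))
    return out


def write_ground_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: [list(span) for span in v] for k, v in truth.items()}, fh, indent=1)
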