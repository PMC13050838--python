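"""Pairwise sequence similarity and greedy identity-threshold deduplication.

Similarity is the number of identically aligned residues in an optimal
global alignment divided by the length of the shorter sequence.  Clustering
is exact greedy (longest-first) rather than word-heuristic: each sequence
joins the first representative it matches at or above the threshold,
otherwise it founds a new cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align

from .sequence_io import LabeledDataset, ProteinSequence


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring; gaps are affine and end gaps are penalized."""

    match_score: float = 1.0
    mismatch_score: float = 0.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if self.match_score <= self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


@dataclass(frozen=True)
class SimilarityResult:
    sim: float
    matches: int
    min_len: int


@dataclass
class ClusterReport:
    representatives: list[str]
    removed: dict[str, str] = field(default_factory=dict)
    threshold: float = 0.90

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "threshold": self.threshold,
                    "representatives": self.representatives,
                    "removed": self.removed,
                },
                fh,
                indent=1,
            )


def _aligner(p: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = p.match_score
    aligner.mismatch_score = p.mismatch_score
    aligner.open_gap_score = p.gap_open
    aligner.extend_gap_score = p.gap_extend
    return aligner


def pairwise_similarity(
    a: ProteinSequence,
    b: ProteinSequence,
    params: AlignmentParams = AlignmentParams(),
) -> SimilarityResult:
    """Identity of the optimal global alignment, normalized by the shorter length."""
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(params)
    alignment = aligner.align(a.residues, b.residues)[0]
    matches = int(alignment.counts().identities)
    min_len = min(len(a), len(b))
    return SimilarityResult(sim=matches / min_len, matches=matches, min_len=min_len)


def filter_redundant(
    ds: LabeledDataset,
    threshold: float = 0.90,
    params: AlignmentParams = AlignmentParams(),
) -> tuple[LabeledDataset, ClusterReport]:
    """Greedy incremental clustering at a sequence-identity threshold.

    Sequences are processed in descending length order (ties broken by id);
    a sequence joins the first existing representative whose similarity is
    >= ``threshold``, otherwise it becomes a new representative.  Only
    representatives are retained.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1]: {threshold}")
    order = sorted(ds.sequences, key=lambda s: (-len(s), s.id))
    representatives: list[ProteinSequence] = []
    removed: dict[str, str] = {}
    for seq in order:
        home = None
        for rep in representatives:
            if pairwise_similarity(seq, rep, params).sim >= threshold:
                home = rep
                break
        if home is None:
            representatives.append(seq)
        else:
            removed[seq.id] = home.id
    report = ClusterReport(
        representatives=[r.id for r in representatives],
        removed=removed,
        threshold=threshold,
    )
    return LabeledDataset(list(representatives)), report
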