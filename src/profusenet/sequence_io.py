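"""Reading, validation, labelling, and splitting of protein sequence datasets.

Labels ride either in the FASTA header as a ``|label=<class>`` tag or in a
sidecar two-column TSV manifest (``id<TAB>class``); the manifest wins when
both are present.  Splits are stratified and fully seed-deterministic.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)
POSITIVE_LABEL = "CML"
NEGATIVE_LABEL = "Control"

_LABEL_TAG = re.compile(r"\|label=([^|\s]+)")
_STRIP = re.compile(r"[\s0-9]+")


@dataclass(frozen=True)
class ProteinSequence:
    """A validated amino-acid sequence with an optional binary class label."""

    id: str
    residues: str
    label: str | None = None

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residues")
        bad = set(self.residues) - _CANONICAL_SET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: non-canonical residues {sorted(bad)}"
            )

    def __len__(self):
        return len(self.residues)


@dataclass
class LabeledDataset:
    """An ordered, id-unique collection of sequences."""

    sequences: list[ProteinSequence]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for seq in self.sequences:
            if seq.id in seen:
                raise ValueError(f"duplicate sequence id: {seq.id!r}")
            seen.add(seq.id)

    def __len__(self):
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sequences:
            key = s.label if s.label is not None else "<unlabeled>"
            counts[key] = counts.get(key, 0) + 1
        return counts

    def subset(self, ids: list[str]) -> "LabeledDataset":
        by_id = {s.id: s for s in self.sequences}
        return LabeledDataset([by_id[i] for i in ids])


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions plus the shuffling seed."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if any(not (0.0 < f < 1.0) for f in self.fractions):
            raise ValueError(f"each fraction must lie in (0,1): {self.fractions}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1: {self.fractions}")


def validate_sequence(raw: str) -> tuple[str | None, str | None]:
    """Clean a raw residue string.

    Uppercases and strips whitespace/digits.  Any remaining non-canonical
    code (including B, J, O, U, X, Z and ``*``) rejects the record, mirroring
    the exclusion of incomplete/ambiguous database entries.

    Returns ``(cleaned, None)`` on success or ``(None, reason)`` on rejection.
    """
    if raw is None:
        raise ValueError("raw sequence is None")
    cleaned = _STRIP.sub("", raw).upper()
    if not cleaned:
        return None, "empty after cleaning"
    bad = set(cleaned) - _CANONICAL_SET
    if bad:
        return None, f"non-canonical residues: {''.join(sorted(bad))}"
    return cleaned, None


def read_label_manifest(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``id<TAB>class`` manifest."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
            labels[parts[0]] = parts[1]
    return labels


def read_fasta(path: str | Path, manifest: str | Path | None = None) -> LabeledDataset:
    """Read a labeled FASTA file into a validated dataset.

    Records failing :func:`validate_sequence` are skipped and recorded on the
    returned dataset's ``skipped`` list together with the reason.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = read_label_manifest(manifest) if manifest is not None else {}

    sequences: list[ProteinSequence] = []
    skipped: list[tuple[str, str]] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        rid = record.id.split("|label=")[0]
        if rid in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rid!r}")
        seen.add(rid)
        cleaned, reason = validate_sequence(str(record.seq))
        if cleaned is None:
            skipped.append((rid, reason))
            continue
        label = sidecar.get(rid)
        if label is None:
            m = _LABEL_TAG.search(record.description)
            label = m.group(1) if m else None
        sequences.append(ProteinSequence(rid, cleaned, label))
    if not sequences and not skipped:
        raise ValueError(f"no parseable FASTA records in {path}")
    return LabeledDataset(sequences, skipped=skipped)


def write_fasta(ds: LabeledDataset, path: str | Path, width: int = 60) -> None:
    """Write a dataset to FASTA, carrying labels as ``|label=`` header tags."""
    records = []
    for s in ds.sequences:
        name = s.id if s.label is None else f"{s.id}|label={s.label}"
        records.append(SeqRecord(Seq(s.residues), id=name, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_label_manifest(ds: LabeledDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in ds.sequences:
            if s.label is not None:
                fh.write(f"{s.id}\t{s.label}\n")


def stratified_split(
    ds: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Split into train/validation/test with deterministic rounding.

    Per class: sizes are the floor of each fraction times the class size,
    with the remainder assigned to the training split.  Shuffling is driven
    solely by ``spec.seed``.
    """
    unlabeled = [s.id for s in ds.sequences if s.label is None]
    if unlabeled:
        raise ValueError(f"unlabeled sequences cannot be split: {unlabeled[:5]}")
    by_class: dict[str, list[ProteinSequence]] = {}
    for s in ds.sequences:
        by_class.setdefault(s.label, []).append(s)
    for cls, members in by_class.items():
        if len(members) < 3:
            raise ValueError(
                f"class {cls!r} has {len(members)} sequences; need at least 3"
            )

    rng = np.random.default_rng(spec.seed)
    parts: tuple[list, list, list] = ([], [], [])
    for cls in sorted(by_class):
        members = by_class[cls]
        order = rng.permutation(len(members))
        n = len(members)
        n_val = int(np.floor(spec.fractions[1] * n))
        n_test = int(np.floor(spec.fractions[2] * n))
        n_train = int(np.floor(spec.fractions[0] * n))
        n_train += n - (n_train + n_val + n_test)  # remainder -> train
        shuffled = [members[i] for i in order]
        parts[0].extend(shuffled[:n_train])
        parts[1].extend(shuffled[n_train : n_train + n_val])
        parts[2].extend(shuffled[n_train + n_val :])
    return tuple(LabeledDataset(p) for p in parts)


def write_split_manifest(
    splits: dict[str, LabeledDataset], path: str | Path
) -> None:
    with open(path, "w") as fh:
        json.dump({name: ds.ids for name, ds in splits.items()}, fh, indent=1)
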