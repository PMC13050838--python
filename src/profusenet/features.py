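"""Per-sequence descriptors and their fusion into a single feature vector.

Three components are computed per sequence and concatenated in fixed order:

* a pooled residue-embedding vector (128-dim by default),
* type-I pseudo amino acid composition (20 + lambda = 25-dim by default),
* dipeptide composition reduced by variance-ranked selection (229-dim
  by default, from the canonical 400 ordered pairs).

Selection and z-score normalization are fitted on the training split only
and applied frozen elsewhere.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import CANONICAL_RESIDUES, ProteinSequence

AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}
DIPEPTIDES = ["".join(p) for p in itertools.product(CANONICAL_RESIDUES, repeat=2)]

# Standard per-residue physicochemical scales used by type-I PseAAC:
# hydrophobicity, hydrophilicity (Hopp-Woods), and side-chain mass.
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


def _standardized_property_matrix(tables: list[dict[str, float]]) -> np.ndarray:
    """(n_props, 20) property matrix, each row zero mean / unit variance."""
    mat = np.array([[t[aa] for aa in CANONICAL_RESIDUES] for t in tables])
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    return (mat - mu) / sd


DEFAULT_PROPERTIES = _standardized_property_matrix(
    [_HYDROPHOBICITY, _HYDROPHILICITY, _SIDE_CHAIN_MASS]
)


@dataclass(frozen=True)
class PseAACConfig:
    lambda_: int = 5
    weight: float = 0.05
    properties: np.ndarray = field(default_factory=lambda: DEFAULT_PROPERTIES)

    def __post_init__(self):
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.properties.shape[1] != 20:
            raise ValueError("property table must cover all 20 residues")

    @property
    def dim(self) -> int:
        return 20 + self.lambda_


def pseaac(seq: ProteinSequence | str, cfg: PseAACConfig = PseAACConfig()) -> np.ndarray:
    """Classic type-I pseudo amino acid composition (20 + lambda values, sum 1)."""
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    n = len(residues)
    if n <= cfg.lambda_:
        raise ValueError(
            f"sequence length {n} must exceed sequence-order depth {cfg.lambda_}"
        )
    idx = np.array([AA_INDEX[a] for a in residues])
    freqs = np.bincount(idx, minlength=20) / n
    props = cfg.properties[:, idx]  # (n_props, n)
    thetas = np.empty(cfg.lambda_)
    for k in range(1, cfg.lambda_ + 1):
        diff = props[:, :-k] - props[:, k:]
        thetas[k - 1] = np.mean(diff * diff)  # mean over props and positions
    denom = 1.0 + cfg.weight * thetas.sum()
    return np.concatenate([freqs / denom, cfg.weight * thetas / denom])


def dpc(seq: ProteinSequence | str) -> np.ndarray:
    """Normalized frequencies of the 400 ordered dipeptides (lexicographic)."""
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    n = len(residues)
    if n < 2:
        raise ValueError(f"sequence length {n} too short for dipeptides")
    idx = np.array([AA_INDEX[a] for a in residues])
    codes = idx[:-1] * 20 + idx[1:]
    return np.bincount(codes, minlength=400) / (n - 1)


@dataclass
class DPCSelector:
    """Variance-ranked retention of dipeptide features, fitted on train only."""

    keep: int = 229
    selected_indices: list[int] = field(default_factory=list)
    fitted: bool = False

    @property
    def selected_names(self) -> list[str]:
        return [DIPEPTIDES[i] for i in self.selected_indices]

    def transform(self, rows: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("DPCSelector used before fitting")
        return np.atleast_2d(rows)[:, self.selected_indices]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"keep": self.keep, "selected_indices": self.selected_indices}, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "DPCSelector":
        with open(path) as fh:
            d = json.load(fh)
        return cls(keep=d["keep"], selected_indices=d["selected_indices"], fitted=True)


def fit_dpc_selector(train_matrix: np.ndarray, keep: int = 229) -> DPCSelector:
    """Rank the 400 dipeptide columns by training variance (descending).

    Ties are broken lexicographically by dipeptide name, so the selection is
    fully deterministic.
    """
    train_matrix = np.atleast_2d(train_matrix)
    if train_matrix.shape[0] < 2:
        raise ValueError("need at least 2 training rows to rank variances")
    if not (1 <= keep <= 400):
        raise ValueError(f"keep must be in [1, 400]: {keep}")
    variances = train_matrix.var(axis=0)  # population variance
    order = sorted(range(400), key=lambda i: (-variances[i], DIPEPTIDES[i]))
    return DPCSelector(keep=keep, selected_indices=order[:keep], fitted=True)


# ---------------------------------------------------------------------------
# Embedding backends
# ---------------------------------------------------------------------------

class LookupEmbeddingBackend:
    """Offline default: a fixed, seeded per-residue embedding table.

    Requires no downloads; the downstream convolutional stack learns on top
    of this stationary encoding.  ``token_dim`` is 128, so the projection
    step is bypassed.
    """

    name = "lookup"

    def __init__(self, token_dim: int = 128, max_len: int = 512, seed: int = 0):
        self.token_dim = token_dim
        self.max_len = max_len
        rng = np.random.default_rng(seed)
        self.table = rng.normal(0.0, 1.0 / np.sqrt(token_dim), size=(20, token_dim))

    def residue_vectors(self, residues: str) -> np.ndarray:
        idx = np.array([AA_INDEX[a] for a in residues])
        return self.table[idx]


class ProtBertBackend:  # pragma: no cover - requires optional heavyweight deps
    """Pre-trained protein language model backend (optional, 1024-dim)."""

    name = "protbert"

    def __init__(self, max_len: int = 512, model_name: str = "Rostlab/prot_bert"):
        self.token_dim = 1024
        self.max_len = max_len
        try:
            import torch  # noqa: F401
            import transformers  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "the 'protbert' backend needs torch and transformers installed; "
                "use the offline 'lookup' backend instead"
            ) from exc
        raise NotImplementedError(
            "pre-trained backend is a pluggable extension point; not bundled"
        )


def get_backend(name: str, **kwargs):
    if name == "lookup":
        return LookupEmbeddingBackend(**kwargs)
    if name == "protbert":
        return ProtBertBackend(**kwargs)
    raise KeyError(f"unknown embedding backend: {name!r}")


def embed_tokens(
    seq: ProteinSequence | str, backend
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue embedding matrix padded/truncated to the backend's max_len.

    Returns ``(matrix, mask)`` with ``matrix`` of shape (max_len, token_dim);
    sequences longer than max_len keep their first max_len residues, shorter
    ones are right-padded with zero rows and mask 0.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    length = min(len(residues), backend.max_len)
    matrix = np.zeros((backend.max_len, backend.token_dim))
    matrix[:length] = backend.residue_vectors(residues[:length])
    mask = np.zeros(backend.max_len)
    mask[:length] = 1.0
    return matrix, mask


@dataclass
class EmbeddingProjector:
    """Linear map compressing token embeddings (e.g. 1024 -> 128).

    For backends that already emit the target dimension the projection is
    bypassed (identity).
    """

    in_dim: int
    out_dim: int = 128
    matrix: np.ndarray | None = None

    @classmethod
    def seeded(cls, in_dim: int, out_dim: int = 128, seed: int = 0) -> "EmbeddingProjector":
        rng = np.random.default_rng(seed)
        mat = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(in_dim, out_dim))
        return cls(in_dim=in_dim, out_dim=out_dim, matrix=mat)

    @classmethod
    def identity(cls, dim: int) -> "EmbeddingProjector":
        return cls(in_dim=dim, out_dim=dim, matrix=np.eye(dim))


def project_embedding(
    matrix: np.ndarray,
    mask: np.ndarray,
    projector: EmbeddingProjector | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the (optional) projection per position and mask-mean pool.

    Returns ``(projected L x out_dim matrix, pooled out_dim vector)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if projector is None:
        projected = matrix
    else:
        if projector.matrix.shape[0] != matrix.shape[1]:
            raise ValueError(
                f"projection expects {projector.matrix.shape[0]}-dim tokens, "
                f"got {matrix.shape[1]}"
            )
        projected = matrix @ projector.matrix
    count = mask.sum()
    if count == 0:
        raise ValueError("cannot pool a fully masked sequence")
    pooled = (projected * mask[:, None]).sum(axis=0) / count
    return projected, pooled


# ---------------------------------------------------------------------------
# Fusion and normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FusedFeatureVector:
    values: np.ndarray
    slices: dict[str, slice]

    def component(self, name: str) -> np.ndarray:
        return self.values[self.slices[name]]


def fuse(
    embedding128: np.ndarray, pseaac25: np.ndarray, dpc229: np.ndarray,
    expected: tuple[int, int, int] = (128, 25, 229),
) -> FusedFeatureVector:
    """Concatenate the three components in fixed order (embedding, pseaac, dpc)."""
    parts = {"embedding": embedding128, "pseaac": pseaac25, "dpc": dpc229}
    slices: dict[str, slice] = {}
    offset = 0
    for (name, vec), exp in zip(parts.items(), expected):
        vec = np.asarray(vec)
        if vec.ndim != 1 or vec.shape[0] != exp:
            raise ValueError(
                f"component {name!r} has length {vec.shape}, expected ({exp},)"
            )
        slices[name] = slice(offset, offset + exp)
        offset += exp
    return FusedFeatureVector(
        values=np.concatenate([parts[n] for n in parts]), slices=slices
    )


@dataclass
class Normalizer:
    """Per-feature z-scoring, fitted on the training split only.

    Uses the population standard deviation; constant columns map to 0.
    """

    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    fitted: bool = False

    def transform(self, rows: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("Normalizer used before fitting")
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        out = np.zeros_like(rows)
        nz = self.sigma > 0
        out[:, nz] = (rows[:, nz] - self.mu[nz]) / self.sigma[nz]
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"mu": self.mu.tolist(), "sigma": self.sigma.tolist()}, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "Normalizer":
        with open(path) as fh:
            d = json.load(fh)
        return cls(mu=np.array(d["mu"]), sigma=np.array(d["sigma"]), fitted=True)


def fit_normalizer(train_rows: np.ndarray) -> Normalizer:
    train_rows = np.atleast_2d(np.asarray(train_rows, dtype=float))
    return Normalizer(
        mu=train_rows.mean(axis=0), sigma=train_rows.std(axis=0), fitted=True
    )


def apply_normalizer(normalizer: Normalizer, rows: np.ndarray) -> np.ndarray:
    return normalizer.transform(rows)


# ---------------------------------------------------------------------------
# Dataset-level featurization
# ---------------------------------------------------------------------------

COMPONENT_DIMS = {"embedding": 128, "pseaac": 25, "dpc": 229}


@dataclass(frozen=True)
class FeatureConfig:
    """Everything needed to turn sequences into model inputs."""

    backend: str = "lookup"
    token_dim: int = 128
    max_len: int = 512
    embed_seed: int = 0
    pseaac: PseAACConfig = field(default_factory=PseAACConfig)
    dpc_keep: int = 229
    components: tuple[str, ...] = ("embedding", "pseaac", "dpc")

    @property
    def fusion_dim(self) -> int:
        dims = {
            "embedding": self.token_dim if self.token_dim != 1024 else 128,
            "pseaac": self.pseaac.dim,
            "dpc": self.dpc_keep,
        }
        return sum(dims[c] for c in self.components)


@dataclass
class FeaturizedSplit:
    """Model-ready arrays for one data split.

    ``tokens`` holds residue indices (-1 = padding) so the embedding lookup
    can be done lazily per batch; ``fused`` is already z-scored.
    """

    ids: list[str]
    tokens: np.ndarray       # (N, L) int16, -1 where padded
    mask: np.ndarray         # (N, L) float
    fused: np.ndarray        # (N, fusion_dim) normalized
    labels: np.ndarray       # (N,) int, Control=0 / CML=1
    embedding_table: np.ndarray  # (20, token_dim)

    def __len__(self):
        return len(self.ids)

    def token_matrix(self, rows: np.ndarray | list[int]) -> np.ndarray:
        """(n, L, token_dim) embedded tokens for the given row indices."""
        ids = self.tokens[rows]
        mat = self.embedding_table[np.clip(ids, 0, None)]
        mat[ids < 0] = 0.0
        return mat


@dataclass
class FeaturePipeline:
    """Frozen featurization artifacts (backend table, selector, normalizer)."""

    config: FeatureConfig
    backend: LookupEmbeddingBackend
    selector: DPCSelector
    normalizer: Normalizer
    fit_ids: list[str]

    def encode_tokens(self, ds) -> tuple[np.ndarray, np.ndarray]:
        n, length = len(ds), self.config.max_len
        tokens = np.full((n, length), -1, dtype=np.int16)
        mask = np.zeros((n, length))
        for i, seq in enumerate(ds):
            m = min(len(seq), length)
            tokens[i, :m] = [AA_INDEX[a] for a in seq.residues[:m]]
            mask[i, :m] = 1.0
        return tokens, mask

    def raw_fused(self, ds) -> np.ndarray:
        """Unnormalized fused rows in component order for a dataset."""
        rows = []
        for seq in ds:
            parts = []
            for comp in self.config.components:
                if comp == "embedding":
                    matrix, mask = embed_tokens(seq, self.backend)
                    _, pooled = project_embedding(matrix, mask, None)
                    parts.append(pooled)
                elif comp == "pseaac":
                    parts.append(pseaac(seq, self.config.pseaac))
                elif comp == "dpc":
                    parts.append(self.selector.transform(dpc(seq))[0])
                else:
                    raise KeyError(f"unknown feature component: {comp!r}")
            rows.append(np.concatenate(parts))
        return np.array(rows)

    def featurize(self, ds) -> FeaturizedSplit:
        tokens, mask = self.encode_tokens(ds)
        fused = self.normalizer.transform(self.raw_fused(ds))
        labels = np.array(
            [0 if s.label != "CML" else 1 for s in ds], dtype=np.int64
        )
        return FeaturizedSplit(
            ids=ds.ids,
            tokens=tokens,
            mask=mask,
            fused=fused,
            labels=labels,
            embedding_table=self.backend.table,
        )


def fit_feature_pipeline(train_ds, config: FeatureConfig = FeatureConfig()) -> FeaturePipeline:
    """Fit selector and normalizer on the training split only."""
    backend = get_backend(
        config.backend,
        token_dim=config.token_dim,
        max_len=config.max_len,
        seed=config.embed_seed,
    )
    if "dpc" in config.components:
        train_dpc = np.array([dpc(s) for s in train_ds])
        selector = fit_dpc_selector(train_dpc, keep=config.dpc_keep)
    else:
        selector = DPCSelector(keep=config.dpc_keep, selected_indices=[], fitted=True)
    pipeline = FeaturePipeline(
        config=config,
        backend=backend,
        selector=selector,
        normalizer=Normalizer(),
        fit_ids=list(train_ds.ids),
    )
    pipeline.normalizer = fit_normalizer(pipeline.raw_fused(train_ds))
    return pipeline
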