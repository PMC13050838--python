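"""Integrated-Gradients attribution over token-embedding positions.

The path integral from an all-zero baseline to the input is approximated
with a midpoint Riemann sum; the fused descriptor vector (when present)
travels the same path so that the completeness identity holds for the
target-class logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor
from .model import DualCNNBiLSTM


@dataclass(frozen=True)
class IGConfig:
    steps: int = 50
    target_class: int = 1

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


@dataclass
class AttributionMap:
    """Per-position importance (length = unpadded sequence length)."""

    scores: np.ndarray
    fused_attribution: float
    completeness_gap: float
    target_class: int
    channel_scores: np.ndarray = field(repr=False, default=None)


def _target_logit(model: DualCNNBiLSTM, tokens: Tensor, mask: np.ndarray,
                  fused: Tensor | None, target: int) -> np.ndarray:
    logits = model.forward_tensor(tokens, mask, fused, train=False)
    return logits.data[:, target]


def integrated_gradients(
    model: DualCNNBiLSTM,
    tokens: np.ndarray,
    mask: np.ndarray,
    fused: np.ndarray | None = None,
    cfg: IGConfig = IGConfig(),
) -> AttributionMap:
    """Attribute the target-class logit to input positions.

    ``tokens``: (L, embed_dim) embedded sequence; ``mask``: (L,);
    ``fused``: (fusion_dim,) when the model uses late fusion.

    All Riemann-sum interpolation points are evaluated as one batch, so a
    single backward pass yields every step's gradient.
    """
    tokens = np.asarray(tokens, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    m = cfg.steps
    alphas = (np.arange(1, m + 1) - 0.5) / m  # midpoint rule

    batch_tokens = Tensor(alphas[:, None, None] * tokens[None])
    batch_mask = np.broadcast_to(mask, (m, mask.shape[0]))
    use_fusion = model.spec.use_late_fusion
    if use_fusion:
        if fused is None:
            raise ValueError("model uses late fusion: a fused vector is required")
        fused = np.asarray(fused, dtype=np.float64)
        batch_fused = Tensor(alphas[:, None] * fused[None])
    else:
        batch_fused = None

    logits = model.forward_tensor(batch_tokens, batch_mask, batch_fused, train=False)
    target_sum = logits.data[:, cfg.target_class].sum()  # noqa: F841 (diagnostic)
    selector = np.zeros_like(logits.data)
    selector[:, cfg.target_class] = 1.0
    # Seed the backward pass with d(sum of target logits)/dlogits.
    logits.grad = selector
    for node in _topo(logits):
        if node._backward is not None:
            node._backward()

    token_attr = tokens * batch_tokens.grad.mean(axis=0)  # (L, D)
    fused_attr = 0.0
    if use_fusion:
        fused_attr = float((fused * batch_fused.grad.mean(axis=0)).sum())

    length = int(mask.sum())
    channel_scores = token_attr[:length]
    scores = channel_scores.sum(axis=1)  # signed sum keeps completeness

    f_input = _target_logit(
        model, Tensor(tokens[None]), mask[None],
        Tensor(fused[None]) if use_fusion else None, cfg.target_class,
    )[0]
    f_baseline = _target_logit(
        model, Tensor(np.zeros_like(tokens)[None]), mask[None],
        Tensor(np.zeros_like(fused)[None]) if use_fusion else None,
        cfg.target_class,
    )[0]
    gap = abs(float(token_attr.sum()) + fused_attr - (f_input - f_baseline))
    return AttributionMap(
        scores=scores,
        fused_attribution=fused_attr,
        completeness_gap=gap,
        target_class=cfg.target_class,
        channel_scores=channel_scores,
    )


def _topo(root: Tensor) -> list[Tensor]:
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return list(reversed(topo))


def top_k_positions(attribution: AttributionMap, k: int) -> list[int]:
    """Positions (1-based) ranked by score descending; ties by position."""
    if k <= 0:
        raise ValueError("k must be positive")
    scores = attribution.scores
    if k > len(scores):
        raise ValueError(f"k={k} exceeds sequence length {len(scores)}")
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return [i + 1 for i in order[:k]]


def attribution_table(
    seq_id: str, residues: str, attribution: AttributionMap
) -> list[tuple[str, int, str, float]]:
    """Rows (id, position 1-based, residue, score) for TSV export."""
    return [
        (seq_id, i + 1, residues[i], float(score))
        for i, score in enumerate(attribution.scores)
    ]
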