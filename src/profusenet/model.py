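"""Dual-branch CNN -> BiLSTM -> GAP -> dense -> softmax classifier.

Two parallel 1-D convolutions (kernel sizes 3 and 7, 128 filters each,
"same" padding) read the embedded sequence; their pooled feature maps are
concatenated channel-wise and fed to a bidirectional LSTM (64 units per
direction).  Mask-aware global average pooling yields a fixed-length
vector which, under late fusion, is concatenated with the z-scored
382-dim descriptor vector before the dense head.

Architecture toggles (``use_conv``, ``dual_branch``, ``use_bilstm``,
``use_late_fusion``) express the ablation variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class ModelSpec:
    embed_dim: int = 128
    kernel_a: int = 3
    kernel_b: int = 7
    filters: int = 128
    pool_size: int = 2
    pool_stride: int = 2
    bilstm_units: int = 64
    dense_units: int = 128
    dropout: float = 0.5
    n_classes: int = 2
    use_late_fusion: bool = True
    fusion_dim: int = 382
    use_conv: bool = True
    dual_branch: bool = True
    use_bilstm: bool = True

    def __post_init__(self):
        for k in (self.kernel_a, self.kernel_b):
            if k <= 0 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and positive: {k}")
        for v in (self.embed_dim, self.filters, self.bilstm_units,
                  self.dense_units, self.n_classes):
            if v <= 0:
                raise ValueError("all unit counts must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError(f"dropout must be in [0, 1): {self.dropout}")
        if not (self.use_conv or self.use_bilstm):
            raise ValueError("at least one of conv / bilstm stages is required")

    @property
    def conv_out_channels(self) -> int:
        if not self.use_conv:
            return self.embed_dim
        return self.filters * (2 if self.dual_branch else 1)

    @property
    def gap_dim(self) -> int:
        if self.use_bilstm:
            return 2 * self.bilstm_units
        return self.conv_out_channels

    @property
    def dense_in_dim(self) -> int:
        return self.gap_dim + (self.fusion_dim if self.use_late_fusion else 0)

    def to_dict(self) -> dict:
        return asdict(self)


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class DualCNNBiLSTM:
    """The classifier; parameters live in ``self.params`` (name -> Tensor)."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        if spec.use_conv and spec.dual_branch and spec.kernel_a == spec.kernel_b:
            warnings.warn(
                "kernel_a == kernel_b: the dual branches are degenerate",
                stacklevel=2,
            )
        self.spec = spec
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        d = spec.embed_dim

        if spec.use_conv:
            for name, k in (("a", spec.kernel_a), ("b", spec.kernel_b)):
                if name == "b" and not spec.dual_branch:
                    continue
                self._add(f"conv_{name}.W",
                          _glorot(rng, (k, d, spec.filters), k * d, spec.filters))
                self._add(f"conv_{name}.b", np.zeros(spec.filters))

        if spec.use_bilstm:
            h = spec.bilstm_units
            in_dim = spec.conv_out_channels
            for direction in ("fwd", "bwd"):
                self._add(f"lstm_{direction}.Wx",
                          _glorot(rng, (in_dim, 4 * h), in_dim, 4 * h))
                self._add(f"lstm_{direction}.Wh",
                          _glorot(rng, (h, 4 * h), h, 4 * h))
                bias = np.zeros(4 * h)
                bias[h : 2 * h] = 1.0  # forget-gate bias
                self._add(f"lstm_{direction}.b", bias)

        self._add("dense.W",
                  _glorot(rng, (spec.dense_in_dim, spec.dense_units),
                          spec.dense_in_dim, spec.dense_units))
        self._add("dense.b", np.zeros(spec.dense_units))
        self._add("out.W",
                  _glorot(rng, (spec.dense_units, spec.n_classes),
                          spec.dense_units, spec.n_classes))
        self._add("out.b", np.zeros(spec.n_classes))

    def _add(self, name: str, data: np.ndarray):
        self.params[name] = Tensor(data, requires_grad=True)

    # ------------------------------------------------------------------
    def _lstm_direction(self, xs: Tensor, direction: str) -> list[Tensor]:
        n, t_steps, _ = xs.shape
        h_units = self.spec.bilstm_units
        wx = self.params[f"lstm_{direction}.Wx"]
        wh = self.params[f"lstm_{direction}.Wh"]
        b = self.params[f"lstm_{direction}.b"]
        h = Tensor(np.zeros((n, h_units)))
        c = Tensor(np.zeros((n, h_units)))
        order = range(t_steps) if direction == "fwd" else range(t_steps - 1, -1, -1)
        outputs: list[Tensor | None] = [None] * t_steps
        for t in order:
            x_t = nn.select_time(xs, t)
            gates = nn.add(nn.add(nn.matmul(x_t, wx), nn.matmul(h, wh)), b)
            i = nn.sigmoid(nn.getcols(gates, 0, h_units))
            f = nn.sigmoid(nn.getcols(gates, h_units, 2 * h_units))
            g = nn.tanh(nn.getcols(gates, 2 * h_units, 3 * h_units))
            o = nn.sigmoid(nn.getcols(gates, 3 * h_units, 4 * h_units))
            c = nn.add(nn.mul(f, c), nn.mul(i, g))
            h = nn.mul(o, nn.tanh(c))
            outputs[t] = h
        return outputs

    def _dropout(self, x: Tensor, train: bool, rng: np.random.Generator | None) -> Tensor:
        p = self.spec.dropout
        if not train or p == 0.0:
            return x
        keep = rng.random(x.shape) >= p
        return nn.scale(x, keep / (1.0 - p))

    def forward_tensor(
        self,
        tokens: Tensor,
        mask: np.ndarray,
        fused: Tensor | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Return class logits (N, C) as a graph node.

        ``tokens``: (N, L, embed_dim); ``mask``: (N, L); ``fused``:
        (N, fusion_dim) when late fusion is enabled.
        """
        spec = self.spec
        mask = np.asarray(mask, dtype=np.float64)
        # Padded token rows must never influence the output.
        x = nn.scale(tokens, mask[:, :, None])

        if spec.use_conv:
            branches = []
            for name in ("a",) + (("b",) if spec.dual_branch else ()):
                conv = nn.relu(
                    nn.conv1d(x, self.params[f"conv_{name}.W"],
                              self.params[f"conv_{name}.b"])
                )
                pooled = nn.maxpool1d(conv, spec.pool_size, spec.pool_stride)
                branches.append(self._dropout(pooled, train, rng))
            seq = branches[0] if len(branches) == 1 else nn.concat(branches, axis=2)
            t2 = mask.shape[1] // spec.pool_stride
            pooled_mask = mask[:, : t2 * spec.pool_stride].reshape(
                mask.shape[0], t2, spec.pool_stride
            ).max(axis=2)
        else:
            seq = x
            pooled_mask = mask

        if spec.use_bilstm:
            fwd = self._lstm_direction(seq, "fwd")
            bwd = self._lstm_direction(seq, "bwd")
            steps = [nn.concat([f, b], axis=1) for f, b in zip(fwd, bwd)]
            seq = nn.stack_time(steps)

        gap = nn.masked_mean(seq, pooled_mask)

        if spec.use_late_fusion:
            if fused is None:
                raise ValueError("late fusion enabled but no fused vector given")
            if fused.shape[-1] != spec.fusion_dim:
                raise ValueError(
                    f"fused vector has dim {fused.shape[-1]}, "
                    f"spec expects {spec.fusion_dim}"
                )
            gap = nn.concat([gap, fused], axis=1)

        hidden = nn.relu(
            nn.add(nn.matmul(gap, self.params["dense.W"]), self.params["dense.b"])
        )
        hidden = self._dropout(hidden, train, rng)
        logits = nn.add(
            nn.matmul(hidden, self.params["out.W"]), self.params["out.b"]
        )
        return logits

    def forward(
        self,
        tokens: np.ndarray,
        mask: np.ndarray,
        fused: np.ndarray | None = None,
    ) -> np.ndarray:
        """Inference-mode class probabilities (dropout off)."""
        fused_t = None if fused is None else Tensor(np.atleast_2d(fused))
        tokens = np.asarray(tokens, dtype=np.float64)
        if tokens.ndim == 2:
            tokens = tokens[None]
            mask = np.atleast_2d(mask)
        logits = self.forward_tensor(Tensor(tokens), mask, fused_t, train=False)
        return nn.softmax(logits.data)

    # ------------------------------------------------------------------
    def parameter_list(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self.params[k].data = v.copy()

    def save(self, path) -> None:
        np.savez(path, **self.get_weights())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_weights({k: data[k] for k in data.files})


def build_model(spec: ModelSpec, seed: int = 0) -> DualCNNBiLSTM:
    """Deterministically initialize a classifier from its spec."""
    return DualCNNBiLSTM(spec, seed=seed)


def count_parameters(model) -> int:
    """Exact trainable parameter count (stable across runs)."""
    return int(sum(p.data.size for p in model.params.values()))
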