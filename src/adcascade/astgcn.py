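"""Attention-based spatial-temporal graph convolutional network (stage 1).

The gait classifier stacks blocks of graph convolution over the skeleton
(spatial) followed by 1-D convolution along the frame axis (temporal), with a
learnable edge-importance mask per block and partition subset, and an
hourglass attention module that gates features multiplicatively.  A global
average pool over time and joints feeds a softmax head that separates
healthy controls from patients.

The spatial operator per partition subset k is

    f_out = ( Λ^{-1/2} ((A + I) ⊙ M_k) Λ^{-1/2} ) f_in W_k ,

where M_k is the edge-importance mask (initialized to ones, so an untrained
layer reduces exactly to the unmasked normalized-adjacency form).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .graph import PartitionedAdjacency

F32 = np.float32


@dataclass(frozen=True)
class AstGcnConfig:
    """Backbone plan for the gait network.

    The default follows the reference ST-GCN plan: ten blocks with channels
    64/128/256, temporal kernel 9, temporal stride 2 at blocks 5 and 8, one
    hourglass attention module after block 9, dropout 0.5 from mid-network on.
    """

    channels: tuple[int, ...] = (64, 64, 64, 64, 128, 128, 128, 256, 256, 256)
    strides: tuple[int, ...] = (1, 1, 1, 1, 2, 1, 1, 2, 1, 1)
    temporal_kernel: int = 9
    attention: str = "after-9"  # none | after-3 | after-6 | after-9 | all
    num_classes: int = 2
    dropout: float = 0.5
    dropout_from_block: int = 5
    in_channels: int = 3

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")
        for b in self.attention_blocks():
            if not 1 <= b <= len(self.channels):
                raise ValueError(f"attention placement {b} outside 1..{len(self.channels)}")

    def attention_blocks(self) -> tuple[int, ...]:
        if self.attention == "none":
            return ()
        if self.attention == "all":
            return (3, 6, 9)
        if self.attention.startswith("after-"):
            return (int(self.attention.split("-", 1)[1]),)
        raise ValueError(f"unknown attention placement {self.attention!r}")

    @classmethod
    def small(cls, attention: str = "after-3", dropout: float = 0.0) -> "AstGcnConfig":
        """A narrow five-block plan for desk-scale experiments."""
        return cls(
            channels=(16, 16, 32, 32, 64),
            strides=(1, 1, 2, 1, 2),
            temporal_kernel=9,
            attention=attention,
            dropout=dropout,
            dropout_from_block=4,
        )


class GraphSpatialConv(nn.Layer):
    """Per-frame graph convolution with edge-importance masks.

    Weights W_k are 1×1 channel maps per partition subset; the joint axis is
    mixed by the normalized subset operator elementwise-scaled by the
    learnable mask M_k.  No temporal mixing happens here.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        subsets: np.ndarray,
        rng: np.random.Generator,
        edge_importance: bool = True,
        name: str = "gcn",
    ) -> None:
        K, V, _ = subsets.shape
        self.A = np.asarray(subsets, dtype=F32)
        self.W = nn.Param(nn.he_normal(rng, (K, out_ch, in_ch), in_ch * K), f"{name}.W")
        self.b = nn.Param(np.zeros(out_ch), f"{name}.b")
        self.M = nn.Param(np.ones((K, V, V)), f"{name}.M") if edge_importance else None
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache: tuple | None = None

    def params(self) -> list[nn.Param]:
        out = [self.W, self.b]
        if self.M is not None:
            out.append(self.M)
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=F32)
        B, C, T, V = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {C}")
        if V != self.A.shape[1]:
            raise ValueError(f"clip has V={V} joints but graph has {self.A.shape[1]}")
        K = self.A.shape[0]
        y = np.zeros((B, self.out_ch, T, V), dtype=F32)
        hs = []
        for k in range(K):
            h = np.tensordot(self.W.value[k], x, axes=(1, 1)).transpose(1, 0, 2, 3)
            Ak = self.A[k] * self.M.value[k] if self.M is not None else self.A[k]
            y += h @ Ak.T
            hs.append(h)
        y += self.b.value[None, :, None, None]
        self._cache = (x, hs)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, hs = self._cache
        gy = np.ascontiguousarray(gy, dtype=F32)
        K = self.A.shape[0]
        gx = np.zeros_like(x)
        for k in range(K):
            Ak = self.A[k] * self.M.value[k] if self.M is not None else self.A[k]
            gh = gy @ Ak
            if self.M is not None:
                V = self.A.shape[1]
                gAk = gy.reshape(-1, V).T @ hs[k].reshape(-1, V)
                self.M.grad[k] += gAk * self.A[k]
            self.W.grad[k] += np.tensordot(gh, x, axes=([0, 2, 3], [0, 2, 3]))
            gx += np.tensordot(gh, self.W.value[k], axes=(1, 0)).transpose(0, 3, 1, 2)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        return gx


def spatial_graph_conv(
    features: np.ndarray,
    subsets: np.ndarray,
    edge_masks: np.ndarray | None,
    weights: np.ndarray,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Functional form of the masked spatial graph convolution.

    ``features`` is (C_in, T, V) or (B, C_in, T, V); ``subsets`` the (K, V, V)
    normalized partition operators; ``edge_masks`` the (K, V, V) masks (None
    for all-ones); ``weights`` the (K, C_out, C_in) channel maps.
    """
    squeeze = features.ndim == 3
    x = features[None] if squeeze else features
    K = subsets.shape[0]
    y = None
    for k in range(K):
        h = np.tensordot(weights[k], x, axes=(1, 1)).transpose(1, 0, 2, 3)
        Ak = subsets[k] if edge_masks is None else subsets[k] * edge_masks[k]
        term = h @ Ak.T
        y = term if y is None else y + term
    if bias is not None:
        y = y + bias[None, :, None, None]
    return y[0] if squeeze else y


class STGCNBlock(nn.Layer):
    """Graph conv → BN → ReLU → temporal conv → BN, residual, ReLU, dropout."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        subsets: np.ndarray,
        temporal_kernel: int,
        stride: int,
        dropout: float,
        rng: np.random.Generator,
        residual: bool = True,
        name: str = "block",
    ) -> None:
        self.gcn = GraphSpatialConv(in_ch, out_ch, subsets, rng, name=f"{name}.gcn")
        self.bn1 = nn.BatchNorm2d(out_ch, name=f"{name}.bn1")
        self.relu1 = nn.ReLU()
        self.tcn = nn.Conv2d(
            out_ch, out_ch, (temporal_kernel, 1), (stride, 1), "same", rng, name=f"{name}.tcn"
        )
        self.bn2 = nn.BatchNorm2d(out_ch, name=f"{name}.bn2")
        self.relu_out = nn.ReLU()
        self.drop = nn.Dropout(dropout, rng)
        if not residual:
            self.res: nn.Layer | None = None
            self._identity = False
        elif in_ch == out_ch and stride == 1:
            self.res = None
            self._identity = True
        else:
            self.res = nn.Sequential([
                nn.Conv2d(in_ch, out_ch, (1, 1), (stride, 1), "same", rng, name=f"{name}.res"),
                nn.BatchNorm2d(out_ch, name=f"{name}.resbn"),
            ])
            self._identity = False

    def params(self) -> list[nn.Param]:
        out = self.gcn.params() + self.bn1.params() + self.tcn.params() + self.bn2.params()
        if self.res is not None:
            out += self.res.params()
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.res is not None:
            r = self.res.forward(x, train=train)
        elif self._identity:
            r = x
        else:
            r = None
        y = self.gcn.forward(x, train=train)
        y = self.bn1.forward(y, train=train)
        y = self.relu1.forward(y, train=train)
        y = self.tcn.forward(y, train=train)
        y = self.bn2.forward(y, train=train)
        if r is not None:
            y = y + r
        y = self.relu_out.forward(y, train=train)
        return self.drop.forward(y, train=train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = self.drop.backward(gy)
        gy = self.relu_out.backward(gy)
        g_main = self.bn2.backward(gy)
        g_main = self.tcn.backward(g_main)
        g_main = self.relu1.backward(g_main)
        g_main = self.bn1.backward(g_main)
        gx = self.gcn.backward(g_main)
        if self.res is not None:
            gx = gx + self.res.backward(gy)
        elif self._identity:
            gx = gx + gy
        return gx


class HourglassAttention(nn.Layer):
    """Temporal hourglass gate: downsample ×4 twice, upsample back, sigmoid.

    The mask branch applies two stride-4 temporal convolutions (T → T/4 →
    T/16), two nearest-neighbor upsampling steps back to T, a 1×1 convolution
    and a sigmoid, producing a gate g ∈ (0, 1).  The output is the trunk
    scaled by (1 + g), so attention can only emphasize, never erase.
    """

    def __init__(
        self,
        channels: int,
        rng: np.random.Generator,
        kernel: int = 5,
        factor: int = 4,
        name: str = "att",
    ) -> None:
        self.factor = factor
        self.down1 = nn.Conv2d(channels, channels, (kernel, 1), (factor, 1), "same", rng, name=f"{name}.down1")
        self.dbn1 = nn.BatchNorm2d(channels, name=f"{name}.dbn1")
        self.drelu1 = nn.ReLU()
        self.down2 = nn.Conv2d(channels, channels, (kernel, 1), (factor, 1), "same", rng, name=f"{name}.down2")
        self.dbn2 = nn.BatchNorm2d(channels, name=f"{name}.dbn2")
        self.drelu2 = nn.ReLU()
        self.up1 = nn.UpsampleH(factor)
        self.up2 = nn.UpsampleH(factor)
        self.head = nn.Conv2d(channels, channels, (1, 1), (1, 1), "same", rng, name=f"{name}.head")
        self.sigmoid = nn.Sigmoid()
        self._cache: tuple | None = None

    def params(self) -> list[nn.Param]:
        return (
            self.down1.params() + self.dbn1.params() + self.down2.params()
            + self.dbn2.params() + self.head.params()
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=F32)
        T = x.shape[2]
        h1 = self.drelu1.forward(self.dbn1.forward(self.down1.forward(x, train), train), train)
        t1 = h1.shape[2]
        h2 = self.drelu2.forward(self.dbn2.forward(self.down2.forward(h1, train), train), train)
        u1 = self.up1.forward(h2, train)[:, :, :t1, :]
        u2 = self.up2.forward(u1, train)[:, :, :T, :]
        g = self.sigmoid.forward(self.head.forward(u2, train), train)
        self._cache = (x, g, t1, u1.shape[2] * self.factor, h2.shape[2] * self.factor)
        return x * (1.0 + g)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, g, t1, full2, full1 = self._cache
        gy = np.asarray(gy, dtype=F32)
        gx = gy * (1.0 + g)
        gg = gy * x
        gu2 = self.head.backward(self.sigmoid.backward(gg))
        pad2 = full2 - gu2.shape[2]
        if pad2:
            gu2 = np.pad(gu2, ((0, 0), (0, 0), (0, pad2), (0, 0)))
        gu1 = self.up2.backward(gu2)
        pad1 = full1 - gu1.shape[2]
        if pad1:
            gu1 = np.pad(gu1, ((0, 0), (0, 0), (0, pad1), (0, 0)))
        gh2 = self.up1.backward(gu1)
        gh1 = self.down2.backward(self.dbn2.backward(self.drelu2.backward(gh2)))
        gx_branch = self.down1.backward(self.dbn1.backward(self.drelu1.backward(gh1)))
        return gx + gx_branch


class AstGcn:
    """The full stage-1 network: clips (B, 3, T, V) → two-class logits."""

    def __init__(self, config: AstGcnConfig, adjacency: PartitionedAdjacency, seed: int = 0) -> None:
        self.config = config
        self.adjacency = adjacency
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        self.input_bn = nn.BatchNorm2d(config.in_channels, name="input_bn")
        att = set(config.attention_blocks())
        self.layers: list[nn.Layer] = []
        self.attention_modules: list[HourglassAttention] = []
        in_ch = config.in_channels
        for bi, (ch, st) in enumerate(zip(config.channels, config.strides), start=1):
            drop = config.dropout if bi >= config.dropout_from_block else 0.0
            self.layers.append(
                STGCNBlock(
                    in_ch, ch, adjacency.subsets, config.temporal_kernel, st,
                    drop, rng, residual=(bi > 1), name=f"block{bi}",
                )
            )
            # dropout layers share one stream so training stays seed-reproducible
            self.layers[-1].drop.rng = self._dropout_rng
            if bi in att:
                module = HourglassAttention(ch, rng, name=f"att{bi}")
                self.layers.append(module)
                self.attention_modules.append(module)
            in_ch = ch
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(in_ch, config.num_classes, rng)

    # -- plumbing ---------------------------------------------------------
    def params(self) -> list[nn.Param]:
        out = self.input_bn.params()
        for layer in self.layers:
            out.extend(layer.params())
        out.extend(self.fc.params())
        return out

    def parameter_count(self) -> int:
        return nn.parameter_count(self.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (B, {self.config.in_channels}, T, V), got {x.shape}")
        if x.shape[3] != self.adjacency.n_nodes:
            raise ValueError(
                f"clip has V={x.shape[3]} joints but the graph has {self.adjacency.n_nodes}"
            )
        h = self.input_bn.forward(x, train=train)
        for layer in self.layers:
            h = layer.forward(h, train=train)
        return self.fc.forward(self.pool.forward(h, train=train), train=train)

    def backward(self, glogits: np.ndarray) -> None:
        g = self.pool.backward(self.fc.backward(glogits))
        for layer in reversed(self.layers):
            g = layer.backward(g)
        self.input_bn.backward(g)

    def predict_proba(self, clips: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Per-clip class probabilities in evaluation mode."""
        out = []
        for start in range(0, len(clips), batch_size):
            logits = self.forward(clips[start : start + batch_size], train=False)
            out.append(nn.softmax(logits))
        return np.concatenate(out, axis=0)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint: all parameters, BN running stats and the config."""
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._batchnorms()):
            arrays[f"bn_{i}_mean"] = bn.running_mean
            arrays[f"bn_{i}_var"] = bn.running_var
        arrays["adjacency_subsets"] = self.adjacency.subsets
        arrays["adjacency_masks"] = self.adjacency.masks
        arrays["adjacency_degrees"] = self.adjacency.degrees
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)

    def _batchnorms(self) -> list[nn.BatchNorm2d]:
        found = [self.input_bn]

        def walk(obj) -> None:
            for attr in vars(obj).values():
                if isinstance(attr, nn.BatchNorm2d):
                    found.append(attr)
                elif isinstance(attr, nn.Sequential):
                    for sub in attr.layers:
                        if isinstance(sub, nn.BatchNorm2d):
                            found.append(sub)

        for layer in self.layers:
            walk(layer)
        return found

    @classmethod
    def load(cls, path: str | Path) -> "AstGcn":
        with np.load(path, allow_pickle=False) as zf:
            cfg = AstGcnConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in json.loads(str(zf["config"])).items()
            })
            adjacency = PartitionedAdjacency(
                subsets=zf["adjacency_subsets"],
                masks=zf["adjacency_masks"],
                degrees=zf["adjacency_degrees"],
            )
            model = cls(cfg, adjacency)
            for i, p in enumerate(model.params()):
                p.value[...] = zf[f"param_{i}"]
            for i, bn in enumerate(model._batchnorms()):
                bn.running_mean[...] = zf[f"bn_{i}_mean"]
                bn.running_var[...] = zf[f"bn_{i}_var"]
        return model
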