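"""Spatial-temporal convolutional network for EEG epochs (stage 2).

Each module applies a spatial convolution (kernel K_s along the electrode
axis) followed by a temporal convolution (kernel K_t along time, where the
stride lives), so the epoch is alternately convolved across channels and
across samples without ever leaving the time domain.  The default plan::

    layer 0:  batch normalization over the 3 input planes
    module 1: 3 → 4,  K_s = 1,  K_t = 33, stride 1
    module 2: 4 → 4,  K_s = 15, K_t = 33, stride 4
    module 3: 4 → 16, K_s = C,  K_t = 33, stride 1   (collapses the electrode axis)
    module 4: 16 → 8, K_s = 1,  K_t = 33, stride 4
    flatten → affine → softmax

On a 3 × 62 × 512 epoch this yields an 8 × 1 × 32 feature map, i.e. a
256-dimensional flattened vector, feeding the two-class (MCI vs AD) head.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn

F32 = np.float32

#: (in_channels, out_channels, K_s, K_t, temporal stride); K_s None means
#: "the full electrode extent" (a valid convolution collapsing it to 1).
DEFAULT_PLAN: tuple[tuple[int, int, int | None, int, int], ...] = (
    (3, 4, 1, 33, 1),
    (4, 4, 15, 33, 4),
    (4, 16, None, 33, 1),
    (16, 8, 1, 33, 4),
)


@dataclass(frozen=True)
class StCnnConfig:
    plan: tuple[tuple[int, int, int | None, int, int], ...] = DEFAULT_PLAN
    n_electrodes: int = 62
    time_points: int = 512  # concatenated eyes-open + eyes-closed length
    num_classes: int = 2

    def __post_init__(self) -> None:
        prev_out = self.plan[0][0]
        for i, (cin, cout, ks, kt, stride) in enumerate(self.plan, start=1):
            if cin != prev_out:
                raise ValueError(f"module {i}: in_channels {cin} != previous out {prev_out}")
            prev_out = cout


class StCnnModule(nn.Layer):
    """One spatial + temporal convolution pair with BN and ELU."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k_spatial: int | None,
        k_temporal: int,
        stride: int,
        n_electrodes: int,
        rng: np.random.Generator,
        name: str = "mod",
    ) -> None:
        ks = n_electrodes if k_spatial is None else int(k_spatial)
        if ks > n_electrodes:
            raise ValueError(
                f"spatial kernel {ks} exceeds electrode extent {n_electrodes}"
            )
        # a full-extent spatial kernel collapses the electrode axis (valid
        # convolution); anything smaller is same-padded
        pad = "valid" if ks == n_electrodes else "same"
        self.spatial = nn.Conv2d(in_ch, out_ch, (ks, 1), (1, 1), pad, rng, name=f"{name}.s")
        self.temporal = nn.Conv2d(out_ch, out_ch, (1, k_temporal), (1, stride), "same", rng, name=f"{name}.t")
        self.bn = nn.BatchNorm2d(out_ch, name=f"{name}.bn")
        self.act = nn.ELU()

    def params(self) -> list[nn.Param]:
        return self.spatial.params() + self.temporal.params() + self.bn.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.spatial.forward(x, train=train)
        y = self.temporal.forward(y, train=train)
        y = self.bn.forward(y, train=train)
        return self.act.forward(y, train=train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.act.backward(gy)
        g = self.bn.backward(g)
        g = self.temporal.backward(g)
        return self.spatial.backward(g)


def stcnn_module(
    x: np.ndarray,
    in_ch: int,
    out_ch: int,
    k_spatial: int | None,
    k_temporal: int,
    stride: int,
    seed: int = 0,
) -> np.ndarray:
    """Functional single-module forward (fresh random weights); shape probe."""
    mod = StCnnModule(
        in_ch, out_ch, k_spatial, k_temporal, stride,
        n_electrodes=x.shape[-2], rng=np.random.default_rng(seed),
    )
    squeeze = x.ndim == 3
    y = mod.forward(x[None] if squeeze else x, train=False)
    return y[0] if squeeze else y


class StCnn:
    """EEG epochs (B, 3, C, 2T) → two-class logits."""

    def __init__(self, config: StCnnConfig = StCnnConfig(), seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        self.input_bn = nn.BatchNorm2d(config.plan[0][0], name="input_bn")
        self.modules: list[StCnnModule] = []
        elec = config.n_electrodes
        for i, (cin, cout, ks, kt, stride) in enumerate(config.plan, start=1):
            mod = StCnnModule(cin, cout, ks, kt, stride, elec, rng, name=f"mod{i}")
            self.modules.append(mod)
            elec = 1 if (ks is None or ks == elec) else elec
        self.flatten = nn.Flatten()
        self.flat_dim = self._probe_flat_dim()
        self.fc = nn.Linear(self.flat_dim, config.num_classes, rng)

    def _probe_flat_dim(self) -> int:
        x = np.zeros(
            (1, self.config.plan[0][0], self.config.n_electrodes, self.config.time_points),
            dtype=F32,
        )
        for mod in self.modules:
            x = mod.forward(x, train=False)
        return int(np.prod(x.shape[1:]))

    def params(self) -> list[nn.Param]:
        out = self.input_bn.params()
        for mod in self.modules:
            out.extend(mod.params())
        out.extend(self.fc.params())
        return out

    def parameter_count(self) -> int:
        return nn.parameter_count(self.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        expected = (self.config.plan[0][0], self.config.n_electrodes, self.config.time_points)
        if x.ndim != 4 or x.shape[1:] != expected:
            raise ValueError(f"expected epochs shaped (B, {expected[0]}, {expected[1]}, {expected[2]}), got {x.shape}")
        h = self.input_bn.forward(x, train=train)
        for mod in self.modules:
            h = mod.forward(h, train=train)
        return self.fc.forward(self.flatten.forward(h, train=train), train=train)

    def backward(self, glogits: np.ndarray) -> None:
        g = self.flatten.backward(self.fc.backward(glogits))
        for mod in reversed(self.modules):
            g = mod.backward(g)
        self.input_bn.backward(g)

    def predict_proba(self, epochs: np.ndarray, batch_size: int = 128) -> np.ndarray:
        out = []
        for start in range(0, len(epochs), batch_size):
            logits = self.forward(np.ascontiguousarray(epochs[start : start + batch_size]), train=False)
            out.append(nn.softmax(logits))
        return np.concatenate(out, axis=0)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._batchnorms()):
            arrays[f"bn_{i}_mean"] = bn.running_mean
            arrays[f"bn_{i}_var"] = bn.running_var
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)

    def _batchnorms(self) -> list[nn.BatchNorm2d]:
        return [self.input_bn] + [mod.bn for mod in self.modules]

    @classmethod
    def load(cls, path: str | Path) -> "StCnn":
        with np.load(path, allow_pickle=False) as zf:
            raw = json.loads(str(zf["config"]))
            raw["plan"] = tuple(tuple(m) for m in raw["plan"])
            model = cls(StCnnConfig(**raw))
            for i, p in enumerate(model.params()):
                p.value[...] = zf[f"param_{i}"]
            for i, bn in enumerate(model._batchnorms()):
                bn.running_mean[...] = zf[f"bn_{i}_mean"]
                bn.running_var[...] = zf[f"bn_{i}_var"]
        return model
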