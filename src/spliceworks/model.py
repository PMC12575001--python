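"""The dilated residual convolutional splice-site model.

Architecture: an initial 1x1 convolution projects the 4-channel one-hot
input to `channels` features; a stack of residual units follows, each unit
being two (BatchNorm -> LeakyReLU -> dilated Conv) blocks whose output is
added back to the unit input; after every fourth unit a 1x1 "skip"
convolution adds the running features into a skip accumulator; the
accumulator is cropped by CL/2 on each side and projected to 3 channels
(none / acceptor / donor) with a softmax at every position.

The crop CL = 2 * sum_i AR_i * (W_i - 1) equals the flanking size, so the
output is exactly `input length - flank` positions long for any input, and
the receptive field never extends past the crop: predicting a long
sequence whole or in overlapping windows gives identical probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import AdamW, BatchNorm1d, Conv1d, LeakyReLU, Parameter

__all__ = [
    "ModelConfig",
    "build_config",
    "cropping_length",
    "SpliceModel",
    "softmax",
    "CHECKPOINT_FORMAT_VERSION",
]

CHECKPOINT_FORMAT_VERSION = 1

#: Kernel-size / dilation-rate schedules for the four supported flanks.
_ARCHITECTURES: dict[int, tuple[list[int], list[int]]] = {
    80: ([11] * 4, [1] * 4),
    400: ([11] * 8, [1] * 4 + [4] * 4),
    2000: ([11] * 8 + [21] * 4, [1] * 4 + [4] * 4 + [10] * 4),
    10000: (
        [11] * 8 + [21] * 4 + [41] * 4,
        [1] * 4 + [4] * 4 + [10] * 4 + [25] * 4,
    ),
}


@dataclass
class ModelConfig:
    flank: int
    W: list[int] = field(default_factory=list)
    AR: list[int] = field(default_factory=list)
    channels: int = 32
    negative_slope: float = 0.1
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def __post_init__(self):
        if len(self.W) != len(self.AR):
            raise ValueError("W and AR must have equal length")
        if any(w < 1 or w % 2 == 0 for w in self.W):
            raise ValueError("all kernel sizes must be odd and positive")
        if any(a < 1 for a in self.AR):
            raise ValueError("all dilation rates must be positive")

    @property
    def n_units(self) -> int:
        return len(self.W)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


def build_config(flank: int, channels: int = 32) -> ModelConfig:
    """Standard architecture for one of the four supported flanking sizes."""
    if flank not in _ARCHITECTURES:
        raise ValueError(
            f"unsupported flanking size {flank}; valid values are "
            f"{sorted(_ARCHITECTURES)}"
        )
    W, AR = _ARCHITECTURES[flank]
    return ModelConfig(flank=flank, W=list(W), AR=list(AR), channels=channels)


def cropping_length(config: ModelConfig) -> int:
    """CL = 2 * sum_i AR_i * (W_i - 1), the total output shortening."""
    return 2 * int(sum(a * (w - 1) for w, a in zip(config.W, config.AR)))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class _ResidualUnit:
    def __init__(self, cfg: ModelConfig, kernel: int, dilation: int,
                 rng: np.random.Generator, name: str):
        c = cfg.channels
        self.bn1 = BatchNorm1d(c, cfg.bn_eps, cfg.bn_momentum, f"{name}.bn1")
        self.act1 = LeakyReLU(cfg.negative_slope)
        self.conv1 = Conv1d(c, c, kernel, dilation, rng, f"{name}.conv1")
        self.bn2 = BatchNorm1d(c, cfg.bn_eps, cfg.bn_momentum, f"{name}.bn2")
        self.act2 = LeakyReLU(cfg.negative_slope)
        self.conv2 = Conv1d(c, c, kernel, dilation, rng, f"{name}.conv2")

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = self.bn1.forward(x, training)
        y = self.act1.forward(y, training)
        y = self.conv1.forward(y, training)
        y = self.bn2.forward(y, training)
        y = self.act2.forward(y, training)
        y = self.conv2.forward(y, training)
        return x + y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dy = self.conv2.backward(dout)
        dy = self.act2.backward(dy)
        dy = self.bn2.backward(dy)
        dy = self.conv1.backward(dy)
        dy = self.act1.backward(dy)
        dy = self.bn1.backward(dy)
        return dout + dy

    def layers(self):
        return [self.bn1, self.conv1, self.bn2, self.conv2]


class SpliceModel:
    """The splice-site network for one flanking size.

    forward() maps one-hot windows (n, len, 4) to per-position class
    probabilities (n, len - flank, 3) over (none, acceptor, donor).
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.channels
        self.conv_in = Conv1d(4, c, 1, 1, rng, "conv_in")
        self.skip_init = Conv1d(c, c, 1, 1, rng, "skip_init")
        self.units: list[_ResidualUnit] = []
        self.skip_convs: dict[int, Conv1d] = {}
        for i, (w, ar) in enumerate(zip(config.W, config.AR)):
            self.units.append(_ResidualUnit(config, w, ar, rng, f"unit{i}"))
            if (i + 1) % 4 == 0 or i == config.n_units - 1:
                self.skip_convs[i] = Conv1d(c, c, 1, 1, rng, f"skip{i}")
        self.conv_out = Conv1d(c, 3, 1, 1, rng, "conv_out")
        self.crop = cropping_length(config) // 2
        if cropping_length(config) != config.flank:
            raise ValueError(
                f"configuration cropping length {cropping_length(config)} "
                f"does not equal the flanking size {config.flank}"
            )
        self._fwd_cache: dict | None = None

    # ---- structure ----------------------------------------------------
    def _layer_groups(self) -> list[list]:
        """Parameter-bearing layers in network order, grouped."""
        groups: list[list] = [[self.conv_in, self.skip_init]]
        for i, u in enumerate(self.units):
            g = u.layers()
            if i in self.skip_convs:
                g = g + [self.skip_convs[i]]
            groups.append(g)
        groups.append([self.conv_out])
        return groups

    def all_layers(self) -> list:
        return [l for grp in self._layer_groups() for l in grp]

    def parameters(self) -> list[Parameter]:
        return [p for l in self.all_layers() for p in l.params()]

    def set_trainable(self, last_k: int | None = None) -> None:
        """Freeze everything except the last `last_k` layer groups
        (None = unfreeze all).  Frozen BatchNorm layers also stop
        updating their running statistics."""
        groups = self._layer_groups()
        if last_k is None:
            cutoff = 0
        else:
            cutoff = max(len(groups) - last_k, 0)
        for gi, grp in enumerate(groups):
            train = gi >= cutoff
            for layer in grp:
                for p in layer.params():
                    p.trainable = train
                if isinstance(layer, BatchNorm1d):
                    layer.update_stats = train

    # ---- forward / backward -------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[2] != 4:
            raise ValueError("input must have shape (n, length, 4)")
        if x.shape[1] <= self.config.flank:
            raise ValueError(
                f"input length {x.shape[1]} must exceed the flanking size "
                f"{self.config.flank}"
            )
        a = self.conv_in.forward(x, training)
        skip = self.skip_init.forward(a, training)
        cur = a
        for i, unit in enumerate(self.units):
            cur = unit.forward(cur, training)
            if i in self.skip_convs:
                skip = skip + self.skip_convs[i].forward(cur, training)
        c = self.crop
        cropped = skip[:, c : skip.shape[1] - c, :]
        logits = self.conv_out.forward(cropped, training)
        if training:
            self._fwd_cache = {"L": skip.shape[1]}
        return logits

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Per-position class probabilities, rows summing to 1."""
        return softmax(self.forward_logits(x, training))

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dlogits."""
        L = self._fwd_cache["L"]
        c = self.crop
        dcropped = self.conv_out.backward(dlogits)
        n, _, ch = dcropped.shape
        dskip = np.zeros((n, L, ch), dtype=np.float32)
        dskip[:, c : L - c, :] = dcropped
        dcur = np.zeros_like(dskip)
        for i in range(len(self.units) - 1, -1, -1):
            if i in self.skip_convs:
                dcur = dcur + self.skip_convs[i].backward(dskip)
            dcur = self.units[i].backward(dcur)
        da = dcur + self.skip_init.backward(dskip)
        self.conv_in.backward(da)
        self._fwd_cache = None

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Inference-mode probabilities, batched for memory control."""
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(x[i : i + batch_size], training=False))
        return np.concatenate(outs, axis=0)

    # ---- serialization -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for p in self.parameters():
            state[p.name] = p.data
        for layer in self.all_layers():
            if isinstance(layer, BatchNorm1d):
                prefix = layer.gamma.name.rsplit(".", 1)[0]
                state[f"{prefix}.running_mean"] = layer.running_mean
                state[f"{prefix}.running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        params = {p.name: p for p in self.parameters()}
        for name, p in params.items():
            if name not in state:
                raise ValueError(f"checkpoint is missing parameter {name!r}")
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {name!r}")
            p.data = np.asarray(state[name], dtype=np.float32).copy()
        for layer in self.all_layers():
            if isinstance(layer, BatchNorm1d):
                prefix = layer.gamma.name.rsplit(".", 1)[0]
                layer.running_mean = np.asarray(
                    state[f"{prefix}.running_mean"], dtype=np.float32
                ).copy()
                layer.running_var = np.asarray(
                    state[f"{prefix}.running_var"], dtype=np.float32
                ).copy()

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        """Serialize weights + config + format version (.npz container)."""
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": json.loads(self.config.to_json()),
        }
        if extra:
            meta.update(extra)
        arrays = {f"param/{k}": v for k, v in self.state_arrays().items()}
        np.savez(
            path, __meta__=np.frombuffer(
                json.dumps(meta).encode(), dtype=np.uint8
            ), **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> tuple["SpliceModel", dict]:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint format: {meta.get('format_version')}"
                )
            state = {
                k[len("param/"):]: data[k]
                for k in data.files
                if k.startswith("param/")
            }
        config = ModelConfig(**meta["config"])
        model = cls(config)
        model.load_state_arrays(state)
        return model, meta

    def copy(self) -> "SpliceModel":
        clone = SpliceModel(self.config)
        clone.load_state_arrays(self.state_arrays())
        return clone
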