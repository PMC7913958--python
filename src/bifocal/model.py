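"""The bifocal classifier: two plain convolutional subnets, feature
concatenation, one classification layer.

Each subnet mirrors the topology of a 26-layer bottleneck residual network —
a 7x7 stride-2 stem, four stages of triple-convolution bottleneck blocks —
but deliberately carries **no** identity shortcuts.  Both subnets end in
global average pooling, so the wide (context) and narrow (index) paths yield
equal-length feature vectors regardless of their different input sizes; the
two vectors are concatenated and classified by a single fully connected
softmax layer.

A 50-layer residual reference is described here only structurally, to count
parameters against: the bifocal default is required to stay at or below half
of its trainable-parameter count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

__all__ = [
    "BCNNConfig",
    "BifocalNet",
    "SubnetNet",
    "build_bcnn",
    "build_subnet",
    "count_parameters",
    "parameter_ratio",
    "resnet50_parameter_count",
    "save_model",
    "load_model",
]

#: bottleneck expansion factor (1x1 -> 3x3 -> 1x1*EXPANSION)
EXPANSION = 4


@dataclass
class BCNNConfig:
    """Architecture hyper-parameters.

    ``input_sizes`` is (wide, narrow) edge length in pixels as fed to the
    network.  Tiles are always extracted at 512/256 from the slide; a desk-
    scale configuration may present them downsampled (e.g. 64/32), which
    changes compute but not the parameter count.
    """

    num_classes: int = 6
    base_width: int = 32
    blocks_per_stage: tuple[int, ...] = (2, 2, 2, 2)
    input_sizes: tuple[int, int] = (512, 256)
    rng_seed: int = 0

    @property
    def feature_len(self) -> int:
        return self.base_width * 2 ** (len(self.blocks_per_stage) - 1) * EXPANSION

    def validate(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.base_width < 1 or any(b < 1 for b in self.blocks_per_stage):
            raise ValueError("base_width and block counts must be positive")
        if self.input_sizes[0] < 2 * self.input_sizes[1]:
            raise ValueError("wide input must be at least twice the narrow input")


def _bottleneck(in_ch: int, width: int, stride: int, rng, dtype) -> list[nn.Module]:
    """Plain (shortcut-free) bottleneck: 1x1 -> 3x3(stride) -> 1x1*EXPANSION."""
    out = EXPANSION * width
    return [
        nn.Conv2d(in_ch, width, 1, rng=rng, dtype=dtype),
        nn.BatchNorm2d(width, dtype=dtype),
        nn.ReLU(),
        nn.Conv2d(width, width, 3, stride=stride, rng=rng, dtype=dtype),
        nn.BatchNorm2d(width, dtype=dtype),
        nn.ReLU(),
        nn.Conv2d(width, out, 1, rng=rng, dtype=dtype),
        nn.BatchNorm2d(out, dtype=dtype),
        nn.ReLU(),
    ]


def _make_path(cfg: BCNNConfig, rng: np.random.Generator, dtype=np.float32) -> nn.Sequential:
    layers: list[nn.Module] = [
        nn.Conv2d(3, cfg.base_width, 7, stride=2, rng=rng, dtype=dtype),
        nn.BatchNorm2d(cfg.base_width, dtype=dtype),
        nn.ReLU(),
        nn.MaxPool2d(),
    ]
    in_ch = cfg.base_width
    for stage, n_blocks in enumerate(cfg.blocks_per_stage):
        width = cfg.base_width * 2**stage
        for b in range(n_blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.extend(_bottleneck(in_ch, width, stride, rng, dtype))
            in_ch = EXPANSION * width
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(layers)


class _Net:
    """Shared trained-network behaviour (forward contract, parameters)."""

    config: BCNNConfig

    def parameters(self) -> list[nn.Param]:  # pragma: no cover - overridden
        raise NotImplementedError

    def set_training(self, mode: bool) -> None:  # pragma: no cover - overridden
        raise NotImplementedError

    def predict_proba(self, wide: np.ndarray, narrow: np.ndarray) -> np.ndarray:
        """Probability vectors (rows sum to 1) for a batch, no augmentation."""
        self.set_training(False)
        return nn.softmax(self.forward(wide, narrow))


class BifocalNet(_Net):
    def __init__(self, config: BCNNConfig, dtype=np.float32):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        self.wide_path = _make_path(config, rng, dtype)
        self.narrow_path = _make_path(config, rng, dtype)
        self.fc = nn.Linear(2 * config.feature_len, config.num_classes, rng=rng, dtype=dtype)
        self.within_parameter_budget = True

    def parameters(self) -> list[nn.Param]:
        return self.wide_path.parameters() + self.narrow_path.parameters() + self.fc.parameters()

    def set_training(self, mode: bool) -> None:
        self.wide_path.set_training(mode)
        self.narrow_path.set_training(mode)
        self.fc.set_training(mode)

    def forward(self, wide: np.ndarray, narrow: np.ndarray) -> np.ndarray:
        sw, sn = self.config.input_sizes
        if wide.shape[2:] != (sw, sw) or narrow.shape[2:] != (sn, sn):
            raise ValueError(
                f"expected input sizes {(sw, sn)}, got {wide.shape[2:]} / {narrow.shape[2:]}"
            )
        fw = self.wide_path.forward(wide)
        fn = self.narrow_path.forward(narrow)
        self._feat_len = fw.shape[1]
        return self.fc.forward(np.concatenate([fw, fn], axis=1))

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.fc.backward(dlogits)
        k = self._feat_len
        self.wide_path.backward(dfeat[:, :k])
        self.narrow_path.backward(dfeat[:, k:])


class SubnetNet(_Net):
    """Single-path ablation: one subnet on the narrow tile + classifier."""

    def __init__(self, config: BCNNConfig, dtype=np.float32):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        self.path = _make_path(config, rng, dtype)
        self.fc = nn.Linear(config.feature_len, config.num_classes, rng=rng, dtype=dtype)

    def parameters(self) -> list[nn.Param]:
        return self.path.parameters() + self.fc.parameters()

    def set_training(self, mode: bool) -> None:
        self.path.set_training(mode)
        self.fc.set_training(mode)

    def forward(self, wide: np.ndarray, narrow: np.ndarray) -> np.ndarray:
        sn = self.config.input_sizes[1]
        if narrow.shape[2:] != (sn, sn):
            raise ValueError(f"expected narrow input size {sn}, got {narrow.shape[2:]}")
        return self.fc.forward(self.path.forward(narrow))

    def backward(self, dlogits: np.ndarray) -> None:
        self.path.backward(self.fc.backward(dlogits))


def build_bcnn(config: BCNNConfig | None = None, dtype=np.float32) -> BifocalNet:
    """Instantiate the bifocal network; warns if it exceeds the half-of-
    ResNet-50 parameter budget."""
    config = config if config is not None else BCNNConfig()
    model = BifocalNet(config, dtype=dtype)
    budget = 0.5 * resnet50_parameter_count(config.num_classes)
    if count_parameters(model) > budget:
        model.within_parameter_budget = False
        warnings.warn(
            f"bifocal configuration exceeds the parameter budget "
            f"({count_parameters(model)} > {budget:.0f})",
            stacklevel=2,
        )
    return model


def build_subnet(config: BCNNConfig | None = None, dtype=np.float32) -> SubnetNet:
    return SubnetNet(config if config is not None else BCNNConfig(), dtype=dtype)


def count_parameters(model) -> int:
    """Total number of trainable scalars."""
    return sum(p.size for p in model.parameters())


def parameter_ratio(model, reference) -> float:
    """count(model) / count(reference); either argument may be a raw count."""
    num = model if isinstance(model, (int, np.integer)) else count_parameters(model)
    den = reference if isinstance(reference, (int, np.integer)) else count_parameters(reference)
    if den == 0:
        raise ValueError("reference model has no parameters")
    return num / den


def resnet50_parameter_count(num_classes: int = 6) -> int:
    """Trainable-parameter count of the standard 50-layer residual network.

    Enumerated from the canonical architecture (7x7/64 stem, bottleneck
    stages [3,4,6,3] at widths [64,128,256,512] with expansion 4, projection
    shortcut in the first block of each stage, batch norm after every
    convolution, no convolution biases, final fully connected head).  With
    the 1000-class head this comes to 25,557,032, matching the reference
    implementations in the literature.
    """

    def conv(cin, cout, k):
        return cin * cout * k * k

    def bn(c):
        return 2 * c

    total = conv(3, 64, 7) + bn(64)
    in_ch = 64
    for width, n_blocks in zip((64, 128, 256, 512), (3, 4, 6, 3)):
        out_ch = 4 * width
        for b in range(n_blocks):
            total += conv(in_ch, width, 1) + bn(width)
            total += conv(width, width, 3) + bn(width)
            total += conv(width, out_ch, 1) + bn(out_ch)
            if b == 0:  # projection shortcut
                total += conv(in_ch, out_ch, 1) + bn(out_ch)
            in_ch = out_ch
    total += 2048 * num_classes + num_classes
    return total


# ---------------------------------------------------------------------------
# checkpointing

_KINDS = {"bifocal": BifocalNet, "subnet": SubnetNet}


def save_model(model: _Net, path) -> None:
    """Persist weights + architecture config in one self-describing .npz."""
    kind = "bifocal" if isinstance(model, BifocalNet) else "subnet"
    meta = {"kind": kind, "config": asdict(model.config)}
    arrays = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    bns = [m for m in _iter_modules(model) if isinstance(m, nn.BatchNorm2d)]
    for i, b in enumerate(bns):
        arrays[f"rm{i}"] = b.running_mean
        arrays[f"rv{i}"] = b.running_var
    np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> BifocalNet | SubnetNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg_d = meta["config"]
        cfg_d["blocks_per_stage"] = tuple(cfg_d["blocks_per_stage"])
        cfg_d["input_sizes"] = tuple(cfg_d["input_sizes"])
        cfg = BCNNConfig(**cfg_d)
        model = _KINDS[meta["kind"]](cfg)
        for i, p in enumerate(model.parameters()):
            p.value[...] = data[f"p{i}"]
        bns = [m for m in _iter_modules(model) if isinstance(m, nn.BatchNorm2d)]
        for i, b in enumerate(bns):
            b.running_mean[...] = data[f"rm{i}"]
            b.running_var[...] = data[f"rv{i}"]
    return model


def _iter_modules(model: _Net):
    paths = []
    if isinstance(model, BifocalNet):
        paths = [model.wide_path, model.narrow_path]
    elif isinstance(model, SubnetNet):
        paths = [model.path]
    for p in paths:
        yield from p.layers
    yield model.fc
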