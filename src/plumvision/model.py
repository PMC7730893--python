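"""The 16-weight-layer VGG-variant defect classifier.

Thirteen 3x3 convolution layers (each followed by batch normalisation and
ReLU, with five interleaved 2x2 max-pool stages), adaptive average pooling
onto a fixed grid, then three fully connected layers (1024-1024-5 by
default).  Adaptive pooling decouples the fully connected dimensions from the
input resolution, so any RGB input of at least 32x32 pixels is accepted.

The final fully connected layer is bias-free and its weight matrix is exposed
separately from the penultimate feature vector so that the weight-biased
softmax loss can operate on (features, class weights) directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn import (
    AdaptiveAvgPool2d,
    BatchNorm2d,
    Conv2d,
    Flatten,
    Linear,
    MaxPool2d,
    ReLU,
    Sequential,
)

__all__ = ["NetworkSpec", "DefectNet", "build_network", "predict",
           "audit_architecture", "count_parameters", "save_checkpoint",
           "load_checkpoint", "NotFinalizedError"]

#: VGG-16 convolutional plan: channel widths with 'M' marking max-pool stages.
DEFAULT_CONV_PLAN = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
                     512, 512, 512, "M", 512, 512, 512, "M"]

MIN_INPUT_SIZE = 32


class NotFinalizedError(RuntimeError):
    """Raised when predicting with a weight-averaged model whose batch-norm
    statistics have not been recomputed."""


@dataclass
class NetworkSpec:
    """Architecture hyper-parameters.

    ``width_multiplier`` scales every convolutional width and the fully
    connected width; it exists for desk-scale experiments and is 1.0 for the
    full network.
    """

    conv_plan: list = field(default_factory=lambda: list(DEFAULT_CONV_PLAN))
    fc_units: int = 1024
    num_classes: int = 5
    pool_grid: tuple[int, int] = (1, 1)
    width_multiplier: float = 1.0

    def scaled_plan(self) -> list:
        out = []
        for item in self.conv_plan:
            if item == "M":
                out.append("M")
            else:
                out.append(max(4, int(round(item * self.width_multiplier))))
        return out

    def scaled_fc(self) -> int:
        return max(8, int(round(self.fc_units * self.width_multiplier)))


class DefectNet:
    """Convolutional feature extractor + 3-layer fully connected classifier."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.spec = spec
        layers: list = []
        in_ch = 3
        for item in spec.scaled_plan():
            if item == "M":
                layers.append(MaxPool2d())
            else:
                layers.append(Conv2d(in_ch, item, 3, rng=rng))
                layers.append(BatchNorm2d(item))
                layers.append(ReLU())
                in_ch = item
        layers.append(AdaptiveAvgPool2d(spec.pool_grid))
        layers.append(Flatten())
        flat = in_ch * spec.pool_grid[0] * spec.pool_grid[1]
        fc = spec.scaled_fc()
        layers.append(Linear(flat, fc, rng=rng))
        layers.append(ReLU())
        layers.append(Linear(fc, fc, rng=rng))
        layers.append(ReLU())
        self.backbone = Sequential(layers)
        # classifier head: bias-free so logits are pure w^T x
        self.head = Linear(fc, spec.num_classes, bias=False, rng=rng)
        self.feature_dim = fc
        # a freshly built network carries no pending weight average
        self.swa_pending = False
        # a head trained under the w-softmax loss is a cosine classifier:
        # inference then scores against the unit-normalised weight rows
        self.cosine_head = False

    # -- modes ---------------------------------------------------------------
    def set_mode(self, train: bool) -> None:
        self.backbone.set_mode(train)
        self.head.set_mode(train)

    # -- forward/backward ----------------------------------------------------
    def features(self, x: np.ndarray) -> np.ndarray:
        """Penultimate activations (input to the classifier head)."""
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        if x.shape[2] < MIN_INPUT_SIZE or x.shape[3] < MIN_INPUT_SIZE:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} below the minimum "
                f"{MIN_INPUT_SIZE}x{MIN_INPUT_SIZE}")
        return self.backbone.forward(x.astype(np.float32, copy=False))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Raw class scores (logits)."""
        feats = self.features(x)
        if self.cosine_head:
            W = self.head.W
            Wn = W / np.linalg.norm(W, axis=1, keepdims=True)
            return feats @ Wn.T
        return self.head.forward(feats)

    def backward_from_features(self, dfeat: np.ndarray) -> None:
        self.backbone.backward(dfeat)

    # -- parameter access ----------------------------------------------------
    def named_params(self) -> dict[str, np.ndarray]:
        out = {f"backbone.{k}": v for k, v in self.backbone.named_params().items()}
        out["head.W"] = self.head.W
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out = {f"backbone.{k}": v for k, v in self.backbone.named_grads().items()}
        out["head.W"] = self.head.dW
        return out

    def load_params(self, params: dict[str, np.ndarray]) -> None:
        own = self.named_params()
        if set(own) != set(params):
            missing = set(own) ^ set(params)
            raise ValueError(f"parameter name mismatch: {sorted(missing)[:5]}")
        for name, arr in params.items():
            if own[name].shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            own[name][...] = arr

    # -- BN buffers ----------------------------------------------------------
    def bn_layers(self) -> list[BatchNorm2d]:
        return [l for l in self.backbone.layers if isinstance(l, BatchNorm2d)]

    def bn_buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for i, bn in enumerate(self.bn_layers()):
            out[f"bn{i}.mean"] = bn.running_mean
            out[f"bn{i}.var"] = bn.running_var
        return out


def build_network(spec: NetworkSpec | None = None,
                  seed: int | None = None) -> DefectNet:
    """Construct the classifier with seeded He initialisation."""
    return DefectNet(spec or NetworkSpec(), rng=np.random.default_rng(seed))


def predict(net: DefectNet, batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode class indices and score vectors for a batch.

    Deterministic: batch norm uses running statistics.  Refuses a model whose
    weights were averaged but whose statistics were never recomputed.
    """
    if net.swa_pending:
        raise NotFinalizedError(
            "model holds an averaged weight set but batch-norm statistics "
            "were not recomputed; call swa.finalize first")
    net.set_mode(False)
    scores = net.forward(batch)
    return scores.argmax(axis=1), scores


def count_parameters(net: DefectNet) -> int:
    return int(sum(p.size for p in net.named_params().values()))


def audit_architecture(net: DefectNet) -> dict:
    """Programmatic audit of the built network against its contract."""
    layers = net.backbone.layers
    convs = [l for l in layers if isinstance(l, Conv2d)]
    pools = [l for l in layers if isinstance(l, MaxPool2d)]
    fcs = [l for l in layers if isinstance(l, Linear)] + [net.head]
    bn_after_conv = all(
        isinstance(layers[i + 1], BatchNorm2d) and isinstance(layers[i + 2], ReLU)
        for i, l in enumerate(layers) if isinstance(l, Conv2d))
    return {
        "n_conv": len(convs),
        "n_fc": len(fcs),
        "n_weight_layers": len(convs) + len(fcs),
        "n_maxpool": len(pools),
        "all_kernels_3x3": all(c.k == 3 for c in convs),
        "bn_relu_after_every_conv": bn_after_conv,
        "has_adaptive_pool": any(isinstance(l, AdaptiveAvgPool2d) for l in layers),
    }


# -- checkpoints -------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(net: DefectNet, path, extra: dict | None = None) -> None:
    """Single-file .npz checkpoint with a JSON header describing the spec."""
    header = {
        "version": CHECKPOINT_VERSION,
        "spec": {
            "conv_plan": net.spec.conv_plan,
            "fc_units": net.spec.fc_units,
            "num_classes": net.spec.num_classes,
            "pool_grid": list(net.spec.pool_grid),
            "width_multiplier": net.spec.width_multiplier,
        },
        "swa_pending": net.swa_pending,
        "cosine_head": net.cosine_head,
        "extra": extra or {},
    }
    arrays = {f"param/{k}": v for k, v in net.named_params().items()}
    arrays.update({f"buffer/{k}": v for k, v in net.bn_buffers().items()})
    np.savez(path, header=json.dumps(header), **arrays)


def load_checkpoint(path) -> tuple[DefectNet, dict]:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        spec = NetworkSpec(
            conv_plan=header["spec"]["conv_plan"],
            fc_units=header["spec"]["fc_units"],
            num_classes=header["spec"]["num_classes"],
            pool_grid=tuple(header["spec"]["pool_grid"]),
            width_multiplier=header["spec"]["width_multiplier"],
        )
        net = DefectNet(spec, rng=np.random.default_rng(0))
        net.load_params({k[len("param/"):]: data[k] for k in data.files
                         if k.startswith("param/")})
        for i, bn in enumerate(net.bn_layers()):
            bn.running_mean[...] = data[f"buffer/bn{i}.mean"]
            bn.running_var[...] = data[f"buffer/bn{i}.var"]
        net.swa_pending = bool(header["swa_pending"])
        net.cosine_head = bool(header.get("cosine_head", False))
    return net, header
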