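"""Per-modality models: encoder + classifier + gradient-matching head.

Each imaging modality (sMRI, ALFF, ReHo) gets its own three-part model:

* an **encoder** mapping a 3D volume to a feature vector of length ``d_feat``
  (1024 with the full-scale 3D-ResNet-10 backbone; 32 with the tiny CNN
  used for desk-scale experiments),
* a linear **classifier** head producing two class scores,
* a linear **gradient-matching (GM) head**, also ``d_feat -> 2``, whose
  cross-entropy gradient is the unit of cross-site exchange.

The GM head is deliberately a single linear layer: the exchanged gradient is
low-dimensional (``2*d_feat + 2`` numbers), cheap to share, and its cosine
geometry is well conditioned.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from io import BytesIO
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "EncoderConfig",
    "ModelState",
    "ModalityModel",
    "FusionMLP",
    "build_encoder",
    "build_classifier",
    "build_gm_head",
    "build_modality_model",
    "flatten_params",
    "unflatten_params",
    "save_checkpoint",
    "load_checkpoint",
]

ENCODER_VARIANTS = ("tiny_cnn_3d", "resnet10_3d")


@dataclass(frozen=True)
class EncoderConfig:
    variant: str = "tiny_cnn_3d"
    d_feat: int = 32
    seed: int = 0
    # spatial shape the encoder is built for (tiny variant keeps a coarse
    # spatial grid before its projection layer, so it is shape-specific)
    input_shape: tuple[int, int, int] = (16, 16, 16)

    def __post_init__(self):
        if self.variant not in ENCODER_VARIANTS:
            raise ValueError(
                f"unknown encoder variant {self.variant!r}; "
                f"expected one of {ENCODER_VARIANTS}")
        if self.d_feat < 1:
            raise ValueError("d_feat must be >= 1")
        if any(s % 4 for s in self.input_shape):
            raise ValueError("input_shape axes must be multiples of 4")


def build_encoder(config: EncoderConfig) -> nn.Sequential:
    """Build a volume -> feature-vector encoder.

    ``tiny_cnn_3d`` is two conv blocks with pooling — a first-class,
    desk-scale backbone, not a test shim.  ``resnet10_3d`` is the standard
    10-layer residual 3D CNN; its 512-channel pooled output is projected to
    ``d_feat`` by a final linear layer.
    """
    rng = np.random.default_rng(config.seed)
    if config.variant == "tiny_cnn_3d":
        # two conv blocks, each halving resolution; the coarse spatial grid
        # is kept (flattened, not globally pooled) so localized signal
        # survives into the projection layer
        grid = tuple(s // 4 for s in config.input_shape)
        d_flat = 16 * int(np.prod(grid))
        return nn.Sequential(
            nn.Conv3d(1, 8, kernel=3, stride=1, pad=1, rng=rng),
            nn.ReLU(),
            nn.MaxPool3d(),
            nn.Conv3d(8, 16, kernel=3, stride=1, pad=1, rng=rng),
            nn.ReLU(),
            nn.AvgPool3d(),
            nn.Flatten(),
            nn.Linear(d_flat, config.d_feat, rng=rng),
        )
    return _resnet10_3d(config.d_feat, rng)


def _basic_block(c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator) -> nn.Residual:
    body = nn.Sequential(
        nn.Conv3d(c_in, c_out, kernel=3, stride=stride, pad=1, rng=rng),
        nn.BatchNorm3d(c_out),
        nn.ReLU(),
        nn.Conv3d(c_out, c_out, kernel=3, stride=1, pad=1, rng=rng),
        nn.BatchNorm3d(c_out),
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = nn.Sequential(
            nn.Conv3d(c_in, c_out, kernel=1, stride=stride, pad=0, rng=rng),
            nn.BatchNorm3d(c_out),
        )
    return nn.Residual(body, shortcut)


def _resnet10_3d(d_feat: int, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv3d(1, 64, kernel=7, stride=2, pad=3, rng=rng),
        nn.BatchNorm3d(64),
        nn.ReLU(),
        _basic_block(64, 64, 1, rng),
        _basic_block(64, 128, 2, rng),
        _basic_block(128, 256, 2, rng),
        _basic_block(256, 512, 2, rng),
        nn.GlobalAvgPool3d(),
        nn.Linear(512, d_feat, rng=rng),
    )


def build_classifier(d_feat: int, rng: np.random.Generator | None = None) -> nn.Linear:
    return nn.Linear(d_feat, 2, rng=rng)


def build_gm_head(d_feat: int, rng: np.random.Generator | None = None) -> nn.Linear:
    """Single linear layer d_feat -> 2; parameter count 2*d_feat + 2."""
    if d_feat < 1:
        raise ValueError("d_feat must be >= 1")
    return nn.Linear(d_feat, 2, rng=rng)


# ---------------------------------------------------------------------------
# Model state: named parameter arrays with a stable flatten order
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """Ordered name -> array snapshot of a model's trainable parameters.

    Keys look like ``encoder.3.W``; insertion order defines the flatten
    order, so ``flatten_params`` / ``unflatten_params`` form a bijection.
    """

    items: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "ModelState":
        return ModelState({k: v.copy() for k, v in self.items.items()})

    def __add__(self, other: "ModelState") -> "ModelState":
        return ModelState({k: self.items[k] + other.items[k] for k in self.items})

    def n_params(self) -> int:
        return sum(v.size for v in self.items.values())


def flatten_params(state: ModelState) -> np.ndarray:
    if not state.items:
        return np.zeros(0)
    return np.concatenate([v.ravel() for v in state.items.values()])


def unflatten_params(vector: np.ndarray, template: ModelState) -> ModelState:
    expected = template.n_params()
    if vector.size != expected:
        raise ValueError(
            f"parameter vector has length {vector.size}, expected {expected}")
    out, pos = {}, 0
    for k, v in template.items.items():
        out[k] = vector[pos:pos + v.size].reshape(v.shape).copy()
        pos += v.size
    return ModelState(out)


class ModalityModel:
    """Encoder + classifier + GM head for one imaging modality."""

    COMPONENTS = ("encoder", "classifier", "gm_head")

    def __init__(self, encoder: nn.Sequential, classifier: nn.Linear,
                 gm_head: nn.Linear, config: EncoderConfig) -> None:
        self.encoder = encoder
        self.classifier = classifier
        self.gm_head = gm_head
        self.config = config

    # -- forward -----------------------------------------------------------
    @property
    def dtype(self) -> np.dtype:
        return self.classifier.params["W"].dtype

    def astype(self, dtype) -> "ModalityModel":
        """Cast all parameters and buffers in place; returns self."""
        for comp in self.COMPONENTS:
            for layer, k in self.component(comp).named_parameters():
                layer.params[k] = layer.params[k].astype(dtype)
                layer.grads[k] = layer.grads[k].astype(dtype)
                for bk in layer.buffers:
                    layer.buffers[bk] = layer.buffers[bk].astype(dtype)
        return self

    def encode(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 3:
            x = x[None]
        return self.encoder(x[:, None, :, :, :].astype(self.dtype),
                            train=train)

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.classifier(self.encode(x, train=train), train=train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(x))

    # -- parameters --------------------------------------------------------
    def component(self, name: str) -> nn.Layer:
        return getattr(self, name)

    def named_parameters(self, components=COMPONENTS):
        for comp in components:
            yield from self.component(comp).named_parameters()

    def zero_grad(self) -> None:
        for comp in self.COMPONENTS:
            self.component(comp).zero_grad()

    def state(self) -> ModelState:
        items = {}
        for comp in self.COMPONENTS:
            for i, (layer, k) in enumerate(self.component(comp).named_parameters()):
                items[f"{comp}.{i}.{k}"] = layer.params[k].copy()
        return ModelState(items)

    def set_state(self, state: ModelState) -> None:
        for comp in self.COMPONENTS:
            for i, (layer, k) in enumerate(self.component(comp).named_parameters()):
                layer.params[k] = state.items[f"{comp}.{i}.{k}"].copy()

    def gm_head_matrix(self) -> np.ndarray:
        """GM-head parameters as the augmented matrix [W | b], shape (2, d+1).

        This row-major layout is the canonical layout of exchanged GM
        gradients throughout the package.
        """
        return np.hstack([self.gm_head.params["W"],
                          self.gm_head.params["b"][:, None]])

    def set_gm_head_matrix(self, wb: np.ndarray) -> None:
        self.gm_head.params["W"] = wb[:, :-1].copy()
        self.gm_head.params["b"] = wb[:, -1].copy()


def build_modality_model(config: EncoderConfig) -> ModalityModel:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC1A55]))
    encoder = build_encoder(config)
    classifier = build_classifier(config.d_feat, rng=rng)
    gm_head = build_gm_head(config.d_feat, rng=rng)
    return ModalityModel(encoder, classifier, gm_head, config)


class FusionMLP:
    """Three-layer fully connected fusion classifier: d_fused -> hidden -> 2."""

    def __init__(self, d_in: int, hidden: int = 128,
                 seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.d_in, self.hidden = d_in, hidden
        self.net = nn.Sequential(
            nn.Linear(d_in, hidden, rng=rng),
            nn.ReLU(),
            nn.Linear(hidden, 2, rng=rng),
        )

    def logits(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net(z, train=train)

    def predict_proba(self, z: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(z))

    def named_parameters(self):
        return self.net.named_parameters()

    def zero_grad(self):
        self.net.zero_grad()

    def state(self) -> ModelState:
        return ModelState({f"mlp.{i}.{k}": layer.params[k].copy()
                           for i, (layer, k) in enumerate(self.named_parameters())})

    def set_state(self, state: ModelState) -> None:
        for i, (layer, k) in enumerate(self.named_parameters()):
            layer.params[k] = state.items[f"mlp.{i}.{k}"].copy()


# ---------------------------------------------------------------------------
# Checkpoints: one zip archive of named arrays + a config JSON
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, state: ModelState, config: dict,
                    extras: dict[str, np.ndarray] | None = None) -> Path:
    path = Path(path)
    arrays = dict(state.items)
    if extras:
        arrays.update({f"extra:{k}": v for k, v in extras.items()})
    buf = BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("params.npz", buf.getvalue())
        zf.writestr("config.json", json.dumps(config, indent=2))
    return path


def load_checkpoint(path: str | Path
                    ) -> tuple[ModelState, dict, dict[str, np.ndarray]]:
    with zipfile.ZipFile(Path(path)) as zf:
        with zf.open("params.npz") as f:
            npz = np.load(BytesIO(f.read()))
            arrays = {k: npz[k] for k in npz.files}
        config = json.loads(zf.read("config.json"))
    state_items = {k: v for k, v in arrays.items() if not k.startswith("extra:")}
    extras = {k[len("extra:"):]: v for k, v in arrays.items()
              if k.startswith("extra:")}
    return ModelState(state_items), config, extras
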