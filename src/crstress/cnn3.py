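"""The three-convolutional-layer binary classifier (CNN3), its training
loop, and study-level prediction.

Architecture: three blocks of [6x6 conv, stride 2, padding 2 -> batch
norm -> ReLU -> 2x2 max pool], a flatten, two hidden fully connected
layers (each with batch norm and ReLU) and a single-logit output read
through a sigmoid. Training minimises binary cross-entropy with Adam and
keeps the parameters of the epoch with the best validation loss. A study
is called malignant from the maximum of its two side-level probabilities
— the "suspicious on either side" rule.

Everything is seeded: parameter initialisation and the per-epoch batch
order derive from the configured seeds, so a rerun reproduces the same
model bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _nn
from ._nn.layers import conv_out_size
from .preprocess import SideInput


@dataclass
class ModelConfig:
    conv_channels: tuple[int, int, int] = (16, 32, 64)
    kernel: int = 6
    stride: int = 2
    padding: int = 2
    pool_kernel: int = 2
    fc_sizes: tuple[int, int, int] = (256, 64, 1)

    def __post_init__(self):
        if self.fc_sizes[-1] != 1:
            raise ValueError("final layer must emit a single logit")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    pos_weight: float = 1.0  # >1 upweights the malignant class
    checkpoint: str = "auroc"  # "auroc" or "loss": best-epoch criterion

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.checkpoint not in ("auroc", "loss"):
            raise ValueError("checkpoint must be 'auroc' or 'loss'")


def stage_output_shape(h: int, w: int, config: ModelConfig) -> list[tuple[int, int]]:
    """Spatial extents after each conv+pool block (closed form)."""
    shapes = []
    for _ in config.conv_channels:
        h = conv_out_size(h, config.kernel, config.stride, config.padding)
        w = conv_out_size(w, config.kernel, config.stride, config.padding)
        h, w = h // config.pool_kernel, w // config.pool_kernel
        shapes.append((h, w))
    return shapes


class TrainedModel:
    """A CNN3 network plus its configuration and training history."""

    def __init__(self, net: _nn.Sequential, config: ModelConfig,
                 input_shape: tuple[int, int], conv_relu_indices: list[int]):
        self.net = net
        self.config = config
        self.input_shape = input_shape
        self.conv_relu_indices = conv_relu_indices  # ReLU outputs per block
        self.history: list[dict] = []
        self.trained = False

    # ---- inference -------------------------------------------------

    def _batch(self, inputs) -> np.ndarray:
        arrs = [si.pixels if isinstance(si, SideInput) else si for si in inputs]
        x = np.stack(arrs).astype(np.float32)[:, None]
        if x.shape[2:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[2:]} differs from the trained "
                f"shape {self.input_shape}")
        return x

    def predict_proba(self, inputs) -> np.ndarray:
        """Malignancy probability per side input (evaluation mode)."""
        x = self._batch(inputs)
        logits = self.net.forward(x, train=False)[:, 0]
        return _nn.sigmoid(logits)

    def forward_logits(self, inputs, train=False) -> np.ndarray:
        return self.net.forward(self._batch(inputs), train=train)[:, 0]

    # ---- persistence -----------------------------------------------

    def save(self, path):
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.net.state_dict())
        meta = {"model_config": asdict(self.config),
                "input_shape": list(self.input_shape),
                "conv_relu_indices": self.conv_relu_indices,
                "trained": self.trained, "history": self.history}
        (path / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path):
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        cfg = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in meta["model_config"].items()})
        model = build_model(cfg, *meta["input_shape"])
        with np.load(path / "weights.npz") as z:
            model.net.load_state_dict(dict(z.items()))
        model.trained = meta["trained"]
        model.history = meta["history"]
        return model


def build_model(config: ModelConfig | None = None, input_h: int = 77,
                input_w: int = 76, seed: int = 0,
                dtype=np.float32) -> TrainedModel:
    """Assemble an untrained CNN3 for a given input extent."""
    config = config or ModelConfig()
    shapes = stage_output_shape(input_h, input_w, config)
    if min(shapes[-1]) < 1:
        raise ValueError(
            f"input {input_h}x{input_w} too small for "
            f"{len(config.conv_channels)} conv+pool stages (got {shapes})")
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    conv_relu_indices = []
    in_ch = 1
    for ch in config.conv_channels:
        layers += [_nn.Conv2d(in_ch, ch, config.kernel, config.stride,
                              config.padding, rng=rng, dtype=dtype),
                   _nn.BatchNorm2d(ch, dtype=dtype),
                   _nn.ReLU(),
                   _nn.MaxPool2d(config.pool_kernel)]
        conv_relu_indices.append(len(layers) - 2)
        in_ch = ch
    layers.append(_nn.Flatten())
    n_flat = config.conv_channels[-1] * shapes[-1][0] * shapes[-1][1]
    sizes = (n_flat,) + tuple(config.fc_sizes)
    for i in range(len(config.fc_sizes) - 1):
        layers += [_nn.Linear(sizes[i], sizes[i + 1], rng=rng, dtype=dtype),
                   _nn.BatchNorm1d(sizes[i + 1], dtype=dtype),
                   _nn.ReLU()]
    layers.append(_nn.Linear(sizes[-2], sizes[-1], rng=rng, dtype=dtype))
    return TrainedModel(_nn.Sequential(*layers), config,
                        (input_h, input_w), conv_relu_indices)


def _val_metrics(model: TrainedModel, x: np.ndarray, y: np.ndarray,
                 groups: np.ndarray | None,
                 batch_size: int) -> tuple[float, float]:
    """Evaluation-mode validation BCE and AUROC.

    When ``groups`` is given (one id per side input) the AUROC is
    computed at study level — max logit and max label per group — which
    is the endpoint the classifier is used for.
    """
    total, n = 0.0, 0
    logits_all = []
    for i in range(0, len(x), batch_size):
        logits = model.net.forward(x[i:i + batch_size], train=False)[:, 0]
        loss, _ = _nn.bce_with_logits(logits, y[i:i + batch_size])
        total += loss * len(logits)
        n += len(logits)
        logits_all.append(logits)
    scores = np.concatenate(logits_all)
    labels = y
    if groups is not None:
        uniq, inv = np.unique(groups, return_inverse=True)
        g_scores = np.full(len(uniq), -np.inf)
        g_labels = np.zeros(len(uniq))
        np.maximum.at(g_scores, inv, scores)
        np.maximum.at(g_labels, inv, labels)
        scores, labels = g_scores, g_labels
    if len(np.unique(labels)) == 2:
        from sklearn.metrics import roc_auc_score

        val_auroc = float(roc_auc_score(labels, scores))
    else:
        val_auroc = float("nan")
    return total / n, val_auroc


def train(model: TrainedModel, train_set: list[SideInput],
          val_set: list[SideInput],
          config: TrainConfig | None = None) -> TrainedModel:
    """Fit with Adam on BCE; keep the best-validation-loss parameters."""
    config = config or TrainConfig()
    if not train_set or not val_set:
        raise ValueError("empty training or validation set")
    y_train = np.array([si.label for si in train_set], dtype=np.float32)
    if len(set(y_train.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    x_train = np.stack([si.pixels for si in train_set]).astype(np.float32)[:, None]
    x_val = np.stack([si.pixels for si in val_set]).astype(np.float32)[:, None]
    y_val = np.array([si.label for si in val_set], dtype=np.float32)
    # group validation sides by subject so the checkpoint metric is the
    # study-level max-rule AUROC; fall back to side level without ids
    ids = [si.subject_id for si in val_set]
    val_groups = np.array(ids) if all(ids) else None

    opt = _nn.Adam(model.net.params(), lr=config.learning_rate,
                   beta1=config.beta1, beta2=config.beta2, eps=config.epsilon)
    rng = np.random.default_rng(config.seed)
    w_pos = config.pos_weight
    # Checkpoint selection: validation BCE is non-monotone in ranking
    # quality here, because the healthy contralateral side of a malignant
    # study carries label 1; a confident model pays a growing BCE penalty
    # on those sides even as its discrimination improves. Validation
    # AUROC (the study's endpoint metric) is therefore the default
    # best-epoch criterion; "loss" restores plain best-validation-BCE.
    use_auroc = config.checkpoint == "auroc" and len(set(
        int(si.label) for si in val_set)) == 2
    best = (-np.inf, model.net.state_dict())
    model.history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_train))
        epoch_loss, nb = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = model.net.forward(x_train[idx], train=True)[:, 0]
            loss, dlogits = _nn.bce_with_logits(logits, y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // config.batch_size}: "
                    f"lr={config.learning_rate}, logits range "
                    f"[{logits.min():.3g}, {logits.max():.3g}]")
            if w_pos != 1.0:
                scale = np.where(y_train[idx] == 1, w_pos, 1.0)
                dlogits = (dlogits * scale).astype(dlogits.dtype)
            model.net.backward(dlogits[:, None])
            opt.step()
            epoch_loss += loss
            nb += 1
        val_loss, val_auroc = _val_metrics(model, x_val, y_val, val_groups,
                                           config.batch_size)
        model.history.append({"epoch": epoch,
                              "train_loss": epoch_loss / max(nb, 1),
                              "val_loss": val_loss,
                              "val_auroc": val_auroc})
        criterion = val_auroc if use_auroc else -val_loss
        if criterion > best[0]:
            best = (criterion, model.net.state_dict())
    model.net.load_state_dict(best[1])
    model.trained = True
    return model


def predict_study(model: TrainedModel, left: SideInput,
                  right: SideInput) -> float:
    """Study-level malignancy probability: max over the two sides."""
    p = model.predict_proba([left, right])
    return float(p.max())
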