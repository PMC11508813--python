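"""Training loop, inference, and checkpoint I/O for the segmentation model."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from whealmeter.nn import layers as L
from whealmeter.nn.model import FCN, NetworkConfig, build_network


class TrainingDivergedError(RuntimeError):
    """The loss became non-finite during training."""


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings; defaults match the reference protocol."""

    epochs: int = 400
    batch_size: int = 32
    learning_rate: float = 1e-4
    seed: int = 0
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


def _to_input(image: np.ndarray) -> np.ndarray:
    """uint8/float ``(H, W, 3)`` image -> normalized ``(3, H, W)`` float."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got {img.shape}")
    if img.max() > 1.5:  # uint8 range
        img = img / 255.0
    return (img - 0.5).transpose(2, 0, 1)


def _prepare_dataset(dataset) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([_to_input(img) for img, _ in dataset])
    ys = np.stack([np.asarray(mask, dtype=np.intp) for _, mask in dataset])
    if xs.shape[2:] != ys.shape[1:]:
        raise ValueError("image and mask spatial dimensions differ")
    return xs, ys


def train(
    model: FCN, dataset: list, config: TrainingConfig
) -> tuple[FCN, list[float]]:
    """Train with Adam on per-pixel cross-entropy; returns per-epoch mean loss.

    ``dataset`` is a list of ``(image, mask)`` pairs.  The batch size is
    clipped to the dataset size.  Reproducible given ``config.seed``.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    xs, ys = _prepare_dataset(dataset)
    n = xs.shape[0]
    bs = min(config.batch_size, n)
    rng = np.random.default_rng(config.seed)
    opt = L.Adam(model.params(), lr=config.learning_rate)

    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            logits = model.forward_logits(xs[idx])
            loss, dlogits = L.softmax_cross_entropy(logits, ys[idx])
            if not math.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss {loss} at epoch {len(history) + 1}"
                )
            model.backward(dlogits)
            opt.step(model.grads())
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
    return model, history


def predict_proba(model: FCN, image: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities ``(H, W, C)`` at the image's own size.

    Images whose dimensions are not divisible by 32 are resized (bilinear)
    for the network and the probability map is resized back.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    if h % 32 or w % 32:
        wn, hn = model.config.input_size
        img_r = resize(img, (hn, wn), order=1, preserve_range=True, anti_aliasing=True)
    else:
        img_r = img
    probs = model.forward(_to_input(img_r)[None])[0]  # (C, H', W')
    probs = probs.transpose(1, 2, 0)
    if probs.shape[:2] != (h, w):
        probs = resize(probs, (h, w), order=1, preserve_range=True, anti_aliasing=False)
        probs = probs / probs.sum(axis=-1, keepdims=True)
    return probs


def classes_from_proba(probs: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over an ``(H, W, C)`` probability map.

    Ties resolve to the lowest class index, i.e. toward background (class 0).
    """
    return np.asarray(probs).argmax(axis=-1).astype(np.uint8)


def predict_mask(model: FCN, image: np.ndarray) -> np.ndarray:
    """Argmax class mask for one image (ties resolve to background)."""
    return classes_from_proba(predict_proba(model, image))


def save_model(model: FCN, path) -> None:
    """Checkpoint: parameter arrays + JSON-encoded config, NumPy ``.npz``."""
    np.savez_compressed(
        path,
        __config__=np.frombuffer(model.config_json().encode(), dtype=np.uint8),
        **model.state_dict(),
    )


def load_model(path) -> FCN:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
        cfg_dict["encoder_widths"] = tuple(cfg_dict["encoder_widths"])
        cfg_dict["convs_per_block"] = tuple(cfg_dict["convs_per_block"])
        model = build_network(NetworkConfig(**cfg_dict))
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
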