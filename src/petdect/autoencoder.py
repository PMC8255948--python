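"""Single-image convolutional autoencoders for anatomical feature extraction.

A RED-CNN or U-Net is trained, unsupervised, to reproduce the X-ray CT prior
image itself (sum-of-squares reconstruction loss, Adam).  After training, the
activation of the penultimate layer — multi-channel, at input resolution —
serves as the per-pixel feature vector for building the kernel matrix.

Default learning rates: 1e-4 (RED-CNN) and 1e-2 (U-Net); 300 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .kernels import FeatureMap
from .nn import Adam, REDCNN, UNet

DEFAULT_LR = {"redcnn": 1e-4, "unet": 1e-2}


@dataclass
class TrainingTrace:
    """Per-epoch sum-of-squares reconstruction loss."""

    losses: list = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.losses[-1]

    def __len__(self) -> int:
        return len(self.losses)


def build_model(architecture: str, image_shape: tuple[int, int],
                redcnn_width: int = 60,
                unet_channels: tuple[int, int, int, int] = (32, 64, 96, 112),
                unet_penultimate: int = 12, seed: int = 0):
    """Instantiate a RED-CNN or U-Net autoencoder with deterministic init."""
    if architecture == "redcnn":
        return REDCNN(width=redcnn_width, seed=seed)
    if architecture == "unet":
        return UNet(image_shape=image_shape, channels=unet_channels,
                    penultimate_channels=unet_penultimate, seed=seed)
    raise ValueError(f"unknown architecture {architecture!r}")


def _normalize_input(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("input must be a 2D image")
    if not np.all(np.isfinite(x)):
        raise ValueError("input image must be finite")
    top = x.max()
    out = (x / top if top > 0 else x)[None]
    return out.astype(np.float32)  # (1, H, W) in [0, 1]


def train_autoencoder(model, x: np.ndarray, epochs: int = 300,
                      lr: float = 1e-2) -> TrainingTrace:
    """Train ``model`` to reconstruct the (internally [0,1]-normalized) image.

    Full-image gradient steps with Adam; deterministic given the model's
    initialization seed.  Raises if the loss diverges to NaN.
    """
    target = _normalize_input(x)
    opt = Adam(model.params(), lr=lr)
    trace = TrainingTrace()
    for epoch in range(epochs):
        acts = model.forward(target)
        resid = acts["out"] - target
        with np.errstate(over="ignore"):
            loss = float(np.sum(resid * resid))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"autoencoder training diverged at epoch {epoch} (lr={lr}); "
                "reduce the learning rate"
            )
        model.backward(2.0 * resid, acts)
        opt.step(model.grads())
        trace.losses.append(loss)
    return trace


def extract_cnn_features(model, x: np.ndarray, layer: str = "penultimate") -> FeatureMap:
    """Feature map from one CNN layer: one row per pixel, one column per channel.

    Only layers whose spatial size equals the input qualify; ``"penultimate"``
    selects the architecture's default feature layer.
    """
    xin = _normalize_input(x)
    if layer == "penultimate":
        layer = model.feature_layer_default
    acts = model.forward(xin)
    if layer not in acts or layer in ("x", "out"):
        raise ValueError(f"unknown feature layer {layer!r}; "
                         f"choose from {model.layer_names()}")
    feat = acts[layer]
    if feat.shape[1:] != xin.shape[1:]:
        raise ValueError(
            f"layer {layer!r} has spatial size {feat.shape[1:]}, which does "
            f"not match the input {xin.shape[1:]}; pick a full-resolution layer"
        )
    n_p = feat.shape[1] * feat.shape[2]
    return FeatureMap(features=feat.reshape(feat.shape[0], n_p).T.copy(),
                      kind="cnn")


class ConvAutoencoder(BaseEstimator, TransformerMixin):
    """Unsupervised autoencoder feature extractor (scikit-learn style).

    Parameters
    ----------
    architecture : {"redcnn", "unet"}
    epochs : int
        Training epochs (full-image gradient steps).
    lr : float or None
        Learning rate; None selects the architecture default
        (1e-4 RED-CNN, 1e-2 U-Net).
    layer : str
        Feature layer; "penultimate" picks the architecture default.
    redcnn_width, unet_channels, unet_penultimate : widths
        Channel configuration; defaults meet the reference parameter budgets
        (~7e5 for RED-CNN, ~3.4e5 for U-Net).
    seed : int
        Initialization seed; training is deterministic given it.

    Attributes
    ----------
    model_ : trained network
    loss_trace_ : TrainingTrace
    n_params_ : int
    """

    def __init__(self, architecture: str = "unet", epochs: int = 300,
                 lr: float | None = None, layer: str = "penultimate",
                 redcnn_width: int = 60,
                 unet_channels: tuple = (32, 64, 96, 112),
                 unet_penultimate: int = 12, seed: int = 0):
        self.architecture = architecture
        self.epochs = epochs
        self.lr = lr
        self.layer = layer
        self.redcnn_width = redcnn_width
        self.unet_channels = unet_channels
        self.unet_penultimate = unet_penultimate
        self.seed = seed

    def fit(self, x: np.ndarray, y=None):
        x = np.asarray(x, dtype=float)
        self.model_ = build_model(
            self.architecture, x.shape, redcnn_width=self.redcnn_width,
            unet_channels=tuple(self.unet_channels),
            unet_penultimate=self.unet_penultimate, seed=self.seed,
        )
        lr = DEFAULT_LR[self.architecture] if self.lr is None else self.lr
        self.loss_trace_ = train_autoencoder(self.model_, x, epochs=self.epochs,
                                             lr=lr)
        self.n_params_ = self.model_.n_params
        return self

    def transform(self, x: np.ndarray) -> FeatureMap:
        return extract_cnn_features(self.model_, x, layer=self.layer)
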