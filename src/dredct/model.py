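"""Patch-based classification models.

Two backbones share one contract (224 x 224 x 3 in, 3 class probabilities
out):

``tiny-test``
    :class:`TinyPatchClassifier` — a small train-from-scratch network
    implemented in numpy: images are split into non-overlapping P x P
    patches (P = 16 by default, so a 224-pixel side yields 196 patches),
    each patch is tokenised by the magnitude of its per-channel 2D DCT
    spectrum, linearly embedded, rectified, mean-pooled over patches, and
    classified by a linear softmax head.  Trained with Adam on
    cross-entropy.  It runs on one CPU in seconds and needs no downloads,
    which makes the full enhancement -> training -> evaluation pipeline
    testable end to end.

``pretrained-vit``
    The ``vit_base_patch16_224`` vision transformer consumed as a black box
    through torch/timm with its classification head replaced by a fresh
    3-class softmax layer.  Available only when those optional dependencies
    are installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.fft import dct
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .augment import AugmentationPolicy, augment
from .enhancer import EnhancementConfig, enhance_image
from .io import DatasetManifest, load_manifest_images

__all__ = [
    "PatchSpec",
    "TrainConfig",
    "patch_count",
    "TinyPatchClassifier",
    "build_model",
    "fine_tune",
    "predict",
]


@dataclass(frozen=True)
class PatchSpec:
    """Geometry of the patch tokenisation: side x side image, P x P patches."""

    image_side: int = 224
    patch_side: int = 16
    channels: int = 3

    def __post_init__(self):
        if self.image_side % self.patch_side != 0:
            raise ValueError(
                f"image side {self.image_side} not divisible by patch side {self.patch_side}"
            )

    @property
    def n_patches(self) -> int:
        return (self.image_side // self.patch_side) ** 2


def patch_count(spec: PatchSpec) -> int:
    """Number of non-overlapping patches: N = H*W / P^2."""
    return (spec.image_side * spec.image_side) // (spec.patch_side**2)


@dataclass(frozen=True)
class TrainConfig:
    """Fine-tuning hyperparameters.

    Defaults are the reference settings for the pretrained backbone:
    learning rate 1e-4, Adam, batch size 16, 10 epochs, 224-pixel input.
    The tiny backbone trains from scratch, where 1e-4 is far below a useful
    step size; :meth:`for_tiny` scales the rate accordingly.
    """

    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 10
    image_side: int = 224
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training configuration")

    @classmethod
    def for_tiny(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """Settings scaled to the small train-from-scratch backbone."""
        kw = dict(learning_rate=3e-3, batch_size=16, epochs=10, seed=seed)
        kw.update(overrides)
        return cls(**kw)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    """Standard Adam optimizer over a list of parameter arrays."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class TinyPatchClassifier(ClassifierMixin, BaseEstimator):
    """Small patch-embedding classifier trained from scratch with Adam.

    Architecture: each non-overlapping P x P patch is mapped to the
    magnitude of its per-channel orthonormal 2D DCT spectrum (a fixed,
    phase-invariant tokenisation that exposes local frequency content), then
    a shared linear embedding to ``embed_dim`` units, ReLU, mean pooling
    over patches, and a linear softmax head.  Inputs are standardised per
    channel with statistics fitted on the training images.

    Parameters
    ----------
    patch_size : side of the square patches (image side must be divisible).
    embed_dim : width of the patch embedding.
    learning_rate, batch_size, epochs : Adam settings.
    seed : seeds initialisation and batch shuffling; a fixed seed makes
        single-threaded runs exactly reproducible.
    """

    def __init__(
        self,
        patch_size: int = 16,
        embed_dim: int = 32,
        learning_rate: float = 3e-3,
        batch_size: int = 16,
        epochs: int = 10,
        seed: int = 0,
    ):
        self.patch_size = patch_size
        self.embed_dim = embed_dim
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _patches(self, X: np.ndarray) -> np.ndarray:
        """Tokenise images into per-patch |2D DCT| feature vectors."""
        n, h, w, c = X.shape
        p = self.patch_size
        if h % p or w % p:
            raise ValueError(f"image side {h}x{w} not divisible by patch size {p}")
        Xp = X.reshape(n, h // p, p, w // p, p, c)
        Xp = Xp.transpose(0, 1, 3, 5, 2, 4)  # (n, gh, gw, c, p, p)
        spec = dct(dct(Xp, type=2, norm="ortho", axis=-1), type=2, norm="ortho", axis=-2)
        return np.abs(spec).reshape(n, (h // p) * (w // p), c * p * p)

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            X = X[None]
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError(f"expected images of shape (n, H, W, 3), got {X.shape}")
        return X

    def _forward(self, Xp: np.ndarray):
        # ReLU before pooling: rectification turns zero-mean high-frequency
        # texture into non-zero pooled energy (an odd activation would
        # cancel it under mean pooling)
        h = np.maximum(Xp @ self.W1_ + self.b1_, 0.0)
        pooled = h.mean(axis=1)
        logits = pooled @ self.W2_ + self.b2_
        return h, pooled, logits

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.std_

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None, augment_fn=None):
        """Train on images X (n, H, W, 3) with string or integer labels y.

        ``augment_fn(X, epoch) -> X_aug`` is applied to the training images
        at the start of every epoch (validation data is never augmented).
        Records a per-epoch trace in ``history_``.
        """
        X = self._check_X(X)
        y = np.asarray(y)
        if len(X) == 0 or len(X) != len(y):
            raise ValueError("X and y must be non-empty and of equal length")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        rng = np.random.default_rng(self.seed)

        self.mean_ = X.mean(axis=(0, 1, 2))
        std = X.std(axis=(0, 1, 2))
        self.std_ = np.where(std > 0, std, 1.0)

        d_in = self.patch_size * self.patch_size * 3
        self.W1_ = rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, self.embed_dim))
        self.b1_ = np.zeros(self.embed_dim)
        self.W2_ = rng.normal(
            0.0, 1.0 / np.sqrt(self.embed_dim), size=(self.embed_dim, n_classes)
        )
        self.b2_ = np.zeros(n_classes)

        opt = _Adam([self.W1_, self.b1_, self.W2_, self.b2_], lr=self.learning_rate)
        history = {"epoch": [], "train_loss": [], "train_accuracy": []}
        has_val = X_val is not None and y_val is not None
        if has_val:
            X_val = self._check_X(X_val)
            y_val = np.asarray(y_val)
            history["val_accuracy"] = []

        n = len(X)
        # without augmentation the tokenisation is epoch-invariant: do it once
        Xp_all = self._patches(self._normalize(X)) if augment_fn is None else None
        for epoch in range(self.epochs):
            if augment_fn is not None:
                X_ep = self._check_X(augment_fn(X, epoch))
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                yb = y_idx[idx]
                if Xp_all is not None:
                    Xp = Xp_all[idx]
                else:
                    Xp = self._patches(self._normalize(X_ep[idx]))
                h, pooled, logits = self._forward(Xp)
                probs = _softmax(logits)
                losses.append(
                    -np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)).mean()
                    * len(yb)
                )
                correct += int((logits.argmax(axis=1) == yb).sum())

                # backward pass
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                gW2 = pooled.T @ dlogits
                gb2 = dlogits.sum(axis=0)
                dpooled = dlogits @ self.W2_.T
                dh = dpooled[:, None, :] / Xp.shape[1] * (h > 0.0)
                gW1 = np.einsum("bpi,bpj->ij", Xp, dh)
                gb1 = dh.sum(axis=(0, 1))
                opt.step([gW1, gb1, gW2, gb2])

            history["epoch"].append(epoch + 1)
            history["train_loss"].append(float(np.sum(losses) / n))
            history["train_accuracy"].append(correct / n)
            if has_val:
                history["val_accuracy"].append(float(self.score(X_val, y_val)))

        self.history_ = pd.DataFrame(history)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "W1_")
        X = self._normalize(self._check_X(X))
        _, _, logits = self._forward(self._patches(X))
        return _softmax(logits)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # argmax breaks ties toward the lower class index (classes_ order)
        return self.classes_[proba.argmax(axis=1)]


def build_model(n_classes: int = 3, backbone: str = "tiny-test", **kwargs):
    """Construct a classifier for the requested backbone mode.

    ``tiny-test`` returns a :class:`TinyPatchClassifier`; ``pretrained-vit``
    requires the optional torch/timm dependencies and pretrained weights and
    raises a clear error when they are unavailable.
    """
    if backbone == "tiny-test":
        return TinyPatchClassifier(**kwargs)
    if backbone == "pretrained-vit":
        try:
            from ._vit import PretrainedViTClassifier
        except ImportError as exc:
            raise RuntimeError(
                "backbone 'pretrained-vit' (vit_base_patch16_224) needs the optional "
                "torch and timm dependencies plus downloadable weights; install them "
                "or use backbone='tiny-test' for a download-free run"
            ) from exc
        return PretrainedViTClassifier(n_classes=n_classes, **kwargs)
    raise ValueError(f"unknown backbone {backbone!r}")


def _make_augment_fn(policy: AugmentationPolicy, seed: int):
    def augment_fn(X: np.ndarray, epoch: int) -> np.ndarray:
        rng = np.random.default_rng([seed, epoch])
        return np.stack([augment(img, policy, rng) for img in X])

    return augment_fn


def fine_tune(
    model,
    train_manifest: DatasetManifest,
    val_manifest: DatasetManifest,
    cfg: TrainConfig,
    enhancement: EnhancementConfig | None = None,
    augmentation: AugmentationPolicy | None = None,
):
    """Train ``model`` on the manifests, optionally enhancing every image.

    Enhancement (when configured) runs once per loaded image, before
    normalisation, on real-valued planes; per-epoch augmentation then acts
    on the enhanced images.  Returns ``(model, trace)`` with the per-epoch
    loss/accuracy trace.
    """
    if len(train_manifest) == 0 or len(val_manifest) == 0:
        raise ValueError("train and validation manifests must be non-empty")
    if set(train_manifest.paths) & set(val_manifest.paths):
        raise ValueError("train and validation manifests overlap")
    X_tr, y_tr = load_manifest_images(train_manifest, side=cfg.image_side)
    X_va, y_va = load_manifest_images(val_manifest, side=cfg.image_side)
    if enhancement is not None:
        X_tr = np.stack([enhance_image(x, enhancement) for x in X_tr])
        X_va = np.stack([enhance_image(x, enhancement) for x in X_va])
    model.set_params(
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        seed=cfg.seed,
    )
    augment_fn = (
        _make_augment_fn(augmentation, cfg.seed) if augmentation is not None else None
    )
    model.fit(X_tr, y_tr, X_val=X_va, y_val=y_va, augment_fn=augment_fn)
    return model, model.history_


def predict(model, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels for a stack of images."""
    proba = model.predict_proba(images)
    labels = model.classes_[proba.argmax(axis=1)]
    return proba, labels
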