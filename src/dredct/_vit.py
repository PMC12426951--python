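"""Optional pretrained vision-transformer backbone (requires torch + timm).

The backbone ``vit_base_patch16_224`` is consumed as a black box; only its
classification head is replaced by a fresh 3-class softmax layer.  All
layers are fine-tuned by default (``freeze_backbone`` switches the backbone
to feature-extractor mode).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import timm  # noqa: F401 - hard requirement for this module
import torch
from sklearn.base import BaseEstimator, ClassifierMixin

BACKBONE_NAME = "vit_base_patch16_224"


class PretrainedViTClassifier(ClassifierMixin, BaseEstimator):
    """Fine-tunable ViT-B/16 with a replaced 3-class head."""

    def __init__(
        self,
        n_classes: int = 3,
        learning_rate: float = 1e-4,
        batch_size: int = 16,
        epochs: int = 10,
        seed: int = 0,
        freeze_backbone: bool = False,
        device: str = "cpu",
    ):
        self.n_classes = n_classes
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.freeze_backbone = freeze_backbone
        self.device = device

    def _build(self):
        try:
            model = timm.create_model(
                BACKBONE_NAME, pretrained=True, num_classes=self.n_classes
            )
        except Exception as exc:  # no network / missing weight cache
            raise RuntimeError(
                f"pretrained weights for {BACKBONE_NAME!r} are unavailable "
                f"({exc}); use backbone='tiny-test' for a download-free run"
            ) from exc
        if self.freeze_backbone:
            for name, p in model.named_parameters():
                if not name.startswith("head"):
                    p.requires_grad_(False)
        return model.to(self.device)

    def _tensor(self, X: np.ndarray) -> "torch.Tensor":
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        # images arrive in [0, 255] (possibly beyond, post-enhancement);
        # normalise with the backbone's training statistics
        mean = np.array([0.485, 0.456, 0.406], dtype=np.float32) * 255.0
        std = np.array([0.229, 0.224, 0.225], dtype=np.float32) * 255.0
        X = (X - mean) / std
        return torch.from_numpy(X.transpose(0, 3, 1, 2)).to(self.device)

    def fit(self, X, y, X_val=None, y_val=None, augment_fn=None):
        torch.manual_seed(self.seed)
        self.classes_, y_idx = np.unique(np.asarray(y), return_inverse=True)
        model = self._build()
        opt = torch.optim.Adam(
            (p for p in model.parameters() if p.requires_grad), lr=self.learning_rate
        )
        loss_fn = torch.nn.CrossEntropyLoss()
        rng = np.random.default_rng(self.seed)
        X = np.asarray(X, dtype=np.float32)
        y_t = torch.from_numpy(y_idx)
        history = {"epoch": [], "train_loss": [], "train_accuracy": []}
        if X_val is not None:
            history["val_accuracy"] = []
        n = len(X)
        for epoch in range(self.epochs):
            X_ep = augment_fn(X, epoch) if augment_fn is not None else X
            order = rng.permutation(n)
            model.train()
            total_loss, correct = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = self._tensor(X_ep[idx])
                yb = y_t[idx]
                opt.zero_grad()
                logits = model(xb)
                loss = loss_fn(logits, yb)
                loss.backward()
                opt.step()
                total_loss += float(loss) * len(idx)
                correct += int((logits.argmax(1) == yb).sum())
            history["epoch"].append(epoch + 1)
            history["train_loss"].append(total_loss / n)
            history["train_accuracy"].append(correct / n)
            if X_val is not None:
                history["val_accuracy"].append(
                    float(np.mean(self.predict(X_val) == np.asarray(y_val)))
                )
            self.model_ = model
        self.model_ = model
        self.history_ = pd.DataFrame(history)
        return self

    @torch.no_grad()
    def predict_proba(self, X) -> np.ndarray:
        self.model_.eval()
        out = []
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        for start in range(0, len(X), self.batch_size):
            logits = self.model_(self._tensor(X[start : start + self.batch_size]))
            out.append(torch.softmax(logits, dim=1).cpu().numpy())
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
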