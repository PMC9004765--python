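"""Compact numpy feed-forward network with dropout for bin classification.

Architecture: input → four 512-node fully-connected ReLU layers with 50%
(inverted) dropout between them → softmax output.  Trained with Adam on the
cross-entropy loss, mini-batches of 128, early stopping on validation loss
with the best-validation-epoch weights retained.  Fully deterministic for a
fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = ["MLPConfig", "DropoutMLP"]


@dataclass(frozen=True)
class MLPConfig:
    hidden_layers: tuple[int, ...] = (512, 512, 512, 512)
    dropout: float = 0.5
    epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 1e-3
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DropoutMLP:
    """Feed-forward softmax classifier trained with Adam + dropout."""

    def __init__(self, n_features: int, classes: Sequence[str],
                 config: MLPConfig = MLPConfig()):
        self.n_features = int(n_features)
        self.classes = list(classes)
        self.config = config
        rng = np.random.default_rng(config.seed)
        sizes = [self.n_features, *config.hidden_layers, len(self.classes)]
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(s) for s in sizes[1:]]
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    # ----- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray, rng: Optional[np.random.Generator] = None):
        """Returns (probabilities, per-layer activations, dropout masks)."""
        acts = [x]
        masks = []
        h = x
        n_hidden = len(self.weights) - 1
        for i in range(n_hidden):
            h = np.maximum(h @ self.weights[i] + self.biases[i], 0.0)
            if rng is not None and self.config.dropout > 0:
                keep = 1.0 - self.config.dropout
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
        probs = _softmax(h @ self.weights[-1] + self.biases[-1])
        return probs, acts, masks

    def _backward(self, probs, acts, masks, y_onehot):
        n = len(y_onehot)
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = (probs - y_onehot) / n
        grads_w[-1] = acts[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        for i in range(len(self.weights) - 2, -1, -1):
            delta = delta @ self.weights[i + 1].T
            if masks[i] is not None:
                delta = delta * masks[i]
            delta = delta * (acts[i + 1] > 0)
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
        return grads_w, grads_b

    # ----- training -----------------------------------------------------------

    def fit(self, x: np.ndarray, y: np.ndarray,
            x_val: Optional[np.ndarray] = None,
            y_val: Optional[np.ndarray] = None) -> "DropoutMLP":
        """Train on integer class labels; early-stop on validation loss."""
        cfg = self.config
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite features")
        n_classes = len(self.classes)
        eye = np.eye(n_classes)
        rng = np.random.default_rng(cfg.seed + 1)
        m_w = [np.zeros_like(w) for w in self.weights]
        v_w = [np.zeros_like(w) for w in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_weights = None
        stale = 0
        for _ in range(cfg.epochs):
            order = rng.permutation(len(x))
            epoch_loss = 0.0
            for s in range(0, len(x), cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                xb, yb = x[idx], eye[y[idx]]
                probs, acts, masks = self._forward(xb, rng)
                epoch_loss += -np.sum(np.log(probs[np.arange(len(idx)), y[idx]] + 1e-12))
                gw, gb = self._backward(probs, acts, masks, yb)
                step += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for i in range(len(self.weights)):
                    m_w[i] = beta1 * m_w[i] + (1 - beta1) * gw[i]
                    v_w[i] = beta2 * v_w[i] + (1 - beta2) * gw[i] ** 2
                    self.weights[i] -= lr_t * m_w[i] / (np.sqrt(v_w[i]) + eps)
                    m_b[i] = beta1 * m_b[i] + (1 - beta1) * gb[i]
                    v_b[i] = beta2 * v_b[i] + (1 - beta2) * gb[i] ** 2
                    self.biases[i] -= lr_t * m_b[i] / (np.sqrt(v_b[i]) + eps)
            self.history["train_loss"].append(epoch_loss / len(x))
            if x_val is not None and len(x_val):
                val_probs = self.predict_proba(x_val)
                val_loss = float(
                    -np.mean(np.log(val_probs[np.arange(len(y_val)), y_val] + 1e-12))
                )
                self.history["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_weights = ([w.copy() for w in self.weights],
                                    [b.copy() for b in self.biases])
                    stale = 0
                else:
                    stale += 1
                    if stale > cfg.patience:
                        break
        if best_weights is not None:
            self.weights, self.biases = best_weights
        return self

    # ----- inference ----------------------------------------------------------

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        probs, _, _ = self._forward(np.asarray(x, dtype=float), rng=None)
        return probs

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)

    # ----- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights (npz) plus a JSON sidecar with layout and classes."""
        path = Path(path)
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(path, **arrays)
        sidecar = {
            "n_features": self.n_features,
            "classes": self.classes,
            "config": {
                "hidden_layers": list(self.config.hidden_layers),
                "dropout": self.config.dropout,
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "learning_rate": self.config.learning_rate,
                "patience": self.config.patience,
                "seed": self.config.seed,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DropoutMLP":
        path = Path(path)
        npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
        sidecar = json.loads(npz_path.with_suffix(".json").read_text())
        cfg = MLPConfig(
            hidden_layers=tuple(sidecar["config"]["hidden_layers"]),
            dropout=sidecar["config"]["dropout"],
            epochs=sidecar["config"]["epochs"],
            batch_size=sidecar["config"]["batch_size"],
            learning_rate=sidecar["config"]["learning_rate"],
            patience=sidecar["config"]["patience"],
            seed=sidecar["config"]["seed"],
        )
        model = cls(sidecar["n_features"], sidecar["classes"], cfg)
        data = np.load(npz_path)
        model.weights = [data[f"w{i}"] for i in range(len(model.weights))]
        model.biases = [data[f"b{i}"] for i in range(len(model.biases))]
        return model
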