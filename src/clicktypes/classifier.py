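"""Balanced training sets, augmentation, and the feed-forward bin classifier.

Each training example is the concatenation of a bin cluster's mean
normalized spectrum (181 values), ICI probability histogram (60 values) and
mean waveform envelope (100 values) — a 341-vector.  Every class contributes
the same number of examples (5000 by default): classes with more labelled
bins are subsampled at random, classes with fewer are topped up by
augmentation — Gaussian noise on spectrum and envelope, empirical-resample
perturbation on the ICI histogram.  Augmented examples are confined to the
training split; test and validation stay purely real.  The split is
70/20/10 train/test/validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from clicktypes.detection import ENVELOPE_POINTS, GRID_KHZ
from clicktypes.features import ICI_BIN_WIDTH_S, ICI_MAX_S
from clicktypes.network import DropoutMLP, MLPConfig

__all__ = [
    "NetworkConfig",
    "TrainingExample",
    "TrainingSets",
    "FEATURE_COLUMNS",
    "N_FEATURES",
    "build_training_set",
    "augment_spectrum_envelope",
    "augment_ici",
    "augment_example",
    "train_network",
    "classify_bins",
]

_N_SPEC = len(GRID_KHZ)
_N_ICI = int(round(ICI_MAX_S / ICI_BIN_WIDTH_S))
_N_ENV = ENVELOPE_POINTS

#: fixed feature layout: spectrum ‖ ICI ‖ envelope
FEATURE_COLUMNS = (
    [f"spec_{f:.1f}" for f in GRID_KHZ]
    + [f"ici_{i:02d}" for i in range(_N_ICI)]
    + [f"env_{i:03d}" for i in range(_N_ENV)]
)
N_FEATURES = len(FEATURE_COLUMNS)

_SPEC_SLICE = slice(0, _N_SPEC)
_ICI_SLICE = slice(_N_SPEC, _N_SPEC + _N_ICI)
_ENV_SLICE = slice(_N_SPEC + _N_ICI, N_FEATURES)


@dataclass(frozen=True)
class NetworkConfig:
    """Classifier configuration (architecture, balancing, split)."""

    hidden_layers: tuple[int, ...] = (512, 512, 512, 512)
    dropout: float = 0.5
    epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 1e-3
    patience: int = 10
    examples_per_class: int = 5000
    split: tuple[int, int, int] = (70, 20, 10)  # train/test/validation, percent
    augment_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.split) != 100:
            raise ValueError("split must sum to 100")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    def mlp_config(self) -> MLPConfig:
        return MLPConfig(
            hidden_layers=self.hidden_layers,
            dropout=self.dropout,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            patience=self.patience,
            seed=self.seed,
        )


@dataclass
class TrainingExample:
    """One classifier example: 341 features, class label, augmentation flag."""

    features: np.ndarray
    class_label: str
    augmented: bool = False


@dataclass
class TrainingSets:
    """Partitioned, class-balanced train/test/validation example sets."""

    train: list[TrainingExample]
    test: list[TrainingExample]
    validation: list[TrainingExample]
    classes: list[str]

    def arrays(self, subset: str) -> tuple[np.ndarray, np.ndarray]:
        """(features, integer labels) for one subset."""
        examples: list[TrainingExample] = getattr(self, subset)
        index = {c: i for i, c in enumerate(self.classes)}
        x = np.stack([e.features for e in examples])
        y = np.array([index[e.class_label] for e in examples])
        return x, y


def _renorm01(seg: np.ndarray) -> np.ndarray:
    lo, hi = seg.min(), seg.max()
    return (seg - lo) / (hi - lo) if hi > lo else np.zeros_like(seg)


def augment_spectrum_envelope(example: TrainingExample, noise_sd: float = 0.05,
                              rng: Optional[np.random.Generator] = None) -> TrainingExample:
    """New example with Gaussian noise added to spectrum and envelope segments.

    Each perturbed segment is re-min-max-normalized to [0, 1]; the ICI
    segment and the class label are untouched.  ``noise_sd = 0`` returns an
    exact copy (flagged augmented).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    f = example.features.copy()
    if noise_sd > 0:
        f[_SPEC_SLICE] = _renorm01(f[_SPEC_SLICE] + rng.normal(0, noise_sd, _N_SPEC))
        f[_ENV_SLICE] = _renorm01(f[_ENV_SLICE] + rng.normal(0, noise_sd, _N_ENV))
    return TrainingExample(features=f, class_label=example.class_label, augmented=True)


def augment_ici(example: TrainingExample, class_ici_pool: np.ndarray,
                perturb_weight: float = 0.2, n_draws: int = 100,
                rng: Optional[np.random.Generator] = None) -> TrainingExample:
    """New example whose ICI histogram is perturbed by empirical resampling.

    ``n_draws`` pseudo-counts are drawn from the class's pooled empirical ICI
    distribution and blended into the histogram with weight
    ``perturb_weight``; the result is re-normalized to sum 1.  Zero weight is
    the identity; an empty/degenerate pool falls back to an unmodified copy.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    f = example.features.copy()
    pool = np.asarray(class_ici_pool, dtype=float)
    hist = f[_ICI_SLICE]
    if perturb_weight > 0 and pool.size == hist.size and pool.sum() > 0 and hist.sum() > 0:
        draws = rng.multinomial(n_draws, pool / pool.sum()) / n_draws
        new = (1.0 - perturb_weight) * hist + perturb_weight * draws
        f[_ICI_SLICE] = new / new.sum()
    return TrainingExample(features=f, class_label=example.class_label, augmented=True)


def augment_example(example: TrainingExample, class_ici_pool: np.ndarray,
                    noise_sd: float = 0.05,
                    rng: Optional[np.random.Generator] = None) -> TrainingExample:
    """Spectrum/envelope noise plus ICI resampling in one step."""
    rng = rng if rng is not None else np.random.default_rng(0)
    return augment_ici(augment_spectrum_envelope(example, noise_sd, rng),
                       class_ici_pool, rng=rng)


def _examples_from_frame(frame: pd.DataFrame) -> list[TrainingExample]:
    feats = frame[FEATURE_COLUMNS].to_numpy(dtype=float)
    return [
        TrainingExample(features=feats[i], class_label=lab)
        for i, lab in enumerate(frame["label"])
    ]


def build_training_set(labelled_bins: pd.DataFrame,
                       config: NetworkConfig = NetworkConfig(),
                       rng: Optional[np.random.Generator] = None,
                       classes: Optional[Sequence[str]] = None) -> TrainingSets:
    """Class-balanced 70/20/10 train/test/validation sets with augmentation.

    Every class contributes exactly ``examples_per_class`` examples: classes
    with more labelled bins are subsampled at random; classes with fewer
    keep all their real bins — test and validation are filled with real
    examples first — and the training split is topped up with augmented
    copies.  ``classes`` fixes the expected class list (a class without any
    labelled bin is a hard error); by default the classes present in the
    data are used.  Deterministic for a fixed seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_total = config.examples_per_class
    n_train = n_total * config.split[0] // 100
    n_test = n_total * config.split[1] // 100
    n_val = n_total - n_train - n_test
    classes = sorted(classes) if classes is not None else sorted(labelled_bins["label"].unique())
    train: list[TrainingExample] = []
    test: list[TrainingExample] = []
    val: list[TrainingExample] = []
    for cls in classes:
        sub = labelled_bins[labelled_bins["label"] == cls]
        if len(sub) == 0:
            raise ValueError(f"class {cls!r} has no labelled bins")
        examples = _examples_from_frame(sub)
        order = rng.permutation(len(examples))
        if len(examples) >= n_total:
            chosen = [examples[i] for i in order[:n_total]]
            test.extend(chosen[:n_test])
            val.extend(chosen[n_test:n_test + n_val])
            train.extend(chosen[n_test + n_val:])
            continue
        shuffled = [examples[i] for i in order]
        # test/validation take real examples first (augmentation never leaks
        # into them); scale their size down proportionally for tiny classes
        m = len(shuffled)
        take_test = n_test if m >= n_test + n_val + 1 else max(1, m * config.split[1] // 100)
        take_val = n_val if m >= n_test + n_val + 1 else max(1, m * config.split[2] // 100)
        take_val = min(take_val, max(m - take_test - 1, 0))
        test.extend(shuffled[:take_test])
        val.extend(shuffled[take_test:take_test + take_val])
        real_train = shuffled[take_test + take_val:]
        train.extend(real_train)
        pool = np.mean([e.features[_ICI_SLICE] for e in examples], axis=0)
        need = n_train - len(real_train)
        source = real_train if real_train else shuffled
        for k in range(need):
            src = source[int(rng.integers(len(source)))]
            train.append(augment_example(src, pool, config.augment_noise_sd, rng))
    return TrainingSets(train=train, test=test, validation=val, classes=classes)


def train_network(sets: TrainingSets,
                  config: NetworkConfig = NetworkConfig()) -> DropoutMLP:
    """Train the feed-forward classifier on the prepared sets.

    Minimizes cross-entropy with Adam; validation loss is recorded per epoch
    and the best-validation-epoch weights are retained (see the model's
    ``history``).
    """
    if len(sets.classes) < 2:
        raise ValueError("need at least 2 classes")
    x, y = sets.arrays("train")
    xv, yv = sets.arrays("validation") if sets.validation else (None, None)
    model = DropoutMLP(x.shape[1], sets.classes, config.mlp_config())
    model.fit(x, y, xv, yv)
    return model


def classify_bins(model: DropoutMLP, bin_features: pd.DataFrame) -> pd.DataFrame:
    """Label bin clusters: argmax class plus max-probability confidence.

    Every row receives a label (mixed or noisy clusters included); the
    confidence is the winning softmax probability, always ≥ 1/n_classes.
    """
    out_cols = ["label", "confidence"]
    if len(bin_features) == 0:
        meta_cols = [c for c in ("bin_start", "cluster_id") if c in bin_features.columns]
        return pd.DataFrame(columns=meta_cols + out_cols)
    missing = [c for c in FEATURE_COLUMNS if c not in bin_features.columns]
    if missing:
        raise ValueError(f"feature columns missing: {missing[:3]}...")
    x = bin_features[FEATURE_COLUMNS].to_numpy(dtype=float)
    if x.shape[1] != model.n_features:
        raise ValueError("feature dimension does not match the trained model")
    probs = model.predict_proba(x)
    idx = np.argmax(probs, axis=1)
    out = pd.DataFrame(
        {
            "label": [model.classes[i] for i in idx],
            "confidence": probs[np.arange(len(idx)), idx],
        },
        index=bin_features.index,
    )
    for col in ("bin_start", "cluster_id"):
        if col in bin_features.columns:
            out.insert(0, col, bin_features[col])
    return out
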