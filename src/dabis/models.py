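"""Small trainable classifiers, one per modality.

The audit framework is model-agnostic; these compact architectures exist
so a full audit trains in seconds on one CPU while remaining strong
enough to learn both structural signal and histogram-level acquisition
bias.  A registry maps architecture ids to builders; custom models plug
in through the same fit-step/score contract.

``histogram_baseline`` is the deliberately crippled control: a logistic
model on per-channel histogram summaries.  Since those features depend
only on each channel's value multiset, its decision values are exactly
identical on original and shuffled data — the feature family that
survives shuffling.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .data import TEXT_VOCAB, DatasetManifest
from .nn import (Conv, Dense, Flatten, GlobalMaxPool, MaxPool, ReLU,
                 SequentialClassifier)
from .roc_metrics import AurocEstimate, ScoreSet, bootstrap_ci


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Recipe for a registered model.

    ``input_shape`` is channels-first without the batch axis
    (e.g. ``(1, 32, 32)`` for a grayscale image).
    """

    architecture: str
    input_shape: tuple
    n_classes: int = 2
    seed: int = 0
    max_parameters: int = 500_000


def _conv_out(size: int, k: int) -> int:
    return size - k + 1


def _build_cnn(spec: ModelSpec, ndim: int, k: int, widths: tuple,
               hidden: int) -> SequentialClassifier:
    rng = np.random.default_rng(spec.seed)
    c_in = spec.input_shape[0]
    sizes = list(spec.input_shape[1:])
    layers = []
    for w in widths:
        if any(s < k for s in sizes):
            break  # input too small for another block
        layers += [Conv(c_in, w, k, ndim, rng), ReLU()]
        sizes = [_conv_out(s, k) for s in sizes]
        if all(s >= 2 for s in sizes):
            layers += [MaxPool()]
            sizes = [s // 2 for s in sizes]
        c_in = w
    if not layers:
        raise ValueError(
            f"input shape {spec.input_shape} too small for kernel {k}")
    layers += [Flatten(),
               Dense(c_in * int(np.prod(sizes)), hidden, rng), ReLU(),
               Dense(hidden, spec.n_classes, rng)]
    return SequentialClassifier(layers, spec.n_classes)


def _build_small_cnn2d(spec: ModelSpec) -> SequentialClassifier:
    if len(spec.input_shape) != 3:
        raise ValueError(f"small_cnn2d expects (C, H, W), got {spec.input_shape}")
    return _build_cnn(spec, ndim=2, k=3, widths=(8, 16), hidden=32)


def _build_small_cnn1d(spec: ModelSpec) -> SequentialClassifier:
    if len(spec.input_shape) != 2:
        raise ValueError(f"small_cnn1d expects (C, T), got {spec.input_shape}")
    return _build_cnn(spec, ndim=1, k=5, widths=(8, 16), hidden=32)


def _build_small_cnn3d(spec: ModelSpec) -> SequentialClassifier:
    if len(spec.input_shape) != 4:
        raise ValueError(f"small_cnn3d expects (C, D, H, W), got {spec.input_shape}")
    return _build_cnn(spec, ndim=3, k=3, widths=(4, 8), hidden=32)


def _build_char_cnn_text(spec: ModelSpec) -> SequentialClassifier:
    """Character-level 1-D CNN over one-hot characters.

    Letter-shuffle sensitivity matters here: a bag-of-characters model
    would be shuffle-invariant and understate the shortcut estimate, so
    the model convolves over character n-grams and global-max-pools.
    """
    if len(spec.input_shape) != 2:
        raise ValueError(
            f"char_cnn_text expects (vocab, length), got {spec.input_shape}")
    rng = np.random.default_rng(spec.seed)
    v = spec.input_shape[0]
    layers = [Conv(v, 32, 5, 1, rng), ReLU(),
              Conv(32, 32, 5, 1, rng), ReLU(),
              GlobalMaxPool(),
              Dense(32, spec.n_classes, rng)]
    return SequentialClassifier(layers, spec.n_classes)


def _build_mlp(spec: ModelSpec) -> SequentialClassifier:
    rng = np.random.default_rng(spec.seed)
    n_in = int(np.prod(spec.input_shape))
    layers = [Flatten(), Dense(n_in, 64, rng), ReLU(),
              Dense(64, spec.n_classes, rng)]
    return SequentialClassifier(layers, spec.n_classes)


MODEL_REGISTRY = {
    "small_cnn2d": _build_small_cnn2d,
    "small_cnn1d": _build_small_cnn1d,
    "small_cnn3d": _build_small_cnn3d,
    "char_cnn_text": _build_char_cnn_text,
    "mlp": _build_mlp,
}


def default_input_shape(architecture: str, modality: str, sample_shape: tuple,
                        text_max_len: int = 256) -> tuple:
    if modality == "text":
        return (len(TEXT_VOCAB), text_max_len)
    return tuple(sample_shape)


def build_model(spec: ModelSpec) -> SequentialClassifier:
    """Instantiate a freshly initialised registered model.

    Deterministic under ``spec.seed``; verifies the parameter budget and
    that a forward pass accepts the declared input shape.
    """
    if spec.architecture not in MODEL_REGISTRY:
        raise ValueError(
            f"unknown architecture {spec.architecture!r}; registered ids: "
            f"{sorted(MODEL_REGISTRY)}")
    model = MODEL_REGISTRY[spec.architecture](spec)
    if model.n_parameters > spec.max_parameters:
        raise ValueError(
            f"{spec.architecture} has {model.n_parameters} parameters, "
            f"over the {spec.max_parameters} bound")
    probe = np.zeros((1,) + tuple(spec.input_shape))
    out = model.forward(probe)
    if out.shape != (1, spec.n_classes):
        raise ValueError(
            f"{spec.architecture} produced output shape {out.shape} for "
            f"input {spec.input_shape}; expected (1, {spec.n_classes})")
    return model


def histogram_features(arr: np.ndarray) -> np.ndarray:
    """Per-channel first-order summaries: mean, sd, deciles.

    Computed from the sorted channel values so the features — and any
    model built on them — are bit-identical on original and shuffled
    versions of the same sample.
    """
    arr = np.asarray(arr, dtype=float)
    feats = []
    for ch in arr.reshape(arr.shape[0], -1):
        v = np.sort(ch)
        deciles = np.quantile(v, np.linspace(0.1, 0.9, 9))
        feats.append(np.concatenate([[v.mean(), v.std()], deciles]))
    return np.concatenate(feats)


def histogram_baseline(manifest: DatasetManifest, seed: int = 0,
                       test_fraction: float = 0.2,
                       n_bootstrap: int = 1000,
                       splits=None) -> AurocEstimate:
    """AUROC of a logistic model on per-channel histogram summaries.

    Trained on a patient-level 80/20 split of the manifest.  By
    construction the returned scores are shuffle-invariant, so this
    measures exactly the histogram-level (acquisition-bias-accessible)
    signal in the data.
    """
    from .training import make_splits

    if manifest.modality == "text":
        raise ValueError("histogram_baseline requires an array modality")
    if splits is None:
        splits = make_splits(
            manifest, (1.0 - test_fraction, 0.0, test_fraction),
            seed=seed)
    data = manifest.load_data()
    feats = np.stack([histogram_features(np.asarray(d, dtype=float))
                      for d in data])
    y = manifest.label_indices()
    train_idx = np.concatenate([splits.indices(manifest, "train"),
                                splits.indices(manifest, "val")])
    test_idx = splits.indices(manifest, "test")
    clf = make_pipeline(StandardScaler(),
                        LogisticRegression(max_iter=2000, random_state=seed))
    clf.fit(feats[train_idx], y[train_idx])
    scores = clf.predict_proba(feats[test_idx])
    scoreset = ScoreSet(scores, y[test_idx], manifest.class_names)
    return bootstrap_ci(scoreset, n_bootstrap=n_bootstrap, seed=seed)


def model_factory(architecture: str, input_shape: tuple, n_classes: int,
                  seed: int = 0):
    """Closure producing a freshly initialised model per call (the driver
    resets parameters between the plain and shuffled arms)."""
    spec = ModelSpec(architecture=architecture, input_shape=tuple(input_shape),
                     n_classes=n_classes, seed=seed)

    def factory():
        return build_model(spec)

    factory.spec = spec
    return factory


def histogram_baseline_scores(manifest: DatasetManifest, seed: int = 0,
                              splits=None) -> Optional[ScoreSet]:
    """Full-manifest scores of the histogram baseline (train on 80%,
    score everything); used by invariance checks."""
    from .training import make_splits

    if manifest.modality == "text":
        raise ValueError("histogram_baseline requires an array modality")
    if splits is None:
        splits = make_splits(manifest, (0.8, 0.0, 0.2), seed=seed)
    data = manifest.load_data()
    feats = np.stack([histogram_features(np.asarray(d, dtype=float))
                      for d in data])
    y = manifest.label_indices()
    train_idx = np.concatenate([splits.indices(manifest, "train"),
                                splits.indices(manifest, "val")])
    clf = make_pipeline(StandardScaler(),
                        LogisticRegression(max_iter=2000, random_state=seed))
    clf.fit(feats[train_idx], y[train_idx])
    return ScoreSet(clf.predict_proba(feats), y, manifest.class_names)
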