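"""Feature-extraction backbones and trainable classifier heads.

Two classifiers are trained on top of frozen convolutional backbones: a
2-class IRP classifier (is the integrated relaxation pressure normal or above
the cutoff?) fed 299x299x3 tensors, and a 5-class swallow-pattern classifier
fed 224x224x3 tensors.  The head in both cases is the same design: globally
average-pooled backbone features -> 20% dropout -> dense softmax, trained
with Adam on mini-batches of 32 that are reshuffled every epoch.

Backbones
---------
``tiny_test_cnn`` is a three-block convolutional stack with seeded random
weights, small enough that the whole pipeline trains and tests in seconds on
a CPU with nothing downloaded.  Random convolutional features followed by a
trained linear readout are a classical, surprisingly strong baseline; two
normalized coordinate channels are appended to the input so that globally
pooled features retain coarse spatial information (where in the swallow
window the pressure ridge sits).

``inception_v3`` and ``densenet201`` names are accepted and enforce their
input contracts (299 / 224); with ``weights="random"`` they yield seeded
random-weight stacks honoring those contracts.  ``weights="imagenet"`` raises
:class:`PretrainedWeightsUnavailableError`: no pretrained weight source is
bundled, and the pipeline's behaviour is exercised with the tiny backbone.

Dataset discipline: the train split fits the head, the test split is
monitored every epoch (and selects the checkpoint); the validation split is
evaluated exactly once, after training, and its metrics live on the returned
classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np

from . import evalmetrics
from .preprocess import NormalizedTensor
from .types import IRPClass, SwallowPattern

__all__ = [
    "BackboneSpec",
    "HeadConfig",
    "TrainConfig",
    "RandomConvBackbone",
    "TrainedClassifier",
    "PretrainedWeightsUnavailableError",
    "get_backbone",
    "extract_features",
    "split_dataset",
    "train_classifier",
    "predict",
]


class PretrainedWeightsUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class BackboneSpec:
    """Which feature extractor to use and how it is initialized."""

    name: str = "tiny_test_cnn"
    weights: str = "random"
    frozen: bool = True
    seed: int = 0

    _INPUT_SIZES = {
        "inception_v3": (299,),
        "densenet201": (224,),
        "tiny_test_cnn": (224, 299),
    }

    def __post_init__(self) -> None:
        if self.name not in self._INPUT_SIZES:
            raise ValueError(f"unknown backbone {self.name!r}")
        if self.weights not in ("random", "imagenet"):
            raise ValueError(f"unknown weights source {self.weights!r}")
        if not self.frozen:
            raise ValueError("backbones are feature extractors here; frozen only")

    @property
    def input_sizes(self) -> tuple[int, ...]:
        return self._INPUT_SIZES[self.name]


# conv channel plans per backbone name
_CHANNEL_PLANS = {
    "tiny_test_cnn": (32, 64, 128),
    "inception_v3": (32, 64, 128, 256),
    "densenet201": (32, 64, 128, 256),
}
_POOL_SIZE = 56  # spatial size after the stem's block-average downsample


class RandomConvBackbone:
    """Seeded random-weight convolutional feature extractor.

    Stem: append normalized x/y coordinate channels, centre-crop to a
    multiple of 56 and block-average down to 56x56.  Body: 3x3 valid
    convolutions with He-scaled seeded Gaussian weights, ReLU, and 2x2 max
    pooling between blocks.  Head side: global average pooling to a fixed-
    length vector.
    """

    def __init__(self, spec: BackboneSpec):
        if spec.weights == "imagenet":
            raise PretrainedWeightsUnavailableError(
                f"no pretrained weight source is bundled for {spec.name}; "
                "use weights='random' or the tiny_test_cnn backbone"
            )
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        channels = _CHANNEL_PLANS[spec.name]
        self._layers = []
        c_in = 5  # RGB + 2 coordinate channels
        for c_out in channels:
            fan_in = 9 * c_in
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
            b = np.zeros(c_out)
            self._layers.append((w.astype(np.float32), b.astype(np.float32)))
            c_in = c_out
        self.feature_dim = channels[-1]

    def extract(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=np.float32)
        if x.ndim != 3 or x.shape[2] != 3 or x.shape[0] != x.shape[1]:
            raise ValueError(f"expected square H x H x 3 tensor, got {x.shape}")
        if x.shape[0] not in self.spec.input_sizes:
            raise ValueError(
                f"backbone {self.spec.name} accepts sizes {self.spec.input_sizes}, "
                f"got {x.shape[0]}"
            )
        h = x.shape[0]
        yy, xx = np.meshgrid(
            np.linspace(-1, 1, h, dtype=np.float32),
            np.linspace(-1, 1, h, dtype=np.float32),
            indexing="ij",
        )
        x = np.concatenate([x, xx[..., None], yy[..., None]], axis=2)
        # centre-crop to a multiple of the pooled size, then block-average
        block = h // _POOL_SIZE
        crop = _POOL_SIZE * block
        off = (h - crop) // 2
        x = x[off : off + crop, off : off + crop]
        x = x.reshape(_POOL_SIZE, block, _POOL_SIZE, block, 5).mean(axis=(1, 3))
        for i, (w, b) in enumerate(self._layers):
            x = _conv3_relu(x, w, b)
            if i < len(self._layers) - 1:
                x = _maxpool2(x)
        return x.mean(axis=(0, 1)).astype(np.float32)


def _conv3_relu(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    h, wd, c = x.shape
    oh, ow = h - 2, wd - 2
    s0, s1, s2 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, (oh, ow, 3, 3, c), (s0, s1, s0, s1, s2)
    ).reshape(oh * ow, 9 * c)
    out = patches @ w + b
    return np.maximum(out, 0.0).reshape(oh, ow, w.shape[1])


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    return x[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2, c).max(axis=(1, 3))


def get_backbone(spec: BackboneSpec) -> RandomConvBackbone:
    return RandomConvBackbone(spec)


def extract_features(tensor, backbone: RandomConvBackbone) -> np.ndarray:
    """Fixed-length feature vector for one normalized tensor; deterministic."""
    values = tensor.values if isinstance(tensor, NormalizedTensor) else tensor
    return backbone.extract(values)


def split_dataset(
    items: Sequence,
    fractions: Sequence[float] = (0.7, 0.15, 0.15),
    seed: int = 0,
    labels: Sequence[Hashable] | None = None,
) -> tuple[list, ...]:
    """Disjoint, exhaustive, label-stratified split; deterministic under seed.

    Quotas per class follow the largest-remainder rule, and every split
    receives at least one item of every class (possible because a class with
    fewer items than splits is an error).
    """
    if len(items) == 0:
        raise ValueError("cannot split an empty dataset")
    fractions = tuple(fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    n_splits = len(fractions)
    if labels is None:
        labels = [0] * len(items)
    if len(labels) != len(items):
        raise ValueError("labels must match items in length")

    by_class: dict[Hashable, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    rng = np.random.default_rng(seed)
    split_indices: list[list[int]] = [[] for _ in range(n_splits)]
    for lab in sorted(by_class, key=str):
        idx = np.array(by_class[lab])
        if len(idx) < n_splits:
            raise ValueError(
                f"class {lab!r} has {len(idx)} items, fewer than {n_splits} splits"
            )
        idx = idx[rng.permutation(len(idx))]
        m = len(idx)
        quotas = [int(np.floor(f * m)) for f in fractions]
        remainders = [f * m - q for f, q in zip(fractions, quotas)]
        for j in sorted(range(n_splits), key=lambda j: -remainders[j])[
            : m - sum(quotas)
        ]:
            quotas[j] += 1
        while min(quotas) == 0:  # stratification floor
            quotas[int(np.argmax(quotas))] -= 1
            quotas[int(np.argmin(quotas))] += 1
        start = 0
        for j, q in enumerate(quotas):
            split_indices[j].extend(idx[start : start + q].tolist())
            start += q
    return tuple([items[i] for i in sorted(part)] for part in split_indices)


@dataclass(frozen=True)
class HeadConfig:
    """Softmax head over globally averaged features."""

    n_classes: int
    dropout_rate: float = 0.20
    pooling: str = "global_average"

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must lie in [0, 1), got {self.dropout_rate}")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 30
    shuffle_each_epoch: bool = True
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        fr = self.split_fractions
        if any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must be positive and sum to 1: {fr}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


_ENUM_REGISTRY = {"SwallowPattern": SwallowPattern, "IRPClass": IRPClass}


class TrainedClassifier:
    """Frozen backbone + trained softmax head, with training history.

    ``validation_report`` holds the once-computed metrics on the validation
    split; the split itself is not retained.
    """

    def __init__(
        self,
        weight: np.ndarray,
        bias: np.ndarray,
        mu: np.ndarray,
        sd: np.ndarray,
        class_order: tuple,
        head: HeadConfig,
        backbone: RandomConvBackbone | None = None,
        history: dict | None = None,
        validation_report: "evalmetrics.MetricReport | None" = None,
    ):
        self.weight = weight
        self.bias = bias
        self.mu = mu
        self.sd = sd
        self.class_order = tuple(class_order)
        self.head = head
        self.backbone = backbone
        self.history = history or {}
        self.validation_report = validation_report

    # -- inference ---------------------------------------------------------
    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        F = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if F.shape[1] != self.weight.shape[0]:
            raise ValueError(
                f"feature width {F.shape[1]} != trained width {self.weight.shape[0]}"
            )
        z = ((F - self.mu) / self.sd) @ self.weight + self.bias
        return _softmax(z)

    def predict(self, x):
        """Label and class probabilities for one tensor or feature vector."""
        if isinstance(x, NormalizedTensor) or (
            isinstance(x, np.ndarray) and x.ndim == 3
        ):
            if self.backbone is None:
                raise ValueError("classifier has no backbone; pass features instead")
            x = extract_features(x, self.backbone)
        probs = self.predict_proba(x)[0]
        return self.class_order[int(np.argmax(probs))], probs

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(
            path / "head.npz", weight=self.weight, bias=self.bias, mu=self.mu, sd=self.sd
        )
        enum_name = type(self.class_order[0]).__name__
        meta = {
            "classes": [getattr(c, "value", c) for c in self.class_order],
            "class_enum": enum_name if enum_name in _ENUM_REGISTRY else None,
            "head": {"n_classes": self.head.n_classes, "dropout_rate": self.head.dropout_rate},
            "backbone": None
            if self.backbone is None
            else {
                "name": self.backbone.spec.name,
                "weights": self.backbone.spec.weights,
                "seed": self.backbone.spec.seed,
            },
        }
        (path / "classifier.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        path = Path(path)
        meta = json.loads((path / "classifier.json").read_text())
        arrays = np.load(path / "head.npz")
        enum_cls = _ENUM_REGISTRY.get(meta["class_enum"])
        classes = tuple(
            enum_cls(c) if enum_cls is not None else c for c in meta["classes"]
        )
        backbone = None
        if meta["backbone"] is not None:
            backbone = get_backbone(BackboneSpec(**meta["backbone"]))
        return cls(
            weight=arrays["weight"],
            bias=arrays["bias"],
            mu=arrays["mu"],
            sd=arrays["sd"],
            class_order=classes,
            head=HeadConfig(**meta["head"]),
            backbone=backbone,
        )


def train_classifier(
    features: np.ndarray,
    labels: Sequence[Hashable],
    head: HeadConfig,
    train_cfg: TrainConfig,
    *,
    class_order: Sequence[Hashable] | None = None,
    backbone: RandomConvBackbone | None = None,
) -> TrainedClassifier:
    """Train the softmax head on extracted features.

    The stratified 70/15/15 split (by default) is drawn from
    ``train_cfg.seed``; mini-batches of ``batch_size`` with per-epoch
    reshuffling are optimized with Adam under categorical cross-entropy, with
    inverted dropout on the input features.  The checkpoint with the best
    test-split loss is returned, and the validation split is evaluated once
    on it.
    """
    F = np.asarray(features, dtype=np.float64)
    labels = list(labels)
    if F.ndim != 2 or F.shape[0] != len(labels):
        raise ValueError("features must be (n_items, dim) matching labels")
    present = sorted(set(labels), key=str)
    if len(present) < 2:
        raise ValueError("dataset must contain at least two classes")
    order = tuple(class_order) if class_order is not None else tuple(present)
    if not set(labels) <= set(order):
        raise ValueError("labels outside the declared class order")
    if head.n_classes != len(order):
        raise ValueError(
            f"head has {head.n_classes} classes but class order has {len(order)}"
        )

    idx_splits = split_dataset(
        list(range(len(labels))), train_cfg.split_fractions, train_cfg.seed, labels
    )
    tr, te, va = (np.array(s, dtype=int) for s in idx_splits)
    lut = {c: k for k, c in enumerate(order)}
    y = np.array([lut[lab] for lab in labels])

    mu = F[tr].mean(axis=0)
    sd = np.maximum(F[tr].std(axis=0), 1e-6)
    X = (F - mu) / sd
    K, D = len(order), F.shape[1]
    Y = np.eye(K)[y]

    rng = np.random.default_rng(train_cfg.seed)
    W = rng.normal(0.0, 0.01, size=(D, K))
    b = np.zeros(K)
    mW = np.zeros_like(W)
    vW = np.zeros_like(W)
    mb = np.zeros_like(b)
    vb = np.zeros_like(b)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    def eval_split(idx: np.ndarray) -> tuple[float, float]:
        probs = _softmax(X[idx] @ W + b)
        loss = -np.log(np.clip(probs[np.arange(len(idx)), y[idx]], 1e-12, None)).mean()
        acc = float((probs.argmax(axis=1) == y[idx]).mean())
        return float(loss), acc

    history: dict[str, list[float]] = {
        "train_loss": [],
        "train_acc": [],
        "test_loss": [],
        "test_acc": [],
    }
    best = (np.inf, W.copy(), b.copy())
    p_drop = head.dropout_rate
    for _ in range(train_cfg.epochs):
        perm = rng.permutation(len(tr)) if train_cfg.shuffle_each_epoch else np.arange(len(tr))
        for start in range(0, len(tr), train_cfg.batch_size):
            batch = tr[perm[start : start + train_cfg.batch_size]]
            Xb = X[batch]
            if p_drop > 0:
                mask = rng.random(Xb.shape) >= p_drop
                Xb = Xb * mask / (1.0 - p_drop)
            probs = _softmax(Xb @ W + b)
            delta = (probs - Y[batch]) / len(batch)
            gW = Xb.T @ delta
            gb = delta.sum(axis=0)
            step += 1
            mW = beta1 * mW + (1 - beta1) * gW
            vW = beta2 * vW + (1 - beta2) * gW**2
            mb = beta1 * mb + (1 - beta1) * gb
            vb = beta2 * vb + (1 - beta2) * gb**2
            corr1 = 1 - beta1**step
            corr2 = 1 - beta2**step
            W -= train_cfg.learning_rate * (mW / corr1) / (np.sqrt(vW / corr2) + eps)
            b -= train_cfg.learning_rate * (mb / corr1) / (np.sqrt(vb / corr2) + eps)
        tr_loss, tr_acc = eval_split(tr)
        te_loss, te_acc = eval_split(te)
        if not (np.isfinite(tr_loss) and np.isfinite(te_loss)):
            raise RuntimeError(
                f"non-finite loss at epoch {len(history['train_loss'])}: "
                f"train={tr_loss}, test={te_loss}; lower the learning rate"
            )
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["test_loss"].append(te_loss)
        history["test_acc"].append(te_acc)
        if te_loss < best[0]:
            best = (te_loss, W.copy(), b.copy())

    _, W, b = best
    clf = TrainedClassifier(
        weight=W,
        bias=b,
        mu=mu,
        sd=sd,
        class_order=order,
        head=head,
        backbone=backbone,
        history=history,
    )
    va_pred = [order[k] for k in clf.predict_proba(F[va]).argmax(axis=1)]
    va_true = [labels[i] for i in va]
    cm = evalmetrics.confusion_matrix(va_true, va_pred, order)
    clf.validation_report = evalmetrics.classification_report(cm)
    return clf


def predict(classifier: TrainedClassifier, tensor):
    """Label and probabilities for one input; ties break by class order."""
    return classifier.predict(tensor)
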