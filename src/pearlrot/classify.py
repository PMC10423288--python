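"""Shape classification: frozen convolutional features + metadata-fused head.

Transfer-learning setup: a *frozen* convolutional backbone maps each
224 x 224 x 3 rotation image to a fixed feature vector; two per-sample
metadata scalars (days of cultivation, days from graft to acquisition) are
z-scored on the training split and appended; a small trainable head
(dense -> dropout -> dense softmax) maps the fused vector to the three
shape classes.  Only the head and the normalisation statistics are fitted.

Two backbones are registered.  ``tiny-cnn`` is a small frozen conv stack
with fixed-seed random filters: random convolutional features are a
well-established cheap image embedding, and the backbone needs no
pretrained-weight download, so the whole pipeline runs self-contained.
``vgg16-frozen`` uses the ImageNet-pretrained VGG-16 convolutional base
(flattened final max-pool, 7*7*512 = 25088 features) and requires
torch/torchvision at runtime.

The trainable head is implemented directly in NumPy (softmax cross-entropy,
inverted dropout, Adam), which keeps training deterministic under a fixed
seed and dependency-light.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging import PearlSample
from .simulate import CLASSES

__all__ = [
    "BackboneSpec",
    "HeadSpec",
    "MetadataNormalizer",
    "TrainedModel",
    "TINY_CNN",
    "VGG16_FROZEN",
    "backbone_by_name",
    "extract_features",
    "fuse_metadata",
    "train_classifier",
    "predict_sample",
    "predict_proba",
    "predict_pearl",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class BackboneSpec:
    """A frozen image-feature extractor."""

    name: str
    output_dim: int
    deterministic: bool = True
    seed: int = 7  # filter seed for the random-feature backbone

    def __post_init__(self) -> None:
        if self.output_dim <= 0:
            raise ValueError("output_dim must be positive")


TINY_CNN = BackboneSpec(name="tiny-cnn", output_dim=256)
VGG16_FROZEN = BackboneSpec(name="vgg16-frozen", output_dim=7 * 7 * 512)


def backbone_by_name(name: str) -> BackboneSpec:
    for spec in (TINY_CNN, VGG16_FROZEN):
        if spec.name == name:
            return spec
    raise ValueError(f"unknown backbone {name!r}")


@dataclass(frozen=True)
class HeadSpec:
    """Trainable classification head architecture."""

    dense_widths: tuple[int, ...] = (256,)
    dropout_rates: tuple[float, ...] = (0.5,)
    n_classes: int = 3
    metadata_dim: int = 2

    def __post_init__(self) -> None:
        if len(self.dense_widths) != len(self.dropout_rates):
            raise ValueError("one dropout rate per dense layer")
        if any(not (0.0 <= r < 1.0) for r in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")


DEFAULT_HYPERPARAMS: dict = {
    "lr": 1e-3,
    "epochs": 30,
    "batch": 16,
    "seed": 0,
    "patience": 10,
    "use_metadata": True,
}


@dataclass
class MetadataNormalizer:
    """Per-feature mean/sd fitted on the training split only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray) -> "MetadataNormalizer":
        v = np.asarray(values, dtype=float)
        mean = v.mean(axis=0)
        sd = v.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean=mean, sd=sd)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd


# ---------------------------------------------------------------------------
# frozen backbones

_tiny_weights_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _tiny_weights(seed: int) -> tuple[np.ndarray, np.ndarray]:
    if seed not in _tiny_weights_cache:
        rng = np.random.default_rng(seed)
        w1 = rng.normal(0.0, math.sqrt(2.0 / (3 * 9)), size=(8, 3, 3, 3))
        w2 = rng.normal(0.0, math.sqrt(2.0 / (8 * 9)), size=(16, 8, 3, 3))
        _tiny_weights_cache[seed] = (w1, w2)
    return _tiny_weights_cache[seed]


def _conv_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid 2-D multichannel convolution. x: (H, W, C); w: (F, C, k, k)."""
    k = w.shape[-1]
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(0, 1))
    # win: (H-k+1, W-k+1, C, k, k)
    return np.tensordot(win, w, axes=([2, 3, 4], [1, 2, 3]))


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, wdt = x.shape[0] // 2 * 2, x.shape[1] // 2 * 2
    x = x[:h, :wdt]
    return x.reshape(h // 2, 2, wdt // 2, 2, -1).max(axis=(1, 3))


def _adaptive_avgpool(x: np.ndarray, out: int = 4) -> np.ndarray:
    rows = np.array_split(np.arange(x.shape[0]), out)
    cols = np.array_split(np.arange(x.shape[1]), out)
    pooled = np.empty((out, out, x.shape[2]))
    for i, ri in enumerate(rows):
        for j, cj in enumerate(cols):
            pooled[i, j] = x[np.ix_(ri, cj)].mean(axis=(0, 1))
    return pooled


def _tiny_cnn_features(image: np.ndarray, seed: int) -> np.ndarray:
    if image.shape[:2] != (224, 224) or image.shape[2] != 3:
        raise ValueError("tiny-cnn expects a 224 x 224 x 3 image")
    x = image.astype(float) / 255.0
    x = x.reshape(56, 4, 56, 4, 3).mean(axis=(1, 3))  # 4x4 block mean -> 56x56x3
    w1, w2 = _tiny_weights(seed)
    x = np.maximum(_conv_valid(x, w1), 0.0)  # 54x54x8
    x = _maxpool2(x)  # 27x27x8
    x = np.maximum(_conv_valid(x, w2), 0.0)  # 25x25x16
    x = _adaptive_avgpool(x, 4)  # 4x4x16
    return x.reshape(-1)


def _vgg16_features(image: np.ndarray) -> np.ndarray:
    try:
        import torch  # type: ignore
        from torchvision.models import vgg16  # type: ignore
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise RuntimeError(
            "the vgg16-frozen backbone requires torch and torchvision; "
            "use the self-contained 'tiny-cnn' backbone instead"
        ) from exc
    model = vgg16(weights="IMAGENET1K_V1").features.eval()  # pragma: no cover
    x = torch.from_numpy(image.astype(np.float32) / 255.0).permute(2, 0, 1)[None]  # pragma: no cover
    mean = torch.tensor([0.485, 0.456, 0.406]).view(1, 3, 1, 1)  # pragma: no cover
    std = torch.tensor([0.229, 0.224, 0.225]).view(1, 3, 1, 1)  # pragma: no cover
    with torch.no_grad():  # pragma: no cover
        out = model((x - mean) / std)  # pragma: no cover
    return out.numpy().reshape(-1)  # pragma: no cover


def extract_features(image: np.ndarray, backbone: BackboneSpec = TINY_CNN) -> np.ndarray:
    """Deterministic feature vector of ``backbone.output_dim`` for one image."""
    if backbone.name == "tiny-cnn":
        feats = _tiny_cnn_features(image, backbone.seed)
    elif backbone.name == "vgg16-frozen":
        feats = _vgg16_features(image)
    else:
        raise ValueError(f"unknown backbone {backbone.name!r}")
    if feats.size != backbone.output_dim:
        raise RuntimeError("backbone returned an unexpected feature dimension")
    return feats


def fuse_metadata(
    features: np.ndarray,
    culture_days: float,
    acq_offset_days: float,
    normalizer: MetadataNormalizer,
) -> np.ndarray:
    """Append the two z-scored metadata scalars to the image features."""
    if normalizer is None:
        raise ValueError("metadata normalizer is not fitted")
    z = normalizer.transform(np.array([[culture_days, acq_offset_days]]))[0]
    return np.concatenate([np.asarray(features, dtype=float), z])


# ---------------------------------------------------------------------------
# trainable head (NumPy MLP: dense/ReLU/dropout stack + softmax output)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class TrainedModel:
    """Frozen backbone + fitted head + input-normalisation statistics."""

    backbone: BackboneSpec
    head: HeadSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_scaler: MetadataNormalizer
    metadata_normalizer: MetadataNormalizer | None
    history: pd.DataFrame
    use_metadata: bool = True
    classes: tuple[str, ...] = CLASSES

    def _design(self, features: np.ndarray, meta: np.ndarray) -> np.ndarray:
        x = self.feature_scaler.transform(features)
        if self.use_metadata:
            if self.metadata_normalizer is None:
                raise ValueError("metadata normalizer missing")
            x = np.hstack([x, self.metadata_normalizer.transform(meta)])
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        return _softmax(h @ self.weights[-1] + self.biases[-1])


def _sample_arrays(
    samples: Sequence[PearlSample],
    backbone: BackboneSpec,
    feature_cache: dict[int, np.ndarray] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    feats = []
    for s in samples:
        key = id(s)
        if feature_cache is not None and key in feature_cache:
            feats.append(feature_cache[key])
        else:
            f = extract_features(s.image, backbone)
            if feature_cache is not None:
                feature_cache[key] = f
            feats.append(f)
    meta = np.array([[s.culture_days, s.acq_offset_days] for s in samples], dtype=float)
    y = np.array([CLASSES.index(s.label) for s in samples])
    return np.vstack(feats), meta, y


def train_classifier(
    train_samples: Sequence[PearlSample],
    val_samples: Sequence[PearlSample],
    head: HeadSpec = HeadSpec(),
    hyperparams: dict | None = None,
    backbone: BackboneSpec = TINY_CNN,
    feature_cache: dict[int, np.ndarray] | None = None,
) -> TrainedModel:
    """Fit the head on the training split (backbone stays frozen).

    The input features and the two metadata scalars are z-scored with
    statistics from the training split only.  Training uses minibatch Adam
    on softmax cross-entropy with inverted dropout; the per-epoch train and
    validation accuracies are recorded, and the weights of the best
    validation epoch are restored (early stopping with patience).
    Deterministic under a fixed ``seed``.
    """
    hp = {**DEFAULT_HYPERPARAMS, **(hyperparams or {})}
    if not train_samples:
        raise ValueError("empty training split")
    train_pearls = {s.pearl_id for s in train_samples}
    if val_samples and train_pearls & {s.pearl_id for s in val_samples}:
        raise ValueError("train and validation splits share pearls")
    Ftr, Mtr, ytr = _sample_arrays(train_samples, backbone, feature_cache)
    present = set(ytr.tolist())
    if len(present) < len(CLASSES):
        missing = [c for i, c in enumerate(CLASSES) if i not in present]
        warnings.warn(f"classes missing from training split: {missing}", stacklevel=2)

    feature_scaler = MetadataNormalizer.fit(Ftr)
    meta_norm = MetadataNormalizer.fit(Mtr) if hp["use_metadata"] else None

    model = TrainedModel(
        backbone=backbone,
        head=head,
        weights=[],
        biases=[],
        feature_scaler=feature_scaler,
        metadata_normalizer=meta_norm,
        history=pd.DataFrame(),
        use_metadata=bool(hp["use_metadata"]),
    )
    Xtr = model._design(Ftr, Mtr)
    if val_samples:
        Fva, Mva, yva = _sample_arrays(val_samples, backbone, feature_cache)
        Xva = model._design(Fva, Mva)
    else:
        Xva, yva = None, None

    rng = np.random.default_rng(hp["seed"])
    dims = [Xtr.shape[1], *head.dense_widths, head.n_classes]
    weights = [rng.normal(0.0, math.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1])) for i in range(len(dims) - 1)]
    biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
    params = weights + biases
    opt = _Adam(params, hp["lr"])

    n = Xtr.shape[0]
    batch = max(1, min(hp["batch"], n))
    history = []
    best = (-1.0, None, -1)  # (val_acc, params snapshot, epoch)
    model.weights, model.biases = weights, biases
    for epoch in range(1, hp["epochs"] + 1):
        perm = rng.permutation(n)
        for start in range(0, n, batch):
            idx = perm[start : start + batch]
            x, y = Xtr[idx], ytr[idx]
            # forward with dropout
            acts = [x]
            masks = []
            h = x
            for li, (w, b) in enumerate(zip(weights[:-1], biases[:-1])):
                h = np.maximum(h @ w + b, 0.0)
                rate = head.dropout_rates[li]
                if rate > 0:
                    mask = (rng.random(h.shape) >= rate) / (1.0 - rate)
                    h = h * mask
                else:
                    mask = None
                masks.append(mask)
                acts.append(h)
            probs = _softmax(h @ weights[-1] + biases[-1])
            # backward
            delta = probs.copy()
            delta[np.arange(len(y)), y] -= 1.0
            delta /= len(y)
            grads_w = [np.zeros_like(w) for w in weights]
            grads_b = [np.zeros_like(b) for b in biases]
            for li in range(len(weights) - 1, -1, -1):
                grads_w[li] = acts[li].T @ delta
                grads_b[li] = delta.sum(axis=0)
                if li > 0:
                    delta = delta @ weights[li].T
                    if masks[li - 1] is not None:
                        delta = delta * masks[li - 1]
                    delta = delta * (acts[li] > 0)
            opt.step(params, grads_w + grads_b)
        train_acc = float(np.mean(model.forward(Xtr).argmax(axis=1) == ytr))
        if Xva is not None and len(yva):
            val_acc = float(np.mean(model.forward(Xva).argmax(axis=1) == yva))
        else:
            val_acc = train_acc
        history.append({"epoch": epoch, "train_acc": train_acc, "val_acc": val_acc})
        if val_acc > best[0]:
            best = (val_acc, ([w.copy() for w in weights], [b.copy() for b in biases]), epoch)
        elif hp["patience"] is not None and epoch - best[2] >= hp["patience"]:
            break
    if best[1] is not None:
        model.weights, model.biases = best[1]
    model.history = pd.DataFrame(history)
    return model


def predict_proba(
    model: TrainedModel,
    samples: Sequence[PearlSample],
    feature_cache: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """(n, 3) class-probability matrix in the fixed class order."""
    F, M, _ = _sample_arrays(samples, model.backbone, feature_cache)
    return model.forward(model._design(F, M))


def predict_sample(
    model: TrainedModel,
    sample: PearlSample,
    feature_cache: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Class probabilities (3-vector, sums to 1) for one sample."""
    return predict_proba(model, [sample], feature_cache)[0]


def majority_vote(probs: np.ndarray) -> str:
    """Modal argmax class over sample probability rows.

    Ties are broken by the highest mean predicted probability among the
    tied classes.
    """
    probs = np.atleast_2d(probs)
    votes = probs.argmax(axis=1)
    counts = np.bincount(votes, minlength=len(CLASSES))
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if tied.size == 1:
        return CLASSES[tied[0]]
    mean_p = probs.mean(axis=0)
    return CLASSES[tied[np.argmax(mean_p[tied])]]


def predict_pearl(
    model: TrainedModel,
    samples: Sequence[PearlSample],
    feature_cache: dict[int, np.ndarray] | None = None,
) -> str:
    """Per-pearl prediction: majority vote over the pearl's samples.

    Ties are broken by the highest mean predicted probability among the tied
    classes.  All samples must belong to the same pearl.
    """
    if not samples:
        raise ValueError("need at least one sample")
    ids = {s.pearl_id for s in samples}
    if len(ids) != 1:
        raise ValueError(f"samples from multiple pearls: {sorted(ids)}")
    return majority_vote(predict_proba(model, samples, feature_cache))


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: TrainedModel, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    arrays = {f"w{i}": w for i, w in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    arrays["feat_mean"] = model.feature_scaler.mean
    arrays["feat_sd"] = model.feature_scaler.sd
    np.savez(d / "head.npz", **arrays)
    meta = {
        "backbone": {"name": model.backbone.name, "output_dim": model.backbone.output_dim, "seed": model.backbone.seed},
        "head": {
            "dense_widths": list(model.head.dense_widths),
            "dropout_rates": list(model.head.dropout_rates),
            "n_classes": model.head.n_classes,
            "metadata_dim": model.head.metadata_dim,
        },
        "use_metadata": model.use_metadata,
        "classes": list(model.classes),
        "metadata_normalizer": None
        if model.metadata_normalizer is None
        else {"mean": model.metadata_normalizer.mean.tolist(), "sd": model.metadata_normalizer.sd.tolist()},
    }
    (d / "model.json").write_text(json.dumps(meta, indent=2))
    model.history.to_csv(d / "history.csv", index=False)


def load_model(directory: str | Path) -> TrainedModel:
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    data = np.load(d / "head.npz")
    n_layers = len(meta["head"]["dense_widths"]) + 1
    weights = [data[f"w{i}"] for i in range(n_layers)]
    biases = [data[f"b{i}"] for i in range(n_layers)]
    bb = meta["backbone"]
    mn = meta["metadata_normalizer"]
    return TrainedModel(
        backbone=BackboneSpec(name=bb["name"], output_dim=bb["output_dim"], seed=bb["seed"]),
        head=HeadSpec(
            dense_widths=tuple(meta["head"]["dense_widths"]),
            dropout_rates=tuple(meta["head"]["dropout_rates"]),
            n_classes=meta["head"]["n_classes"],
            metadata_dim=meta["head"]["metadata_dim"],
        ),
        weights=weights,
        biases=biases,
        feature_scaler=MetadataNormalizer(mean=data["feat_mean"], sd=data["feat_sd"]),
        metadata_normalizer=None if mn is None else MetadataNormalizer(mean=np.asarray(mn["mean"]), sd=np.asarray(mn["sd"])),
        history=pd.read_csv(d / "history.csv"),
        use_metadata=meta["use_metadata"],
        classes=tuple(meta["classes"]),
    )
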