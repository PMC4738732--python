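"""Feature Property: a linear SVM from 27-D pixel features to salience.

Training samples are drawn per image from the extremes of the expert ground
truth: positives from the top 20% most-fixated pixels, negatives from the
bottom 50%, never from the strip between the two strata, never within 10 px
of the image border, 100 samples per image at a 1:1 class ratio.  Features
are standardised to zero mean / unit variance with parameters estimated on
the training set only, and a liblinear-style L2-regularised hinge-loss SVM
(cost c = 1) is fit.  At test time the raw decision value W.f + b is used as
the per-pixel Feature Property map, not the sign.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .features import N_CHANNELS, FeatureStack
from .gaze import DensityMap

__all__ = [
    "SampleSet",
    "Normalizer",
    "LinearSaliencyModel",
    "select_samples",
    "pool_samples",
    "fit_normalizer",
    "train_fp",
    "predict_fp",
    "save_model",
    "load_model",
]


@dataclass
class SampleSet:
    """Labelled pixel samples: features (n, 27), labels in {+1, -1}."""

    features: np.ndarray
    labels: np.ndarray
    provenance: list  # (image_id, x, y) per sample

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2 or self.features.shape[1] != N_CHANNELS:
            raise ValueError(f"features must be (n, {N_CHANNELS})")
        if set(np.unique(self.labels)) - {-1, 1}:
            raise ValueError("labels must be +1/-1")
        if len(self.labels) != len(self.features) or len(self.provenance) != len(self.features):
            raise ValueError("features, labels and provenance must align")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class Normalizer:
    """Per-channel zero-mean / unit-std transform fitted on training data."""

    mean: np.ndarray
    std: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.std + self.mean


@dataclass
class LinearSaliencyModel:
    """Weights, bias and cost of the linear Feature Property SVM."""

    W: np.ndarray
    b: float
    c: float
    normalizer: Normalizer
    channel_names: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float).reshape(-1)
        if self.W.shape != (N_CHANNELS,):
            raise ValueError(f"W must have {N_CHANNELS} components")
        if not np.isfinite(self.W).all() or not np.isfinite(self.b):
            raise ValueError("model parameters must be finite")
        if self.c <= 0:
            raise ValueError("cost must be positive")


def select_samples(stack: FeatureStack, gt: DensityMap,
                   top_pct: float = 20.0, bottom_pct: float = 50.0,
                   margin: int = 10, n_samples: int = 100,
                   neg_pos_ratio: float = 1.0, seed: int = 0,
                   image_id: str = "") -> SampleSet:
    """Draw labelled pixel samples from the extremes of one ground truth.

    Positives come from pixels whose ground-truth value is at or above the
    (100 - top_pct) percentile, negatives from pixels at or below the
    bottom_pct percentile; the strip between the strata is never sampled,
    and no sample lies within ``margin`` px of the image border.  Sampling is
    uniform without replacement, seeded.
    """
    if not (0 < top_pct and 0 < bottom_pct):
        raise ValueError("percent strata must be positive")
    if gt.shape != stack.shape:
        raise ValueError("ground truth and feature stack shapes differ")
    h, w = gt.shape
    v = gt.values
    hi = np.percentile(v, 100.0 - top_pct)
    lo = np.percentile(v, bottom_pct)
    if hi <= lo:
        raise ValueError("configuration error: top and bottom strata overlap")

    valid = np.zeros((h, w), dtype=bool)
    valid[margin:h - margin, margin:w - margin] = True
    pos_idx = np.argwhere((v >= hi) & valid)
    neg_idx = np.argwhere((v <= lo) & valid)

    n_pos = int(round(n_samples / (1.0 + neg_pos_ratio)))
    n_neg = n_samples - n_pos
    rng = np.random.default_rng(seed)
    if len(pos_idx) < n_pos or len(neg_idx) < n_neg:
        warnings.warn(f"{image_id or 'image'}: stratum too small, reducing "
                      f"sample counts", stacklevel=2)
        n_pos = min(n_pos, len(pos_idx))
        n_neg = min(n_neg, len(neg_idx))

    feats, labels, prov = [], [], []
    mat = stack.channels
    for idx, n_take, lab in ((pos_idx, n_pos, 1), (neg_idx, n_neg, -1)):
        take = idx[rng.choice(len(idx), size=n_take, replace=False)]
        for (y, x) in take:
            feats.append(mat[:, y, x])
            labels.append(lab)
            prov.append((image_id, int(x), int(y)))
    return SampleSet(features=np.array(feats).reshape(-1, N_CHANNELS),
                     labels=np.array(labels, dtype=int), provenance=prov)


def pool_samples(sets: Sequence[SampleSet]) -> SampleSet:
    """Concatenate per-image sample sets into one training set."""
    if not sets:
        raise ValueError("nothing to pool")
    return SampleSet(
        features=np.concatenate([s.features for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        provenance=[p for s in sets for p in s.provenance])


def fit_normalizer(samples: SampleSet) -> Normalizer:
    """Per-channel mean/std (population std); constant channels get std 1."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    mean = samples.features.mean(axis=0)
    std = samples.features.std(axis=0)
    # Rounding can leave a numerically tiny std on a constant channel.
    degenerate = std <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if np.any(degenerate):
        warnings.warn("constant feature channel(s); std forced to 1",
                      stacklevel=2)
        std = np.where(degenerate, 1.0, std)
    return Normalizer(mean=mean, std=std)


def train_fp(samples: SampleSet, c: float = 1.0, seed: int = 0,
             tol: float = 1e-4, max_iter: int = 50_000) -> LinearSaliencyModel:
    """Fit the linear SVM on standardised samples.

    L2-regularised hinge loss at misclassification cost ``c`` (default 1),
    solved in the dual as liblinear does; solver randomness is pinned by
    ``seed`` and tolerance ``tol`` for reproducibility.  Large costs need a
    tighter ``tol`` (and more iterations) to reach a stable optimum.
    """
    classes = set(np.unique(samples.labels))
    if classes != {-1, 1}:
        raise ValueError("training requires both classes present")
    normalizer = fit_normalizer(samples)
    Z = normalizer.transform(samples.features)
    svm = LinearSVC(C=c, loss="hinge", tol=tol, random_state=seed,
                    max_iter=max_iter)
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        svm.fit(Z, samples.labels)
    return LinearSaliencyModel(W=svm.coef_[0], b=float(svm.intercept_[0]),
                               c=c, normalizer=normalizer, seed=seed)


def predict_fp(model: LinearSaliencyModel, stack: FeatureStack) -> DensityMap:
    """Per-pixel decision value W.f + b on standardised features.

    The raw margin (possibly negative) is kept rather than the predicted
    label: the map's ordering carries the salience information, and the
    downstream combination step decides how to rescale it.
    """
    mat = stack.as_matrix()
    vals = model.normalizer.transform(mat) @ model.W + model.b
    return DensityMap(values=vals.reshape(stack.shape), kind="saliency")


def save_model(model: LinearSaliencyModel, path) -> None:
    payload = {
        "W": model.W.tolist(), "b": model.b, "c": model.c,
        "mean": model.normalizer.mean.tolist(),
        "std": model.normalizer.std.tolist(),
        "channel_names": list(model.channel_names), "seed": model.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> LinearSaliencyModel:
    d = json.loads(Path(path).read_text())
    return LinearSaliencyModel(
        W=np.array(d["W"]), b=float(d["b"]), c=float(d["c"]),
        normalizer=Normalizer(mean=np.array(d["mean"]), std=np.array(d["std"])),
        channel_names=tuple(d.get("channel_names", ())),
        seed=int(d.get("seed", 0)))
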