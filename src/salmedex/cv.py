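"""10-fold cross-validation over an image set, with ablation controls.

Each fold trains the Feature Property SVM and the Position Property prior on
the training images only, predicts saliency for each held-out image, scores
it, and averages per-image metrics.  The paper-style "10 times 10-fold"
protocol is realised as independent seeded repetitions of the whole split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureStack, extract_features
from .fixtures import RetinalImage
from .fp_model import pool_samples, predict_fp, select_samples, train_fp
from .gaze import DensityMap
from .metrics import evaluate_map
from .pp_prior import position_prior
from .saliency import CombineConfig, combine

__all__ = [
    "FoldSplit",
    "CrossValConfig",
    "AggregateTable",
    "make_folds",
    "evaluate_dataset",
    "evaluate_ablation",
    "aggregate_models",
]

METRIC_NAMES = ("auc", "emd", "ss", "sensitivity", "specificity", "youden")


@dataclass(frozen=True)
class FoldSplit:
    """Partition of image ids into k near-equal folds."""

    k: int
    assignments: dict  # image_id -> fold index
    seed: int

    def fold_ids(self, fold: int) -> list:
        return [i for i, f in self.assignments.items() if f == fold]


@dataclass(frozen=True)
class CrossValConfig:
    """Everything a CV run needs beyond the data and the seed."""

    k: int = 10
    samples_per_image: int = 100
    top_pct: float = 20.0
    bottom_pct: float = 50.0
    margin: int = 10
    neg_pos_ratio: float = 1.0
    svm_cost: float = 1.0
    combine: CombineConfig = field(default_factory=CombineConfig)
    gt_top_fraction: float = 20.0
    region_fraction: float = 50.0
    emd_grid_size: int = 16
    compute_emd: bool = True


@dataclass
class AggregateTable:
    """Per-image metric rows plus their per-metric means."""

    per_image: pd.DataFrame
    means: dict

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "AggregateTable":
        df = pd.DataFrame(rows)
        means = {m: float(df[m].mean()) for m in METRIC_NAMES if m in df}
        return cls(per_image=df, means=means)


def make_folds(image_ids: Sequence[str], k: int = 10, seed: int = 0) -> FoldSplit:
    """Seeded random partition into k folds with sizes differing by <= 1."""
    ids = list(image_ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} images for {k} folds")
    if len(set(ids)) != len(ids):
        raise ValueError("image ids must be unique")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignments = {ids[j]: int(i % k) for i, j in enumerate(perm)}
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def _train_fold(stacks: Mapping[str, FeatureStack],
                gts: Mapping[str, DensityMap],
                train_ids: Sequence[str], seed: int,
                config: CrossValConfig):
    """Fit SVM + prior on the training fold only."""
    sets = []
    for j, iid in enumerate(train_ids):
        sets.append(select_samples(
            stacks[iid], gts[iid], top_pct=config.top_pct,
            bottom_pct=config.bottom_pct, margin=config.margin,
            n_samples=config.samples_per_image,
            neg_pos_ratio=config.neg_pos_ratio,
            seed=seed * 100_003 + j, image_id=iid))
    model = train_fp(pool_samples(sets), c=config.svm_cost, seed=seed)
    prior = position_prior([gts[iid] for iid in train_ids])
    return model, prior


def evaluate_dataset(images: Sequence[RetinalImage],
                     gts: Sequence[DensityMap],
                     k: int = 10, seed: int = 0,
                     config: CrossValConfig = CrossValConfig(),
                     stacks: Mapping[str, FeatureStack] | None = None) -> AggregateTable:
    """Full k-fold cross-validated evaluation of the pipeline.

    ``stacks`` may carry precomputed feature stacks keyed by image id to
    avoid re-extracting features across repetitions.
    """
    if len(images) != len(gts):
        raise ValueError("images and ground truths must align")
    ids = [img.image_id for img in images]
    img_by_id = dict(zip(ids, images))
    gt_by_id = dict(zip(ids, gts))
    if stacks is None:
        stacks = {iid: extract_features(img_by_id[iid]) for iid in ids}

    split = make_folds(ids, k=k, seed=seed)
    rows = []
    for fold in range(k):
        test_ids = split.fold_ids(fold)
        train_ids = [i for i in ids if split.assignments[i] != fold]
        model, prior = _train_fold(stacks, gt_by_id, train_ids,
                                   seed=seed * 1009 + fold, config=config)
        for iid in test_ids:
            try:
                fp = predict_fp(model, stacks[iid])
                ms = combine(fp, prior, config.combine)
                rep = evaluate_map(ms, gt_by_id[iid],
                                   gt_top_fraction=config.gt_top_fraction,
                                   region_fraction=config.region_fraction,
                                   emd_grid_size=config.emd_grid_size,
                                   compute_emd=config.compute_emd)
            except ValueError as exc:
                warnings.warn(f"skipping degenerate image {iid}: {exc}",
                              stacklevel=2)
                continue
            rows.append({"image_id": iid, "fold": fold, **rep.as_dict()})
    return AggregateTable.from_rows(rows)


def evaluate_ablation(images: Sequence[RetinalImage],
                      gts: Sequence[DensityMap],
                      k: int = 5, seed: int = 0,
                      config: CrossValConfig = CrossValConfig(),
                      stacks: Mapping[str, FeatureStack] | None = None) -> dict:
    """Mean AUC of the full model vs a prior-only and a random control.

    ``prior_only`` replaces the SVM decision map with a constant (so the
    combined map is just the smoothed prior); ``random`` scores a seeded
    uniform-noise map.  One training pass per fold serves all three
    variants.
    """
    ids = [img.image_id for img in images]
    img_by_id = dict(zip(ids, images))
    gt_by_id = dict(zip(ids, gts))
    if stacks is None:
        stacks = {iid: extract_features(img_by_id[iid]) for iid in ids}

    split = make_folds(ids, k=k, seed=seed)
    rng = np.random.default_rng(seed + 2**20)
    aucs = {"full": [], "prior_only": [], "random": []}
    for fold in range(k):
        test_ids = split.fold_ids(fold)
        train_ids = [i for i in ids if split.assignments[i] != fold]
        model, prior = _train_fold(stacks, gt_by_id, train_ids,
                                   seed=seed * 1009 + fold, config=config)
        for iid in test_ids:
            gt = gt_by_id[iid]
            shape = gt.shape
            fp = predict_fp(model, stacks[iid])
            ms_full = combine(fp, prior, config.combine)
            ones = DensityMap(values=np.ones(shape), kind="saliency")
            ms_prior = combine(ones, prior, CombineConfig(
                sigma=config.combine.sigma, fp_rescale="none"))
            ms_rand = DensityMap(values=rng.random(shape), kind="saliency")
            for name, ms in (("full", ms_full), ("prior_only", ms_prior),
                             ("random", ms_rand)):
                rep = evaluate_map(ms, gt,
                                   gt_top_fraction=config.gt_top_fraction,
                                   region_fraction=config.region_fraction,
                                   compute_emd=False)
                aucs[name].append(rep.auc)
    return {name: float(np.mean(v)) for name, v in aucs.items()}


def aggregate_models(per_model_scores: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Tabulate per-model metric scores and append a cross-model Average.

    ``per_model_scores`` maps model name -> {metric: value}; the returned
    frame has metrics as rows, models as columns, and an ``Average`` column
    holding the arithmetic mean across models.
    """
    if not per_model_scores:
        raise ValueError("no model scores given")
    df = pd.DataFrame(per_model_scores)
    df["Average"] = df.mean(axis=1)
    return df
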