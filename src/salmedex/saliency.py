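"""Combining Feature Property and Position Property into the saliency map.

The two evidence maps are combined by an intersection (Hadamard product)
followed by Gaussian smoothing:

    M_s = (M_f o M_p) * GF(delta),      delta = 10 px by default.

The SVM decision map M_f is real-valued; by default it is min–max rescaled
to [0, 1] before the product so M_s stays a nonnegative salience surface
(raw mode is kept for ablation).  The Gaussian is truncated at +/-4 delta
with reflective boundary padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .features import extract_features
from .fixtures import RetinalImage
from .fp_model import LinearSaliencyModel, predict_fp
from .gaze import DensityMap
from .pp_prior import PositionPrior

__all__ = ["CombineConfig", "combine", "run_pipeline"]


@dataclass(frozen=True)
class CombineConfig:
    """Smoothing width (px) and Feature-Property rescale mode."""

    sigma: float = 10.0
    fp_rescale: str = "minmax"  # or "none"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.fp_rescale not in ("minmax", "none"):
            raise ValueError("fp_rescale must be 'minmax' or 'none'")


def combine(fp_map: DensityMap, prior: PositionPrior,
            config: CombineConfig = CombineConfig()) -> DensityMap:
    """M_s = (M_f o M_p) convolved with a Gaussian of width ``sigma``."""
    if fp_map.shape != prior.shape:
        raise ValueError("feature map and prior shapes differ")
    mf = fp_map.values
    if config.fp_rescale == "minmax":
        lo, hi = mf.min(), mf.max()
        mf = (mf - lo) / (hi - lo) if hi > lo else np.zeros_like(mf)
    prod = mf * prior.values
    out = gaussian_filter(prod, config.sigma, truncate=4.0, mode="reflect")
    return DensityMap(values=out, kind="saliency")


def run_pipeline(model: LinearSaliencyModel, prior: PositionPrior,
                 image: RetinalImage,
                 config: CombineConfig = CombineConfig()) -> DensityMap:
    """Image -> 27-channel features -> SVM decision map -> combined map."""
    stack = extract_features(image)
    fp = predict_fp(model, stack)
    return combine(fp, prior, config)
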