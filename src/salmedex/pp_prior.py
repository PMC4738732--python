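"""Position Property: a statistical location prior from training ground truth.

Expert fixations on fundus images concentrate near the fovea — clinically,
the decisive exudates sit within a small zone around the foveal centre — so
where a pixel *is* carries salience information independent of what it looks
like.  The prior is the pixelwise sum of the training images' ground-truth
density maps, min–max rescaled to [0, 1]:

    M_p = (sum_i M_i - min) / (max - min)

Within cross-validation the sum runs over the training fold only, so no test
ground truth ever reaches the prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gaze import DensityMap

__all__ = ["PositionPrior", "position_prior"]


@dataclass
class PositionPrior:
    """Min–max normalised sum of ground-truth maps; values in [0, 1]."""

    values: np.ndarray
    n_images: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("prior must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("prior must be finite")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("prior must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def position_prior(gt_maps: Sequence[DensityMap]) -> PositionPrior:
    """Sum the ground-truth maps and rescale the result to [0, 1]."""
    if not gt_maps:
        raise ValueError("need at least one ground-truth map")
    shape = gt_maps[0].shape
    total = np.zeros(shape)
    for m in gt_maps:
        if m.shape != shape:
            raise ValueError("all ground-truth maps must share one shape")
        total = total + m.values
    lo, hi = total.min(), total.max()
    if hi == lo:
        raise ValueError("degenerate prior: summed map is constant")
    return PositionPrior(values=(total - lo) / (hi - lo), n_images=len(gt_maps))
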