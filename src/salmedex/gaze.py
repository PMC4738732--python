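"""From raw fixation logs to continuous ground-truth density maps.

An observer's fixations are turned into a "landscape map" by dropping the
first second of free viewing and convolving a unit-integral isotropic
Gaussian over the remaining fixation locations.  Per-observer maps are then
overlapped (summed) across observers and min–max rescaled to [0, 1] to give
the per-image ground truth the rest of the pipeline trains on and evaluates
against.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "FixationSequence",
    "DensityMap",
    "discard_initial_window",
    "fixation_density",
    "aggregate_observers",
    "ground_truth_map",
    "read_fixations_csv",
    "save_density",
    "load_density",
]

#: Default smoothing for the fixation landscape, as a fraction of image width.
DEFAULT_SIGMA_FRAC = 0.02

#: Seconds of initial free viewing discarded before building ground truth.
DEFAULT_DISCARD_SECONDS = 1.0


@dataclass
class FixationSequence:
    """Timed gaze samples of one observer on one image.

    ``samples`` is an (n, 3) array of ``(t_seconds, x, y)`` rows with
    nondecreasing timestamps; ``x`` is the column and ``y`` the row, 0-based.
    """

    observer_id: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1, 3)
        t = self.samples[:, 0]
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("timestamps must be nondecreasing")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class DensityMap:
    """Per-pixel map: ground truth, saliency or prior.

    Ground-truth and prior maps are nonnegative by contract; ``saliency``
    maps may carry raw real-valued SVM decision values (the ordering is the
    information), so only finiteness is enforced for them.
    """

    values: np.ndarray
    kind: str = "ground_truth"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.kind != "saliency" and self.values.size and self.values.min() < 0:
            raise ValueError("values must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def discard_initial_window(seq: FixationSequence, window: float) -> FixationSequence:
    """Drop samples with ``t < window`` seconds; order preserved."""
    if window < 0:
        raise ValueError("window must be nonnegative")
    keep = seq.samples[:, 0] >= window
    return FixationSequence(observer_id=seq.observer_id, samples=seq.samples[keep])


def fixation_density(seq: FixationSequence, shape: tuple[int, int],
                     sigma: float) -> DensityMap:
    """Sum of unit-integral Gaussians centred at each fixation.

    Fixations are accumulated on the pixel grid (nearest pixel) and smoothed
    with an isotropic Gaussian truncated at +/-4 sigma.  Mass that would fall
    outside the image is lost (constant-zero boundary), so fixations near an
    edge contribute slightly less than one unit.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    h, w = shape
    acc = np.zeros((h, w))
    if len(seq):
        ys = np.clip(np.rint(seq.samples[:, 2]).astype(int), 0, h - 1)
        xs = np.clip(np.rint(seq.samples[:, 1]).astype(int), 0, w - 1)
        np.add.at(acc, (ys, xs), 1.0)
    vals = gaussian_filter(acc, sigma, mode="constant", truncate=4.0)
    return DensityMap(values=vals, kind="ground_truth")


def aggregate_observers(maps: Sequence[DensityMap],
                        normalize_observers: bool = True) -> DensityMap:
    """Overlap per-observer maps into one [0, 1] ground truth.

    With ``normalize_observers`` (default) each map is first scaled to unit
    sum so that observers with more recorded samples do not dominate; the
    pixelwise sum is then min–max rescaled to [0, 1].
    """
    if not maps:
        raise ValueError("need at least one map")
    shape = maps[0].shape
    total = np.zeros(shape)
    for m in maps:
        if m.shape != shape:
            raise ValueError("all maps must share one shape")
        v = m.values
        if normalize_observers:
            s = v.sum()
            v = v / s if s > 0 else v
        total = total + v
    lo, hi = total.min(), total.max()
    if hi == lo:
        raise ValueError("degenerate aggregate: constant map")
    return DensityMap(values=(total - lo) / (hi - lo), kind="ground_truth")


def ground_truth_map(sequences: Iterable[FixationSequence],
                     shape: tuple[int, int],
                     sigma: float | None = None,
                     discard_window: float = DEFAULT_DISCARD_SECONDS,
                     normalize_observers: bool = True) -> DensityMap:
    """Full per-image pipeline: discard, smooth per observer, overlap."""
    if sigma is None:
        sigma = DEFAULT_SIGMA_FRAC * shape[1]
    per_obs = []
    for seq in sequences:
        trimmed = discard_initial_window(seq, discard_window)
        if not len(trimmed):
            warnings.warn(f"observer {seq.observer_id}: no samples after "
                          f"{discard_window}s window", stacklevel=2)
            continue
        per_obs.append(fixation_density(trimmed, shape, sigma))
    if not per_obs:
        raise ValueError("no observer left any samples after the discard window")
    return aggregate_observers(per_obs, normalize_observers=normalize_observers)


def read_fixations_csv(path) -> list[FixationSequence]:
    """Read a ``observer_id,t_seconds,x,y`` CSV into per-observer sequences."""
    df = pd.read_csv(path)
    required = {"observer_id", "t_seconds", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"fixation CSV must have columns {sorted(required)}")
    out = []
    for obs, grp in df.groupby("observer_id", sort=True):
        grp = grp.sort_values("t_seconds", kind="stable")
        out.append(FixationSequence(
            observer_id=str(obs),
            samples=grp[["t_seconds", "x", "y"]].to_numpy(float)))
    return out


def save_density(dmap: DensityMap, path) -> None:
    """Save as a plain NPY array plus a JSON sidecar with the kind."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), dmap.values)
    path.with_suffix(".json").write_text(json.dumps({"kind": dmap.kind}))


def load_density(path) -> DensityMap:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    kind = "ground_truth"
    side = path.with_suffix(".json")
    if side.exists():
        kind = json.loads(side.read_text()).get("kind", kind)
    return DensityMap(values=values, kind=kind)
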