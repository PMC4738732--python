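"""Synthetic fundus images and simulated expert gaze.

The eye-tracking corpus this package models after — DME fundus photographs
viewed by ophthalmologists — is not publicly distributable, so every stage of
the pipeline is exercised on synthetic data instead.  A synthetic image is a
dark circular retinal field carrying an optic disc, a branching vessel tree, a
darker macula and a configurable number of bright yellow exudate lesions whose
centres lie inside a foveal zone.  Simulated observers free-view for the first
second, then split their gaze between lesion-targeted fixations and
centre-biased fixations.

Nothing here claims clinical fidelity: the generator's only jobs are (a) a
known per-pixel lesion truth mask and (b) fixation statistics with the two
structural properties the saliency model exploits — lesion-locked feature
contrast and a spatial centre bias.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SynthConfig",
    "RetinalImage",
    "synth_fundus",
    "synth_fixations",
    "synth_dataset",
    "write_image",
    "write_mask",
    "write_fixations_csv",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic fundus image and its simulated observers.

    Coordinates follow the package convention: ``x`` is the column, ``y`` the
    row, origin top-left, 0-based.  ``fovea_center`` is ``(x, y)``; ``None``
    places the fovea at the image centre.
    """

    image_height: int = 384
    image_width: int = 500
    fovea_center: Optional[tuple[float, float]] = None
    fovea_radius: float = 40.0
    n_lesions: int = 4
    lesion_intensity: float = 0.8
    n_observers: int = 10
    fixations_per_observer: int = 300
    center_bias_sigma: float = 45.0
    sample_rate: float = 30.0
    view_seconds: float = 10.0
    free_view_seconds: float = 1.0
    lesion_weight: float = 0.8
    lesion_jitter: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_observers < 1:
            raise ValueError("need at least one observer")
        if self.fovea_radius < 0 or self.center_bias_sigma <= 0:
            raise ValueError("radii and sigmas must be nonnegative/positive")
        if not 0.0 <= self.lesion_intensity <= 1.0:
            raise ValueError("lesion_intensity must lie in [0, 1]")
        fx, fy = self.fovea_xy
        if not (0 <= fx < self.image_width and 0 <= fy < self.image_height):
            raise ValueError("fovea_center must lie inside the image")

    @property
    def fovea_xy(self) -> tuple[float, float]:
        if self.fovea_center is not None:
            return self.fovea_center
        return (self.image_width / 2.0, self.image_height / 2.0)


@dataclass
class RetinalImage:
    """RGB raster in [0, 1] with an optional binary lesion truth mask."""

    pixels: np.ndarray
    lesion_mask: Optional[np.ndarray] = None
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.lesion_mask is not None:
            self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
            if self.lesion_mask.shape != self.pixels.shape[:2]:
                raise ValueError("lesion_mask shape must match pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


# Colours chosen to mimic fundus photography: warm red field, pale yellow
# optic disc, near-white-yellow hard exudates.
_FIELD_RGB = np.array([0.62, 0.26, 0.10])
_DISC_RGB = np.array([0.95, 0.85, 0.55])
_LESION_RGB = np.array([1.00, 0.95, 0.40])


def _disc_distance(h: int, w: int, cy: float, cx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return np.hypot(yy - cy, xx - cx)


def _draw_vessels(canvas: np.ndarray, rng: np.random.Generator,
                  origin: tuple[float, float], field_r: float) -> np.ndarray:
    """Recursive random-walk vessel tree; returns a soft occupancy map."""
    h, w = canvas.shape
    occ = np.zeros((h, w))

    def walk(y: float, x: float, ang: float, width: float, length: int, depth: int) -> None:
        for _ in range(length):
            ang += rng.normal(0.0, 0.18)
            y += 2.2 * np.sin(ang)
            x += 2.2 * np.cos(ang)
            if not (0 <= y < h and 0 <= x < w):
                return
            r = max(width, 0.6)
            y0, y1 = int(max(0, y - r)), int(min(h, y + r + 1))
            x0, x1 = int(max(0, x - r)), int(min(w, x + r + 1))
            yy, xx = np.mgrid[y0:y1, x0:x1]
            occ[y0:y1, x0:x1] = np.maximum(
                occ[y0:y1, x0:x1], (np.hypot(yy - y, xx - x) <= r).astype(float)
            )
            if depth < 3 and rng.random() < 0.035:
                walk(y, x, ang + rng.choice([-1, 1]) * rng.uniform(0.5, 1.1),
                     width * 0.7, length // 2, depth + 1)

    oy, ox = origin
    n_main = 6
    for i in range(n_main):
        ang = rng.uniform(0, 2 * np.pi)
        walk(oy, ox, ang, width=2.2, length=int(field_r * 0.9), depth=0)
    return np.clip(gaussian_filter(occ, 0.8), 0.0, 1.0)


def synth_fundus(config: SynthConfig) -> RetinalImage:
    """Render one synthetic fundus image with its lesion truth mask.

    Deterministic for a given ``config`` (the RNG is seeded from
    ``config.seed``).  Lesion centres are drawn uniformly from the disc of
    radius ``fovea_radius`` around the fovea, mirroring the clinical fact that
    the diagnostically decisive exudates sit within a small zone around the
    foveal centre.
    """
    if config.n_lesions > 0 and config.fovea_radius == 0:
        raise ValueError("invalid geometry: n_lesions > 0 requires fovea_radius > 0")

    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    fx, fy = config.fovea_xy
    cy, cx = h / 2.0, w / 2.0
    field_r = 0.47 * min(h, w)

    d_field = _disc_distance(h, w, cy, cx)
    field = (d_field <= field_r).astype(float)
    field_soft = gaussian_filter(field, 1.5)

    # Radial vignette plus low-frequency mottle.
    vignette = 1.0 - 0.35 * np.clip(d_field / field_r, 0, 1) ** 2
    mottle = gaussian_filter(rng.standard_normal((h, w)), min(h, w) / 24.0)
    mottle = 0.06 * mottle / (np.abs(mottle).max() + 1e-12)
    base = (_FIELD_RGB[None, None, :] * (vignette + mottle)[:, :, None])

    # Macula: gently darker region around the fovea.
    d_fovea = _disc_distance(h, w, fy, fx)
    macula = 0.25 * np.exp(-(d_fovea ** 2) / (2 * (2.5 * max(config.fovea_radius, 1.0)) ** 2))
    base *= (1.0 - macula)[:, :, None]

    # Optic disc: bright blob offset nasally from the fovea.
    disc_cx = fx - 0.62 * field_r if fx >= cx else fx + 0.62 * field_r
    disc_cy = fy - 0.05 * field_r
    d_disc = _disc_distance(h, w, disc_cy, disc_cx)
    disc_r = 0.10 * min(h, w)
    disc = np.exp(-(d_disc ** 2) / (2 * (disc_r / 1.6) ** 2))
    base = base * (1 - disc[:, :, None]) + _DISC_RGB[None, None, :] * disc[:, :, None]

    # Vessels: dark red tree rooted at the optic disc.
    vessels = _draw_vessels(np.zeros((h, w)), rng, (disc_cy, disc_cx), field_r)
    base *= (1.0 - 0.55 * vessels)[:, :, None]

    # Exudate lesions inside the foveal zone.
    mask = np.zeros((h, w), dtype=bool)
    lesion_layer = np.zeros((h, w))
    base_radius = max(2.0, 0.013 * min(h, w))
    for _ in range(config.n_lesions):
        rr = config.fovea_radius * np.sqrt(rng.random())
        th = rng.uniform(0, 2 * np.pi)
        ly, lx = fy + rr * np.sin(th), fx + rr * np.cos(th)
        rad = base_radius * rng.uniform(0.7, 1.5)
        d = _disc_distance(h, w, ly, lx)
        mask |= d <= rad
        lesion_layer = np.maximum(lesion_layer, np.exp(-(d ** 2) / (2 * (rad / 1.4) ** 2)))

    alpha = (config.lesion_intensity * lesion_layer)[:, :, None]
    img = base * (1 - alpha) + _LESION_RGB[None, None, :] * alpha
    img *= field_soft[:, :, None]
    img = np.clip(img, 0.0, 1.0)
    mask &= field.astype(bool)

    return RetinalImage(pixels=img, lesion_mask=mask,
                        image_id=f"synth-{config.seed:06d}")


def synth_fixations(image: RetinalImage, config: SynthConfig):
    """Simulate one fixation sequence per observer on ``image``.

    The first ``free_view_seconds`` are diffuse samples over the retinal
    field.  Later samples are lesion-targeted with probability
    ``lesion_weight`` (a uniformly chosen lesion pixel plus isotropic Gaussian
    jitter) and centre-biased otherwise (Gaussian around the fovea with
    ``center_bias_sigma``).  Timestamps increase strictly and span
    approximately ``view_seconds``.  With an empty lesion mask every targeted
    draw falls back to the centre-biased component.
    """
    from .gaze import FixationSequence  # local import to avoid a cycle

    if image.lesion_mask is None:
        raise ValueError("synth_fixations requires an image with a lesion_mask")
    h, w = image.shape
    fx, fy = config.fovea_xy
    cy, cx = h / 2.0, w / 2.0
    field_r = 0.45 * min(h, w)
    mask_idx = np.argwhere(image.lesion_mask)  # (row, col)

    seqs = []
    children = np.random.SeedSequence((config.seed, 1)).spawn(config.n_observers)
    for obs, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        n = config.fixations_per_observer
        t = (np.arange(n) + rng.uniform(0.0, 0.5, size=n)) / config.sample_rate
        t *= config.view_seconds / (n / config.sample_rate)
        xs = np.empty(n)
        ys = np.empty(n)
        for i in range(n):
            if t[i] < config.free_view_seconds:
                rr = field_r * np.sqrt(rng.random())
                th = rng.uniform(0, 2 * np.pi)
                xs[i], ys[i] = cx + rr * np.cos(th), cy + rr * np.sin(th)
            elif mask_idx.size and rng.random() < config.lesion_weight:
                py, px = mask_idx[rng.integers(len(mask_idx))]
                xs[i] = px + rng.normal(0.0, config.lesion_jitter) if config.lesion_jitter else float(px)
                ys[i] = py + rng.normal(0.0, config.lesion_jitter) if config.lesion_jitter else float(py)
            else:
                xs[i] = fx + rng.normal(0.0, config.center_bias_sigma)
                ys[i] = fy + rng.normal(0.0, config.center_bias_sigma)
        xs = np.clip(xs, 0, w - 1)
        ys = np.clip(ys, 0, h - 1)
        seqs.append(FixationSequence(observer_id=f"obs{obs:02d}",
                                     samples=np.column_stack([t, xs, ys])))
    return seqs


def synth_dataset(n_images: int, base_config: SynthConfig = SynthConfig(),
                  seed: int = 0):
    """Generate ``n_images`` image/fixation pairs with varied seeds.

    Lesion count varies between 2 and 6 per image, and the fovea is jittered
    around the image centre by up to ~18% of each dimension — as in real
    fundus photography, where framing varies between acquisitions — so the
    per-image ground truths are spatially distinct while the population
    keeps its centre bias.  Returns a list of ``(RetinalImage, sequences)``.
    """
    rng = np.random.default_rng(seed)
    h, w = base_config.image_height, base_config.image_width
    out = []
    for i in range(n_images):
        fx = w / 2.0 + rng.uniform(-0.18, 0.18) * w
        fy = h / 2.0 + rng.uniform(-0.18, 0.18) * h
        cfg = replace(
            base_config,
            seed=int(rng.integers(0, 2**31 - 1)),
            n_lesions=int(rng.integers(2, 7)),
            fovea_center=(fx, fy),
        )
        img = synth_fundus(cfg)
        img.image_id = f"img{i:03d}"
        out.append((img, synth_fixations(img, cfg)))
    return out


def write_image(image: RetinalImage, path) -> None:
    iio.imwrite(Path(path), (np.clip(image.pixels, 0, 1) * 255).astype(np.uint8))


def write_mask(image: RetinalImage, path) -> None:
    if image.lesion_mask is None:
        raise ValueError("image has no lesion mask")
    iio.imwrite(Path(path), (image.lesion_mask.astype(np.uint8) * 255))


def write_fixations_csv(sequences, path) -> None:
    """Write sequences as CSV with header ``observer_id,t_seconds,x,y``."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["observer_id", "t_seconds", "x", "y"])
        for seq in sequences:
            for t, x, y in seq.samples:
                wr.writerow([seq.observer_id, f"{t:.4f}", f"{x:.2f}", f"{y:.2f}"])
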