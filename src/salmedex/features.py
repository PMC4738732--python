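"""The 27 per-pixel low-level feature channels.

Three groups, concatenated in a fixed order:

* 13 steerable-pyramid local-energy maps — 4 orientations x 3 scales of a
  non-subsampled frequency-domain steerable decomposition, plus the lowpass
  residual.  "Local energy" is the squared magnitude of the analytic
  (one-sided) subband response.
* 3 conspicuity maps (intensity, colour opponency, orientation) in the style
  of the classic centre–surround saliency architecture.
* 11 colour statistics — the raw R, G, B values, the per-pixel probability of
  each channel value under its marginal histogram, and five per-pixel joint
  RGB probabilities from 3-D colour histograms of median-filtered copies of
  the image at window sizes 3, 5, 11, 21 and 41 px.

All channels are min–max normalised to [0, 1] per channel (raw mode is
available for the pyramid group) so that no single group dominates the SVM
purely through its numeric range; per-sample standardisation is the training
normaliser's job, not done here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import gabor
from skimage.filters.rank import median as rank_median
from skimage.morphology import footprint_rectangle
from skimage.transform import pyramid_gaussian, resize

from .fixtures import RetinalImage

__all__ = [
    "FeatureStack",
    "steerable_energy",
    "itti_channels",
    "color_features",
    "extract_features",
    "N_CHANNELS",
]

N_CHANNELS = 27
_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)
_N_SCALES = 3
_MEDIAN_WINDOWS = (3, 5, 11, 21, 41)
_HIST_BITS = 3  # 2**3 = 8 bins per colour axis, 512 joint bins


@dataclass
class FeatureStack:
    """27 aligned H x W feature maps with their channel names."""

    channels: np.ndarray  # (27, H, W)
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3 or self.channels.shape[0] != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channels, got shape "
                             f"{self.channels.shape}")
        if len(self.names) != N_CHANNELS:
            raise ValueError("need one name per channel")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("feature channels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def as_matrix(self) -> np.ndarray:
        """Pixels as rows: (H*W, 27)."""
        return self.channels.reshape(N_CHANNELS, -1).T


def _minmax(m: np.ndarray) -> np.ndarray:
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Steerable pyramid
# ---------------------------------------------------------------------------

def _radial_lowpass(r: np.ndarray) -> np.ndarray:
    """Raised-cosine lowpass: 1 below pi/4, 0 above pi/2."""
    out = np.zeros_like(r)
    out[r <= np.pi / 4] = 1.0
    band = (r > np.pi / 4) & (r < np.pi / 2)
    with np.errstate(divide="ignore"):
        out[band] = np.cos(np.pi / 2 * np.log2(4 * r[band] / np.pi))
    return out


def _radial_highpass(r: np.ndarray) -> np.ndarray:
    return np.sqrt(np.clip(1.0 - _radial_lowpass(r) ** 2, 0.0, 1.0))


def _angular_window(theta: np.ndarray, theta_k: float, order: int = 3) -> np.ndarray:
    """One-sided cos^order window selecting a half-plane of orientations."""
    d = np.mod(theta - theta_k + np.pi, 2 * np.pi) - np.pi
    win = np.where(np.abs(d) < np.pi / 2, np.cos(d) ** order, 0.0)
    return 2.0 * win  # analytic-signal doubling


def steerable_energy(image: RetinalImage | np.ndarray,
                     n_scales: int = _N_SCALES,
                     normalize: bool = True) -> tuple[np.ndarray, list[str]]:
    """13 local-energy maps of a non-subsampled steerable pyramid.

    The grayscale image is decomposed in the Fourier domain with
    raised-cosine radial windows (octave-spaced bandpass at ``n_scales``
    scales) times cos^3 angular windows at 0/45/90/135 degrees; subbands stay
    at full resolution, so no upsampling is needed.  Energy is the squared
    magnitude of the complex subband.  The 13th map is the energy of the
    lowpass residual.
    """
    gray = image.pixels if isinstance(image, RetinalImage) else np.asarray(image, float)
    if gray.ndim == 3:
        gray = rgb2gray(gray)
    h, w = gray.shape
    if min(h, w) < 2 ** (n_scales + 2):
        warnings.warn("image is small for the coarsest pyramid scale; "
                      "coarse subbands will overlap heavily", stacklevel=2)

    fy = np.fft.fftfreq(h)[:, None] * 2 * np.pi
    fx = np.fft.fftfreq(w)[None, :] * 2 * np.pi
    r = np.hypot(fy, fx)
    theta = np.arctan2(fy, fx)
    F = np.fft.fft2(gray)

    maps, names = [], []
    low_accum = np.ones_like(r)
    for s in range(n_scales):
        band = _radial_highpass(r * (2 ** s)) * low_accum
        for k, deg in enumerate(_ORIENTATIONS):
            ang = _angular_window(theta, np.deg2rad(deg))
            resp = np.fft.ifft2(F * band * ang)
            maps.append(np.abs(resp) ** 2)
            names.append(f"steer_s{s}_o{int(deg)}")
        low_accum = low_accum * _radial_lowpass(r * (2 ** s))
    # Lowpass residual (13th map).
    resp = np.fft.ifft2(F * low_accum)
    maps.append(np.real(resp) ** 2)
    names.append("steer_lowpass")

    stack = np.stack(maps)
    if normalize:
        stack = np.stack([_minmax(m) for m in stack])
    return stack, names


# ---------------------------------------------------------------------------
# Centre-surround conspicuity channels
# ---------------------------------------------------------------------------

def _normalize_map(m: np.ndarray) -> np.ndarray:
    """Rescale to [0,1] and promote maps with few, strong peaks."""
    m = _minmax(m)
    return m * (1.0 - m.mean()) ** 2


def _pyramid(img: np.ndarray, max_layer: int) -> list[np.ndarray]:
    return list(pyramid_gaussian(img, max_layer=max_layer, downscale=2,
                                 channel_axis=None))


def _center_surround(pyr: list[np.ndarray], centers, deltas) -> list[np.ndarray]:
    out = []
    for c in centers:
        for d in deltas:
            s = c + d
            if s >= len(pyr):
                continue
            surround = resize(pyr[s], pyr[c].shape, order=1, mode="reflect",
                              anti_aliasing=False)
            out.append((np.abs(pyr[c] - surround), c))
    return out


def itti_channels(image: RetinalImage | np.ndarray,
                  normalize: bool = True) -> tuple[np.ndarray, list[str]]:
    """Intensity, colour-opponency and orientation conspicuity maps.

    A dyadic Gaussian pyramid is built per channel; feature maps are
    across-scale centre–surround differences (centres 2–4, surrounds 3–4
    levels further), normalised with a peak-promoting operator and summed
    into one conspicuity map per group, resized to full resolution.
    Orientation uses Gabor energy at 0/45/90/135 degrees on the intensity
    pyramid.
    """
    rgb = image.pixels if isinstance(image, RetinalImage) else np.asarray(image, float)
    h, w = rgb.shape[:2]
    max_layer = max(2, min(8, int(np.log2(min(h, w))) - 2))
    centers = [c for c in (2, 3, 4) if c < max_layer]
    deltas = (3, 4)

    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    inten = (r + g + b) / 3.0

    # Broadly tuned colour channels, zeroed where intensity is negligible.
    R = np.clip(r - (g + b) / 2, 0, None)
    G = np.clip(g - (r + b) / 2, 0, None)
    B = np.clip(b - (r + g) / 2, 0, None)
    Y = np.clip((r + g) / 2 - np.abs(r - g) / 2 - b, 0, None)

    pyr_i = _pyramid(inten, max_layer)
    pyr_R, pyr_G = _pyramid(R, max_layer), _pyramid(G, max_layer)
    pyr_B, pyr_Y = _pyramid(B, max_layer), _pyramid(Y, max_layer)

    def conspicuity(feature_maps) -> np.ndarray:
        acc = np.zeros((h, w))
        for m, level in feature_maps:
            acc += resize(_normalize_map(m), (h, w), order=1, mode="reflect",
                          anti_aliasing=False)
        return acc

    # Intensity.
    ci = conspicuity(_center_surround(pyr_i, centers, deltas))

    # Colour: RG and BY double opponency.
    cc_maps = []
    for c in centers:
        for d in deltas:
            s = c + d
            if s >= len(pyr_i):
                continue
            up = lambda p: resize(p[s], p[c].shape, order=1, mode="reflect",
                                  anti_aliasing=False)
            # Centre-surround contrast of the opponent channels (not the
            # literal double-opponency sum, which fires on uniform colour
            # fields): zero on any constant-colour region, maximal where a
            # rare colour sits on an opposing background.
            rg = np.abs((pyr_R[c] - pyr_G[c]) - (up(pyr_R) - up(pyr_G)))
            by = np.abs((pyr_B[c] - pyr_Y[c]) - (up(pyr_B) - up(pyr_Y)))
            cc_maps.extend([(rg, c), (by, c)])
    cc = conspicuity(cc_maps)

    # Orientation: Gabor energy pyramids, centre-surround per orientation.
    co = np.zeros((h, w))
    for deg in _ORIENTATIONS:
        gpyr = []
        for lvl in pyr_i:
            if min(lvl.shape) < 4:
                gpyr.append(np.zeros_like(lvl))
                continue
            re, im = gabor(lvl, frequency=0.25, theta=np.deg2rad(deg))
            gpyr.append(np.hypot(re, im))
        co += conspicuity(_center_surround(gpyr, centers, deltas))

    stack = np.stack([ci, cc, co])
    if normalize:
        stack = np.stack([_minmax(m) for m in stack])
    names = ["itti_intensity", "itti_color", "itti_orientation"]
    return stack, names


# ---------------------------------------------------------------------------
# Colour-statistics channels
# ---------------------------------------------------------------------------

def color_features(image: RetinalImage | np.ndarray,
                   median_windows=_MEDIAN_WINDOWS) -> tuple[np.ndarray, list[str]]:
    """Raw RGB, marginal colour probabilities and multi-scale joint colour
    probabilities (11 channels).

    Histograms use 8 bins per colour axis.  The joint probability is read
    from a 3-D histogram of the image median-filtered at each window size, so
    rare colours (e.g. bright yellow exudate on a red field) get low
    probability and common background colours get high probability.
    """
    rgb = image.pixels if isinstance(image, RetinalImage) else np.asarray(image, float)
    h, w = rgb.shape[:2]
    n = h * w
    u8 = (np.clip(rgb, 0, 1) * 255).astype(np.uint8)

    maps, names = [], []
    for c, label in enumerate("rgb"):
        maps.append(rgb[..., c].astype(float))
        names.append(f"color_{label}")

    shift = 8 - _HIST_BITS
    for c, label in enumerate("rgb"):
        idx = u8[..., c] >> shift
        hist = np.bincount(idx.ravel(), minlength=2 ** _HIST_BITS) / n
        maps.append(hist[idx])
        names.append(f"color_p{label}")

    for wsize in median_windows:
        if wsize <= 1:
            med = u8
        else:
            fp = footprint_rectangle((wsize, wsize))
            med = np.stack([rank_median(u8[..., c], fp) for c in range(3)], axis=-1)
        ir = med[..., 0] >> shift
        ig = med[..., 1] >> shift
        ib = med[..., 2] >> shift
        code = (ir.astype(np.int32) << (2 * _HIST_BITS)) | \
               (ig.astype(np.int32) << _HIST_BITS) | ib.astype(np.int32)
        hist = np.bincount(code.ravel(), minlength=2 ** (3 * _HIST_BITS)) / n
        maps.append(hist[code])
        names.append(f"color_joint_m{wsize}")

    return np.stack(maps), names


def extract_features(image: RetinalImage | np.ndarray,
                     steerable_normalize: bool = True) -> FeatureStack:
    """Full 27-channel stack: 13 pyramid + 3 conspicuity + 11 colour."""
    s_maps, s_names = steerable_energy(image, normalize=steerable_normalize)
    i_maps, i_names = itti_channels(image)
    c_maps, c_names = color_features(image)
    return FeatureStack(channels=np.concatenate([s_maps, i_maps, c_maps]),
                        names=tuple(s_names + i_names + c_names))
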