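"""Evaluation scores for saliency maps against expert ground truth.

Saliency-model scores: AUC (the map as a continuous classifier of
ground-truth-positive pixels), EMD (exact optimal-transport cost between the
two maps as unit-mass distributions on a coarse grid) and the Similarity
Score (sum of pixelwise minima of the unit-sum maps).  Detection scores:
sensitivity and specificity of the binarised map at a given salient-region
fraction, and Youden's J = sensitivity + specificity - 1.

EMD is computed on block-summed grids (default 16 x 16) because exact
transport on full-resolution images is computationally prohibitive; the grid
size is part of the configuration and absolute EMD values are comparable
only within one configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score

from .gaze import DensityMap

__all__ = [
    "EvalReport",
    "binarize_map",
    "auc_score",
    "emd_grid",
    "emd_score",
    "similarity_score",
    "sens_spec",
    "youden",
    "roc_by_fraction",
    "evaluate_map",
]

DEFAULT_EMD_GRID = 16
DEFAULT_GT_TOP_FRACTION = 20.0
DEFAULT_REGION_FRACTION = 50.0


@dataclass
class EvalReport:
    """All scores of one saliency map against one ground truth."""

    auc: float
    emd: float
    ss: float
    sensitivity: float
    specificity: float
    youden: float
    roc: list = field(default_factory=list)  # (fpr, tpr) pairs

    def __post_init__(self) -> None:
        if not math.isnan(self.youden):
            if abs(self.youden - (self.sensitivity + self.specificity - 1.0)) > 1e-12:
                raise ValueError("youden must equal sensitivity + specificity - 1")

    def as_dict(self) -> dict:
        return {"auc": self.auc, "emd": self.emd, "ss": self.ss,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity, "youden": self.youden}


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, DensityMap) else np.asarray(m, dtype=float)


def binarize_map(dmap, top_fraction: float) -> np.ndarray:
    """Mark the ``top_fraction`` percent most-salient pixels.

    The budget is ceil(top_fraction * H * W / 100).  Ties at the threshold
    are resolved deterministically in raster order (stable sort), so exactly
    the budgeted number of pixels is marked.
    """
    if not 0 < top_fraction < 100:
        raise ValueError("top_fraction must be in (0, 100)")
    v = _values(dmap)
    flat = v.ravel()
    budget = int(np.ceil(top_fraction * flat.size / 100.0))
    if flat.max() == flat.min():
        warnings.warn("constant map: all pixels tie; marking raster-first "
                      "pixels", stacklevel=2)
    order = np.argsort(-flat, kind="stable")
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:budget]] = True
    return mask.reshape(v.shape)


def auc_score(saliency, gt_mask: np.ndarray) -> float:
    """Area under the ROC of the map as a classifier of ``gt_mask``.

    Computed by the rank statistic with midrank tie handling.  1 means the
    map reproduces the ground truth exactly, 0.5 means no relation, 0 means
    perfect anticorrelation.
    """
    mask = np.asarray(gt_mask, dtype=bool).ravel()
    if mask.all() or not mask.any():
        raise ValueError("undefined metric: ground truth has a single class")
    return float(roc_auc_score(mask, _values(saliency).ravel()))


def emd_grid(a: np.ndarray, b: np.ndarray) -> float:
    """Exact earth mover's distance between two nonnegative grids.

    ``a`` and ``b`` are same-shape 2-D arrays; each is normalised to unit
    mass, and the exact optimal-transport cost with Euclidean ground
    distance on the cell lattice is solved as a linear program (HiGHS).
    Only cells with positive mass enter the program.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("grids must be 2-D and same shape")
    if a.min() < 0 or b.min() < 0:
        raise ValueError("grids must be nonnegative")
    sa, sb = a.sum(), b.sum()
    if sa <= 0 or sb <= 0:
        raise ValueError("undefined metric: zero-mass distribution")
    pa, pb = a / sa, b / sb

    # Cells carrying a vanishing share of the mass perturb the cost by at
    # most tol * support * grid-diameter but can make the solver's presolve
    # reject the program, so they are dropped before the solve.
    for tol in (1e-8, 1e-6):
        ia = np.argwhere(pa > tol)
        ib = np.argwhere(pb > tol)
        wa = pa[pa > tol]
        wb = pb[pb > tol]
        wa = wa / wa.sum()
        wb = wb / wb.sum()
        C = cdist(ia.astype(float), ib.astype(float))
        n, m = C.shape
        rows = sp.kron(sp.eye(n), np.ones((1, m)))
        cols = sp.kron(np.ones((1, n)), sp.eye(m))
        # The last column constraint is implied by the others (both marginals
        # sum to one); dropping it keeps the system consistent under rounding.
        A = sp.vstack([rows, cols]).tocsr()[:-1]
        rhs = np.concatenate([wa, wb])[:-1]
        res = linprog(C.ravel(), A_eq=A, b_eq=rhs, bounds=(0, None),
                      method="highs")
        if res.status == 0:
            return float(res.fun)
    raise RuntimeError(f"transport LP failed: {res.message}")


def _block_sum(v: np.ndarray, grid: int) -> np.ndarray:
    h, w = v.shape
    gy = np.minimum((np.arange(h) * grid) // h, grid - 1)
    gx = np.minimum((np.arange(w) * grid) // w, grid - 1)
    code = gy[:, None] * grid + gx[None, :]
    return np.bincount(code.ravel(), weights=v.ravel(),
                       minlength=grid * grid).reshape(grid, grid)


def emd_score(a, b, grid: int = DEFAULT_EMD_GRID) -> float:
    """EMD between two maps after block-downsampling to ``grid`` x ``grid``.

    Result is in grid-cell distance units: moving all mass one cell costs 1.
    """
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError("maps must share one shape")
    return emd_grid(_block_sum(va, grid), _block_sum(vb, grid))


def similarity_score(a, b) -> float:
    """Sum of pixelwise minima of the two unit-sum normalised maps."""
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError("maps must share one shape")
    sa, sb = va.sum(), vb.sum()
    if sa <= 0 or sb <= 0:
        raise ValueError("undefined metric: zero-mass map")
    return float(np.minimum(va / sa, vb / sb).sum())


def sens_spec(saliency, gt_mask: np.ndarray,
              region_fraction: float = DEFAULT_REGION_FRACTION) -> tuple[float, float]:
    """Sensitivity and specificity of the map binarised at a region fraction."""
    mask = np.asarray(gt_mask, dtype=bool)
    if mask.all() or not mask.any():
        raise ValueError("undefined metric: ground truth has a single class")
    pred = binarize_map(saliency, region_fraction)
    tp = np.count_nonzero(pred & mask)
    fn = np.count_nonzero(~pred & mask)
    tn = np.count_nonzero(~pred & ~mask)
    fp = np.count_nonzero(pred & ~mask)
    return float(tp / (tp + fn)), float(tn / (tn + fp))


def youden(sensitivity: float, specificity: float) -> float:
    """Youden's J statistic: sensitivity + specificity - 1."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must lie in [0, 1]")
    return sensitivity + specificity - 1.0


def roc_by_fraction(saliency, gt_mask: np.ndarray,
                    fractions=tuple(range(5, 100, 5))) -> list[tuple[float, float]]:
    """ROC points parameterised by the salient-region fraction (5%...95%)."""
    pts = [(0.0, 0.0)]
    mask = np.asarray(gt_mask, dtype=bool)
    for f in fractions:
        pred = binarize_map(saliency, float(f))
        tp = np.count_nonzero(pred & mask)
        fp = np.count_nonzero(pred & ~mask)
        pts.append((fp / max(np.count_nonzero(~mask), 1),
                    tp / max(np.count_nonzero(mask), 1)))
    pts.append((1.0, 1.0))
    return pts


def evaluate_map(saliency, gt_density,
                 gt_top_fraction: float = DEFAULT_GT_TOP_FRACTION,
                 region_fraction: float = DEFAULT_REGION_FRACTION,
                 emd_grid_size: int = DEFAULT_EMD_GRID,
                 compute_emd: bool = True,
                 with_roc: bool = False) -> EvalReport:
    """Score one saliency map against one continuous ground truth.

    The ground truth is binarised at its top ``gt_top_fraction`` percent
    (matching the positive-sample stratum used in training) for AUC and
    sensitivity/specificity; EMD and SS compare the continuous maps.  The
    saliency map is shifted to be nonnegative before the mass-based scores.
    """
    gt_vals = _values(gt_density)
    sal_vals = _values(saliency)
    gt_mask = binarize_map(gt_vals, gt_top_fraction)

    auc = auc_score(sal_vals, gt_mask)
    sal_nn = sal_vals - min(sal_vals.min(), 0.0)
    emd = emd_score(sal_nn, gt_vals, grid=emd_grid_size) if compute_emd else math.nan
    ss = similarity_score(sal_nn, gt_vals)
    sens, spec = sens_spec(sal_vals, gt_mask, region_fraction)
    roc = roc_by_fraction(sal_vals, gt_mask) if with_roc else []
    return EvalReport(auc=auc, emd=emd, ss=ss, sensitivity=sens,
                      specificity=spec, youden=youden(sens, spec), roc=roc)
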