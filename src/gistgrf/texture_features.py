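"""The 34 global radiomic features: GLCM Haralick set, NGTDM coarseness, FOS range.

Conventions (all recorded in run provenance and configurable):

* gray levels are quantized to ``n_levels`` (default 64) equal-width bins
  over the region's own min-max, so every feature is invariant to a constant
  intensity shift and indifferent to bit depth;
* the GLCM is accumulated symmetrically at Chebyshev offsets in the four
  standard directions (0, 45, 90, 135 degrees) at the stated pixel distance;
  each direction is normalized to probabilities and the four matrices are
  averaged;
* entropies use log base 2 with 0*log(0) = 0;
* the lattice ("ROI_Std") variants are the population (divide-by-N) standard
  deviation of the per-block feature values; the inscribed-square ("SQ")
  variants are computed once over the square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .registry import feature_names, load_registry
from .roi_extraction import InscribedSquare, LatticeGrid

__all__ = [
    "FeatureParams",
    "GlcmMatrix",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "ngtdm_coarseness",
    "fos_range",
    "extract_image_features",
    "zscore_normalize",
]

logger = logging.getLogger(__name__)

NGTDM_EPS = 1e-9

GLCM_FEATURE_NAMES = (
    "Correlation",
    "Difference_entropy",
    "Dissimilarity",
    "Difference_variance",
    "Energy",
    "Entropy",
    "Homogeneity",
    "Information_measure_of_correlation1",
    "Information_measure_of_correlation2",
    "Maximum_probability",
    "Sum_entropy",
    "Sum_variance",
    "Cluster_prominence",
    "Cluster_shade",
    "Sum_of_squares_variance",
)


@dataclass
class FeatureParams:
    """Tunables of the extraction stage."""

    n_levels: int = 64
    block_size: int = 214
    coverage_min: float = 0.9
    roi_glcm_distance: int = 3
    sq_glcm_distance: int = 9
    roi_ngtdm_window: int = 3
    sq_ngtdm_window: int = 9
    directions: tuple[tuple[int, int], ...] | None = None  # None = 4 standard


@dataclass
class GlcmMatrix:
    """Direction-averaged, normalized gray level co-occurrence matrix."""

    p: np.ndarray
    distance: int
    n_levels: int
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool = True


def _standard_offsets(distance: int) -> tuple[tuple[int, int], ...]:
    d = int(distance)
    # 0, 45, 90, 135 degrees with Chebyshev stride d (MATLAB graycomatrix style)
    return ((0, d), (-d, d), (-d, 0), (-d, -d))


def quantize(region: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width quantization of a region to levels 0..n_levels-1.

    Bins span the region's own [min, max]; a constant region maps to level 0.
    """
    region = np.asarray(region, dtype=np.float64)
    lo, hi = region.min(), region.max()
    if hi == lo:
        return np.zeros(region.shape, dtype=np.intp)
    q = np.floor((region - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.clip(q, 0, n_levels - 1)


def compute_glcm(
    region: np.ndarray,
    distance: int,
    n_levels: int = 64,
    offsets: tuple[tuple[int, int], ...] | None = None,
    symmetric: bool = True,
) -> GlcmMatrix:
    """Build the co-occurrence matrix of a rectangular region.

    Pairs are counted for each offset with both endpoints inside the region;
    with ``symmetric`` each pair is counted in both orders. Each direction's
    matrix is normalized to probabilities and directions are averaged.
    """
    q = quantize(region, n_levels)
    h, w = q.shape
    if offsets is None:
        offsets = _standard_offsets(distance)
    mats = []
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), h - max(0, dr)
        c0, c1 = max(0, -dc), w - max(0, dc)
        if r1 <= r0 or c1 <= c0:
            continue
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
        m = counts.reshape(n_levels, n_levels).astype(np.float64)
        if symmetric:
            m = m + m.T
        mats.append(m / m.sum())
    if not mats:
        raise ValueError(
            f"region {q.shape} admits no pixel pair at distance {distance}"
        )
    p = np.mean(mats, axis=0)
    return GlcmMatrix(p=p, distance=distance, n_levels=n_levels,
                      offsets=tuple(offsets), symmetric=symmetric)


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def glcm_features(glcm: GlcmMatrix) -> dict[str, float]:
    """The 15 Haralick-family statistics of a normalized GLCM.

    Marginal statistics use 0-based level indices; all are invariant to the
    index origin. Correlation is defined as 0 when either marginal is
    degenerate (constant region).
    """
    p = glcm.p
    n = glcm.n_levels
    i = np.arange(n, dtype=np.float64)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((i - mu_y) ** 2) @ py))

    ii = i[:, None]
    jj = i[None, :]
    absdiff = np.abs(ii - jj)

    # sum and difference distributions p_{x+y}, p_{|x-y|}
    ksum = np.arange(2 * n - 1, dtype=np.float64)
    kdiff = np.arange(n, dtype=np.float64)
    p_sum = np.bincount((ii + jj).astype(np.intp).ravel(), weights=p.ravel(),
                        minlength=2 * n - 1)
    p_diff = np.bincount(absdiff.astype(np.intp).ravel(), weights=p.ravel(),
                         minlength=n)

    sum_avg = float(ksum @ p_sum)
    diff_avg = float(kdiff @ p_diff)

    hxy = _entropy(p)
    hx = _entropy(px)
    hy = _entropy(py)
    pxy = px[:, None] * py[None, :]
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())

    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sd_x * sd_y > 0:
        correlation = float((((ii - mu_x) * (jj - mu_y)) * p).sum() / (sd_x * sd_y))
    else:
        correlation = 0.0

    cluster_arg = ii + jj - mu_x - mu_y
    return {
        "Correlation": correlation,
        "Difference_entropy": _entropy(p_diff),
        "Dissimilarity": float((absdiff * p).sum()),
        "Difference_variance": float(((kdiff - diff_avg) ** 2) @ p_diff),
        "Energy": float((p**2).sum()),
        "Entropy": hxy,
        "Homogeneity": float((p / (1.0 + absdiff)).sum()),
        "Information_measure_of_correlation1": float(imc1),
        "Information_measure_of_correlation2": imc2,
        "Maximum_probability": float(p.max()),
        "Sum_entropy": _entropy(p_sum),
        "Sum_variance": float(((ksum - sum_avg) ** 2) @ p_sum),
        "Cluster_prominence": float((cluster_arg**4 * p).sum()),
        "Cluster_shade": float((cluster_arg**3 * p).sum()),
        "Sum_of_squares_variance": float((((ii - mu_x) ** 2) * p).sum()),
    }


def ngtdm_coarseness(region: np.ndarray, window: int, n_levels: int = 64) -> float:
    """Amadasun-King coarseness of a rectangular region.

    For every interior pixel k (whose window x window neighbourhood lies
    fully inside the region) with quantized level i, the neighbourhood mean
    excluding the centre is A(k); s(i) sums |i - A(k)| per level, p_i is the
    level's share among interior pixels, and coarseness is
    ``1 / (eps + sum_i p_i * s(i))`` with eps = 1e-9, hence naturally capped
    at 1e9 for perfectly uniform regions.
    """
    q = quantize(region, n_levels).astype(np.float64)
    h, w = q.shape
    r = window // 2
    if h < window or w < window:
        raise ValueError(
            f"region {q.shape} has no pixel with a full {window}x{window} neighbourhood"
        )
    kernel = np.ones((window, window))
    nbr_sum = ndimage.convolve(q, kernel, mode="constant", cval=0.0)
    a_bar = (nbr_sum - q) / (window * window - 1)
    interior = (slice(r, h - r), slice(r, w - r))
    levels = q[interior].astype(np.intp).ravel()
    diffs = np.abs(q[interior] - a_bar[interior]).ravel()
    n_valid = levels.size
    counts = np.bincount(levels, minlength=n_levels)
    s = np.bincount(levels, weights=diffs, minlength=n_levels)
    p_i = counts / n_valid
    weighted = float(np.dot(p_i, s))
    return float(1.0 / (NGTDM_EPS + weighted))


def fos_range(region: np.ndarray) -> float:
    """First-order range: max minus min of the raw (unquantized) gray values."""
    region = np.asarray(region)
    if region.size == 0:
        raise ValueError("empty region")
    return float(region.max() - region.min())


def _base_features(
    block: np.ndarray,
    glcm_distance: int,
    ssv_distance: int,
    ngtdm_window: int,
    params: FeatureParams,
) -> dict[str, float]:
    """All 17 base statistics of one rectangular region."""
    glcm = compute_glcm(block, glcm_distance, params.n_levels, params.directions)
    feats = glcm_features(glcm)
    if ssv_distance != glcm_distance:
        glcm_ssv = compute_glcm(block, ssv_distance, params.n_levels, params.directions)
        feats["Sum_of_squares_variance"] = glcm_features(glcm_ssv)[
            "Sum_of_squares_variance"
        ]
    feats["Coarseness"] = ngtdm_coarseness(block, ngtdm_window, params.n_levels)
    feats["Range_all"] = fos_range(block)
    return feats


def extract_image_features(
    pixels: np.ndarray,
    mask: np.ndarray,
    grid: LatticeGrid,
    square: InscribedSquare,
    params: FeatureParams | None = None,
) -> pd.Series:
    """Compute the 34-feature vector of one oriented, cropped mammogram.

    Lattice (``ROI_Std``) features are the population standard deviation of
    the per-block base statistics across retained blocks; if fewer than two
    blocks are retained the standard deviation is undefined and all lattice
    features are set to 0 with a logged warning. Inscribed-square (``SQ``)
    features are computed once on the square.
    """
    params = params or FeatureParams()
    if square is None:
        raise ValueError("inscribed square is required")
    reg = load_registry()

    bs = grid.block_size
    per_block: list[dict[str, float]] = []
    for r, c in grid.origins:
        block = pixels[r : r + bs, c : c + bs]
        per_block.append(
            _base_features(
                block,
                params.roi_glcm_distance,
                params.sq_glcm_distance,  # lattice Sum_of_squares_variance uses distance 9
                params.roi_ngtdm_window,
                params,
            )
        )
    base_names = list(per_block[0]) if per_block else []
    if len(per_block) >= 2:
        roi_std = {
            name: float(np.std([b[name] for b in per_block]))  # population std
            for name in base_names
        }
    else:
        logger.warning(
            "fewer than 2 lattice blocks retained (%d); lattice features set to 0",
            len(per_block),
        )
        roi_std = {}

    sq_block = pixels[square.row : square.row + square.side,
                      square.col : square.col + square.side]
    sq_feats = _base_features(
        sq_block,
        params.sq_glcm_distance,
        params.sq_glcm_distance,
        params.sq_ngtdm_window,
        params,
    )

    values = []
    for _, row in reg.iterrows():
        if row["region"] == "ROI":
            values.append(roi_std.get(row["base"], 0.0))
        else:
            values.append(sq_feats[row["base"]])
    out = pd.Series(values, index=feature_names(), dtype=float)
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError("non-finite feature value produced")
    return out


def zscore_normalize(
    matrix: pd.DataFrame,
    fit_rows: np.ndarray | list | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-wise z-scoring with parameters estimated on ``fit_rows`` only.

    All rows are transformed with the fitted mean/sd so held-out rows can be
    normalized without leaking into the parameters. Constant columns
    (sd < 1e-12 on the fit rows) map to 0. Returns (transformed, mean, sd).
    """
    fit = matrix if fit_rows is None else matrix.loc[fit_rows]
    if len(fit) < 2:
        raise ValueError("need at least 2 rows to fit normalization")
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=1)
    constant = sd < 1e-12
    safe_sd = sd.where(~constant, 1.0)
    out = (matrix - mean) / safe_sd
    out.loc[:, constant[constant].index] = 0.0
    return out, mean, sd
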