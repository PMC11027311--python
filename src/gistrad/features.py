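"""The 130 global radiomic features: 110 GLCM statistics and 20 FOS.

Second-order texture is summarized by gray-level co-occurrence matrices
(GLCM): normalized counts of quantized gray-level pairs at a fixed pixel
offset. For each pixel distance d in {1, 3, 5, 9, 11} the four standard
angles (0°, 45°, 90°, 135°) are accumulated into a single matrix, counted
symmetrically by default, and 22 statistics are read off each matrix —
22 statistics x 5 distances = 110 features. Only pixel pairs whose both
members lie inside the ROI are counted.

First-order statistics (FOS) describe the raw (unquantized) ROI intensity
histogram: moments, order statistics, and three ranges, 20 in all.

Feature names and order are fixed by :data:`FEATURE_NAMES`: each GLCM
statistic appears as ``<stat>_<d>`` for the five distances in turn, followed
by the 20 FOS names.

Conventions (the quantities below are standard but their details vary across
implementations; these are the ones used here):

* quantization: equal-width binning of the ROI's own [min, max] into
  ``n_levels`` bins labeled 1..N_g; the maximum maps to bin N_g and a
  constant ROI maps everything to bin 1;
* entropies use the natural logarithm (``log_base`` switches to base 2) with
  0 log 0 = 0;
* correlation comes in the two canonical variants (``Correlation_m``:
  (sum_ij ij p - mu_x mu_y) / (sigma_x sigma_y); ``Correlation_p``:
  expectation form), both defined as 0 when either marginal is degenerate;
  homogeneity likewise (``Homogeneity_m``: 1/(1+|i-j|) weights;
  ``Homogeneity``: 1/(1+(i-j)^2) weights);
* FOS standard deviation uses the n-1 denominator; skewness and kurtosis are
  the moment estimators (kurtosis non-excess, normal = 3 — ``excess_kurtosis``
  switches the convention) and both are 0 for a constant ROI; percentiles use
  linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .roi import ROIMask

DISTANCES: tuple[int, ...] = (1, 3, 5, 9, 11)

GLCM_STAT_NAMES: tuple[str, ...] = (
    "Autocorrelation",
    "Contrast",
    "Correlation_m",
    "Correlation_p",
    "Cluster_prominence",
    "Cluster_shade",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "Homogeneity_m",
    "Homogeneity",
    "Maximum_probability",
    "Sum_of_squares_variance",
    "Sum_average",
    "Sum_variance",
    "Sum_entropy",
    "Difference_variance",
    "Difference_entropy",
    "Information_measure_of_correlation1",
    "Information_measure_of_correlation2",
    "Inverse_difference_normalized",
    "Inverse_difference_moment_normalized",
)

FOS_NAMES: tuple[str, ...] = (
    "Mean",
    "Standard_deviation",
    "Skewness",
    "Kurtosis",
    "Minimum",
    "5th_percentile",
    "10th_percentile",
    "15th_percentile",
    "20th_percentile",
    "25th_percentile",
    "Median",
    "75th_percentile",
    "80th_percentile",
    "85th_percentile",
    "90th_percentile",
    "95th_percentile",
    "Maximum",
    "Range_all",
    "Range5",
    "Range2",
)

#: All 130 feature names in canonical order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{d}" for stat in GLCM_STAT_NAMES for d in DISTANCES
) + FOS_NAMES

#: Offsets (drow, dcol) per unit distance for the four standard GLCM angles.
ANGLE_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


class EmptyGLCMError(ValueError):
    """No co-occurring pixel pair exists inside the ROI at this distance."""


@dataclass
class QuantizedROI:
    """ROI gray levels binned to 1..n_levels (0 marks non-ROI pixels)."""

    levels: np.ndarray
    n_levels: int
    quantization_range: tuple[float, float]


@dataclass
class GLCMMatrix:
    p: np.ndarray
    distance: int
    angles: tuple[tuple[int, int], ...]
    symmetric: bool
    pair_count: int


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature extraction stage."""

    n_levels: int = 8
    distances: tuple[int, ...] = DISTANCES
    symmetric: bool = True
    log_base: float = np.e
    excess_kurtosis: bool = False


def quantize(pixels: np.ndarray, roi: ROIMask | np.ndarray, n_levels: int = 8) -> QuantizedROI:
    """Equal-width quantization of ROI intensities into 1..n_levels.

    Bin edges span the ROI's own [min, max]; the maximum maps to bin
    n_levels and a constant ROI maps everything to bin 1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    mask = roi.mask if isinstance(roi, ROIMask) else np.asarray(roi, dtype=bool)
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape != mask.shape:
        raise ValueError("image and ROI shapes differ")
    if not mask.any():
        raise ValueError("empty ROI")
    vals = pixels[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(pixels.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
    else:
        binned = np.floor((pixels[mask] - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
        levels[mask] = np.clip(binned, 1, n_levels)
    return QuantizedROI(levels=levels, n_levels=n_levels, quantization_range=(lo, hi))


def compute_glcm(
    q: QuantizedROI,
    distance: int,
    angles: tuple[tuple[int, int], ...] = ANGLE_OFFSETS,
    symmetric: bool = True,
) -> GLCMMatrix:
    """Gray-level co-occurrence matrix at one pixel distance.

    Pairs are counted at every angle offset scaled by ``distance`` and
    accumulated into a single N_g x N_g matrix; a pair counts only if both
    pixels lie inside the ROI. Symmetric counting also counts each pair
    reversed. The matrix is normalized to sum to 1.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    ng = q.n_levels
    levels = q.levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    rows, cols = levels.shape
    for ar, ac in angles:
        dr, dc = ar * distance, ac * distance
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = levels[r0:r1, c0:c1]
        b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        flat = (a[valid] - 1) * ng + (b[valid] - 1)
        counts += np.bincount(flat, minlength=ng * ng).reshape(ng, ng)
    if symmetric:
        counts = counts + counts.T
    total = int(counts.sum())
    if total == 0:
        raise EmptyGLCMError(f"empty GLCM: no ROI pixel pairs at distance {distance}")
    return GLCMMatrix(
        p=counts / total,
        distance=distance,
        angles=tuple(angles),
        symmetric=symmetric,
        pair_count=total,
    )


def _xlogx(p: np.ndarray, log_base: float) -> np.ndarray:
    """p * log p with the 0 log 0 = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    if log_base != np.e:
        out /= np.log(log_base)
    return out


def glcm_statistics(G: GLCMMatrix, log_base: float = np.e) -> dict[str, float]:
    """The 22 second-order statistics of one normalized GLCM."""
    p = G.p
    ng = p.shape[0]
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]

    px = p.sum(axis=1)  # marginal over rows (first pixel)
    py = p.sum(axis=0)
    idx = np.arange(1, ng + 1)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sigma_x = float(np.sqrt(((idx - mu_x) ** 2 * px).sum()))
    sigma_y = float(np.sqrt(((idx - mu_y) ** 2 * py).sum()))

    # diagonal-band marginals: p_{x+y}(k), k = 2..2*ng ; p_{x-y}(k), k = 0..ng-1
    ksum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(ksum.size)
    kdiff = np.arange(0, ng)
    p_diff = np.zeros(kdiff.size)
    s_idx = (i + j).ravel() - 2
    d_idx = np.abs(i - j).ravel()
    np.add.at(p_sum, s_idx, p.ravel())
    np.add.at(p_diff, d_idx, p.ravel())

    stats: dict[str, float] = {}
    stats["Autocorrelation"] = float((i * j * p).sum())
    stats["Contrast"] = float(((i - j) ** 2 * p).sum())
    if sigma_x * sigma_y == 0:
        stats["Correlation_m"] = 0.0
        stats["Correlation_p"] = 0.0
    else:
        stats["Correlation_m"] = float(
            ((i * j * p).sum() - mu_x * mu_y) / (sigma_x * sigma_y)
        )
        stats["Correlation_p"] = float(
            (((i - mu_x) * (j - mu_y) / (sigma_x * sigma_y)) * p).sum()
        )
    stats["Cluster_prominence"] = float(((i + j - mu_x - mu_y) ** 4 * p).sum())
    stats["Cluster_shade"] = float(((i + j - mu_x - mu_y) ** 3 * p).sum())
    stats["Dissimilarity"] = float((np.abs(i - j) * p).sum())
    stats["Energy"] = float((p**2).sum())
    stats["Entropy"] = float(-_xlogx(p, log_base).sum())
    stats["Homogeneity_m"] = float((p / (1.0 + np.abs(i - j))).sum())
    stats["Homogeneity"] = float((p / (1.0 + (i - j) ** 2)).sum())
    stats["Maximum_probability"] = float(p.max())
    stats["Sum_of_squares_variance"] = float(((i - mu_x) ** 2 * p).sum())
    sum_avg = float((ksum * p_sum).sum())
    stats["Sum_average"] = sum_avg
    stats["Sum_variance"] = float(((ksum - sum_avg) ** 2 * p_sum).sum())
    stats["Sum_entropy"] = float(-_xlogx(p_sum, log_base).sum())
    diff_avg = float((kdiff * p_diff).sum())
    stats["Difference_variance"] = float(((kdiff - diff_avg) ** 2 * p_diff).sum())
    stats["Difference_entropy"] = float(-_xlogx(p_diff, log_base).sum())

    hxy = stats["Entropy"]
    hx = float(-_xlogx(px, log_base).sum())
    hy = float(-_xlogx(py, log_base).sum())
    pxpy = px[:, None] * py[None, :]
    # HXY1 = -sum p log(px py); HXY2 = -sum px py log(px py); 0 log 0 = 0
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log(pxpy), 0.0)
    if log_base != np.e:
        log_pxpy = log_pxpy / np.log(log_base)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-(pxpy * log_pxpy).sum())
    denom = max(hx, hy)
    stats["Information_measure_of_correlation1"] = (
        (hxy - hxy1) / denom if denom > 0 else 0.0
    )
    stats["Information_measure_of_correlation2"] = float(
        np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))
    )
    stats["Inverse_difference_normalized"] = float(
        (p / (1.0 + np.abs(i - j) / ng)).sum()
    )
    stats["Inverse_difference_moment_normalized"] = float(
        (p / (1.0 + ((i - j) / ng) ** 2)).sum()
    )
    return stats


def fos_statistics(
    roi_values: np.ndarray, excess_kurtosis: bool = False
) -> dict[str, float]:
    """The 20 first-order statistics of the raw ROI intensities."""
    v = np.asarray(roi_values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty ROI")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    centered = v - mean
    m2 = float((centered**2).mean())
    if m2 == 0.0:
        skew = 0.0
        kurt = 0.0 if not excess_kurtosis else 0.0
    else:
        skew = float((centered**3).mean() / m2**1.5)
        kurt = float((centered**4).mean() / m2**2)
        if excess_kurtosis:
            kurt -= 3.0
    q = np.percentile(v, [1, 5, 10, 15, 20, 25, 50, 75, 80, 85, 90, 95, 99])
    p1, p5, p10, p15, p20, p25, p50, p75, p80, p85, p90, p95, p99 = map(float, q)
    vmin, vmax = float(v.min()), float(v.max())
    return {
        "Mean": mean,
        "Standard_deviation": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Minimum": vmin,
        "5th_percentile": p5,
        "10th_percentile": p10,
        "15th_percentile": p15,
        "20th_percentile": p20,
        "25th_percentile": p25,
        "Median": p50,
        "75th_percentile": p75,
        "80th_percentile": p80,
        "85th_percentile": p85,
        "90th_percentile": p90,
        "95th_percentile": p95,
        "Maximum": vmax,
        "Range_all": vmax - vmin,
        "Range5": p95 - p5,
        "Range2": p99 - p1,
    }


def extract_features(
    pixels: np.ndarray,
    roi: ROIMask | np.ndarray,
    config: FeatureConfig | None = None,
    image_id: str = "",
) -> pd.Series:
    """The full ordered 130-feature vector for one image.

    GLCM statistics are computed on the quantized ROI at each configured
    distance; FOS statistics on the raw ROI intensities. Raises
    :class:`EmptyGLCMError` (tagged with the image id) if the ROI admits no
    pixel pair at some distance.
    """
    config = config or FeatureConfig()
    mask = roi.mask if isinstance(roi, ROIMask) else np.asarray(roi, dtype=bool)
    q = quantize(pixels, mask, config.n_levels)
    values: dict[str, float] = {}
    for d in config.distances:
        try:
            G = compute_glcm(q, d, symmetric=config.symmetric)
        except EmptyGLCMError as exc:
            raise EmptyGLCMError(f"{exc} (image {image_id or '<unnamed>'})") from exc
        for stat, val in glcm_statistics(G, log_base=config.log_base).items():
            values[f"{stat}_{d}"] = val
    values.update(
        fos_statistics(np.asarray(pixels)[mask], excess_kurtosis=config.excess_kurtosis)
    )
    out = pd.Series(values, name=image_id or None)
    expected = tuple(
        f"{s}_{d}" for s in GLCM_STAT_NAMES for d in config.distances
    ) + FOS_NAMES
    return out.reindex(expected)


class RadiomicFeatureExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer mapping (image, ROI) pairs to the 130-feature
    table.

    Parameters
    ----------
    n_levels : int, default 8
        Gray-level quantization bins for the co-occurrence matrices.
    distances : tuple of int, default (1, 3, 5, 9, 11)
        Pixel distances of the co-occurrence offsets.
    symmetric : bool, default True
        Count each pixel pair in both orders.
    log_base : float, default e
        Base of the entropy logarithms.
    excess_kurtosis : bool, default False
        Report kurtosis as excess (normal = 0) instead of non-excess.

    The transformer is stateless: ``fit`` only validates parameters.
    """

    def __init__(
        self,
        n_levels: int = 8,
        distances: tuple[int, ...] = DISTANCES,
        symmetric: bool = True,
        log_base: float = np.e,
        excess_kurtosis: bool = False,
    ):
        self.n_levels = n_levels
        self.distances = distances
        self.symmetric = symmetric
        self.log_base = log_base
        self.excess_kurtosis = excess_kurtosis

    def _config(self) -> FeatureConfig:
        return FeatureConfig(
            n_levels=self.n_levels,
            distances=tuple(self.distances),
            symmetric=self.symmetric,
            log_base=self.log_base,
            excess_kurtosis=self.excess_kurtosis,
        )

    def fit(self, X, y=None):
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        self.n_features_out_ = len(self.get_feature_names_out())
        return self

    def transform(self, X) -> pd.DataFrame:
        """X: iterable of (pixels, roi) pairs or of (pixels, roi, image_id)
        triples. Returns one feature row per image."""
        config = self._config()
        rows = []
        for item in X:
            pixels, roi, *rest = item
            image_id = rest[0] if rest else ""
            rows.append(extract_features(pixels, roi, config, image_id=image_id))
        return pd.DataFrame(rows)

    def get_feature_names_out(self, input_features=None):
        names = tuple(
            f"{s}_{d}" for s in GLCM_STAT_NAMES for d in tuple(self.distances)
        ) + FOS_NAMES
        return np.asarray(names, dtype=object)
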