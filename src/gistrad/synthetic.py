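"""Synthetic mammography-gist cohorts.

Real screening mammograms and the multi-observer gist experiment behind this
analysis are proprietary, so this module generates a stand-in cohort with the
statistical structure the downstream pipeline assumes:

* a breast-shaped bright foreground (half-ellipse touching the chest-wall
  edge) on a dark background, so that intensity thresholding at gray level
  100 recovers the breast;
* controllable interior texture — correlated Gaussian noise whose spread and
  asymmetry increase with a hidden per-image "latent gist" score, so that
  first-order spread/skew and GLCM cluster-shade features genuinely differ
  between strong- and weak-gist images;
* eight image categories mirroring the screening study design (current
  normals, current cancers, priors at several intervals, and the
  missed / visible / invisible grades of retrospectively reviewed priors);
* a 13-observer score panel per image: each observer reports the latent gist
  plus Gaussian noise, clipped to the 0-100 slider range.

Everything is deterministic given ``SyntheticParams.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm

logger = logging.getLogger(__name__)

#: The eight image categories. Missed / Prior-Visible / Prior-Invisible are
#: retrospective grades of two-year priors; the synthetic cohort treats all
#: eight as disjoint strata. Prior-3 is too rare to form its own model and
#: only ever appears inside the pooled "All" dataset downstream.
CATEGORIES: tuple[str, ...] = (
    "Normal",
    "Cancer",
    "Prior-1",
    "Prior-2",
    "Prior-3",
    "Missed",
    "Prior-Visible",
    "Prior-Invisible",
)

#: Names of the eight per-category classification datasets ("All" pools
#: every labeled image, including Prior-3 members).
MODEL_CATEGORIES: tuple[str, ...] = (
    "All",
    "Normal",
    "Cancer",
    "Prior-1",
    "Prior-2",
    "Missed",
    "Prior-Visible",
    "Prior-Invisible",
)

# Relative cohort sizes of the eight image types in the screening study this
# generator emulates, treated as disjoint stratum weights.
_DEFAULT_TYPE_COUNTS = {
    "Normal": 1409,
    "Cancer": 923,
    "Prior-1": 1438,
    "Prior-2": 419,
    "Prior-3": 2,
    "Missed": 375,
    "Prior-Visible": 308,
    "Prior-Invisible": 755,
}

#: Probability that an image of a given category draws its latent gist from
#: the high component of the mixture; taken from the published per-category
#: high/(high+low) quartile fractions (Prior-3 has no printed split -> 0.5).
DEFAULT_HIGH_WEIGHTS = {
    "Normal": 162 / 659,
    "Cancer": 545 / 616,
    "Prior-1": 268 / 638,
    "Prior-2": 73 / 183,
    "Prior-3": 0.5,
    "Missed": 117 / 197,
    "Prior-Visible": 59 / 127,
    "Prior-Invisible": 92 / 314,
}


def _default_category_mix() -> dict[str, float]:
    total = sum(_DEFAULT_TYPE_COUNTS.values())
    return {k: v / total for k, v in _DEFAULT_TYPE_COUNTS.items()}


@dataclass(frozen=True)
class TextureEffect:
    """Per-family texture shifts applied in proportion to latent gist.

    ``cluster_shade_shift`` and ``skew_shift`` are dimensionless asymmetry
    coefficients (quadratic distortion of the correlated / white noise
    component respectively); ``spread_shift`` is in gray levels added to the
    foreground standard deviation at latent gist 100.

    The defaults are calibrated so that each channel plants a comparable
    standardized shift (Cohen's d, latent 100 vs 0 groups) on its signature
    feature — cluster shade, foreground standard deviation, skewness — so no
    single channel swamps the others in downstream feature importance.
    """

    cluster_shade_shift: float = 0.5
    spread_shift: float = 3.0
    skew_shift: float = 0.2

    @classmethod
    def zero(cls) -> "TextureEffect":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SyntheticParams:
    """Study-design constants and generator knobs for a synthetic cohort."""

    n_images: int = 4191
    category_mix: dict[str, float] = field(default_factory=_default_category_mix)
    texture_effect: TextureEffect = field(default_factory=TextureEffect)
    observer_count: int = 13
    observer_noise_sd: float = 10.0
    image_shape: tuple[int, int] = (128, 128)
    background_level: int = 40
    seed: int = 0
    high_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HIGH_WEIGHTS)
    )

    def __post_init__(self) -> None:
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1 within 1e-9")
        unknown = set(self.category_mix) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in mix: {sorted(unknown)}")
        if not self.background_level < 100:
            raise ValueError("background_level must be < 100")
        if self.observer_noise_sd < 0:
            raise ValueError("observer_noise_sd must be >= 0")


@dataclass
class CohortImage:
    """One grayscale image with its metadata.

    ``latent_gist`` is synthetic ground truth: the hidden 0-100 strength of
    the gist signal that drives both the planted texture and the observer
    panel. The analysis pipeline never reads it.
    """

    image_id: str
    pixels: np.ndarray
    laterality: str
    category: str
    latent_gist: float

    def __post_init__(self) -> None:
        if self.laterality not in ("L", "R"):
            raise ValueError(f"laterality must be 'L' or 'R', got {self.laterality!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class GistPanel:
    """Observer gist scores for one image and their average."""

    image_id: str
    scores: np.ndarray
    mean_score: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size == 0:
            raise ValueError("panel needs at least one observer score")
        if self.scores.min() < 0 or self.scores.max() > 100:
            raise ValueError("observer scores must lie in [0, 100]")
        if abs(self.mean_score - self.scores.mean()) > 1e-9:
            raise ValueError("mean_score does not match the scores")


# texture model constants: foreground mean intensity, baseline spread, the
# Gaussian smoothing width of the correlated component, and the fraction of
# the field variance carried by the correlated component.
_FG_MEAN = 170.0
_FG_BASE_SD = 12.0
_SMOOTH_SIGMA = 2.0
_CORRELATED_WEIGHT = 0.6


def _breast_mask(shape: tuple[int, int], laterality: str) -> np.ndarray:
    """Half-ellipse foreground touching the chest-wall edge."""
    rows, cols = shape
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    b = 0.45 * rows  # vertical semi-axis
    a = 0.70 * cols  # horizontal semi-axis
    x = c if laterality == "L" else (cols - 1 - c)
    return ((r - rows / 2) / b) ** 2 + (x / a) ** 2 <= 1.0


def generate_image(
    params: SyntheticParams,
    category: str,
    latent_gist: float,
    rng: np.random.Generator,
    image_id: str = "img",
    laterality: str | None = None,
) -> CohortImage:
    """Generate one synthetic mammogram-like image.

    The foreground is correlated Gaussian noise: a smoothed white-noise field
    (unit variance after smoothing) mixed with an independent white component.
    A quadratic distortion ``y = z + a (z^2 - 1)`` skews each component in
    proportion to ``latent_gist / 100``, and the planted spread shift scales
    the overall standard deviation. Foreground pixels are clipped to
    [100, 255], background to [0, 99], so that thresholding at 100 exactly
    recovers the breast.
    """
    rows, cols = params.image_shape
    if rows < 64 or cols < 64:
        raise ValueError(f"image_shape {params.image_shape} too small; need >= 64x64")
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if laterality is None:
        laterality = "L" if rng.random() < 0.5 else "R"

    t = float(latent_gist) / 100.0
    eff = params.texture_effect

    zc = ndimage.gaussian_filter(
        rng.standard_normal((rows, cols)), _SMOOTH_SIGMA, mode="reflect"
    )
    zc /= zc.std() or 1.0
    zw = rng.standard_normal((rows, cols))

    yc = zc + (eff.cluster_shade_shift * t) * (zc**2 - 1.0)
    yw = zw + (eff.skew_shift * t) * (zw**2 - 1.0)
    fld = np.sqrt(_CORRELATED_WEIGHT) * yc + np.sqrt(1 - _CORRELATED_WEIGHT) * yw

    sd = _FG_BASE_SD + eff.spread_shift * t
    foreground = np.clip(np.rint(_FG_MEAN + sd * fld), 100, 255)

    background = np.clip(
        np.rint(params.background_level + 5.0 * rng.standard_normal((rows, cols))),
        0,
        99,
    )

    mask = _breast_mask((rows, cols), laterality)
    pixels = np.where(mask, foreground, background).astype(np.uint8)
    return CohortImage(
        image_id=image_id,
        pixels=pixels,
        laterality=laterality,
        category=category,
        latent_gist=float(latent_gist),
    )


def generate_panel(
    image: CohortImage, params: SyntheticParams, rng: np.random.Generator
) -> GistPanel:
    """Simulate the observer panel: latent gist plus Gaussian noise, clipped
    to the bounded 0-100 slider."""
    if not 0.0 <= image.latent_gist <= 100.0:
        raise ValueError("latent_gist must be in [0, 100]")
    noise = rng.normal(0.0, params.observer_noise_sd, size=params.observer_count)
    scores = np.clip(image.latent_gist + noise, 0.0, 100.0)
    return GistPanel(image_id=image.image_id, scores=scores, mean_score=scores.mean())


def _draw_latent_gist(
    category: str, high_weights: dict[str, float], rng: np.random.Generator
) -> float:
    """Two-component latent gist mixture: truncated Gaussians at 25 and 75
    (sd 10, truncated to [0, 100]) with category-specific high weight."""
    mean = 75.0 if rng.random() < high_weights.get(category, 0.5) else 25.0
    a, b = (0.0 - mean) / 10.0, (100.0 - mean) / 10.0
    return float(truncnorm.rvs(a, b, loc=mean, scale=10.0, random_state=rng))


def generate_cohort(
    params: SyntheticParams,
) -> tuple[list[CohortImage], list[GistPanel], dict]:
    """Generate the full cohort: images, observer panels, and a manifest.

    The manifest dict records every generator parameter plus a per-image
    table (image_id, laterality, category, latent_gist) as a DataFrame under
    ``"records"``. Identical params (including seed) give bit-identical
    cohorts.
    """
    if params.n_images < 8:
        raise ValueError("n_images must be >= 8")
    nonzero = [c for c, w in params.category_mix.items() if w > 0]
    if len(nonzero) == 1:
        logger.warning("degenerate category_mix: all mass on %s", nonzero[0])

    rng = np.random.default_rng(params.seed)
    cats = list(params.category_mix)
    probs = np.array([params.category_mix[c] for c in cats])
    width = len(str(params.n_images))

    images: list[CohortImage] = []
    panels: list[GistPanel] = []
    rows = []
    for i in range(params.n_images):
        category = cats[rng.choice(len(cats), p=probs)]
        latent = _draw_latent_gist(category, params.high_weights, rng)
        image_id = f"img{i:0{width}d}"
        img = generate_image(params, category, latent, rng, image_id=image_id)
        panel = generate_panel(img, params, rng)
        images.append(img)
        panels.append(panel)
        rows.append(
            {
                "image_id": image_id,
                "laterality": img.laterality,
                "category": category,
                "latent_gist": latent,
            }
        )

    manifest = {
        "params": _params_dict(params),
        "records": pd.DataFrame(rows),
    }
    return images, panels, manifest


def _params_dict(params: SyntheticParams) -> dict:
    d = asdict(params)
    d["image_shape"] = list(params.image_shape)
    return d


def panels_to_frame(panels: Sequence[GistPanel]) -> pd.DataFrame:
    """Panel table: image_id, observer_1..observer_k, mean_score."""
    k = len(panels[0].scores)
    rows = []
    for p in panels:
        row = {"image_id": p.image_id}
        row.update({f"observer_{o + 1}": p.scores[o] for o in range(k)})
        row["mean_score"] = p.mean_score
        rows.append(row)
    return pd.DataFrame(rows)
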