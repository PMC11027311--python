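"""Gist labeling: panel averaging, quartile split, per-category datasets.

The gist signal is noisy, so each image's 13 observer scores are averaged
into one score. High- and low-gist classes are the top and bottom quartiles
of the averaged scores over the full pool; the middle half is excluded
(kept, labeled ``excluded``, never silently dropped). Quartiles are
rank-based — the ceil(n/4) highest and lowest scoring images — which on a
pool of 4191 distinct scores gives exactly 1048 high and 1048 low and is
deterministic under ties (broken by ascending image id). The split is
computed once on the full pool; the eight per-category datasets are subsets
of it ("All" pools everything, including Prior-3 members, which are too few
to form their own category model).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .synthetic import MODEL_CATEGORIES, GistPanel

LABELS = ("high", "low", "excluded")


def average_panel(panel: GistPanel) -> float:
    """Arithmetic mean of the observer scores."""
    scores = np.asarray(panel.scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty observer panel")
    return float(scores.mean())


def quartile_split(mean_scores: pd.Series) -> pd.Series:
    """Label each image high / low / excluded by rank-based quartiles.

    The ceil(n/4) highest-scoring images are ``high``, the ceil(n/4) lowest
    are ``low``, the remainder ``excluded``. Images are ranked by
    (mean score, image id), so ties at a cut are broken by ascending image
    id and the split is deterministic.
    """
    mean_scores = pd.Series(mean_scores, dtype=float)
    n = len(mean_scores)
    if n < 4:
        raise ValueError(f"need at least 4 images to form quartiles, got {n}")
    if mean_scores.index.has_duplicates:
        raise ValueError("duplicate image ids in score pool")
    k = math.ceil(n / 4)
    # stable rank by (score, image_id): sort by id first, then stably by score
    order = mean_scores.sort_index(kind="mergesort").sort_values(kind="mergesort")
    labels = pd.Series("excluded", index=order.index, dtype=object)
    labels.iloc[:k] = "low"
    labels.iloc[n - k :] = "high"
    return labels.reindex(mean_scores.index)


def label_panels(panels: list[GistPanel], categories: pd.Series) -> pd.DataFrame:
    """Labels table (image_id, category, mean_score, label) from raw panels."""
    means = pd.Series(
        {p.image_id: average_panel(p) for p in panels}, name="mean_score"
    )
    labels = quartile_split(means)
    return pd.DataFrame(
        {
            "image_id": means.index,
            "category": categories.reindex(means.index).to_numpy(),
            "mean_score": means.to_numpy(),
            "label": labels.to_numpy(),
        }
    ).reset_index(drop=True)


def build_category_datasets(
    samples: pd.DataFrame, feature_table: pd.DataFrame
) -> dict[str, tuple[pd.DataFrame, pd.Series]]:
    """Materialize the eight (features, labels) classification datasets.

    ``samples`` must have columns image_id, category, label; ``feature_table``
    is indexed by image_id. "All" contains every non-excluded image; each of
    the seven category datasets filters by its category. Raises if any
    labeled image lacks a feature row.
    """
    labeled = samples[samples["label"].isin(("high", "low"))]
    missing = [i for i in labeled["image_id"] if i not in feature_table.index]
    if missing:
        raise KeyError(f"missing feature rows for image_ids: {missing[:10]}")
    datasets: dict[str, tuple[pd.DataFrame, pd.Series]] = {}
    for name in MODEL_CATEGORIES:
        sub = labeled if name == "All" else labeled[labeled["category"] == name]
        X = feature_table.loc[sub["image_id"]]
        y = pd.Series(
            sub["label"].to_numpy(), index=sub["image_id"].to_numpy(), name="label"
        )
        datasets[name] = (X, y)
    return datasets
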