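"""Scree-test selection of important features and family grouping.

A model's 130 importance scores are sorted descending and the "important"
features are those before the elbow. The elbow rule is parameter-free: cut
at the first occurrence of the largest consecutive gap in the sorted scores.
Selected features are grouped into base-feature families by stripping the
pixel-distance suffix from GLCM names and pooling the three range variants,
so results can be summarized across the eight category models.

The package ships the importance scores published for the eight mammography
gist classifiers (``load_reported_importances``); the gap rule reproduces
six of the eight published scree counts on those rounded scores (the Missed
and Prior-Invisible elbows were identified visually and no simple gap rule
recovers them — a documented divergence).
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import DISTANCES, FOS_NAMES, GLCM_STAT_NAMES

#: Model column names in the shipped reference table.
REPORTED_MODELS = (
    "All",
    "Normal",
    "Cancer",
    "Missed",
    "Prior-Visible",
    "Prior-Invisible",
    "Prior-1",
    "Prior-2",
)


@dataclass
class ScreeSelection:
    ordered_features: list[str]
    gaps: np.ndarray
    cut_index: int
    selected: list[str]
    families: set[str]


def scree_select(importance: pd.Series) -> ScreeSelection:
    """Select important features by the largest-gap elbow rule.

    Scores are sorted descending (ties keep the input feature order); the
    cut falls after the rank at which the first occurrence of the maximum
    consecutive gap appears. If all scores are equal there is no elbow and
    every feature is selected.
    """
    importance = pd.Series(importance, dtype=float)
    if importance.isna().any() or not np.isfinite(importance.to_numpy()).all():
        raise ValueError("importance scores must be finite")
    if (importance < 0).any():
        raise ValueError("importance scores must be non-negative")
    v = importance.to_numpy()
    order = np.lexsort((np.arange(len(v)), -v))
    ordered = [importance.index[i] for i in order]
    s = v[order]
    gaps = s[:-1] - s[1:]
    if gaps.size == 0 or gaps.max() == 0:
        cut = len(v)  # flat scree: no elbow, keep everything
    else:
        cut = int(np.argmax(gaps)) + 1
    selected = ordered[:cut]
    return ScreeSelection(
        ordered_features=ordered,
        gaps=gaps,
        cut_index=cut,
        selected=selected,
        families=group_families(selected),
    )


_GLCM_NAME_RE = re.compile(
    r"^(?P<base>" + "|".join(map(re.escape, GLCM_STAT_NAMES)) + r")_(?P<d>\d+)$"
)


def group_families(feature_names) -> set[str]:
    """Distinct base-feature families of a feature-name collection.

    GLCM names drop their pixel-distance suffix (Cluster_shade_9 ->
    Cluster_shade); the three range variants pool into Range; other FOS
    names map to themselves.
    """
    families: set[str] = set()
    for name in feature_names:
        m = _GLCM_NAME_RE.match(name)
        if m:
            if int(m.group("d")) not in DISTANCES:
                raise ValueError(f"unknown feature name {name!r}")
            families.add(m.group("base"))
        elif name in ("Range_all", "Range5", "Range2"):
            families.add("Range")
        elif name in FOS_NAMES:
            families.add(name)
        else:
            raise ValueError(f"unknown feature name {name!r}")
    return families


def cross_model_summary(selections: dict[str, ScreeSelection]) -> pd.DataFrame:
    """How many models selected each feature family, sorted descending."""
    counts: dict[str, int] = {}
    for sel in selections.values():
        for fam in sel.families:
            counts[fam] = counts.get(fam, 0) + 1
    out = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["family", "n_models"],
    )
    return out


def load_reported_importances() -> pd.DataFrame:
    """The published 130 x 8 importance-score table.

    Indexed by feature name; one column per model plus ``flag_<model>``
    boolean columns marking the features the original analysis highlighted
    as important.
    """
    ref = importlib.resources.files("gistrad.data").joinpath(
        "reported_importances.csv"
    )
    with ref.open() as f:
        df = pd.read_csv(f, index_col="feature")
    for m in REPORTED_MODELS:
        df[f"flag_{m}"] = df[f"flag_{m}"].astype(bool)
    return df


def reported_flagged_features(df: pd.DataFrame | None = None) -> list[str]:
    """Features highlighted as important in at least one published model."""
    df = load_reported_importances() if df is None else df
    flags = df[[f"flag_{m}" for m in REPORTED_MODELS]].any(axis=1)
    return df.index[flags].tolist()
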