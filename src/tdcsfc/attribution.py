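"""Shapley attribution for the linear classifier and regional aggregation.

For a linear model under feature independence, the Shapley value of feature
j for subject i is exactly ``w_j * (x_ij - background_j)`` (log-odds units),
where the background is the per-feature reference (training-fold means).
Voxels are ranked by mean absolute attribution, the top K selected, and each
atlas region scored by the percentage of selected voxels it contributes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .connectivity import FeatureVector
from .model_eval import LinearModel

__all__ = [
    "ShapMatrix",
    "RegionContribution",
    "linear_shap",
    "top_k_voxels",
    "region_contributions",
]

DEFAULT_TOP_K = 1000


@dataclass
class ShapMatrix:
    """Per-subject x per-feature attributions in log-odds units."""

    values: np.ndarray
    background_mean: np.ndarray

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)


@dataclass
class RegionContribution:
    region_label: int
    region_name: str
    n_top_voxels: int
    percent: float


def linear_shap(
    model: LinearModel, X: np.ndarray, background: np.ndarray
) -> ShapMatrix:
    """Exact Shapley values of a linear model with independent features.

    Satisfies local accuracy: per subject the attributions sum to
    ``margin(x) - margin(background)``.
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.weights):
        raise ValueError(
            f"feature matrix width {X.shape[-1]} does not match "
            f"{len(model.weights)} model weights"
        )
    if background.shape != (X.shape[1],):
        raise ValueError("background length does not match feature count")
    values = (X - background) * model.weights
    return ShapMatrix(values=values, background_mean=background)


def top_k_voxels(shap: ShapMatrix, k: int = DEFAULT_TOP_K):
    """Indices (and scores) of the k features with the largest mean absolute
    attribution; ties break by canonical feature index."""
    if k <= 0:
        raise ValueError("k must be positive")
    scores = shap.mean_abs()
    if k > len(scores):
        raise ValueError(f"k={k} exceeds {len(scores)} features")
    # stable sort on (-score, index): equal scores keep canonical order
    order = np.argsort(-scores, kind="stable")
    top = order[:k]
    return top, scores[top]


def region_contributions(
    voxel_indices: np.ndarray,
    feature_vector: FeatureVector,
    names: Optional[dict[int, str]] = None,
) -> list[RegionContribution]:
    """Percentage of the selected voxels belonging to each region, sorted
    descending.  Indices outside the feature map count as 'unassigned';
    percentages sum to 100."""
    voxel_indices = np.asarray(voxel_indices)
    k = len(voxel_indices)
    labels = feature_vector.region_labels
    counts: dict[int, int] = {}
    unassigned = 0
    for idx in voxel_indices:
        if 0 <= idx < len(labels):
            lab = int(labels[idx])
            counts[lab] = counts.get(lab, 0) + 1
        else:
            unassigned += 1
    out = [
        RegionContribution(
            region_label=lab,
            region_name=(names or {}).get(lab, f"region_{lab:02d}"),
            n_top_voxels=c,
            percent=100.0 * c / k,
        )
        for lab, c in counts.items()
    ]
    if unassigned:
        out.append(
            RegionContribution(-1, "unassigned", unassigned, 100.0 * unassigned / k)
        )
    out.sort(key=lambda r: (-r.percent, r.region_label))
    return out


def contributions_table(contribs: Sequence[RegionContribution]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_label": c.region_label,
                "region": c.region_name,
                "n_top_voxels": c.n_top_voxels,
                "percent": c.percent,
            }
            for c in contribs
        ]
    )
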