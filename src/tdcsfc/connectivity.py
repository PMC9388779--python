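"""Seed-based functional connectivity: sphere ROI, Fisher-Z map, features.

The seed is a sphere (default 15 mm radius at MNI (-48, 0, 0), the left
superior temporal gyrus).  Its mean time series is correlated with every
voxel's series; the Pearson r map is variance-stabilized with the Fisher Z
transform and atlas-masked into a deterministic feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import AtlasParcellation, BoldSeries, FCMap

__all__ = [
    "SeedSpec",
    "FeatureVector",
    "make_sphere_mask",
    "seed_fc_map",
    "fisher_z",
    "extract_roi_features",
    "scatter_features",
]

#: correlations are clamped to +/-(1 - R_CLAMP_EPS) before arctanh
R_CLAMP_EPS = 1e-7

#: minimum number of non-censored volumes for a stable correlation
MIN_VOLUMES = 10


@dataclass(frozen=True)
class SeedSpec:
    """Spherical seed ROI in mm coordinates."""

    center_mni_mm: tuple[float, float, float] = (-48.0, 0.0, 0.0)
    radius_mm: float = 15.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass
class FeatureVector:
    """Atlas-masked FC features in canonical order.

    Ordering is region label ascending, then voxel raster (C) order within a
    region; ``region_labels`` and ``voxel_coords`` map each feature back to
    its region and voxel for attribution.
    """

    values: np.ndarray
    region_labels: np.ndarray  # per-feature atlas label
    voxel_coords: np.ndarray  # per-feature (i, j, k)
    subject_id: str = ""

    def __len__(self) -> int:
        return len(self.values)


def make_sphere_mask(
    seed: SeedSpec, grid_dims: Sequence[int], affine: np.ndarray
) -> np.ndarray:
    """Boolean mask of voxels whose *center* lies within the seed sphere."""
    idx = np.indices(tuple(grid_dims), dtype=float)
    coords = np.einsum("ij,j...->...i", affine[:3, :3], idx) + affine[:3, 3]
    dist = np.sqrt(((coords - np.asarray(seed.center_mni_mm)) ** 2).sum(axis=-1))
    mask = dist <= seed.radius_mm
    if not mask.any():
        raise ValueError("seed sphere contains no voxel centers on this grid")
    return mask


def fisher_z(r) -> np.ndarray:
    """Fisher Z transform z = arctanh(r), with r clamped to keep z finite."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("|r| must be <= 1")
    clamped = np.clip(r, -(1 - R_CLAMP_EPS), 1 - R_CLAMP_EPS)
    return np.arctanh(clamped)


def seed_fc_map(
    bold: BoldSeries,
    seed_mask: np.ndarray,
    censor_mask: Optional[np.ndarray] = None,
    seed: Optional[SeedSpec] = None,
) -> FCMap:
    """Voxelwise Fisher-Z correlation with the seed-mean time series.

    Censored volumes are dropped from the correlation; zero-variance voxels
    get z = 0 so the fixed-size 3D feature matrix is preserved.
    """
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    keep = np.ones(bold.n_volumes, dtype=bool)
    if censor_mask is not None:
        censor_mask = np.asarray(censor_mask, dtype=bool)
        if censor_mask.shape[0] != bold.n_volumes:
            raise ValueError("censor mask length does not match volumes")
        keep = ~censor_mask
    if int(keep.sum()) < MIN_VOLUMES:
        raise ValueError(
            f"only {int(keep.sum())} non-censored volumes; need >= {MIN_VOLUMES}"
        )

    data = bold.data[..., keep].reshape(-1, int(keep.sum())).astype(float)
    seed_series = data[seed_mask.ravel()].mean(axis=0)

    s = seed_series - seed_series.mean()
    s_norm = np.sqrt((s**2).sum())
    v = data - data.mean(axis=1, keepdims=True)
    v_norm = np.sqrt((v**2).sum(axis=1))
    ok = (v_norm > 0) & (s_norm > 0)
    r = np.zeros(data.shape[0])
    r[ok] = (v[ok] @ s) / (v_norm[ok] * s_norm)
    r = np.clip(r, -1.0, 1.0)  # guard rounding

    z = np.zeros(data.shape[0])
    z[ok] = fisher_z(r[ok])
    return FCMap(
        z_values=z.reshape(bold.grid_dims),
        affine=bold.affine,
        seed=seed,
        subject_id=bold.subject_id,
    )


def extract_roi_features(
    fcmap: FCMap, atlas: AtlasParcellation, region_labels: Sequence[int]
) -> FeatureVector:
    """Concatenate z-values of the selected regions in canonical order.

    The order is independent of the order in which ``region_labels`` is
    given: labels ascending, raster order within each label.
    """
    if fcmap.z_values.shape != atlas.labels.shape:
        raise ValueError("FC map and atlas grids differ")
    labels = sorted(set(int(l) for l in region_labels))
    if not labels:
        raise ValueError("no regions selected")
    for lab in labels:
        if lab not in atlas.names:
            raise ValueError(f"unknown atlas label {lab}")

    values, feat_labels, coords = [], [], []
    for lab in labels:
        mask = atlas.labels == lab
        ijk = np.argwhere(mask)  # raster (C) order
        values.append(fcmap.z_values[mask])
        feat_labels.append(np.full(len(ijk), lab, dtype=np.int32))
        coords.append(ijk)
    return FeatureVector(
        values=np.concatenate(values),
        region_labels=np.concatenate(feat_labels),
        voxel_coords=np.concatenate(coords),
        subject_id=fcmap.subject_id,
    )


def scatter_features(fv: FeatureVector, grid_dims: Sequence[int]) -> np.ndarray:
    """Scatter a feature vector back onto the 3D grid (round-trip check)."""
    vol = np.zeros(tuple(grid_dims))
    vol[tuple(fv.voxel_coords.T)] = fv.values
    return vol
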