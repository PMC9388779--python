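"""Core in-memory containers shared across the pipeline stages.

Volumes are kept as plain numpy arrays with a NIfTI-style 4x4 RAS affine;
:mod:`tdcsfc.io` converts to and from :class:`nibabel.Nifti1Image`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "BoldSeries",
    "AtlasParcellation",
    "FCMap",
    "SubjectRecord",
    "composite_motion",
]

#: Radius (mm) of the sphere used to convert rotational displacement to mm.
ROTATION_SPHERE_RADIUS_MM = 50.0


@dataclass
class BoldSeries:
    """One subject's 4D BOLD series.

    Parameters
    ----------
    data:
        Array of shape ``(X, Y, Z, T)``.
    affine:
        4x4 voxel-to-mm (RAS) affine shared with the atlas.
    tr_s:
        Repetition time in seconds.
    motion:
        Optional ``(T, 6)`` rigid-body parameter series
        (3 translations in mm, 3 rotations in radians).
    brain_mask:
        Optional boolean in-brain mask of shape ``(X, Y, Z)``; when absent,
        the global signal is computed over all voxels.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float
    motion: Optional[np.ndarray] = None
    brain_mask: Optional[np.ndarray] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape[0] != self.n_volumes:
                raise ValueError(
                    f"motion series length {self.motion.shape[0]} does not match "
                    f"{self.n_volumes} volumes"
                )

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def global_signal(self) -> np.ndarray:
        """Mean in-brain signal per volume, shape ``(T,)``."""
        if self.brain_mask is not None:
            vox = self.data[self.brain_mask]
        else:
            vox = self.data.reshape(-1, self.n_volumes)
        return vox.mean(axis=0)

    def copy_with(self, data: np.ndarray) -> "BoldSeries":
        return BoldSeries(
            data=data,
            affine=self.affine,
            tr_s=self.tr_s,
            motion=self.motion,
            brain_mask=self.brain_mask,
            subject_id=self.subject_id,
        )


def composite_motion(motion: np.ndarray) -> np.ndarray:
    """Scan-to-scan composite motion in mm, shape ``(T,)``.

    Defined as the maximum over the six rigid-body parameters of the absolute
    scan-to-scan displacement, with rotations converted to arc length on a
    50 mm sphere.  The first volume has composite motion 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim == 1:
        motion = motion[:, None]
    scale = np.ones(motion.shape[1])
    if motion.shape[1] == 6:
        scale[3:] = ROTATION_SPHERE_RADIUS_MM
    diffs = np.abs(np.diff(motion, axis=0)) * scale
    out = np.zeros(motion.shape[0])
    out[1:] = diffs.max(axis=1)
    return out


@dataclass
class AtlasParcellation:
    """Integer-labelled parcellation sharing a grid/affine with the BOLD data.

    ``labels == 0`` marks background (outside gray matter); every other label
    names one contiguous region via ``names``.
    """

    labels: np.ndarray
    affine: np.ndarray
    names: dict[int, str]
    seed_home_label: int

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D volume")
        if self.seed_home_label not in self.names:
            raise ValueError("seed_home_label missing from the name table")

    @property
    def region_labels(self) -> list[int]:
        return sorted(self.names)

    def region_mask(self, label: int) -> np.ndarray:
        if label not in self.names:
            raise ValueError(f"unknown atlas label {label}")
        return self.labels == label

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class FCMap:
    """Voxelwise Fisher-Z seed-connectivity map on the BOLD grid."""

    z_values: np.ndarray
    affine: np.ndarray
    seed: "object" = None  # SeedSpec; kept loose to avoid an import cycle
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.z_values.ndim != 3:
            raise ValueError("FC map must be a 3D volume")
        if not np.all(np.isfinite(self.z_values)):
            raise ValueError("FC map contains non-finite values")


@dataclass
class SubjectRecord:
    """Clinical/demographic covariates for one patient.

    ``sex`` is coded 1 = male, 0 = female.  Scores follow the clinical scales:
    SAPS/SANS (positive/negative symptoms), MADRS (depression) and the
    PSYRATS auditory-hallucination total whose pre/post change defines the
    responder label.  Missing covariates are ``nan`` and are mean-imputed by
    :func:`tdcsfc.model_eval.clinical_baseline_features`.
    """

    subject_id: str
    age: float
    sex: int
    education_years: float
    duration_untreated_months: float
    duration_illness_months: float
    olanzapine_equiv: float
    pre_saps: float
    pre_sans: float
    pre_madrs: float
    pre_psyrats: float
    post_psyrats: float
    intended_responder: Optional[bool] = None
    extras: dict = field(default_factory=dict)

    @property
    def percent_improvement(self) -> float:
        return 100.0 * (self.pre_psyrats - self.post_psyrats) / self.pre_psyrats

    @property
    def is_responder(self) -> bool:
        # >=25% PSYRATS-AH reduction ("at least a 25% reduction")
        return self.percent_improvement >= 25.0
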