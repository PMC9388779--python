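"""NIfTI / TSV / JSON serialization helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .types import AtlasParcellation, BoldSeries, FCMap, SubjectRecord

__all__ = [
    "save_bold",
    "load_bold",
    "save_atlas",
    "load_atlas",
    "save_fcmap",
    "records_to_table",
    "array_hash",
]


def save_bold(bold: BoldSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(bold.data, dtype=np.float32), bold.affine)
    img.header.set_zooms((*bold.voxel_size_mm, bold.tr_s))
    nib.save(img, str(path))


def load_bold(path: str | Path, motion: np.ndarray | None = None) -> BoldSeries:
    img = nib.load(str(path))
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 2.0
    return BoldSeries(
        data=np.asanyarray(img.dataobj).astype(np.float32),
        affine=img.affine.copy(),
        tr_s=tr,
        motion=motion,
        subject_id=Path(path).stem.split(".")[0],
    )


def save_atlas(atlas: AtlasParcellation, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine), str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
    meta = {
        "names": {str(k): v for k, v in atlas.names.items()},
        "seed_home_label": atlas.seed_home_label,
    }
    Path(f"{sidecar}.json").write_text(json.dumps(meta, indent=1))


def load_atlas(path: str | Path) -> AtlasParcellation:
    img = nib.load(str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")
    meta = json.loads(Path(f"{sidecar}.json").read_text())
    return AtlasParcellation(
        labels=np.asanyarray(img.dataobj).astype(np.int32),
        affine=img.affine.copy(),
        names={int(k): v for k, v in meta["names"].items()},
        seed_home_label=int(meta["seed_home_label"]),
    )


def save_fcmap(fcmap: FCMap, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(fcmap.z_values.astype(np.float32), fcmap.affine), str(path)
    )


def records_to_table(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "age": r.age,
            "sex": r.sex,
            "education_years": r.education_years,
            "duration_untreated_months": r.duration_untreated_months,
            "duration_illness_months": r.duration_illness_months,
            "olanzapine_equiv": r.olanzapine_equiv,
            "pre_saps": r.pre_saps,
            "pre_sans": r.pre_sans,
            "pre_madrs": r.pre_madrs,
            "pre_psyrats": r.pre_psyrats,
            "post_psyrats": r.post_psyrats,
            "is_responder": int(r.is_responder),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def array_hash(*arrays) -> str:
    """Stable sha256 over the bytes of the given arrays/strings."""
    h = hashlib.sha256()
    for a in arrays:
        if isinstance(a, str):
            h.update(a.encode())
        else:
            arr = np.ascontiguousarray(a)
            h.update(str(arr.dtype).encode())
            h.update(str(arr.shape).encode())
            h.update(arr.tobytes())
    return h.hexdigest()
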