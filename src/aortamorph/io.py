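"""Reading and writing of the pipeline's on-disk artifacts.

Masks travel as NIfTI-1 (spacing in the header/affine, world mm), landmarks
as JSON ``{"stj": [x, y, z], "bt": [x, y, z]}`` in world mm, plane-level
measurements as CSV and shape reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

PLANE_CSV_COLUMNS = [
    "patient_id", "phase", "segment", "plane_index", "s_mm", "d_max", "d_min", "area",
]


def save_mask(img: nib.Nifti1Image, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_mask(path) -> nib.Nifti1Image:
    return nib.load(str(path))


def save_landmarks(landmarks: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = {k: [float(x) for x in v] for k, v in landmarks.items()}
    path.write_text(json.dumps(out, indent=2))
    return path


def load_landmarks(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"landmark file not found: {path}")
    data = json.loads(path.read_text())
    for key in ("stj", "bt"):
        if key not in data:
            raise ValueError(f"landmark file {path} lacks key {key!r}")
    return {k: np.asarray(v, float) for k, v in data.items()}


def planes_to_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=PLANE_CSV_COLUMNS)
    return df


def save_planes_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.4f")
    return path


def save_json(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
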