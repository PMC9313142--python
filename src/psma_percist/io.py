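"""Readers, writers and pipeline configuration.

Volumes travel as NIfTI (.nii/.nii.gz) with the voxel spacing in the header;
tables as UTF-8 comma-separated CSV with a header row and "." decimals;
configuration and model reports as JSON.  Arrays are (z, y, x) in memory and
stored (x, y, z) in NIfTI, with a diagonal affine carrying the spacing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .quant import SuvVolume


class SchemaError(ValueError):
    """A table is missing required columns."""


def save_volume(volume: SuvVolume, path: str | Path) -> None:
    data = np.transpose(volume.values, (2, 1, 0))
    affine = np.diag([volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def load_volume(path: str | Path) -> SuvVolume:
    img = nib.load(str(path))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)).astype(float)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return SuvVolume(data, spacing)


def save_labels(labels: np.ndarray, spacing, path: str | Path) -> None:
    data = np.transpose(labels, (2, 1, 0))
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.int16), affine), str(path))


def load_labels(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)).astype(np.int32)


LESION_TABLE_COLUMNS = [
    "patient_id",
    "lesion_id",
    "site",
    "suv_peak_t0",
    "suv_peak_t1",
]
PATIENT_TABLE_COLUMNS = [
    "patient_id",
    "tl_psma_t0",
    "tl_psma_t1",
    "new_lesions",
    "psa_t0",
    "psa_t1",
]


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input table: {path}")
    df = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Configuration of the four-stage pipeline (simulate/quantify/respond/analyze).

    All thresholds are percentages on the natural scale of the respective
    definitions (30% imaging, 50%/25% biochemical) and are positive numbers.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    # simulate
    n_patients: int = 40
    n_phantom_patients: int = 2
    # quant
    peak_diameter_mm: float = 12.0
    aorta_diameter_mm: float = 10.0
    aorta_length_mm: float = 30.0
    min_volume_ml: float = 0.3
    connectivity: int = 26
    tl_mode: str = "per_lesion"
    # response
    imaging_threshold_pct: float = 30.0
    psa_reduction_pct: float = 50.0
    psa_increase_pct: float = 25.0
    match_tolerance_mm: float = 15.0
    # stats
    min_spec: float = 0.80
    bootstrap_B: int = 200
    alpha: float = 0.05
    cohort_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "imaging_threshold_pct",
            "psa_reduction_pct",
            "psa_increase_pct",
            "match_tolerance_mm",
            "min_volume_ml",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def write_manifest(path: str | Path, config: PipelineConfig, counts: dict) -> None:
    import statsmodels

    manifest = {
        "config": dataclasses.asdict(config),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "counts": counts,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
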