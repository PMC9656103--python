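"""Cohort directory and feature-matrix I/O.

Directory layout: one sub-directory per patient holding
``t2.nii.gz, adc.nii.gz, t2_mask.nii.gz, adc_mask.nii.gz, t2_norm.nii.gz,
adc_norm.nii.gz`` plus a top-level ``clinical.csv`` with columns
patient_id, age, psa, prostate_volume, psa_density, mean_adc, label.
Feature matrices are CSVs (patients x named features, full-precision
scientific notation) with a JSON sidecar recording provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ClinicalRecord, LesionStudy
from .volume import read_nifti, read_nifti_mask, write_nifti

__all__ = [
    "write_cohort",
    "read_cohort",
    "read_clinical_table",
    "write_feature_matrix",
    "read_feature_matrix",
]

_CLINICAL_COLUMNS = [
    "patient_id",
    "age",
    "psa",
    "prostate_volume",
    "psa_density",
    "mean_adc",
    "label",
]

_FILES = {
    "t2": "t2.nii.gz",
    "adc": "adc.nii.gz",
    "t2_lesion_mask": "t2_mask.nii.gz",
    "adc_lesion_mask": "adc_mask.nii.gz",
    "t2_norm_roi": "t2_norm.nii.gz",
    "adc_norm_roi": "adc_norm.nii.gz",
}


def write_cohort(studies: list[LesionStudy], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for study in studies:
        pdir = out / study.clinical.patient_id
        pdir.mkdir(exist_ok=True)
        for attr, fname in _FILES.items():
            write_nifti(getattr(study, attr), pdir / fname)
        rec = study.clinical
        rows.append(
            {
                "patient_id": rec.patient_id,
                "age": rec.age,
                "psa": rec.psa,
                "prostate_volume": rec.prostate_volume,
                "psa_density": rec.psa_density,
                "mean_adc": rec.mean_adc,
                "label": rec.label,
            }
        )
    pd.DataFrame(rows, columns=_CLINICAL_COLUMNS).to_csv(
        out / "clinical.csv", index=False, float_format="%.17g"
    )
    return out


def read_clinical_table(cohort_dir: str | Path) -> pd.DataFrame:
    path = Path(cohort_dir) / "clinical.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing clinical table: {path}")
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clinical.csv missing columns: {missing}")
    return table


def read_cohort(cohort_dir: str | Path) -> list[LesionStudy]:
    """Load a cohort directory; grid mismatches raise per-patient errors."""
    cohort_dir = Path(cohort_dir)
    table = read_clinical_table(cohort_dir)
    studies = []
    for _, row in table.iterrows():
        pid = str(row["patient_id"])
        pdir = cohort_dir / pid
        vols = {}
        for attr, fname in _FILES.items():
            path = pdir / fname
            if not path.exists():
                raise FileNotFoundError(f"patient {pid}: missing file {path}")
            vols[attr] = (
                read_nifti_mask(path) if "mask" in attr or "norm" in attr else read_nifti(path)
            )
        rec = ClinicalRecord(
            patient_id=pid,
            age=float(row["age"]),
            psa=float(row["psa"]),
            prostate_volume=float(row["prostate_volume"]),
            psa_density=float(row["psa_density"]),
            mean_adc=float(row["mean_adc"]),
            label=int(row["label"]),
        )
        try:
            studies.append(LesionStudy(clinical=rec, **vols))
        except ValueError as exc:
            raise ValueError(f"patient {pid}: {exc}") from exc
    return studies


def write_feature_matrix(
    features: pd.DataFrame, path: str | Path, sidecar: dict | None = None
) -> None:
    """Write patients x features CSV plus a JSON provenance sidecar."""
    path = Path(path)
    features.to_csv(path, index=True, index_label="patient_id", float_format="%.17g")
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps the %.17g formatted values bit-exact
    return pd.read_csv(path, index_col="patient_id", float_precision="round_trip")
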