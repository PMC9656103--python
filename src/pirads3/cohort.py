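"""Patient-level data structures: clinical record and lesion study."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import ImageVolume, MaskVolume

__all__ = ["ClinicalRecord", "LesionStudy", "CLINICAL_FEATURES"]

#: Clinical candidate features entering the selection pool alongside radiomics.
CLINICAL_FEATURES = ("age", "psa", "psa_density", "mean_adc")


@dataclass
class ClinicalRecord:
    """One patient's clinical data.

    ``label`` is 1 for clinically significant prostate cancer (Gleason score
    >= 3+4) and 0 otherwise; ``psa_density`` is PSA (ng/mL) divided by
    prostate volume (mL).
    """

    patient_id: str
    age: float
    psa: float
    prostate_volume: float
    psa_density: float
    mean_adc: float
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        for name in ("age", "psa", "prostate_volume", "psa_density", "mean_adc"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if not np.isclose(self.psa_density, self.psa / self.prostate_volume, rtol=1e-2):
            raise ValueError("psa_density inconsistent with psa / prostate_volume")

    def features(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in CLINICAL_FEATURES}


@dataclass
class LesionStudy:
    """One patient's images, lesion masks and normalization ROIs."""

    clinical: ClinicalRecord
    t2: ImageVolume
    adc: ImageVolume
    t2_lesion_mask: MaskVolume
    adc_lesion_mask: MaskVolume
    t2_norm_roi: MaskVolume
    adc_norm_roi: MaskVolume

    def __post_init__(self) -> None:
        for img, msk, roi, name in (
            (self.t2, self.t2_lesion_mask, self.t2_norm_roi, "t2"),
            (self.adc, self.adc_lesion_mask, self.adc_norm_roi, "adc"),
        ):
            if not img.same_grid(msk) or not img.same_grid(roi):
                raise ValueError(f"{name}: masks must share the image grid")
            if msk.n_voxels == 0:
                raise ValueError(f"{name}: lesion mask is empty")
            if np.any(msk.voxels & roi.voxels):
                raise ValueError(f"{name}: lesion and normalization ROI overlap")

    def modality(self, name: str) -> tuple[ImageVolume, MaskVolume, MaskVolume]:
        """(image, lesion mask, normalization ROI) for 't2' or 'adc'."""
        if name == "t2":
            return self.t2, self.t2_lesion_mask, self.t2_norm_roi
        if name == "adc":
            return self.adc, self.adc_lesion_mask, self.adc_norm_roi
        raise KeyError(f"unknown modality {name!r}")
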