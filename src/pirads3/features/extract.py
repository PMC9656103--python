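"""Per-patient feature extraction.

Feature names follow the grammar ``<modality>-<image>_<family>_<Feature>``,
e.g. ``T2-wavelet-LLL_glcm_InverseVariance``. The ``proposed`` preset yields
exactly 958 radiomic features per patient: for each of the two modalities,
107 features on the original image (14 shape + 18 first-order + 24 GLCM +
16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM) and 93 (no shape) on each of the
four wavelet sub-bands, 2 x (107 + 4 x 93) = 958.

Features that cannot be computed on a degenerate ROI are returned as NaN
sentinels and reported through the ``warnings`` list argument; downstream
selection excludes them.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from ..cohort import LesionStudy
from ..preprocess import (
    PreprocessPreset,
    normalize_by_reference_roi,
    normalize_range_mu3sigma,
    normalize_zscore,
    quantize_fbn,
    resample,
    resample_mask,
    wavelet_decompose,
)
from ..volume import ImageVolume, MaskVolume
from .firstorder import FIRSTORDER_FEATURE_NAMES, firstorder_features
from .glcm import GLCM_FEATURE_NAMES, build_glcm, glcm_features
from .gldm import GLDM_FEATURE_NAMES, build_gldm, gldm_features
from .glrlm import GLRLM_FEATURE_NAMES, build_glrlm, glrlm_features
from .glszm import GLSZM_FEATURE_NAMES, build_glszm, glszm_features
from .ngtdm import NGTDM_FEATURE_NAMES, build_ngtdm, ngtdm_features
from .shape import SHAPE_FEATURE_NAMES, shape_features

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_FAMILIES",
    "feature_name",
    "proposed_feature_names",
    "core_feature_names",
    "extract_feature_vector",
    "mean_adc_2d_roi",
    "HECTORS_FEATURES",
    "JIN_FEATURES",
]

FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "shape": SHAPE_FEATURE_NAMES,
    "firstorder": FIRSTORDER_FEATURE_NAMES,
    "glcm": GLCM_FEATURE_NAMES,
    "glrlm": GLRLM_FEATURE_NAMES,
    "glszm": GLSZM_FEATURE_NAMES,
    "gldm": GLDM_FEATURE_NAMES,
    "ngtdm": NGTDM_FEATURE_NAMES,
}

_TEXTURE_FAMILIES = ("glcm", "glrlm", "glszm", "gldm", "ngtdm")


def feature_name(modality: str, image: str, family: str, feature: str) -> str:
    return f"{modality}-{image}_{family}_{feature}"


def proposed_feature_names() -> list[str]:
    """The 958 radiomic feature names of the proposed preset, in order."""
    names: list[str] = []
    for mod in ("T2", "ADC"):
        for fam in FEATURE_FAMILIES:
            names += [feature_name(mod, "original", fam, f) for f in FEATURE_FAMILIES[fam]]
        for band in ("LLL", "LLH", "HHL", "HHH"):
            for fam in FEATURE_FAMILIES:
                if fam == "shape":
                    continue
                names += [
                    feature_name(mod, f"wavelet-{band}", fam, f)
                    for f in FEATURE_FAMILIES[fam]
                ]
    return names


def core_feature_names() -> list[str]:
    """Reduced radiomic inventory for desk-scale selection runs: the feature
    families the proposed model draws from, on the low-frequency band —
    T2-LLL GLCM (24) and ADC-LLL GLSZM (16) features."""
    return [
        feature_name("T2", "wavelet-LLL", "glcm", f) for f in FEATURE_FAMILIES["glcm"]
    ] + [
        feature_name("ADC", "wavelet-LLL", "glszm", f) for f in FEATURE_FAMILIES["glszm"]
    ]


#: Radiomic feature inventory of the re-implemented T2-based random-forest
#: model (20 features, all on the original T2 image).
HECTORS_FEATURES = (
    "T2-original_shape_Elongation",
    "T2-original_shape_Flatness",
    "T2-original_firstorder_10Percentile",
    "T2-original_firstorder_InterquartileRange",
    "T2-original_firstorder_Mean",
    "T2-original_firstorder_Median",
    "T2-original_firstorder_RootMeanSquared",
    "T2-original_glcm_Autocorrelation",
    "T2-original_glcm_DifferenceEntropy",
    "T2-original_glcm_InverseVariance",
    "T2-original_glcm_JointAverage",
    "T2-original_glcm_JointEnergy",
    "T2-original_gldm_LargeDependenceLowGrayLevelEmphasis",
    "T2-original_glrlm_LongRunEmphasis",
    "T2-original_glrlm_LongRunHighGrayLevelEmphasis",
    "T2-original_glszm_GrayLevelVariance",
    "T2-original_glszm_SizeZoneNonUniformity",
    "T2-original_glszm_SmallAreaEmphasis",
    "T2-original_ngtdm_Complexity",
    "T2-original_ngtdm_Strength",
)

#: Radiomic feature inventory of the re-implemented T2+DWI logistic model
#: (4 features); the ADC volume stands in for DWI.
JIN_FEATURES = (
    "T2-wavelet-HHL_glcm_ClusterTendency",
    "DWI-original_glcm_Idmn",
    "DWI-wavelet-LLL_glrlm_LongRunLowGrayLevelEmphasis",
    "DWI-wavelet-LLL_glszm_SizeZoneNonUniformityNormalized",
)


def _parse_requests(include: list[str] | None, preset: PreprocessPreset) -> dict | None:
    """Group requested names by (modality label, image, family); None = all."""
    if include is None:
        return None
    groups: dict[tuple[str, str, str], set[str]] = {}
    for name in include:
        head, family, feat = name.rsplit("_", 2)
        mod, image = head.split("-", 1)
        groups.setdefault((mod, image, family), set()).add(feat)
    return groups


def _compute_family(fam: str, q, image: ImageVolume, mask: MaskVolume, n_bins: int) -> dict[str, float]:
    if fam == "firstorder":
        return firstorder_features(image, mask, n_bins)
    if fam == "shape":
        return shape_features(mask)
    if fam == "glcm":
        return glcm_features(build_glcm(q))
    if fam == "glrlm":
        return glrlm_features(build_glrlm(q), q.n_voxels)
    if fam == "glszm":
        return glszm_features(build_glszm(q), q.n_voxels)
    if fam == "gldm":
        return gldm_features(build_gldm(q))
    if fam == "ngtdm":
        return ngtdm_features(*build_ngtdm(q))
    raise KeyError(fam)


def extract_feature_vector(
    study: LesionStudy,
    preset: PreprocessPreset,
    include: list[str] | None = None,
    warnings: list[str] | None = None,
) -> dict[str, float]:
    """Extract the radiomic feature vector of one patient.

    Parameters
    ----------
    study : LesionStudy
        Images, lesion masks and normalization ROIs for one patient.
    preset : PreprocessPreset
        Protocol preset controlling normalization, grids, bins and bands.
    include : list of str, optional
        Restrict computation to these feature names (families and derived
        images not requested are skipped entirely).
    warnings : list, optional
        Degenerate-feature messages are appended here; NaN sentinels mark the
        affected values in the returned mapping.

    Returns
    -------
    dict
        Ordered feature name -> value mapping; deterministic given inputs.
    """
    label_map = {"t2": "T2", "adc": "DWI" if preset.name == "jin" else "ADC"}
    requested = _parse_requests(include, preset)
    out: dict[str, float] = {}
    warn = warnings if warnings is not None else []

    for mod in preset.modalities:
        mod_label = label_map[mod]
        image, lesion, norm_roi = study.modality(mod)

        if preset.normalization == "reference_roi":
            image = normalize_by_reference_roi(image, norm_roi)
        elif preset.normalization == "mu3sigma":
            image = normalize_range_mu3sigma(image, lesion)
        elif preset.normalization == "zscore":
            image = normalize_zscore(image)
        else:
            raise ValueError(f"unknown normalization {preset.normalization!r}")

        spacing = preset.target_spacing[mod]
        image_r = resample(image, spacing, mode="bspline")
        mask_r = resample_mask(lesion, spacing)
        if mask_r.n_voxels == 0:
            raise ValueError(
                f"patient {study.clinical.patient_id}: lesion mask empty after resampling"
            )

        derived: list[tuple[str, ImageVolume, int]] = [
            ("original", image_r, preset.n_bins_original[mod])
        ]
        bands = preset.wavelet_bands.get(mod, ())
        wanted_bands = tuple(
            b
            for b in bands
            if requested is None
            or any(img == f"wavelet-{b}" and m == mod_label for m, img, _ in requested)
        )
        if wanted_bands:
            decomposed = wavelet_decompose(image_r, wanted_bands)
            derived += [
                (f"wavelet-{b}", decomposed[b], preset.n_bins_wavelet[mod])
                for b in wanted_bands
            ]

        for image_name, img, n_bins in derived:
            fams = {}
            for fam in FEATURE_FAMILIES:
                if fam == "shape" and image_name != "original":
                    continue
                if requested is not None:
                    key = (mod_label, image_name, fam)
                    if key not in requested:
                        continue
                    fams[fam] = requested[key]
                else:
                    fams[fam] = None
            if not fams:
                continue
            needs_texture = any(f in _TEXTURE_FAMILIES for f in fams)
            q = (
                quantize_fbn(img, mask_r, n_bins).cropped()
                if needs_texture
                else None
            )
            for fam, feats in fams.items():
                try:
                    values = _compute_family(fam, q, img, mask_r, n_bins)
                except ValueError as exc:
                    msg = (
                        f"patient {study.clinical.patient_id}: {mod_label}-{image_name}"
                        f"_{fam} degenerate ({exc}); NaN sentinel"
                    )
                    warn.append(msg)
                    logger.warning(msg)
                    values = {f: np.nan for f in FEATURE_FAMILIES[fam]}
                for feat in FEATURE_FAMILIES[fam]:
                    if feats is None or feat in feats:
                        out[feature_name(mod_label, image_name, fam, feat)] = values[feat]
    return out


def mean_adc_2d_roi(adc: ImageVolume, lesion_mask: MaskVolume) -> float:
    """Mean ADC within the largest circular 2D ROI inscribed in the lesion.

    The axial slice of maximal lesion area is chosen; the disc centre and
    radius come from the in-plane Euclidean distance transform (ties broken
    toward the first maximal pixel in scan order), so the disc never exceeds
    the lesion margin.
    """
    if not adc.same_grid(lesion_mask):
        raise ValueError("mask must share the image grid")
    areas = lesion_mask.voxels.sum(axis=(1, 2))
    k = int(np.argmax(areas))
    if areas[k] == 0:
        raise ValueError("lesion mask is empty")
    sl = lesion_mask.voxels[k]
    sx, sy, _ = adc.spacing
    # pad so that beyond-image pixels count as background
    dist = ndimage.distance_transform_edt(np.pad(sl, 1), sampling=(sy, sx))[1:-1, 1:-1]
    cy, cx = np.unravel_index(int(np.argmax(dist)), dist.shape)
    radius = float(dist[cy, cx]) * (1.0 - 1e-9)
    yy, xx = np.indices(sl.shape)
    d = np.sqrt(((yy - cy) * sy) ** 2 + ((xx - cx) * sx) ** 2)
    disc = d <= radius
    return float(adc.voxels[k][disc].mean())
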